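"""Exception hierarchy for famseg."""


class FamsegError(Exception):
    """Base class for all famseg errors."""


class PedParseError(FamsegError):
    """A PED line could not be parsed; message names the line number."""


class PedValidationError(FamsegError):
    """A structurally invalid pedigree (unresolved parents, cycles, sex conflicts)."""


class PedigreeLoopError(FamsegError):
    """Marriage loop present; peeling is not applicable, use enumeration fallback."""


class MendelianInconsistencyError(FamsegError):
    """Marker genotypes are impossible under Mendelian transmission."""


class MonomorphicMarkerError(FamsegError):
    """Marker allele frequency of exactly 0 or 1; uninformative, exclude upstream."""


class InconsistentDominantModelError(FamsegError):
    """No dominant carrier assignment explains the affecteds; a phenocopy rate > 0 is needed."""


class SimulationError(FamsegError):
    """Infeasible simulation configuration or resampling non-convergence."""


class ConfigError(FamsegError):
    """Invalid run configuration."""
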