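"""Two-point parametric linkage: exact pedigree likelihoods and LOD scores.

The model is the classical two-locus likelihood used by LINKAGE/SUPERLINK
style programs.  Each individual carries an *ordered diplotype*: a paternal
and a maternal haplotype, each haplotype pairing a disease allele (D/d) with
a marker allele (alt/ref), giving 16 states per person.  The pedigree
likelihood at recombination fraction theta is

    L(theta) = sum over joint diplotypes of
        prod founders   P(diplotype)          (Hardy-Weinberg, linkage equil.)
      x prod non-founders P(diplotype | parents; theta)   (Mendelian + recomb.)
      x prod members    penetrance(phenotype | disease genotype)
      x prod members    1{marker genotype matches diplotype}  (missing -> 1)

and the two-point LOD is log10 L(theta) - log10 L(1/2).

Loop-free pedigrees are evaluated by Elston-Stewart peeling over nuclear
families (vectorised across variants and the theta grid); looped pedigrees
fall back to full enumeration over the diplotype factor graph.  Both code
paths are exposed so that each can serve as the other's cross-check.

The disease model is a dominant reduced-penetrance model by default:
disease allele frequency 0.01, penetrance 0.8 for carriers (one or two
copies), phenocopy rate 0 for non-carriers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import (
    InconsistentDominantModelError,
    MendelianInconsistencyError,
    MonomorphicMarkerError,
    PedigreeLoopError,
)
from .pedigree import Affection, Pedigree, peeling_order

__all__ = [
    "DiseaseModel",
    "MarkerModel",
    "LodCurve",
    "LinkageResult",
    "LodThresholds",
    "DEFAULT_THETA_GRID",
    "pedigree_likelihood",
    "enumeration_likelihood",
    "lod_curve",
    "cumulative_lod",
    "theoretical_max_lod",
    "parsimonious_dominant_carriers",
    "linkage_scan",
    "classify_lod",
]

# Haplotype index h = 2*d + a, with d = 1 for the disease allele and
# a = 1 for the marker alt allele; diplotype g = 4*h_paternal + h_maternal.
_HAP_D = np.array([0, 0, 1, 1])
_HAP_A = np.array([0, 1, 0, 1])
_G_PAT = np.repeat(np.arange(4), 4)
_G_MAT = np.tile(np.arange(4), 4)
N_DISEASE = _HAP_D[_G_PAT] + _HAP_D[_G_MAT]  # disease-allele count per diplotype
N_ALT = _HAP_A[_G_PAT] + _HAP_A[_G_MAT]  # marker alt count per diplotype

DEFAULT_THETA_GRID = tuple(np.round(np.linspace(0.0, 0.5, 51), 2))

_ENUMERATION_LETTERS = "abcdefghijklmnopqrst"
MAX_ENUMERATION_MEMBERS = 12


@dataclass(frozen=True)
class DiseaseModel:
    """Parametric single-locus disease model (dominant by default)."""

    disease_allele_freq: float = 0.01
    penetrance_DD: float = 0.8
    penetrance_Dd: float = 0.8
    phenocopy_dd: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "disease_allele_freq",
            "penetrance_DD",
            "penetrance_Dd",
            "phenocopy_dd",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.penetrance_Dd < self.phenocopy_dd:
            raise ValueError(
                "penetrance_Dd < phenocopy_dd is not a dominant model"
            )

    @property
    def penetrances(self) -> np.ndarray:
        """P(affected | 0, 1, 2 disease alleles)."""
        return np.array(
            [self.phenocopy_dd, self.penetrance_Dd, self.penetrance_DD]
        )


@dataclass(frozen=True)
class MarkerModel:
    """Founder allele frequency of the marker alt allele."""

    alt_allele_freq: float

    def __post_init__(self) -> None:
        if not 0.0 < self.alt_allele_freq < 1.0:
            raise MonomorphicMarkerError(
                f"marker alt allele frequency must lie strictly in (0, 1); "
                f"got {self.alt_allele_freq} (monomorphic markers are "
                "uninformative and should be excluded upstream)"
            )


@dataclass(frozen=True)
class LodThresholds:
    cosegregating: float = 1.0
    suggestive: float = 0.5
    exclusion: float = -2.0


def classify_lod(lod: float, thresholds: LodThresholds = LodThresholds()) -> str:
    if lod < thresholds.exclusion:
        return "excluded"
    if lod >= thresholds.cosegregating:
        return "cosegregating"
    if lod >= thresholds.suggestive:
        return "suggestive"
    return "neutral"


@dataclass
class LodCurve:
    """Per-family two-point LOD values over a theta grid."""

    family_id: str
    variant_key: tuple[str, int, str, str] | None
    theta_grid: np.ndarray
    lod_values: np.ndarray

    def __post_init__(self) -> None:
        self.theta_grid = np.asarray(self.theta_grid, dtype=float)
        self.lod_values = np.asarray(self.lod_values, dtype=float)
        i_half = _index_of_theta(self.theta_grid, 0.5)
        if not abs(self.lod_values[i_half]) <= 1e-9:
            raise ValueError("LOD at theta=0.5 must be 0")

    @property
    def max_lod(self) -> float:
        return float(np.max(self.lod_values))

    @property
    def theta_at_max(self) -> float:
        # ties broken toward smaller theta; grid is ascending
        return float(self.theta_grid[int(np.argmax(self.lod_values))])

    @property
    def lod_at_zero(self) -> float:
        return float(self.lod_values[_index_of_theta(self.theta_grid, 0.0)])


@dataclass
class LinkageResult:
    """Cumulative (cross-family) linkage evidence for one variant."""

    variant_key: tuple[str, int, str, str] | None
    family_max_lod: dict[str, float]
    family_theta_at_max: dict[str, float]
    family_lod_at_zero: dict[str, float]
    cumulative_lod: float
    cumulative_theta: float
    cumulative_lod_at_zero: float
    classification: str
    policy: str = "sum-then-max"


def _index_of_theta(grid: np.ndarray, theta: float) -> int:
    idx = np.nonzero(np.isclose(grid, theta, atol=1e-12))[0]
    if idx.size == 0:
        raise ValueError(f"theta grid must include {theta}")
    return int(idx[0])


# -- model factor construction ----------------------------------------------


def _gamete_probs(thetas: np.ndarray) -> np.ndarray:
    """(n_theta, 16, 4): P(transmitted haplotype | parent diplotype, theta)."""
    t = np.asarray(thetas, dtype=float)
    G = np.zeros((t.size, 16, 4))
    for g in range(16):
        hp, hm = divmod(g, 4)
        rec1 = 2 * _HAP_D[hp] + _HAP_A[hm]
        rec2 = 2 * _HAP_D[hm] + _HAP_A[hp]
        G[:, g, hp] += (1.0 - t) / 2.0
        G[:, g, hm] += (1.0 - t) / 2.0
        G[:, g, rec1] += t / 2.0
        G[:, g, rec2] += t / 2.0
    return G


def _transmission(thetas: np.ndarray) -> np.ndarray:
    """(n_theta, 16 child, 16 father, 16 mother) transmission probabilities."""
    G = _gamete_probs(thetas)
    A = G[:, :, _G_PAT]  # (t, father, child): father transmits child's paternal hap
    B = G[:, :, _G_MAT]  # (t, mother, child)
    return A.transpose(0, 2, 1)[:, :, :, None] * B.transpose(0, 2, 1)[:, :, None, :]


def _founder_prior(q: float, marker_freqs: np.ndarray) -> np.ndarray:
    """(n_var, 16) founder diplotype prior under HWE + linkage equilibrium."""
    p = np.atleast_1d(np.asarray(marker_freqs, dtype=float))
    hap = (q ** _HAP_D * (1.0 - q) ** (1 - _HAP_D))[None, :] * np.where(
        _HAP_A[None, :] == 1, p[:, None], 1.0 - p[:, None]
    )
    return hap[:, _G_PAT] * hap[:, _G_MAT]


def _phenotype_factor(affection: Affection, disease: DiseaseModel) -> np.ndarray:
    pen = disease.penetrances[N_DISEASE]
    if affection is Affection.AFFECTED:
        return pen
    if affection is Affection.UNAFFECTED:
        return 1.0 - pen
    return np.ones(16)


def _marker_factor(alt_counts: np.ndarray) -> np.ndarray:
    """(n_var, 16) marker-compatibility indicators; -1 means missing."""
    counts = np.asarray(alt_counts)
    out = np.ones((counts.size, 16))
    obs = counts >= 0
    out[obs] = (N_ALT[None, :] == counts[obs, None]).astype(float)
    return out


def _member_evidence(
    ped: Pedigree,
    geno: np.ndarray,
    disease: DiseaseModel,
    marker_freqs: np.ndarray,
    state_masks: Mapping[str, np.ndarray] | None,
) -> dict[str, np.ndarray]:
    """(n_var, 16) per-member factors: penetrance x marker x prior (founders)."""
    prior = _founder_prior(disease.disease_allele_freq, marker_freqs)
    evidence: dict[str, np.ndarray] = {}
    for j, m in enumerate(ped.members):
        e = _phenotype_factor(m.affection, disease)[None, :] * _marker_factor(
            geno[:, j]
        )
        if state_masks is not None and m.individual_id in state_masks:
            e = e * np.asarray(state_masks[m.individual_id], dtype=float)[None, :]
        if m.is_founder:
            e = e * prior
        evidence[m.individual_id] = e
    return evidence


# -- peeling engine ----------------------------------------------------------


def _family_log10_likelihood(
    ped: Pedigree,
    geno: np.ndarray,
    disease: DiseaseModel,
    marker_freqs: np.ndarray,
    thetas: Sequence[float],
    state_masks: Mapping[str, np.ndarray] | None = None,
) -> np.ndarray:
    """log10 pedigree likelihood, shape (n_var, n_theta); -inf when impossible.

    ``geno`` holds marker alt-allele counts (-1 = missing) with one column per
    pedigree member, in member order.  Vectorised across variants and thetas.
    """
    geno = np.asarray(geno)
    if geno.ndim != 2 or geno.shape[1] != len(ped):
        raise ValueError("genotype matrix must be (n_variants, n_members)")
    thetas = np.asarray(thetas, dtype=float)
    if np.any((thetas < 0) | (thetas > 0.5)):
        raise ValueError("theta must lie in [0, 0.5]")
    n_var, n_t = geno.shape[0], thetas.size

    if ped.loops_present:
        return _enumeration_grid(ped, geno, disease, marker_freqs, thetas, state_masks)

    T = _transmission(thetas)
    evidence = _member_evidence(ped, geno, disease, marker_freqs, state_masks)
    psi = {
        mid: np.broadcast_to(e[:, None, :], (n_var, n_t, 16)).copy()
        for mid, e in evidence.items()
    }
    log10_scale = np.zeros((n_var, n_t))
    units = peeling_order(ped)
    in_unit: set[str] = set()
    for u in units:
        in_unit.update(u.member_ids)

    def _accumulate(values: np.ndarray) -> None:
        with np.errstate(divide="ignore"):
            np.add(log10_scale, np.log10(values), out=log10_scale)

    for unit in units:
        couple = np.ones((n_var, n_t, 16, 16))
        for cid in unit.children:
            if cid == unit.pivot:
                continue
            couple *= np.einsum("tcfm,vtc->vtfm", T, psi[cid])
        if unit.pivot == unit.father_id:
            msg = np.einsum("vtm,vtfm->vtf", psi[unit.mother_id], couple)
            target = unit.father_id
        elif unit.pivot == unit.mother_id:
            msg = np.einsum("vtf,vtfm->vtm", psi[unit.father_id], couple)
            target = unit.mother_id
        elif unit.pivot is not None:
            joint = (
                psi[unit.father_id][:, :, :, None]
                * psi[unit.mother_id][:, :, None, :]
                * couple
            )
            msg = np.einsum("vtfm,tcfm->vtc", joint, T)
            target = unit.pivot
        else:
            joint = (
                psi[unit.father_id][:, :, :, None]
                * psi[unit.mother_id][:, :, None, :]
                * couple
            )
            _accumulate(joint.sum(axis=(2, 3)))
            continue
        norm = msg.sum(axis=-1, keepdims=True)
        _accumulate(norm[..., 0])
        safe = np.where(norm > 0.0, norm, 1.0)
        psi[target] = psi[target] * (msg / safe)

    for m in ped.members:  # members outside any nuclear unit (e.g. singletons)
        if m.individual_id not in in_unit:
            _accumulate(psi[m.individual_id].sum(axis=-1))
    return log10_scale


# -- enumeration (oracle and loop fallback) ----------------------------------


def _enumeration_scalar(
    ped: Pedigree,
    geno_row: np.ndarray,
    disease: DiseaseModel,
    marker_freq: float,
    theta: float,
    state_masks: Mapping[str, np.ndarray] | None = None,
) -> float:
    """log10 likelihood for one variant at one theta by contracting the full
    diplotype factor graph (one 16-state axis per member)."""
    n = len(ped)
    if n > MAX_ENUMERATION_MEMBERS:
        raise PedigreeLoopError(
            f"family {ped.family_id}: enumeration supports at most "
            f"{MAX_ENUMERATION_MEMBERS} members ({n} given); break the loop "
            "or use a loop-free pedigree"
        )
    letters = {m.individual_id: _ENUMERATION_LETTERS[j] for j, m in enumerate(ped.members)}
    evidence = _member_evidence(
        ped, geno_row[None, :], disease, np.array([marker_freq]), state_masks
    )
    T1 = _transmission(np.array([theta]))[0]
    subs: list[str] = []
    ops: list[np.ndarray] = []
    for m in ped.members:
        subs.append(letters[m.individual_id])
        ops.append(evidence[m.individual_id][0])
        if not m.is_founder:
            subs.append(
                letters[m.individual_id] + letters[m.father_id] + letters[m.mother_id]
            )
            ops.append(T1)
    total = float(np.einsum(",".join(subs) + "->", *ops, optimize="greedy"))
    return math.log10(total) if total > 0.0 else -math.inf


def _enumeration_grid(ped, geno, disease, marker_freqs, thetas, state_masks):
    marker_freqs = np.broadcast_to(
        np.atleast_1d(np.asarray(marker_freqs, dtype=float)), (geno.shape[0],)
    )
    out = np.empty((geno.shape[0], thetas.size))
    for v in range(geno.shape[0]):
        for ti, theta in enumerate(thetas):
            out[v, ti] = _enumeration_scalar(
                ped, geno[v], disease, marker_freqs[v], theta, state_masks
            )
    return out


def _geno_matrix(ped: Pedigree, genotypes: Mapping[str, int | None]) -> np.ndarray:
    unknown = set(genotypes) - set(ped.member_ids)
    if unknown:
        raise ValueError(
            f"genotyped individuals absent from family {ped.family_id}: "
            f"{sorted(unknown)}"
        )
    row = np.full((1, len(ped)), -1, dtype=int)
    for j, m in enumerate(ped.members):
        g = genotypes.get(m.individual_id)
        if g is not None:
            if g not in (0, 1, 2):
                raise ValueError(f"alt allele count must be 0/1/2, got {g!r}")
            row[0, j] = g
    return row


def pedigree_likelihood(
    p: Pedigree,
    genotypes: Mapping[str, int | None],
    d: DiseaseModel,
    m: MarkerModel,
    theta: float,
) -> float:
    """log10 two-locus pedigree likelihood at one recombination fraction.

    ``genotypes`` maps individual id to marker alt-allele count (``None`` or
    absent = untyped).  Returns ``-inf`` for Mendelian-impossible marker
    configurations.  Evaluated by peeling for loop-free pedigrees, by full
    enumeration otherwise.
    """
    if not 0.0 <= theta <= 0.5:
        raise ValueError(f"theta must lie in [0, 0.5], got {theta}")
    row = _geno_matrix(p, genotypes)
    ll = _family_log10_likelihood(
        p, row, d, np.array([m.alt_allele_freq]), np.array([theta])
    )
    return float(ll[0, 0])


def enumeration_likelihood(
    p: Pedigree,
    genotypes: Mapping[str, int | None],
    d: DiseaseModel,
    m: MarkerModel,
    theta: float,
) -> float:
    """log10 likelihood by full diplotype enumeration (peeling cross-check)."""
    if not 0.0 <= theta <= 0.5:
        raise ValueError(f"theta must lie in [0, 0.5], got {theta}")
    row = _geno_matrix(p, genotypes)
    return _enumeration_scalar(p, row[0], d, m.alt_allele_freq, theta)


# -- LOD curves ---------------------------------------------------------------


def lod_curve(
    p: Pedigree,
    genotypes: Mapping[str, int | None],
    d: DiseaseModel,
    m: MarkerModel,
    theta_grid: Sequence[float] = DEFAULT_THETA_GRID,
    variant_key: tuple[str, int, str, str] | None = None,
) -> LodCurve:
    """Two-point LOD curve: lod(theta) = log10 L(theta) - log10 L(1/2)."""
    grid = np.asarray(theta_grid, dtype=float)
    _index_of_theta(grid, 0.0)
    i_half = _index_of_theta(grid, 0.5)
    row = _geno_matrix(p, genotypes)
    ll = _family_log10_likelihood(p, row, d, np.array([m.alt_allele_freq]), grid)[0]
    if not np.isfinite(ll[i_half]):
        raise MendelianInconsistencyError(
            f"family {p.family_id}: marker genotypes are Mendelian-impossible"
        )
    return LodCurve(p.family_id, variant_key, grid, ll - ll[i_half])


def cumulative_lod(
    curves: Sequence[LodCurve],
    policy: str = "sum-then-max",
    thresholds: LodThresholds = LodThresholds(),
) -> LinkageResult:
    """Combine per-family curves for one variant into a cumulative LOD.

    Default policy sums the per-theta curves across families and then
    maximises over theta (summing per-family maxima attained at different
    theta would overstate the evidence); ``sum-of-maxima`` is also offered.
    """
    if not curves:
        raise ValueError("at least one family curve is required")
    keys = {c.variant_key for c in curves}
    if len(keys) != 1:
        raise ValueError(f"mismatched variant keys across curves: {keys}")
    grid = curves[0].theta_grid
    for c in curves[1:]:
        if not np.array_equal(c.theta_grid, grid):
            raise ValueError("all curves must share one theta grid")
    summed = np.sum([c.lod_values for c in curves], axis=0)
    i_zero = _index_of_theta(grid, 0.0)
    if policy == "sum-then-max":
        cum = float(np.max(summed))
        cum_theta = float(grid[int(np.argmax(summed))])
    elif policy == "sum-of-maxima":
        cum = float(sum(c.max_lod for c in curves))
        cum_theta = math.nan
    else:
        raise ValueError(f"unknown cumulative policy {policy!r}")
    cum_zero = float(summed[i_zero])
    # exclusion is judged at tight linkage (theta = 0): the maximised LOD is
    # never negative because the curve is pinned to 0 at theta = 1/2
    if cum_zero < thresholds.exclusion:
        classification = "excluded"
    else:
        classification = classify_lod(cum, thresholds)
    return LinkageResult(
        variant_key=curves[0].variant_key,
        family_max_lod={c.family_id: c.max_lod for c in curves},
        family_theta_at_max={c.family_id: c.theta_at_max for c in curves},
        family_lod_at_zero={c.family_id: c.lod_at_zero for c in curves},
        cumulative_lod=cum,
        cumulative_theta=cum_theta,
        cumulative_lod_at_zero=cum_zero,
        classification=classification,
        policy=policy,
    )


# -- theoretical maximum -----------------------------------------------------


def parsimonious_dominant_carriers(p: Pedigree, d: DiseaseModel) -> set[str]:
    """Greedy minimal dominant carrier assignment consistent with affecteds.

    All affected members carry; every carrier non-founder is closed under the
    rule that one parent must carry, preferring affected, then unknown, then
    unaffected parents (unaffected parents are ruled out at full penetrance).
    """
    affected_ids = {m.individual_id for m in p.affected}
    if not affected_ids:
        raise ValueError(f"family {p.family_id}: no affected members")

    aff_desc_count: dict[str, int] = {}

    def _affected_descendants(ind: str) -> int:
        if ind not in aff_desc_count:
            total = 0
            for child in p.children_of(ind):
                total += (
                    child.affection is Affection.AFFECTED
                ) + _affected_descendants(child.individual_id)
            aff_desc_count[ind] = total
        return aff_desc_count[ind]

    carriers = set(affected_ids)
    queue = sorted(carriers, key=p.member_ids.index)
    full_penetrance = d.penetrance_Dd >= 1.0
    while queue:
        ind = queue.pop(0)
        m = p.member(ind)
        if m.is_founder:
            continue
        if m.father_id in carriers or m.mother_id in carriers:
            continue
        candidates = []
        for pid in (m.father_id, m.mother_id):
            parent = p.member(pid)
            if full_penetrance and parent.affection is Affection.UNAFFECTED:
                continue
            rank = {
                Affection.AFFECTED: 0,
                Affection.UNKNOWN: 1,
                Affection.UNAFFECTED: 2,
            }[parent.affection]
            candidates.append((rank, -_affected_descendants(pid), pid != m.father_id, pid))
        if not candidates:
            raise InconsistentDominantModelError(
                f"family {p.family_id}: affected member {ind} has no admissible "
                "carrier parent under full penetrance with zero phenocopy; "
                "set phenocopy_dd > 0"
            )
        chosen = min(candidates)[-1]
        carriers.add(chosen)
        queue.append(chosen)
    return carriers


def theoretical_max_lod(
    p: Pedigree,
    d: DiseaseModel,
    theta_grid: Sequence[float] = DEFAULT_THETA_GRID,
) -> float:
    """Fully-informative co-segregation bound for one family.

    Constructs a perfectly co-segregating private marker (every carrier of the
    parsimonious dominant assignment heterozygous, everyone else homozygous
    reference) and evaluates the LOD with founder diplotype phase clamped, so
    each scorable meiosis from a carrier parent contributes log10 2 at
    theta = 0.  This is the phase-known bound an ideal fully informative
    marker could reach; real biallelic data (phase unknown) can only do worse.
    """
    carriers = parsimonious_dominant_carriers(p, d)
    grid = np.asarray(theta_grid, dtype=float)
    i_half = _index_of_theta(grid, 0.5)
    _index_of_theta(grid, 0.0)
    masks: dict[str, np.ndarray] = {}
    carrier_founder_state = 4 * 3 + 0  # ((D, alt), (d, ref))
    for m in p.members:
        mask = np.zeros(16)
        if m.individual_id in carriers:
            if m.is_founder:
                mask[carrier_founder_state] = 1.0
            else:
                mask[(N_DISEASE == 1) & (N_ALT == 1)] = 1.0
        else:
            mask[0] = 1.0  # ((d, ref), (d, ref))
        masks[m.individual_id] = mask
    geno = np.full((1, len(p)), -1, dtype=int)
    ll = _family_log10_likelihood(
        p, geno, d, np.array([0.5]), grid, state_masks=masks
    )[0]
    return float(np.max(ll - ll[i_half]))


# -- variant-level scan -------------------------------------------------------


@dataclass
class ScanOutput:
    results: list[LinkageResult]
    skipped: list[dict]

    def top(self, k: int = 10) -> list[LinkageResult]:
        return sorted(self.results, key=lambda r: -r.cumulative_lod)[:k]


def founder_marker_freq(record, pedigrees: Sequence[Pedigree]) -> float:
    """Pseudocounted alt frequency among founder calls, clamped to [1e-3, 1-1e-3]."""
    alt = 0
    called = 0
    for ped in pedigrees:
        for m in ped.founders():
            call = record.calls.get(m.individual_id)
            if call is not None and call.allele_count_alt is not None:
                alt += call.allele_count_alt
                called += 1
    freq = (alt + 1.0) / (2.0 * called + 2.0)
    return float(min(max(freq, 0.001), 0.999))


def _marker_freq_for(record, pedigrees, source: str, annotations) -> float:
    if source == "panel" and annotations is not None:
        ann = annotations.get(record.key) if hasattr(annotations, "get") else None
        if ann is not None and ann.panel_freqs:
            freq = float(np.mean(list(ann.panel_freqs.values())))
            return float(min(max(freq, 0.001), 0.999))
    elif source not in ("panel", "founder"):
        raise ValueError(f"unknown marker frequency source {source!r}")
    return founder_marker_freq(record, pedigrees)


def linkage_scan(
    records: Iterable,
    pedigrees: Sequence[Pedigree],
    d: DiseaseModel = DiseaseModel(),
    theta_grid: Sequence[float] = DEFAULT_THETA_GRID,
    marker_freq_source: str = "founder",
    annotations=None,
    policy: str = "sum-then-max",
    thresholds: LodThresholds = LodThresholds(),
) -> ScanOutput:
    """Two-point LOD scan of QC-passed variant records across families.

    Returns one :class:`LinkageResult` per Mendelian-consistent record plus a
    skip list naming each inconsistent record and the family that failed.
    Deterministic given inputs; vectorised across variants and thetas.
    """
    records = list(records)
    grid = np.asarray(theta_grid, dtype=float)
    i_half = _index_of_theta(grid, 0.5)
    i_zero = _index_of_theta(grid, 0.0)
    if not records:
        return ScanOutput([], [])
    freqs = np.array(
        [_marker_freq_for(r, pedigrees, marker_freq_source, annotations) for r in records]
    )
    per_family_lods: dict[str, np.ndarray] = {}
    for ped in pedigrees:
        geno = np.full((len(records), len(ped)), -1, dtype=int)
        for v, rec in enumerate(records):
            for j, mid in enumerate(ped.member_ids):
                call = rec.calls.get(mid)
                if call is not None and call.allele_count_alt is not None:
                    geno[v, j] = call.allele_count_alt
        ll = _family_log10_likelihood(ped, geno, d, freqs, grid)
        per_family_lods[ped.family_id] = ll - ll[:, i_half : i_half + 1]

    results: list[LinkageResult] = []
    skipped: list[dict] = []
    for v, rec in enumerate(records):
        bad = [
            fid
            for fid, lods in per_family_lods.items()
            if not np.isfinite(lods[v, i_half])
        ]
        if bad:
            skipped.append(
                {"variant_key": rec.key, "reason": "mendelian_inconsistent",
                 "families": bad}
            )
            continue
        curves = [
            LodCurve(fid, rec.key, grid, per_family_lods[fid][v])
            for fid in per_family_lods
        ]
        results.append(cumulative_lod(curves, policy=policy, thresholds=thresholds))
    return ScanOutput(results, skipped)
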