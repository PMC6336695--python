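"""Synthetic multiplex-family cohort generator (PED + VCF + annotations).

The generator inverts the analysis model: pedigrees are built
generation-by-generation to target the study profile (four multiplex
families of 18/16/10/8 members, about a third affected, three of the four
bilineal), a dominant causal variant is gene-dropped through the founders
(Hardy-Weinberg draws, Mendelian transmission, penetrance-sampled
phenotypes, one proband per family resampled until every family has an
affected member), and a background of rare and common variants is dropped
independently per family.  Sequencing depth/quality, missingness and
genotype errors are layered on, and a configurable number of sites
deliberately violate each QC rule.

Ground-truth labels are carried in a truth table and are exact by
construction: background sites are conditioned (bounded re-drops, then
frequency halving) to stay under the alt-carrier artifact threshold,
blanked+missing calls on non-planted sites are capped below the call-rate
threshold, panel-frequency jitter never crosses the 1% rare/common boundary,
deleteriousness scores avoid the CADD-20 boundary, and proband carrier
status is recorded from the genotypes as emitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import SimulationError
from .linkage import DiseaseModel
from .pedigree import Affection, Pedigree, PedigreeMember, Sex, write_ped
from .qc import QcThresholds
from .vcfio import AnnotationRecord, GenotypeCall, VariantRecord, write_annotations, write_vcf

__all__ = [
    "FamilySpec",
    "CausalVariantSpec",
    "BackgroundSpec",
    "PlantedQcSpec",
    "SequencingSpec",
    "SimulationConfig",
    "SimulatedCohort",
    "default_study_families",
    "build_pedigrees",
    "gene_drop",
    "emit_cohort",
    "simulate_cohort",
]


@dataclass(frozen=True)
class FamilySpec:
    size: int
    n_affected_target: int
    generations: int = 3
    bilineal: bool = False

    def __post_init__(self) -> None:
        if self.generations < 2:
            raise SimulationError("families need at least 2 generations")
        if self.n_affected_target > self.size:
            raise SimulationError("n_affected_target cannot exceed family size")


@dataclass(frozen=True)
class CausalVariantSpec:
    """The planted disease variant; common and benign-scored by default,
    matching the profile of variants that co-segregate in practice.

    With ``cosegregating`` (the default) the variant enters each family only
    through its disease-founding line(s): those founders are heterozygous
    carriers and every other founder is homozygous reference, so the variant
    tracks the disease lines within families while ``allele_freq`` still
    sets its population (panel) frequency.  Set ``cosegregating=False`` for
    plain Hardy-Weinberg founder draws; note that a genuinely common variant
    drawn that way often saturates an ascertained family (most founders
    carry) and is then uninformative for linkage.
    """

    allele_freq: float = 0.2
    cadd_phred: float = 5.0
    consequence: str = "intronic"
    chrom: str = "11"
    cosegregating: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.allele_freq < 1.0:
            raise SimulationError("causal allele_freq must be in (0, 1)")


@dataclass(frozen=True)
class BackgroundSpec:
    n_rare: int = 250
    rare_freq_range: tuple[float, float] = (1e-5, 0.01)
    n_common: int = 250
    common_freq_range: tuple[float, float] = (0.01, 0.5)
    p_deleterious_score: float = 0.05


@dataclass(frozen=True)
class PlantedQcSpec:
    n_indel: int = 50
    n_low_call_rate: int = 30
    n_excess_alt_carriers: int = 20
    n_non_autosome: int = 10


@dataclass(frozen=True)
class SequencingSpec:
    mean_depth: float = 60.0
    depth_dispersion: float = 8.0  # gamma shape of the gamma-Poisson depth model
    gq_mean: float = 80.0
    gq_sd: float = 15.0
    missing_rate: float = 0.02
    genotype_error_rate: float = 0.001


def noise_free_sequencing() -> SequencingSpec:
    """Sequencing layer that never blanks a call: tightly concentrated depth
    around 60X, uniformly high genotype quality, no missingness or errors."""
    return SequencingSpec(
        mean_depth=60.0,
        depth_dispersion=1e6,
        gq_mean=80.0,
        gq_sd=0.01,
        missing_rate=0.0,
        genotype_error_rate=0.0,
    )


def default_study_families() -> tuple[FamilySpec, ...]:
    """Four multiplex families, 52 members, 17 affected at the per-family
    rates of the cohort profile; three of four bilineal."""
    return (
        FamilySpec(size=18, n_affected_target=4, generations=3, bilineal=True),
        FamilySpec(size=16, n_affected_target=5, generations=3, bilineal=True),
        FamilySpec(size=10, n_affected_target=5, generations=3, bilineal=True),
        FamilySpec(size=8, n_affected_target=3, generations=3, bilineal=False),
    )


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    family_specs: tuple[FamilySpec, ...] = field(default_factory=default_study_families)
    disease: DiseaseModel = field(default_factory=DiseaseModel)
    causal: CausalVariantSpec = field(default_factory=CausalVariantSpec)
    background: BackgroundSpec = field(default_factory=BackgroundSpec)
    planted: PlantedQcSpec = field(default_factory=PlantedQcSpec)
    sequencing: SequencingSpec = field(default_factory=SequencingSpec)
    panels: tuple[str, ...] = ("POP_A", "POP_B")
    table_matching: bool = False
    max_resample: int = 1000

    def to_dict(self) -> dict:
        return asdict(self)


# -- pedigree construction ---------------------------------------------------


class _FamilyBuilder:
    def __init__(self, family_id: str, rng: np.random.Generator):
        self.family_id = family_id
        self.rng = rng
        self.rows: list[dict] = []
        self.gen: dict[str, int] = {}
        self.partnered: set[str] = set()
        self.couples: list[tuple[str, str]] = []

    def add(self, gen: int, father=None, mother=None, sex: Sex | None = None) -> str:
        iid = f"{self.family_id}_I{len(self.rows) + 1:02d}"
        if sex is None:
            sex = Sex.MALE if self.rng.random() < 0.5 else Sex.FEMALE
        self.rows.append(
            {"id": iid, "father": father, "mother": mother, "sex": sex}
        )
        self.gen[iid] = gen
        return iid

    def couple(self, a: str, b: str) -> tuple[str, str]:
        sex_a = next(r["sex"] for r in self.rows if r["id"] == a)
        father, mother = (a, b) if sex_a is Sex.MALE else (b, a)
        self.partnered.update((a, b))
        self.couples.append((father, mother))
        return father, mother

    def child_of(self, father: str, mother: str, gen: int) -> str:
        return self.add(gen, father=father, mother=mother)


def _build_family(
    family_id: str, spec: FamilySpec, rng: np.random.Generator
) -> tuple[Pedigree, dict]:
    G = spec.generations
    min_size = 2 + (G - 1) + max(G - 2, 0) + (2 if spec.bilineal else 0)
    if spec.size < min_size:
        raise SimulationError(
            f"family {family_id}: size {spec.size} below minimum {min_size} for "
            f"{G} generations (bilineal={spec.bilineal})"
        )
    b = _FamilyBuilder(family_id, rng)
    f0 = b.add(1, sex=Sex.MALE)
    m0 = b.add(1, sex=Sex.FEMALE)
    b.couple(f0, m0)
    meta = {"line_a_founder": f0, "line_b_founder": None}
    second_couple = None
    if spec.bilineal:
        f1 = b.add(1, sex=Sex.MALE)
        m1 = b.add(1, sex=Sex.FEMALE)
        b.couple(f1, m1)
        second_couple = (f1, m1)
        meta["line_b_founder"] = f1
    cur = (f0, m0)
    for gen in range(2, G + 1):
        child = b.child_of(cur[0], cur[1], gen)
        if gen < G:
            if spec.bilineal and gen == 2:
                spouse = b.child_of(second_couple[0], second_couple[1], 2)
                # force opposite sexes so the couple is well formed
                for r in b.rows:
                    if r["id"] == spouse:
                        r["sex"] = (
                            Sex.FEMALE
                            if b.gen[child] and _sex_of(b, child) is Sex.MALE
                            else Sex.MALE
                        )
            else:
                spouse = b.add(
                    gen,
                    sex=Sex.FEMALE if _sex_of(b, child) is Sex.MALE else Sex.MALE,
                )
            cur = b.couple(child, spouse)
    while len(b.rows) < spec.size:
        budget = spec.size - len(b.rows)
        expandable = [
            iid
            for iid in b.gen
            if iid not in b.partnered and b.gen[iid] < G and _has_parents(b, iid)
        ]
        if budget >= 3 and expandable and rng.random() < 0.3:
            iid = expandable[int(rng.integers(len(expandable)))]
            spouse = b.add(
                b.gen[iid],
                sex=Sex.FEMALE if _sex_of(b, iid) is Sex.MALE else Sex.MALE,
            )
            fa, mo = b.couple(iid, spouse)
            b.child_of(fa, mo, b.gen[iid] + 1)
        else:
            eligible = [
                (fa, mo)
                for fa, mo in b.couples
                if max(b.gen[fa], b.gen[mo]) + 1 <= G
            ]
            fa, mo = eligible[int(rng.integers(len(eligible)))]
            b.child_of(fa, mo, max(b.gen[fa], b.gen[mo]) + 1)
    members = [
        PedigreeMember(
            family_id=family_id,
            individual_id=r["id"],
            father_id=r["father"],
            mother_id=r["mother"],
            sex=r["sex"],
            affection=Affection.UNKNOWN,
        )
        for r in b.rows
    ]
    return Pedigree(family_id, members), meta


def _sex_of(b: _FamilyBuilder, iid: str) -> Sex:
    return next(r["sex"] for r in b.rows if r["id"] == iid)


def _has_parents(b: _FamilyBuilder, iid: str) -> bool:
    return next(r["father"] for r in b.rows if r["id"] == iid) is not None


def build_pedigrees(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[list[Pedigree], dict[str, dict]]:
    """Build one pedigree per family spec; returns (pedigrees, line metadata)."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    pedigrees, meta = [], {}
    for i, spec in enumerate(cfg.family_specs, start=1):
        fid = f"F{i}"
        ped, m = _build_family(fid, spec, rng)
        pedigrees.append(ped)
        meta[fid] = m
    return pedigrees, meta


# -- gene dropping ------------------------------------------------------------


def _topological_members(ped: Pedigree) -> list[PedigreeMember]:
    done: set[str] = set()
    out: list[PedigreeMember] = []
    pending = list(ped.members)
    while pending:
        progressed = False
        rest = []
        for m in pending:
            if m.is_founder or (m.father_id in done and m.mother_id in done):
                out.append(m)
                done.add(m.individual_id)
                progressed = True
            else:
                rest.append(m)
        if not progressed:  # pragma: no cover - guarded by Pedigree validation
            raise SimulationError("pedigree is not ancestrally ordered")
        pending = rest
    return out


def _drop_one(
    ped: Pedigree,
    freq: float,
    rng: np.random.Generator,
    force_carriers: Sequence[str] = (),
    founders_only_forced: bool = False,
) -> dict[str, tuple[int, int]]:
    """Drop a biallelic variant through one family; returns allele pairs.

    ``force_carriers`` founders are guaranteed to carry; with
    ``founders_only_forced`` they are the *only* founder carriers (single
    heterozygous copy each), pinning the variant's entry into the family.
    """
    haps: dict[str, tuple[int, int]] = {}
    for m in _topological_members(ped):
        if m.is_founder:
            if founders_only_forced:
                pair = (1, 0) if m.individual_id in force_carriers else (0, 0)
            else:
                pair = (int(rng.random() < freq), int(rng.random() < freq))
                if m.individual_id in force_carriers and sum(pair) == 0:
                    # conditional Hardy-Weinberg draw given carrier status
                    p_hom = freq * freq / (1.0 - (1.0 - freq) ** 2)
                    pair = (1, 1) if rng.random() < p_hom else ((1, 0) if rng.random() < 0.5 else (0, 1))
            haps[m.individual_id] = pair
        else:
            fa = haps[m.father_id]
            mo = haps[m.mother_id]
            haps[m.individual_id] = (
                fa[int(rng.integers(2))],
                mo[int(rng.integers(2))],
            )
    return haps


@dataclass
class GeneDropResult:
    pedigrees: list[Pedigree]
    carriers: dict[str, int]  # individual -> causal alt allele count
    probands: dict[str, str]  # family -> proband individual


def gene_drop(
    pedigrees: Sequence[Pedigree],
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
    line_meta: dict[str, dict] | None = None,
) -> GeneDropResult:
    """Assign causal genotypes and penetrance-sampled phenotypes.

    Founder genotypes are Hardy-Weinberg draws at the causal allele
    frequency (bilineal families force one carrier founder per line of
    descent); affection is sampled from the disease model and the whole
    family is re-dropped until it has at least one affected member.  In
    table-matching mode the sampled affection is replaced by exactly the
    per-family target count, assigning carriers first.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    pen = cfg.disease.penetrances
    out_peds: list[Pedigree] = []
    carriers: dict[str, int] = {}
    probands: dict[str, str] = {}
    for ped, spec in zip(pedigrees, cfg.family_specs):
        force: list[str] = []
        if line_meta and ped.family_id in line_meta:
            m = line_meta[ped.family_id]
            if cfg.causal.cosegregating:
                force = [m["line_a_founder"]]
                if spec.bilineal and m["line_b_founder"]:
                    force.append(m["line_b_founder"])
            elif spec.bilineal:
                # plain Hardy-Weinberg drop, but bilineal families still
                # introduce the allele through both lines of descent
                force = [x for x in (m["line_a_founder"], m["line_b_founder"]) if x]
        elif cfg.causal.cosegregating:
            force = [ped.founders()[0].individual_id]
        # penetrance-driven resampling until the family reaches its affected
        # target, emulating the ascertainment that selected these multiplex
        # families (counts are targeted, not forced: draws above target pass)
        need = max(1, spec.n_affected_target)
        for _ in range(cfg.max_resample):
            haps = _drop_one(
                ped,
                cfg.causal.allele_freq,
                rng,
                force_carriers=force,
                founders_only_forced=cfg.causal.cosegregating,
            )
            counts = {iid: sum(pair) for iid, pair in haps.items()}
            affected = {
                iid for iid, n in counts.items() if rng.random() < pen[n]
            }
            if len(affected) >= need:
                break
        else:
            raise SimulationError(
                f"family {ped.family_id}: affected count never reached "
                f"{need} in {cfg.max_resample} re-drops; infeasible "
                f"configuration (freq={cfg.causal.allele_freq}, "
                f"penetrances={list(pen)})"
            )
        if cfg.table_matching:
            order = list(rng.permutation(ped.member_ids))
            carrier_first = sorted(order, key=lambda i: -counts[i])
            affected = set(carrier_first[: spec.n_affected_target])
        aff_list = [i for i in ped.member_ids if i in affected]
        proband = aff_list[int(rng.integers(len(aff_list)))]
        members = [
            replace(
                m,
                affection=(
                    Affection.AFFECTED
                    if m.individual_id in affected
                    else Affection.UNAFFECTED
                ),
                is_proband=(m.individual_id == proband),
            )
            for m in ped.members
        ]
        out_peds.append(Pedigree(ped.family_id, members))
        carriers.update(counts)
        probands[ped.family_id] = proband
    return GeneDropResult(out_peds, carriers, probands)


# -- cohort emission ----------------------------------------------------------

_BASES = ("A", "C", "G", "T")


@dataclass
class SimulatedCohort:
    out_dir: Path
    vcf: Path
    ped: Path
    annotations: Path
    truth: Path
    probands_file: Path
    config_file: Path
    pedigrees: list[Pedigree]
    probands: dict[str, str]
    truth_table: pd.DataFrame


def _draw_site(rng, chrom_pool, used: set) -> tuple[str, int]:
    while True:
        chrom = chrom_pool[int(rng.integers(len(chrom_pool)))]
        pos = int(rng.integers(100_000, 50_000_000))
        if (chrom, pos) not in used:
            used.add((chrom, pos))
            return chrom, pos


def _drop_background(
    pedigrees: Sequence[Pedigree], freq: float, rng: np.random.Generator
) -> np.ndarray:
    """Alt counts across the whole cohort for one variant (family-independent
    founders, Mendelian descent)."""
    out = []
    for ped in pedigrees:
        haps = _drop_one(ped, freq, rng)
        out.extend(sum(haps[i]) for i in ped.member_ids)
    return np.array(out, dtype=np.int8)


def emit_cohort(
    pedigrees: Sequence[Pedigree],
    truth: GeneDropResult,
    cfg: SimulationConfig,
    out_dir: str | Path,
    rng: np.random.Generator | None = None,
    qc: QcThresholds = QcThresholds(),
) -> SimulatedCohort:
    """Write VCF + PED + annotation TSV + truth table for a gene-dropped cohort."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pedigrees = list(truth.pedigrees)
    samples = [iid for ped in pedigrees for iid in ped.member_ids]
    n = len(samples)
    proband_ids = list(truth.probands.values())
    max_bad_calls = int(np.floor((1.0 - qc.min_call_rate) * n))  # cap is exclusive

    plan: list[dict] = []
    used: set = set()
    autosomes = [str(c) for c in range(1, 23)]

    def _snv_alleles():
        ref = _BASES[int(rng.integers(4))]
        alt = _BASES[int(rng.integers(4))]
        while alt == ref:
            alt = _BASES[int(rng.integers(4))]
        return ref, alt

    # causal variant
    pos = int(rng.integers(100_000, 50_000_000))
    used.add((cfg.causal.chrom, pos))
    ref, alt = _snv_alleles()
    plan.append(
        {
            "category": "causal",
            "chrom": cfg.causal.chrom,
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "freq": cfg.causal.allele_freq,
            "cadd": cfg.causal.cadd_phred,
            "consequence": cfg.causal.consequence,
        }
    )
    bg = cfg.background
    for _ in range(bg.n_rare):
        chrom, pos = _draw_site(rng, autosomes, used)
        ref, alt = _snv_alleles()
        lo, hi = bg.rare_freq_range
        freq = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        plan.append(
            {"category": "background_rare", "chrom": chrom, "pos": pos,
             "ref": ref, "alt": alt, "freq": freq}
        )
    for _ in range(bg.n_common):
        chrom, pos = _draw_site(rng, autosomes, used)
        ref, alt = _snv_alleles()
        freq = float(rng.uniform(*bg.common_freq_range))
        plan.append(
            {"category": "background_common", "chrom": chrom, "pos": pos,
             "ref": ref, "alt": alt, "freq": freq}
        )
    for _ in range(cfg.planted.n_indel):
        chrom, pos = _draw_site(rng, autosomes, used)
        ref = _BASES[int(rng.integers(4))]
        alt = ref + _BASES[int(rng.integers(4))]
        plan.append(
            {"category": "planted_indel", "chrom": chrom, "pos": pos,
             "ref": ref, "alt": alt, "freq": float(rng.uniform(0.001, 0.01))}
        )
    for _ in range(cfg.planted.n_low_call_rate):
        chrom, pos = _draw_site(rng, autosomes, used)
        ref, alt = _snv_alleles()
        plan.append(
            {"category": "planted_low_call_rate", "chrom": chrom, "pos": pos,
             "ref": ref, "alt": alt, "freq": float(rng.uniform(0.001, 0.01))}
        )
    for _ in range(cfg.planted.n_excess_alt_carriers):
        chrom, pos = _draw_site(rng, autosomes, used)
        ref, alt = _snv_alleles()
        plan.append(
            {"category": "planted_excess_alt", "chrom": chrom, "pos": pos,
             "ref": ref, "alt": alt, "freq": 0.25}
        )
    for _ in range(cfg.planted.n_non_autosome):
        chrom, pos = _draw_site(rng, ["X"], used)
        ref, alt = _snv_alleles()
        plan.append(
            {"category": "planted_non_autosome", "chrom": chrom, "pos": pos,
             "ref": ref, "alt": alt, "freq": float(rng.uniform(0.001, 0.01))}
        )

    # deleteriousness scores / consequences / ClinVar for non-causal sites
    for site in plan:
        if site["category"] == "causal":
            site["clinvar"] = "absent"
            continue
        deleterious = rng.random() < bg.p_deleterious_score
        if deleterious:
            site["cadd"] = float(rng.uniform(20.5, 45.0))
            site["consequence"] = ["missense", "stop_gain", "splice"][
                int(rng.choice(3, p=[0.7, 0.15, 0.15]))
            ]
        else:
            site["cadd"] = float(rng.uniform(0.1, 19.5))
            site["consequence"] = ["synonymous", "intronic", "other"][
                int(rng.choice(3, p=[0.4, 0.4, 0.2]))
            ]
        r = rng.random()
        if deleterious and r < 0.04:
            site["clinvar"] = "pathogenic" if r < 0.02 else "likely_pathogenic"
        elif r < 0.08:
            site["clinvar"] = "other"
        else:
            site["clinvar"] = "absent"

    gene_pool = [f"GENE{i:05d}" for i in range(max(1, int(0.9 * len(plan))))]
    for site in plan:
        site["gene"] = (
            "GENE_CAUSAL"
            if site["category"] == "causal"
            else gene_pool[int(rng.integers(len(gene_pool)))]
        )

    # genotypes
    geno = np.zeros((len(plan), n), dtype=np.int8)
    sample_index = {iid: j for j, iid in enumerate(samples)}
    max_carriers = int(np.floor(qc.max_alt_carrier_fraction * n))
    for v, site in enumerate(plan):
        if site["category"] == "causal":
            for iid, count in truth.carriers.items():
                geno[v, sample_index[iid]] = count
            continue
        if site["category"] == "planted_excess_alt":
            k = int(np.ceil(0.4 * n))
            idx = rng.choice(n, size=k, replace=False)
            geno[v, idx] = 1
            continue
        err_rate = (
            cfg.sequencing.genotype_error_rate
            if site["category"] in ("background_rare", "background_common")
            else 0.0
        )

        def _genotyped(freq: float) -> np.ndarray:
            counts = _drop_background(pedigrees, freq, rng)
            if err_rate > 0.0:
                for j in np.nonzero(rng.random(n) < err_rate)[0]:
                    choices = [g for g in (0, 1, 2) if g != counts[j]]
                    counts[j] = choices[int(rng.integers(2))]
            return counts

        counts = _genotyped(site["freq"])
        if site["category"] not in ("planted_indel", "planted_low_call_rate"):
            # condition on passing the alt-carrier artifact filter so truth
            # labels survive QC unchanged (genotype errors included)
            tries = 0
            while int((counts >= 1).sum()) > max_carriers:
                tries += 1
                if tries % 30 == 0:
                    site["freq"] = site["freq"] / 2.0
                counts = _genotyped(site["freq"])
        geno[v] = counts

    # sequencing layer
    seq = cfg.sequencing
    shape = (len(plan), n)
    lam = rng.gamma(seq.depth_dispersion, seq.mean_depth / seq.depth_dispersion, shape)
    depth = rng.poisson(lam).astype(np.int32)
    gq = np.clip(np.round(rng.normal(seq.gq_mean, seq.gq_sd, shape)), 0, 99).astype(
        np.int32
    )
    missing = rng.random(shape) < seq.missing_rate

    bad = (depth < qc.min_depth) | (depth > qc.max_depth) | (gq < qc.min_gq) | missing
    for v, site in enumerate(plan):
        if site["category"] == "planted_low_call_rate":
            need = max_bad_calls + 1  # strictly below the call-rate threshold
            idx = rng.choice(n, size=need, replace=False)
            depth[v, idx] = 5
            continue
        # cap failing calls on every other site so call rate stays passing;
        # planted excess-carrier sites keep every call so blanking cannot
        # erode them below the carrier threshold
        bad_idx = np.nonzero(bad[v])[0]
        allowed = 0 if site["category"] == "planted_excess_alt" else max(max_bad_calls - 1, 0)
        for j in bad_idx[allowed:]:
            depth[v, j] = int(seq.mean_depth)
            gq[v, j] = int(seq.gq_mean)
            missing[v, j] = False

    # order sites by genome coordinate for emission
    order = sorted(
        range(len(plan)),
        key=lambda v: (
            (0, int(plan[v]["chrom"])) if plan[v]["chrom"].isdigit() else (1, 0),
            plan[v]["chrom"],
            plan[v]["pos"],
        ),
    )

    records: list[VariantRecord] = []
    annotations: list[AnnotationRecord] = []
    truth_rows: list[dict] = []
    blanked = (depth < qc.min_depth) | (depth > qc.max_depth) | (gq < qc.min_gq)
    for v in order:
        site = plan[v]
        calls = {}
        for j, iid in enumerate(samples):
            count = None if missing[v, j] else int(geno[v, j])
            calls[iid] = GenotypeCall(iid, count, int(depth[v, j]), float(gq[v, j]))
        rec = VariantRecord(site["chrom"], site["pos"], site["ref"], site["alt"], calls)
        records.append(rec)

        freq = site["freq"]
        is_rare = freq <= 0.01
        panel_freqs = {}
        for panel in cfg.panels:
            if freq < 1e-4 and rng.random() < 0.5:
                continue  # unobserved in this panel
            f = freq * float(np.exp(rng.normal(0.0, 0.15)))
            f = min(f, 0.01) if is_rare else min(max(f, 0.0101), 0.999)
            panel_freqs[panel] = f
        annotations.append(
            AnnotationRecord(
                chrom=site["chrom"],
                pos=site["pos"],
                ref=site["ref"],
                alt=site["alt"],
                gene=site["gene"],
                consequence=site["consequence"],
                cadd_phred=site["cadd"],
                clinvar=site["clinvar"],
                panel_freqs=panel_freqs,
            )
        )
        observed = (~missing[v]) & (~blanked[v])
        proband_carrier = any(
            observed[sample_index[pid]] and geno[v, sample_index[pid]] >= 1
            for pid in proband_ids
        )
        qc_reason = {
            "planted_indel": "indel",
            "planted_low_call_rate": "low_call_rate",
            "planted_excess_alt": "excess_alt_carriers",
            "planted_non_autosome": "non_autosome",
        }.get(site["category"], "")
        if site["category"] == "causal":
            # a high-frequency co-segregating variant can legitimately trip
            # the carrier artifact filter; record what QC will decide
            obs_carriers = int(((geno[v] >= 1) & observed).sum())
            if obs_carriers / n > qc.max_alt_carrier_fraction:
                qc_reason = "excess_alt_carriers"
        truth_rows.append(
            {
                "chrom": site["chrom"],
                "pos": site["pos"],
                "ref": site["ref"],
                "alt": site["alt"],
                "category": site["category"],
                "true_freq": freq,
                "is_rare": is_rare,
                "is_deleterious": site["cadd"] >= 20.0,
                "cadd_phred": site["cadd"],
                "gene": site["gene"],
                "qc_reason": qc_reason,
                "proband_carrier": proband_carrier,
                "n_carriers": int((geno[v] >= 1).sum()),
                "is_causal": site["category"] == "causal",
            }
        )

    truth_df = pd.DataFrame(truth_rows)
    vcf_path = write_vcf(records, samples, out_dir / "cohort.vcf")
    ped_path = write_ped(pedigrees, out_dir / "cohort.ped")
    ann_path = write_annotations(annotations, out_dir / "annotations.tsv")
    truth_path = out_dir / "truth.tsv"
    truth_df.to_csv(truth_path, sep="\t", index=False)
    probands_path = out_dir / "probands.txt"
    probands_path.write_text(
        "".join(f"{fid}\t{iid}\n" for fid, iid in truth.probands.items())
    )
    config_path = out_dir / "config.resolved.yaml"
    config_path.write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
    return SimulatedCohort(
        out_dir=out_dir,
        vcf=vcf_path,
        ped=ped_path,
        annotations=ann_path,
        truth=truth_path,
        probands_file=probands_path,
        config_file=config_path,
        pedigrees=pedigrees,
        probands=dict(truth.probands),
        truth_table=truth_df,
    )


def simulate_cohort(cfg: SimulationConfig, out_dir: str | Path) -> SimulatedCohort:
    """Build pedigrees, gene-drop the causal variant, and emit the cohort."""
    rng = np.random.default_rng(cfg.seed)
    pedigrees, meta = build_pedigrees(cfg, rng)
    truth = gene_drop(pedigrees, cfg, rng, line_meta=meta)
    return emit_cohort(pedigrees, truth, cfg, out_dir, rng)
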