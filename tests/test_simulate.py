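"""Synthetic cohort generator: pedigree construction, gene dropping, emission."""

import dataclasses

import numpy as np
import pytest

from famseg.errors import SimulationError
from famseg.linkage import DiseaseModel, linkage_scan
from famseg.pedigree import Affection, read_ped
from famseg.qc import proband_carrier_set
from famseg.simulate import (
    BackgroundSpec,
    CausalVariantSpec,
    FamilySpec,
    PlantedQcSpec,
    SequencingSpec,
    SimulationConfig,
    build_pedigrees,
    gene_drop,
    noise_free_sequencing,
    simulate_cohort,
)
from famseg.vcfio import read_annotations, read_vcf

GRID11 = tuple(np.round(np.linspace(0.0, 0.5, 11), 2))


def small_config(seed=0, **overrides):
    base = dict(
        seed=seed,
        background=BackgroundSpec(n_rare=30, n_common=30),
        planted=PlantedQcSpec(5, 4, 3, 2),
        sequencing=noise_free_sequencing(),
    )
    base.update(overrides)
    return SimulationConfig(**base)


def test_build_pedigrees_study_profile():
    peds, meta = build_pedigrees(SimulationConfig(seed=1))
    assert [len(p) for p in peds] == [18, 16, 10, 8]
    assert sum(len(p) for p in peds) == 52
    # three of four families are bilineal: a second founder line exists
    assert sum(meta[p.family_id]["line_b_founder"] is not None for p in peds) == 3
    for p in peds:
        assert not p.loops_present


def test_build_pedigrees_trio_spec():
    cfg = SimulationConfig(seed=2, family_specs=(FamilySpec(3, 1, 2),))
    (ped,), _ = build_pedigrees(cfg)
    assert len(ped) == 3 and len(ped.founders()) == 2


def test_build_pedigrees_infeasible_spec_errors():
    cfg = SimulationConfig(seed=2, family_specs=(FamilySpec(3, 1, 3),))
    with pytest.raises(SimulationError, match="minimum"):
        build_pedigrees(cfg)


def test_gene_drop_full_penetrance_affected_equals_carriers():
    cfg = small_config(
        seed=3, disease=DiseaseModel(0.2, 1.0, 1.0, 0.0)
    )
    peds, meta = build_pedigrees(cfg)
    truth = gene_drop(peds, cfg, np.random.default_rng(3), line_meta=meta)
    for ped in truth.pedigrees:
        affected = {m.individual_id for m in ped.affected}
        carriers = {
            i for i in ped.member_ids if truth.carriers[i] >= 1
        }
        assert affected == carriers
        assert truth.probands[ped.family_id] in affected


def test_gene_drop_penetrance_calibration():
    """Affected fraction among carriers ~ 0.8 over many seeded re-drops."""
    cfg = SimulationConfig(
        seed=4, family_specs=(FamilySpec(12, 1, 3, False),)
    )
    n_carrier = n_affected_carrier = 0
    for seed in range(400):
        peds, meta = build_pedigrees(dataclasses.replace(cfg, seed=seed))
        truth = gene_drop(
            peds, dataclasses.replace(cfg, seed=seed),
            np.random.default_rng(seed), line_meta=meta,
        )
        ped = truth.pedigrees[0]
        for m in ped.members:
            if truth.carriers[m.individual_id] >= 1:
                n_carrier += 1
                n_affected_carrier += m.affection is Affection.AFFECTED
    rate = n_affected_carrier / n_carrier
    # ascertainment (>=1 affected demanded) biases mildly upward; the
    # tolerance window covers the binomial error at this sample size
    assert rate == pytest.approx(0.8, abs=0.05)


def test_gene_drop_infeasible_config_reports():
    cfg = small_config(
        seed=5,
        causal=CausalVariantSpec(allele_freq=1e-6, cosegregating=False),
        max_resample=20,
    )
    peds, meta = build_pedigrees(cfg)
    with pytest.raises(SimulationError, match="re-drops"):
        gene_drop(peds, cfg, np.random.default_rng(5), line_meta=meta)


def test_table_matching_mode_hits_cohort_profile(tmp_path):
    cfg = dataclasses.replace(SimulationConfig(seed=6), table_matching=True)
    cohort = simulate_cohort(cfg, tmp_path / "tm")
    assert sum(len(p) for p in cohort.pedigrees) == 52
    assert [len(p.affected) for p in cohort.pedigrees] == [4, 5, 5, 3]
    assert sum(len(p.affected) for p in cohort.pedigrees) == 17


def test_emit_cohort_truth_labels_and_roundtrip(tmp_path):
    cfg = small_config(seed=7)
    cohort = simulate_cohort(cfg, tmp_path / "c")
    truth = cohort.truth_table
    assert (truth.category == "planted_indel").sum() == 5
    assert (truth.qc_reason == "indel").sum() == 5
    # emitted files parse with the pipeline's own readers
    records, samples = read_vcf(cohort.vcf)
    assert len(records) == len(truth)
    assert len(samples) == sum(len(p) for p in cohort.pedigrees)
    anns = read_annotations(cohort.annotations)
    assert len(anns) == len(truth)
    peds = read_ped(cohort.ped)
    assert [p.family_id for p in peds] == [p.family_id for p in cohort.pedigrees]
    # annotation frequencies never cross the 1% rare/common boundary
    by_key = {a.key: a for a in anns}
    for row in truth.itertuples():
        ann = by_key[(str(row.chrom), int(row.pos), str(row.ref), str(row.alt))]
        for f in ann.panel_freqs.values():
            assert (f <= 0.01) == bool(row.is_rare)


def test_emit_cohort_deterministic_bytes(tmp_path):
    cfg = small_config(seed=8)
    a = simulate_cohort(cfg, tmp_path / "a")
    b = simulate_cohort(cfg, tmp_path / "b")
    assert a.vcf.read_bytes() == b.vcf.read_bytes()
    assert a.ped.read_bytes() == b.ped.read_bytes()
    assert a.annotations.read_bytes() == b.annotations.read_bytes()


def test_background_founder_frequency_recovery(tmp_path):
    """Empirical founder alt frequency across many common background sites
    recovers the configured frequency band (law of large numbers)."""
    cfg = small_config(
        seed=9,
        background=BackgroundSpec(
            n_rare=0, n_common=300, common_freq_range=(0.045, 0.055)
        ),
        planted=PlantedQcSpec(0, 0, 0, 0),
    )
    cohort = simulate_cohort(cfg, tmp_path / "freq")
    records, _ = read_vcf(cohort.vcf)
    founders = {
        m.individual_id for p in cohort.pedigrees for m in p.founders()
    }
    truth = cohort.truth_table
    bg = {
        (str(r.chrom), int(r.pos)) for r in truth[truth.category == "background_common"].itertuples()
    }
    alt = tot = 0
    for rec in records:
        if (rec.chrom, rec.pos) not in bg:
            continue
        for iid in founders:
            c = rec.calls[iid]
            if c.allele_count_alt is not None:
                alt += c.allele_count_alt
                tot += 2
    assert alt / tot == pytest.approx(0.05, abs=0.008)


def test_zero_noise_full_penetrance_causal_ranks_first(tmp_path):
    """With clean sequencing and penetrance 1 the gene-dropped causal variant
    tops the cumulative LOD in every seeded replicate."""
    for seed in (11, 12, 13):
        cfg = small_config(
            seed=seed, disease=DiseaseModel(0.01, 1.0, 1.0, 0.0)
        )
        cohort = simulate_cohort(cfg, tmp_path / f"e2e{seed}")
        peds = read_ped(cohort.ped, probands=list(cohort.probands.items()))
        records, _ = read_vcf(cohort.vcf)
        carriers = proband_carrier_set(records, list(cohort.probands.values()))
        scan = linkage_scan(carriers, peds, cfg.disease, GRID11)
        best = max(scan.results, key=lambda r: r.cumulative_lod)
        ck = cohort.truth_table[cohort.truth_table.is_causal].iloc[0]
        assert best.variant_key == (str(ck.chrom), int(ck.pos), str(ck.ref), str(ck.alt))


def test_cumulative_lod_grows_with_cohort_scale(tmp_path):
    """More families -> more cumulative evidence for the causal variant,
    on average across seeds."""
    sizes = {1: [], 2: [], 4: []}
    for n_fam in sizes:
        for seed in range(20, 25):
            specs = tuple(FamilySpec(12, 3, 3, False) for _ in range(n_fam))
            cfg = small_config(
                seed=seed,
                family_specs=specs,
                background=BackgroundSpec(n_rare=0, n_common=0),
                planted=PlantedQcSpec(0, 0, 0, 0),
            )
            cohort = simulate_cohort(cfg, tmp_path / f"s{n_fam}_{seed}")
            peds = read_ped(cohort.ped, probands=list(cohort.probands.items()))
            records, _ = read_vcf(cohort.vcf)
            scan = linkage_scan(records, peds, cfg.disease, GRID11)
            ck = cohort.truth_table[cohort.truth_table.is_causal].iloc[0]
            key = (str(ck.chrom), int(ck.pos), str(ck.ref), str(ck.alt))
            lod = {r.variant_key: r.cumulative_lod for r in scan.results}[key]
            sizes[n_fam].append(lod)
    means = {k: float(np.mean(v)) for k, v in sizes.items()}
    assert means[1] < means[2] < means[4]
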