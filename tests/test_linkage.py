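"""Two-locus pedigree likelihood, LOD curves, and the linkage scan.

The hand-written peeling engine is checked three ways: against the package's
own full-enumeration path, against a from-scratch literal 16^n oracle
(conftest), and against closed-form values for fully informative families.
"""

import math

import numpy as np
import pytest

from famseg.errors import (
    InconsistentDominantModelError,
    MendelianInconsistencyError,
    MonomorphicMarkerError,
)
from famseg.linkage import (
    DiseaseModel,
    LodCurve,
    LodThresholds,
    MarkerModel,
    cumulative_lod,
    enumeration_likelihood,
    linkage_scan,
    lod_curve,
    parsimonious_dominant_carriers,
    pedigree_likelihood,
    theoretical_max_lod,
)
from famseg.pedigree import Affection, Pedigree, Sex
from famseg.vcfio import GenotypeCall, VariantRecord

from conftest import (
    literal_log10_likelihood,
    member,
    phase_known_family,
    random_genotypes,
    random_pedigree,
)

GRID11 = tuple(np.round(np.linspace(0.0, 0.5, 11), 2))
LOG2 = math.log10(2.0)


def nuclear_family(k_affected=3, fid="N"):
    members = [
        member(fid, "dad", sex=Sex.MALE, affection=Affection.AFFECTED),
        member(fid, "mom", sex=Sex.FEMALE, affection=Affection.UNAFFECTED),
    ] + [
        member(fid, f"c{i}", "dad", "mom", affection=Affection.AFFECTED)
        for i in range(k_affected)
    ]
    geno = {"dad": 1, "mom": 0, **{f"c{i}": 1 for i in range(k_affected)}}
    return Pedigree(fid, members), geno


def test_all_unknown_pedigree_has_unit_likelihood(trio):
    """With no phenotypes or genotypes every factor marginalises to one."""
    blank = Pedigree(
        "T",
        [member("T", "dad", sex=Sex.MALE), member("T", "mom", sex=Sex.FEMALE),
         member("T", "kid", "dad", "mom")],
    )
    for theta in (0.0, 0.1, 0.37, 0.5):
        ll = pedigree_likelihood(blank, {}, DiseaseModel(), MarkerModel(0.3), theta)
        assert ll == pytest.approx(0.0, abs=1e-12)


def test_mendelian_impossible_genotypes_signal_minus_inf(trio):
    g = {"dad": 0, "mom": 0, "kid": 2}
    d, m = DiseaseModel(), MarkerModel(0.3)
    assert pedigree_likelihood(trio, g, d, m, 0.1) == -math.inf
    assert enumeration_likelihood(trio, g, d, m, 0.1) == -math.inf
    with pytest.raises(MendelianInconsistencyError):
        lod_curve(trio, g, d, m, GRID11)


def test_affected_child_of_unaffected_parents_impossible_at_full_penetrance():
    """Penetrance 1 + phenocopy 0: unaffected parents are non-carriers, so an
    affected child has likelihood zero at every theta."""
    ped = Pedigree(
        "T",
        [member("T", "dad", sex=Sex.MALE, affection=Affection.UNAFFECTED),
         member("T", "mom", sex=Sex.FEMALE, affection=Affection.UNAFFECTED),
         member("T", "kid", "dad", "mom", affection=Affection.AFFECTED)],
    )
    d = DiseaseModel(0.01, 1.0, 1.0, 0.0)
    for theta in (0.0, 0.2, 0.5):
        assert pedigree_likelihood(ped, {}, d, MarkerModel(0.5), theta) == -math.inf


def test_peeling_matches_literal_oracle_small_pedigrees(trio):
    """Peeling, enumeration and the from-scratch 16^n oracle agree."""
    d = DiseaseModel(0.05, 0.9, 0.8, 0.02)
    m = MarkerModel(0.25)
    cases = [
        (trio, {"dad": 1, "mom": 0, "kid": 1}),
        (trio, {"dad": 2, "kid": 1}),
        (nuclear_family(1, "N1")[0], {"dad": 1, "c0": 1}),
    ]
    for ped, geno in cases:
        for theta in (0.0, 0.3):
            lit = literal_log10_likelihood(ped, geno, d, m, theta)
            peel = pedigree_likelihood(ped, geno, d, m, theta)
            enum = enumeration_likelihood(ped, geno, d, m, theta)
            assert peel == pytest.approx(lit, abs=1e-10)
            assert enum == pytest.approx(lit, abs=1e-10)


def test_peeling_matches_enumeration_on_random_pedigrees():
    rng = np.random.default_rng(11)
    d = DiseaseModel()
    checked = 0
    for _ in range(40):
        ped = random_pedigree(rng)
        geno = random_genotypes(rng, ped)
        m = MarkerModel(float(rng.uniform(0.05, 0.95)))
        theta = float(rng.choice([0.0, 0.1, 0.3, 0.5]))
        peel = pedigree_likelihood(ped, geno, d, m, theta)
        enum = enumeration_likelihood(ped, geno, d, m, theta)
        if math.isinf(peel) or math.isinf(enum):
            assert peel == enum
        else:
            assert peel == pytest.approx(enum, abs=1e-10)
            checked += 1
    assert checked >= 20  # most random draws are Mendelian-consistent


def test_likelihood_invariant_to_member_order_and_allele_relabeling():
    ped, geno = nuclear_family(3)
    d = DiseaseModel()
    base = pedigree_likelihood(ped, geno, d, MarkerModel(0.3), 0.1)
    shuffled = Pedigree("N", [ped.members[i] for i in (4, 0, 3, 1, 2)])
    assert pedigree_likelihood(shuffled, geno, d, MarkerModel(0.3), 0.1) == (
        pytest.approx(base, abs=1e-12)
    )
    flipped = {iid: 2 - g for iid, g in geno.items()}
    assert pedigree_likelihood(ped, flipped, d, MarkerModel(0.7), 0.1) == (
        pytest.approx(base, abs=1e-12)
    )


def test_loop_pedigree_uses_enumeration_fallback(cousin_loop):
    d, m = DiseaseModel(), MarkerModel(0.4)
    geno = {"e": 1, "c": 1, "d": 0}
    for theta in (0.0, 0.2, 0.5):
        peel_path = pedigree_likelihood(cousin_loop, geno, d, m, theta)
        enum = enumeration_likelihood(cousin_loop, geno, d, m, theta)
        assert peel_path == pytest.approx(enum, abs=1e-12)


def test_lod_curve_phase_known_closed_form():
    """k scorable meioses in a phase-known fully informative family give
    max LOD = k*log10(2) exactly, at theta = 0."""
    d = DiseaseModel(0.01, 1.0, 1.0, 0.0)
    for k in (1, 3, 5):
        ped, geno = phase_known_family(k)
        curve = lod_curve(ped, geno, d, MarkerModel(0.5), GRID11)
        assert curve.max_lod == pytest.approx(k * LOG2, abs=1e-9)
        assert curve.theta_at_max == 0.0


def test_lod_curve_phase_unknown_nuclear_family_frozen_value():
    """The bare nuclear family pays the phase-unknown penalty: closed form
    log10(1 / (2(1-q)2^-k + q)) (frozen from the enumeration oracle)."""
    q = 0.01
    ped, geno = nuclear_family(3)
    curve = lod_curve(ped, geno, DiseaseModel(q, 1.0, 1.0, 0.0), MarkerModel(0.5), GRID11)
    expected = -math.log10(2 * (1 - q) * 2 ** -3 + q)
    assert curve.max_lod == pytest.approx(expected, abs=1e-10)


def test_lod_curve_uninformative_marker_is_flat_zero():
    ped, _ = nuclear_family(3)
    geno = {i: 0 for i in ped.member_ids}  # everyone hom-ref
    curve = lod_curve(ped, geno, DiseaseModel(), MarkerModel(0.5), GRID11)
    assert np.allclose(curve.lod_values, 0.0, atol=1e-12)


def test_lod_at_half_is_zero_and_monomorphic_marker_rejected():
    ped, geno = nuclear_family(2)
    curve = lod_curve(ped, geno, DiseaseModel(), MarkerModel(0.3), GRID11)
    assert curve.lod_values[-1] == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(MonomorphicMarkerError):
        MarkerModel(0.0)


def test_cumulative_lod_additivity_and_classes():
    d = DiseaseModel(0.01, 1.0, 1.0, 0.0)
    k1, g1 = phase_known_family(2, "A")
    k2, g2 = phase_known_family(3, "B")
    c1 = lod_curve(k1, g1, d, MarkerModel(0.5), GRID11, variant_key=("1", 5, "A", "T"))
    c2 = lod_curve(k2, g2, d, MarkerModel(0.5), GRID11, variant_key=("1", 5, "A", "T"))
    res = cumulative_lod([c1, c2])
    assert res.cumulative_lod == pytest.approx(5 * LOG2, abs=1e-9)
    assert res.cumulative_theta == 0.0
    assert res.classification == "cosegregating"
    flat = LodCurve("C", ("1", 5, "A", "T"), np.array(GRID11), np.zeros(11))
    assert cumulative_lod([flat, flat]).classification == "neutral"
    assert cumulative_lod([c1]).classification == "suggestive"  # 0.602


def test_cumulative_lod_exclusion_at_theta_zero():
    """Anti-segregation drives LOD(0) below -2 -> excluded, even though the
    maximised LOD is pinned at >= 0 by the theta=1/2 anchor."""
    d = DiseaseModel(0.01, 1.0, 1.0, 0.05)  # phenocopies keep L(0) finite
    ped, geno = phase_known_family(6, "X")
    anti = dict(geno, **{f"c{i}": 0 for i in range(6)})  # affected, no allele
    curve = lod_curve(ped, anti, d, MarkerModel(0.5), GRID11, variant_key=("1", 1, "A", "T"))
    assert curve.lod_at_zero < -2
    res = cumulative_lod([curve])
    assert res.classification == "excluded"


def test_cumulative_lod_rejects_mismatched_keys():
    flat = LodCurve("A", ("1", 1, "A", "T"), np.array(GRID11), np.zeros(11))
    other = LodCurve("B", ("2", 2, "C", "G"), np.array(GRID11), np.zeros(11))
    with pytest.raises(ValueError, match="variant keys"):
        cumulative_lod([flat, other])


def test_parsimonious_carriers_and_theoretical_max(three_gen):
    d = DiseaseModel(0.01, 0.8, 0.8, 0.0)
    carriers = parsimonious_dominant_carriers(three_gen, d)
    assert carriers == {"gf", "dad", "son"}  # the affected line of descent
    # scorable meioses: children of carrier parents = dad, son, grandkid
    got = theoretical_max_lod(three_gen, d, GRID11)
    assert got == pytest.approx(3 * LOG2, abs=1e-9)


def test_theoretical_max_nuclear_and_singleton():
    d = DiseaseModel(0.01, 1.0, 1.0, 0.0)
    ped, _ = nuclear_family(3)
    assert theoretical_max_lod(ped, d, GRID11) == pytest.approx(3 * LOG2, abs=1e-9)
    solo = Pedigree("S", [member("S", "a", sex=Sex.MALE, affection=Affection.AFFECTED)])
    assert theoretical_max_lod(solo, d, GRID11) == pytest.approx(0.0, abs=1e-12)


def test_theoretical_max_bounds_observed_lod(three_gen):
    """The phase-known bound dominates the phase-unknown LOD on the same
    perfectly co-segregating marker."""
    d = DiseaseModel(0.01, 0.8, 0.8, 0.0)
    carriers = parsimonious_dominant_carriers(three_gen, d)
    geno = {i: (1 if i in carriers else 0) for i in three_gen.member_ids}
    observed = lod_curve(three_gen, geno, d, MarkerModel(0.001), GRID11).max_lod
    assert theoretical_max_lod(three_gen, d, GRID11) >= observed - 1e-12


def test_theoretical_max_requires_consistent_model():
    ped = Pedigree(
        "T",
        [member("T", "dad", sex=Sex.MALE, affection=Affection.UNAFFECTED),
         member("T", "mom", sex=Sex.FEMALE, affection=Affection.UNAFFECTED),
         member("T", "kid", "dad", "mom", affection=Affection.AFFECTED)],
    )
    with pytest.raises(InconsistentDominantModelError, match="phenocopy"):
        theoretical_max_lod(ped, DiseaseModel(0.01, 1.0, 1.0, 0.0), GRID11)


def _records_for(ped, genos):
    out = []
    for i, g in enumerate(genos):
        calls = {
            iid: GenotypeCall(iid, g.get(iid), 60, 60.0) for iid in ped.member_ids
        }
        out.append(VariantRecord("1", 1000 + i, "A", "T", calls))
    return out


def test_linkage_scan_skips_inconsistent_records_and_is_deterministic(trio):
    good = {"dad": 1, "mom": 0, "kid": 1}
    bad = {"dad": 0, "mom": 0, "kid": 2}
    records = _records_for(trio, [good, bad])
    scan = linkage_scan(records, [trio], DiseaseModel(), GRID11)
    assert len(scan.results) == 1 and len(scan.skipped) == 1
    assert scan.skipped[0]["reason"] == "mendelian_inconsistent"
    again = linkage_scan(records, [trio], DiseaseModel(), GRID11)
    assert scan.results[0].cumulative_lod == again.results[0].cumulative_lod
    assert scan.results[0].variant_key == ("1", 1000, "A", "T")


def test_linkage_scan_empty_input():
    scan = linkage_scan([], [], DiseaseModel(), GRID11)
    assert scan.results == [] and scan.skipped == []
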