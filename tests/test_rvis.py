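"""Rare-variant-with-informatics-support classification and sub-reports."""

import pytest
from hypothesis import given, strategies as st

from famseg.errors import FamsegError
from famseg.rvis import (
    RvisCriteria,
    is_rvis,
    maf_tier_counts,
    proband_sharing,
    rvis_table,
    subset_reports,
)
from famseg.vcfio import AnnotationRecord, GenotypeCall, VariantRecord


def variant(pos=100, proband_alt=1, chrom="1"):
    calls = {
        "p1": GenotypeCall("p1", proband_alt, 60, 60.0),
        "other": GenotypeCall("other", 1, 60, 60.0),
    }
    return VariantRecord(chrom, pos, "A", "T", calls)


def annotation(pos=100, chrom="1", freqs=None, cadd=25.0, gene="G1",
               consequence="missense", clinvar="absent"):
    return AnnotationRecord(
        chrom, pos, "A", "T", gene, consequence, cadd, clinvar, freqs or {}
    )


@pytest.mark.parametrize(
    "freqs,cadd,proband_alt,expected,reason",
    [
        ({"EUR": 0.009, "AFR": 0.004}, 25.0, 1, True, None),
        ({"EUR": 0.02}, 30.0, 1, False, "frequency"),
        ({"EUR": 0.001}, 19.9, 1, False, "informatics"),  # CADD boundary
        ({"EUR": 0.001}, 20.0, 1, True, None),
        ({"EUR": 0.01}, 20.0, 1, True, None),  # MAF boundary inclusive
        ({}, 25.0, 1, True, None),  # unobserved in all panels = rare
        ({"EUR": 0.001}, None, 1, False, "informatics"),  # missing CADD
        ({"EUR": 0.001}, 25.0, 0, False, "no_proband_carrier"),
        ({"EUR": 0.995}, 25.0, 1, True, None),  # minor-allele folding: MAF 0.005
    ],
)
def test_is_rvis_criteria(freqs, cadd, proband_alt, expected, reason):
    v = variant(proband_alt=proband_alt)
    a = annotation(freqs=freqs, cadd=cadd)
    got, why = is_rvis(v, a, RvisCriteria(), ["p1"])
    assert got is expected and why == reason


def test_is_rvis_key_mismatch_errors():
    with pytest.raises(FamsegError, match="match"):
        is_rvis(variant(pos=100), annotation(pos=999), RvisCriteria(), ["p1"])


@given(
    st.floats(0.0001, 0.01),
    st.floats(20.0, 40.0),
)
def test_is_rvis_monotone_in_criteria(max_maf, min_cadd):
    """Tightening the thresholds never adds a variant to the RVIS set."""
    records = [variant(pos=p) for p in range(1, 30)]
    anns = {
        r.key: annotation(pos=r.pos, freqs={"EUR": 0.0005 * r.pos},
                          cadd=1.5 * r.pos)
        for r in records
    }
    loose = rvis_table(records, anns, RvisCriteria(), ["p1"])
    tight = rvis_table(records, anns, RvisCriteria(max_maf, min_cadd), ["p1"])
    loose_keys = set(map(tuple, loose[["chrom", "pos"]].values))
    tight_keys = set(map(tuple, tight[["chrom", "pos"]].values))
    assert tight_keys <= loose_keys


def test_maf_tier_counts_fixture():
    """5 variants at 0.005, 3 at 0.0005, 2 at 0.00005 under tiers 1%/0.1%/0.01%."""
    records, anns = [], {}
    freqs = [0.005] * 5 + [0.0005] * 3 + [0.00005] * 2
    for i, f in enumerate(freqs):
        r = variant(pos=i + 1)
        records.append(r)
        anns[r.key] = annotation(pos=i + 1, freqs={"EUR": f})
    table = rvis_table(records, anns, RvisCriteria(), ["p1"])
    assert maf_tier_counts(table, [0.01, 0.001, 0.0001]) == {
        0.01: 10, 0.001: 5, 0.0001: 2
    }
    assert maf_tier_counts(table.iloc[0:0], [0.01, 0.001]) == {0.01: 0, 0.001: 0}
    with pytest.raises(ValueError, match="decreasing"):
        maf_tier_counts(table, [0.001, 0.01])


def test_maf_tiers_count_unobserved_as_rare():
    records = [variant(pos=i + 1) for i in range(3)]
    anns = {r.key: annotation(pos=r.pos, freqs={}) for r in records}
    table = rvis_table(records, anns, RvisCriteria(), ["p1"])
    assert maf_tier_counts(table, [0.01, 0.0001]) == {0.01: 3, 0.0001: 3}


def _sharing_cohort():
    """10 RVIS with a known sharing histogram {1: 7, 2: 2, 3: 1}."""
    probands = ["p1", "p2", "p3", "p4"]
    fam = {"p1": "F1", "p2": "F2", "p3": "F3", "p4": "F4"}
    carried_by = [["p1"]] * 4 + [["p2"]] * 2 + [["p3"]] + [["p1", "p3"]] * 2 + [
        ["p1", "p2", "p4"]
    ]
    records, anns = [], {}
    for i, carriers in enumerate(carried_by):
        calls = {
            p: GenotypeCall(p, 1 if p in carriers else 0, 60, 60.0)
            for p in probands
        }
        rec = VariantRecord("1", i + 1, "A", "T", calls)
        records.append(rec)
        anns[rec.key] = annotation(pos=i + 1, freqs={"EUR": 0.001},
                                   gene=f"GENE{i % 6}")
    return records, anns, probands, fam


def test_proband_sharing_histograms():
    records, anns, probands, fam = _sharing_cohort()
    table = rvis_table(records, anns, RvisCriteria(), probands)
    sharing = proband_sharing(table, probands, fam)
    assert sharing["variant_histogram"] == {1: 7, 2: 2, 3: 1}
    # marginals: histogram bins sum to the variant count
    assert sum(sharing["variant_histogram"].values()) == len(table)
    assert sum(sharing["gene_histogram"].values()) == len(sharing["gene_table"])


def test_gene_level_sharing_without_shared_variant():
    """Two families with different variants in one gene: gene-level sharing 2,
    variant-level max 1."""
    probands = ["p1", "p2"]
    fam = {"p1": "FA", "p2": "FB"}
    recs, anns = [], {}
    for pos, carrier in ((1, "p1"), (2, "p2")):
        calls = {p: GenotypeCall(p, int(p == carrier), 60, 60.0) for p in probands}
        rec = VariantRecord("1", pos, "A", "T", calls)
        recs.append(rec)
        anns[rec.key] = annotation(pos=pos, freqs={"EUR": 0.001}, gene="SHARED")
    table = rvis_table(recs, anns, RvisCriteria(), probands)
    sharing = proband_sharing(table, probands, fam)
    assert sharing["gene_table"].iloc[0].n_families == 2
    assert sharing["variant_table"].n_probands.max() == 1


def test_subset_reports():
    probands = ["p1"]
    recs, anns = [], {}
    specs = [
        (1, "stop_gain", "absent", 1),
        (2, "missense", "likely_pathogenic", 1),
        (3, "missense", "absent", 2),  # proband homozygote
        (4, "intronic", "absent", 1),
    ]
    for pos, csq, clv, alt in specs:
        calls = {"p1": GenotypeCall("p1", alt, 60, 60.0)}
        rec = VariantRecord("1", pos, "A", "T", calls)
        recs.append(rec)
        anns[rec.key] = annotation(pos=pos, freqs={"EUR": 0.001},
                                   consequence=csq, clinvar=clv)
    table = rvis_table(recs, anns, RvisCriteria(), probands)
    subsets = subset_reports(table, {r.key: r for r in recs}, probands)
    assert list(subsets["stop_gain"].pos) == [1]
    assert list(subsets["clinvar_pathogenic"].pos) == [2]
    assert list(subsets["proband_homozygous"].pos) == [3]
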