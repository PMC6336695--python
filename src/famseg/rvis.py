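"""Conventional prioritization arm: rare variants with informatics support.

A variant is an RVIS when its minor-allele frequency is at or below 1% in
*every* population panel reporting it (a site unobserved in all panels
counts as rare), its CADD-Phred deleteriousness score is at least 20
(a missing score is not informatics support), and at least one proband
carries the alt allele.  Panels report alt-allele frequencies; each is
folded to min(f, 1-f) before thresholding so the criterion is genuinely a
minor-allele one.

Sub-reports mirror the follow-up triage usually applied to such a list:
sharing across probands at variant and gene level, stop-gain subset,
ClinVar-pathogenic subset, proband-homozygous subset, and tighter MAF tiers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import FamsegError
from .vcfio import AnnotationRecord, VariantRecord

__all__ = [
    "RvisCriteria",
    "is_rvis",
    "rvis_table",
    "maf_tier_counts",
    "proband_sharing",
    "subset_reports",
]


@dataclass(frozen=True)
class RvisCriteria:
    max_maf: float = 0.01
    min_cadd: float = 20.0
    require_proband_carrier: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.max_maf < 1.0:
            raise ValueError("max_maf must be in (0, 1)")
        if self.min_cadd < 0:
            raise ValueError("min_cadd must be >= 0")


def _rare_in_all_panels(a: AnnotationRecord, max_maf: float) -> bool:
    maf = a.max_panel_maf()
    return maf is None or maf <= max_maf


def is_rvis(
    v: VariantRecord,
    a: AnnotationRecord,
    c: RvisCriteria = RvisCriteria(),
    proband_ids: Iterable[str] = (),
) -> tuple[bool, str | None]:
    """Classify one variant; returns (is_rvis, first failing reason or None)."""
    if v.key != a.key:
        raise FamsegError(f"annotation key {a.key} does not match variant {v.key}")
    if not _rare_in_all_panels(a, c.max_maf):
        return False, "frequency"
    if a.cadd_phred is None or a.cadd_phred < c.min_cadd:
        return False, "informatics"
    if c.require_proband_carrier:
        probands = list(proband_ids)
        if not probands:
            raise FamsegError("proband ids required when require_proband_carrier")
        carried = any(
            (call := v.calls.get(pid)) is not None
            and call.allele_count_alt is not None
            and call.allele_count_alt >= 1
            for pid in probands
        )
        if not carried:
            return False, "no_proband_carrier"
    return True, None


def rvis_table(
    records: Sequence[VariantRecord],
    annotations: Mapping[tuple, AnnotationRecord],
    criteria: RvisCriteria = RvisCriteria(),
    proband_ids: Iterable[str] = (),
) -> pd.DataFrame:
    """One row per RVIS with its annotation fields and per-proband carriage."""
    probands = list(proband_ids)
    rows = []
    for rec in records:
        ann = annotations.get(rec.key)
        if ann is None:
            continue
        ok, _ = is_rvis(rec, ann, criteria, probands)
        if not ok:
            continue
        row = {
            "chrom": rec.chrom,
            "pos": rec.pos,
            "ref": rec.ref,
            "alt": rec.alt,
            "gene": ann.gene,
            "consequence": ann.consequence,
            "cadd_phred": ann.cadd_phred,
            "clinvar": ann.clinvar,
            "max_panel_maf": ann.max_panel_maf(),
        }
        for pid in probands:
            call = rec.calls.get(pid)
            row[f"alt_count:{pid}"] = (
                call.allele_count_alt if call is not None else None
            )
        rows.append(row)
    columns = [
        "chrom", "pos", "ref", "alt", "gene", "consequence",
        "cadd_phred", "clinvar", "max_panel_maf",
    ] + [f"alt_count:{pid}" for pid in probands]
    return pd.DataFrame(rows, columns=columns)


def maf_tier_counts(rvis: pd.DataFrame, tiers: Sequence[float]) -> dict[float, int]:
    """RVIS counts surviving successively tighter MAF ceilings.

    ``tiers`` must be strictly decreasing; unobserved frequencies (NaN)
    count as rare in every tier, so counts are monotone non-increasing.
    """
    if any(b >= a for a, b in zip(tiers, tiers[1:])):
        raise ValueError("tiers must be strictly decreasing")
    out: dict[float, int] = {}
    maf = rvis["max_panel_maf"] if len(rvis) else pd.Series(dtype=float)
    for tier in tiers:
        out[tier] = int((maf.isna() | (maf <= tier)).sum()) if len(rvis) else 0
    return out


def proband_sharing(
    rvis: pd.DataFrame,
    proband_ids: Sequence[str],
    family_of_proband: Mapping[str, str],
) -> dict:
    """Sharing of the RVIS list across probands.

    Variant level: how many probands carry each RVIS.  Gene level: how many
    distinct probands' families harbor *any* RVIS in the gene (families may
    share a gene without sharing a variant).  Histograms summarise both.
    """
    probands = list(proband_ids)
    if len(probands) < 2:
        raise FamsegError("proband sharing needs at least two probands")
    cols = [f"alt_count:{pid}" for pid in probands]
    variant_rows = []
    gene_families: dict[str, set[str]] = {}
    for _, row in rvis.iterrows():
        carriers = [
            pid
            for pid, col in zip(probands, cols)
            if pd.notna(row[col]) and row[col] >= 1
        ]
        variant_rows.append(
            {
                "chrom": row["chrom"],
                "pos": row["pos"],
                "ref": row["ref"],
                "alt": row["alt"],
                "gene": row["gene"],
                "n_probands": len(carriers),
            }
        )
        if row["gene"]:
            gene_families.setdefault(row["gene"], set()).update(
                family_of_proband[pid] for pid in carriers
            )
    variant_table = pd.DataFrame(
        variant_rows, columns=["chrom", "pos", "ref", "alt", "gene", "n_probands"]
    )
    gene_table = pd.DataFrame(
        [{"gene": g, "n_families": len(fams)} for g, fams in sorted(gene_families.items())],
        columns=["gene", "n_families"],
    )
    variant_hist = (
        variant_table["n_probands"].value_counts().sort_index().to_dict()
        if len(variant_table)
        else {}
    )
    gene_hist = (
        gene_table["n_families"].value_counts().sort_index().to_dict()
        if len(gene_table)
        else {}
    )
    return {
        "variant_table": variant_table,
        "gene_table": gene_table,
        "variant_histogram": {int(k): int(v) for k, v in variant_hist.items()},
        "gene_histogram": {int(k): int(v) for k, v in gene_hist.items()},
    }


def subset_reports(
    rvis: pd.DataFrame,
    records_by_key: Mapping[tuple, VariantRecord],
    proband_ids: Sequence[str],
) -> dict[str, pd.DataFrame]:
    """Stop-gain, ClinVar-pathogenic, and proband-homozygous subsets.

    The criteria are independent, so one variant may appear in several
    subsets; homozygosity requires a proband with two alt alleles.
    """
    stop_gain = rvis[rvis["consequence"] == "stop_gain"]
    clinvar = rvis[rvis["clinvar"].isin(["pathogenic", "likely_pathogenic"])]

    def _hom(row) -> bool:
        rec = records_by_key.get((row["chrom"], row["pos"], row["ref"], row["alt"]))
        if rec is None:
            return False
        return any(
            (c := rec.calls.get(pid)) is not None and c.allele_count_alt == 2
            for pid in proband_ids
        )

    hom_mask = rvis.apply(_hom, axis=1) if len(rvis) else pd.Series(dtype=bool)
    homozygous = rvis[hom_mask] if len(rvis) else rvis
    return {
        "stop_gain": stop_gain.reset_index(drop=True),
        "clinvar_pathogenic": clinvar.reset_index(drop=True),
        "proband_homozygous": homozygous.reset_index(drop=True),
    }
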