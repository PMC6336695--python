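"""Genotype- and site-level quality control for multi-sample exome VCFs.

The cascade mirrors family-based WES practice: individual calls outside a
depth window (20-250X) or below GQ 20 are *blanked* (set missing without
touching depth/quality); then whole sites are dropped, in fixed order, when
they are indels, have call rate < 80%, have the alt allele called in more
than 30% of individuals (a joint-calling artifact signature in a small
related cohort), or lie off the autosomes.  Each dropped site gets exactly
the first failing reason, so per-reason counts depend on (and pin) the
cascade order.

Call-rate and carrier-fraction denominators are *all* individuals in the
cohort, not just non-missing calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import FamsegError
from .pedigree import Pedigree
from .vcfio import GenotypeCall, VariantRecord, read_vcf, write_vcf

__all__ = [
    "QcThresholds",
    "QcReport",
    "REASON_ORDER",
    "blank_genotype",
    "blank_record",
    "site_filter",
    "apply_site_filters",
    "qc_pipeline",
    "proband_carrier_set",
    "is_autosome",
]

REASON_ORDER = ("indel", "low_call_rate", "excess_alt_carriers", "non_autosome")

_AUTOSOMES = {str(i) for i in range(1, 23)}


def is_autosome(chrom: str) -> bool:
    name = chrom.lower()
    if name.startswith("chr"):
        name = name[3:]
    return name in _AUTOSOMES


@dataclass(frozen=True)
class QcThresholds:
    min_depth: int = 20
    max_depth: int = 250
    min_gq: float = 20.0
    min_call_rate: float = 0.80
    max_alt_carrier_fraction: float = 0.30
    autosomes_only: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.min_call_rate <= 1.0:
            raise ValueError("min_call_rate must be in (0, 1]")
        if not 0.0 < self.max_alt_carrier_fraction <= 1.0:
            raise ValueError("max_alt_carrier_fraction must be in (0, 1]")
        if self.min_depth >= self.max_depth:
            raise ValueError("min_depth must be < max_depth")


@dataclass
class QcReport:
    """Counts through the cascade; ``kept + sum(dropped) == n_input``."""

    n_input: int = 0
    n_kept: int = 0
    n_genotypes_blanked: int = 0
    dropped: dict[str, int] = field(
        default_factory=lambda: {r: 0 for r in REASON_ORDER}
    )

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_kept": self.n_kept,
            "n_genotypes_blanked": self.n_genotypes_blanked,
            "dropped": dict(self.dropped),
        }


def blank_genotype(call: GenotypeCall, t: QcThresholds = QcThresholds()) -> GenotypeCall:
    """Blank the genotype (keep depth/quality untouched) when the call fails
    the depth window or GQ floor; missing depth/quality counts as failing."""
    ok = (
        call.depth is not None
        and call.quality is not None
        and t.min_depth <= call.depth <= t.max_depth
        and call.quality >= t.min_gq
    )
    if ok:
        return call
    return replace(call, allele_count_alt=None)


def blank_record(v: VariantRecord, t: QcThresholds = QcThresholds()) -> tuple[VariantRecord, int]:
    """Apply genotype blanking to every call; returns (record, n_newly_blanked)."""
    new_calls = {}
    n_blanked = 0
    for iid, call in v.calls.items():
        out = blank_genotype(call, t)
        if out.allele_count_alt is None and call.allele_count_alt is not None:
            n_blanked += 1
        new_calls[iid] = out
    return VariantRecord(v.chrom, v.pos, v.ref, v.alt, new_calls), n_blanked


def site_filter(
    v: VariantRecord,
    t: QcThresholds = QcThresholds(),
    n_individuals: int | None = None,
) -> tuple[bool, str | None]:
    """Keep/drop decision with the first failing reason in cascade order.

    Assumes genotype blanking has already been applied.  ``n_individuals``
    defaults to the number of calls on the record and is the denominator for
    both the call rate and the alt-carrier fraction.
    """
    n = n_individuals if n_individuals is not None else len(v.calls)
    if n == 0:
        raise FamsegError(f"site {v.key}: zero individuals")
    if v.is_indel:
        return False, "indel"
    if v.n_called() / n < t.min_call_rate:
        return False, "low_call_rate"
    if len(v.alt_carriers()) / n > t.max_alt_carrier_fraction:  # strictly 'more than'
        return False, "excess_alt_carriers"
    if t.autosomes_only and not is_autosome(v.chrom):
        return False, "non_autosome"
    return True, None


def apply_site_filters(
    records: Iterable[VariantRecord],
    t: QcThresholds = QcThresholds(),
    n_individuals: int | None = None,
) -> tuple[list[VariantRecord], QcReport, list[dict]]:
    """Blank genotypes then run the site cascade over all records."""
    report = QcReport()
    kept: list[VariantRecord] = []
    decisions: list[dict] = []
    for rec in records:
        report.n_input += 1
        blanked, n_blanked = blank_record(rec, t)
        report.n_genotypes_blanked += n_blanked
        keep, reason = site_filter(blanked, t, n_individuals)
        decisions.append(
            {
                "chrom": rec.chrom,
                "pos": rec.pos,
                "ref": rec.ref,
                "alt": rec.alt,
                "decision": "keep" if keep else "drop",
                "reason": reason or "",
            }
        )
        if keep:
            kept.append(blanked)
            report.n_kept += 1
        else:
            report.dropped[reason] += 1
    return kept, report, decisions


def qc_pipeline(
    vcf: str | Path,
    pedigrees: Sequence[Pedigree],
    t: QcThresholds = QcThresholds(),
    out_vcf: str | Path | None = None,
    out_report_tsv: str | Path | None = None,
) -> tuple[list[VariantRecord], QcReport]:
    """Read a multi-sample VCF, verify samples against the pedigrees, and run
    the full QC cascade; optionally write the filtered VCF and a per-site
    decision table."""
    records, samples = read_vcf(vcf)
    members = {m.individual_id for ped in pedigrees for m in ped}
    orphans = sorted(set(samples) - members)
    if orphans:
        raise FamsegError(f"VCF samples absent from pedigrees: {orphans}")
    if not samples:
        raise FamsegError("VCF contains no samples")
    kept, report, decisions = apply_site_filters(records, t, n_individuals=len(samples))
    if out_vcf is not None:
        write_vcf(kept, samples, out_vcf)
    if out_report_tsv is not None:
        pd.DataFrame(
            decisions, columns=["chrom", "pos", "ref", "alt", "decision", "reason"]
        ).to_csv(out_report_tsv, sep="\t", index=False)
    return kept, report


def proband_carrier_set(
    records: Iterable[VariantRecord], proband_ids: Iterable[str]
) -> list[VariantRecord]:
    """Records where at least one proband carries the alt allele (het or hom)."""
    probands = list(proband_ids)
    if not probands:
        raise FamsegError("proband_ids must be non-empty")
    records = list(records)
    known = {iid for rec in records for iid in rec.calls}
    if records:
        unknown = sorted(set(probands) - known)
        if unknown:
            raise FamsegError(f"unknown proband ids: {unknown}")
    out = []
    for rec in records:
        for pid in probands:
            call = rec.calls.get(pid)
            if call is not None and call.allele_count_alt is not None and call.allele_count_alt >= 1:
                out.append(rec)
                break
    return out
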