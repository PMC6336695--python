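"""VCF and annotation-table I/O.

Reading goes through :mod:`cyvcf2` (plain or bgzipped VCF v4.x with GT/DP/GQ
FORMAT fields); multiallelic sites are decomposed into one biallelic record
per alt allele.  Writing uses a minimal deterministic text emitter so that a
fixed simulation seed yields byte-identical files; emitted files round-trip
through the reader.

Annotation tables are TSV with header
``chrom pos ref alt gene consequence cadd_phred clinvar panel:<NAME> ...``
(one column per population panel; empty cells mean unobserved).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .errors import FamsegError

__all__ = [
    "GenotypeCall",
    "VariantRecord",
    "AnnotationRecord",
    "read_vcf",
    "write_vcf",
    "read_annotations",
    "write_annotations",
    "annotations_by_key",
]

CONSEQUENCES = ("stop_gain", "missense", "splice", "synonymous", "intronic", "other")
CLINVAR_CLASSES = ("pathogenic", "likely_pathogenic", "other", "absent")


@dataclass(frozen=True)
class GenotypeCall:
    """One individual's call at one site; ``allele_count_alt`` of ``None``
    marks a missing (or blanked) genotype."""

    individual_id: str
    allele_count_alt: int | None
    depth: int | None = None
    quality: float | None = None


@dataclass
class VariantRecord:
    """One biallelic site (post-decomposition) with per-individual calls."""

    chrom: str
    pos: int
    ref: str
    alt: str
    calls: dict[str, GenotypeCall] = field(default_factory=dict)

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    def alt_carriers(self) -> list[str]:
        return [
            i
            for i, c in self.calls.items()
            if c.allele_count_alt is not None and c.allele_count_alt >= 1
        ]

    def n_called(self) -> int:
        return sum(1 for c in self.calls.values() if c.allele_count_alt is not None)


@dataclass(frozen=True)
class AnnotationRecord:
    """Population frequencies and deleteriousness annotation for one site.

    ``panel_freqs`` holds alt-allele frequencies per population panel; a
    panel absent from the mapping means the variant is unobserved there.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""
    consequence: str = "other"
    cadd_phred: float | None = None
    clinvar: str = "absent"
    panel_freqs: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for panel, freq in self.panel_freqs.items():
            if not 0.0 <= freq <= 1.0:
                raise ValueError(f"panel {panel} frequency {freq} outside [0, 1]")
        if self.cadd_phred is not None and self.cadd_phred < 0:
            raise ValueError("cadd_phred must be >= 0")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        if self.clinvar not in CLINVAR_CLASSES:
            raise ValueError(f"unknown ClinVar class {self.clinvar!r}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    def max_panel_maf(self) -> float | None:
        """Largest minor-allele frequency across panels reporting the site;
        ``None`` when no panel observed it (unobserved = rare by convention)."""
        if not self.panel_freqs:
            return None
        return max(min(f, 1.0 - f) for f in self.panel_freqs.values())


# -- VCF ---------------------------------------------------------------------


def read_vcf(path: str | Path) -> tuple[list[VariantRecord], list[str]]:
    """Read a VCF into decomposed biallelic records; returns (records, samples)."""
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    records: list[VariantRecord] = []
    for var in vcf:
        try:
            depths = var.format("DP")
        except KeyError:
            depths = None
        try:
            quals = var.format("GQ")
        except KeyError:
            quals = None
        gts = var.genotypes  # [allele1, allele2, phased] per sample
        for ai, alt in enumerate(var.ALT, start=1):
            calls: dict[str, GenotypeCall] = {}
            for si, sample in enumerate(samples):
                a1, a2 = gts[si][0], gts[si][1]
                if a1 < 0 or a2 < 0:
                    count: int | None = None
                else:
                    count = int(a1 == ai) + int(a2 == ai)
                dp = None
                if depths is not None:
                    d = int(np.ravel(depths[si])[0])
                    dp = d if d >= 0 else None
                gq = None
                if quals is not None:
                    qv = float(np.ravel(quals[si])[0])
                    gq = qv if qv >= 0 and not math.isnan(qv) else None
                calls[sample] = GenotypeCall(sample, count, dp, gq)
            records.append(
                VariantRecord(str(var.CHROM), int(var.POS), str(var.REF), str(alt), calls)
            )
    vcf.close()
    return records, samples


_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=famseg
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
"""

_GT_STRING = {0: "0/0", 1: "0/1", 2: "1/1", None: "./."}


def write_vcf(
    records: Sequence[VariantRecord], samples: Sequence[str], path: str | Path
) -> Path:
    """Write biallelic records as a plain-text VCF (deterministic byte layout)."""
    path = Path(path)
    chroms = list(dict.fromkeys(r.chrom for r in records))
    with path.open("w") as fh:
        fh.write(_VCF_HEADER)
        for chrom in chroms:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for rec in records:
            cols = [
                rec.chrom,
                str(rec.pos),
                ".",
                rec.ref,
                rec.alt,
                ".",
                "PASS",
                ".",
                "GT:DP:GQ",
            ]
            for s in samples:
                call = rec.calls.get(s)
                if call is None:
                    cols.append("./.:.:.")
                    continue
                dp = "." if call.depth is None else str(int(call.depth))
                gq = "." if call.quality is None else str(int(round(call.quality)))
                cols.append(f"{_GT_STRING[call.allele_count_alt]}:{dp}:{gq}")
            fh.write("\t".join(cols) + "\n")
    return path


# -- annotation tables -------------------------------------------------------


def read_annotations(path: str | Path) -> list[AnnotationRecord]:
    """Read an annotation TSV (``panel:<NAME>`` columns become panel_freqs)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "ref", "alt", "gene", "consequence", "cadd_phred", "clinvar"}
    missing = required - set(df.columns)
    if missing:
        raise FamsegError(f"annotation table lacks columns: {sorted(missing)}")
    panel_cols = [c for c in df.columns if c.startswith("panel:")]
    out: list[AnnotationRecord] = []
    for row in df.to_dict("records"):
        freqs = {
            col.split(":", 1)[1]: float(row[col])
            for col in panel_cols
            if pd.notna(row[col])
        }
        out.append(
            AnnotationRecord(
                chrom=str(row["chrom"]),
                pos=int(row["pos"]),
                ref=str(row["ref"]),
                alt=str(row["alt"]),
                gene="" if pd.isna(row["gene"]) else str(row["gene"]),
                consequence=str(row["consequence"]),
                cadd_phred=None if pd.isna(row["cadd_phred"]) else float(row["cadd_phred"]),
                clinvar=str(row["clinvar"]),
                panel_freqs=freqs,
            )
        )
    return out


def write_annotations(
    annotations: Sequence[AnnotationRecord], path: str | Path
) -> Path:
    panels = sorted({p for a in annotations for p in a.panel_freqs})
    rows = []
    for a in annotations:
        row = {
            "chrom": a.chrom,
            "pos": a.pos,
            "ref": a.ref,
            "alt": a.alt,
            "gene": a.gene,
            "consequence": a.consequence,
            "cadd_phred": a.cadd_phred,
            "clinvar": a.clinvar,
        }
        for p in panels:
            row[f"panel:{p}"] = a.panel_freqs.get(p)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return Path(path)


def annotations_by_key(
    annotations: Iterable[AnnotationRecord],
) -> dict[tuple[str, int, str, str], AnnotationRecord]:
    return {a.key: a for a in annotations}
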