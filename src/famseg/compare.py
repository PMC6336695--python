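"""Headline comparison of the two discovery arms, plus carrier arithmetic.

The comparison crosses the conventional rare-variant list (RVIS) with the
co-segregating set (C-SV: cumulative two-point LOD at or above a threshold,
1.0 by default) and characterises the C-SV: how many are common
(max panel MAF > 1%, the exact complement of the RVIS rarity criterion, so
the rare/common dichotomy is exhaustive with missing frequencies counted as
rare) and how many lack informatics support (CADD < 20 or missing).

The carrier-frequency calculator quantifies the complex-inheritance
argument: under Hardy-Weinberg a dominant variant at allele frequency q is
carried by 1-(1-q)^2 of the population, and independent variants co-occur
in the product of their carrier fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .errors import FamsegError
from .linkage import LinkageResult
from .vcfio import AnnotationRecord

__all__ = [
    "ComparisonReport",
    "compare_sets",
    "carrier_frequency",
    "co_occurrence_frequency",
    "chromosome_distribution",
]


def carrier_frequency(allele_freq: float) -> float:
    """Population fraction carrying >=1 copy under Hardy-Weinberg."""
    if not 0.0 <= allele_freq <= 1.0:
        raise ValueError(f"allele frequency must be in [0, 1], got {allele_freq}")
    return 1.0 - (1.0 - allele_freq) ** 2


def co_occurrence_frequency(allele_freqs: Sequence[float]) -> float:
    """Joint carrier fraction of independent variants (product of carriers)."""
    freqs = list(allele_freqs)
    if not freqs:
        raise FamsegError("co_occurrence_frequency needs at least one frequency")
    out = 1.0
    for q in freqs:
        out *= carrier_frequency(q)
    return out


@dataclass
class ComparisonReport:
    n_rvis: int
    n_csv: int
    n_overlap: int
    lod_threshold: float
    fraction_rvis_with_lod_ge: dict[float, float]
    fraction_csv_common: float
    fraction_csv_without_informatics: float
    per_chromosome_csv: dict[str, int]
    top_csv: pd.DataFrame = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.n_overlap > min(self.n_rvis, self.n_csv):
            raise ValueError("overlap cannot exceed either set size")

    def to_dict(self) -> dict:
        return {
            "n_rvis": self.n_rvis,
            "n_csv": self.n_csv,
            "n_overlap": self.n_overlap,
            "lod_threshold": self.lod_threshold,
            "fraction_rvis_with_lod_ge": {
                str(k): v for k, v in self.fraction_rvis_with_lod_ge.items()
            },
            "fraction_csv_common": self.fraction_csv_common,
            "percent_csv_common": round(100.0 * self.fraction_csv_common),
            "fraction_csv_without_informatics": self.fraction_csv_without_informatics,
            "percent_csv_without_informatics": round(
                100.0 * self.fraction_csv_without_informatics
            ),
            "per_chromosome_csv": dict(self.per_chromosome_csv),
        }


def _rvis_keys(rvis: pd.DataFrame) -> set[tuple]:
    required = {"chrom", "pos", "ref", "alt"}
    if not required.issubset(rvis.columns):
        raise FamsegError(
            f"RVIS table must carry key columns {sorted(required)}"
        )
    return {
        (str(r.chrom), int(r.pos), str(r.ref), str(r.alt))
        for r in rvis.itertuples(index=False)
    }


def compare_sets(
    rvis: pd.DataFrame,
    linkage_results: Sequence[LinkageResult],
    annotations: Mapping[tuple, AnnotationRecord],
    lod_threshold: float = 1.0,
    rvis_lod_fractions: Sequence[float] = (0.5, 1.0),
    max_maf_rare: float = 0.01,
    min_cadd: float = 20.0,
    top_k: int = 10,
) -> ComparisonReport:
    """Cross the RVIS list with the linkage scan and characterise the C-SV."""
    for res in linkage_results:
        if res.variant_key is None or len(res.variant_key) != 4:
            raise FamsegError("linkage results must carry (chrom,pos,ref,alt) keys")
    rvis_keys = _rvis_keys(rvis)
    lod_by_key = {res.variant_key: res.cumulative_lod for res in linkage_results}
    csv_keys = {k for k, lod in lod_by_key.items() if lod >= lod_threshold}
    overlap = rvis_keys & csv_keys

    frac_rvis_lod: dict[float, float] = {}
    for thr in rvis_lod_fractions:
        if rvis_keys:
            n = sum(1 for k in rvis_keys if lod_by_key.get(k, float("-inf")) >= thr)
            frac_rvis_lod[thr] = n / len(rvis_keys)
        else:
            frac_rvis_lod[thr] = 0.0

    n_common = 0
    n_no_informatics = 0
    for key in csv_keys:
        ann = annotations.get(key)
        maf = ann.max_panel_maf() if ann is not None else None
        if maf is not None and maf > max_maf_rare:
            n_common += 1
        cadd = ann.cadd_phred if ann is not None else None
        if cadd is None or cadd < min_cadd:
            n_no_informatics += 1
    n_csv = len(csv_keys)
    frac_common = n_common / n_csv if n_csv else 0.0
    frac_no_info = n_no_informatics / n_csv if n_csv else 0.0

    top = sorted(
        (res for res in linkage_results if res.variant_key in csv_keys),
        key=lambda r: -r.cumulative_lod,
    )[:top_k]
    top_df = pd.DataFrame(
        [
            {
                "chrom": r.variant_key[0],
                "pos": r.variant_key[1],
                "ref": r.variant_key[2],
                "alt": r.variant_key[3],
                "cumulative_lod": r.cumulative_lod,
                "theta": r.cumulative_theta,
                "classification": r.classification,
            }
            for r in top
        ],
        columns=["chrom", "pos", "ref", "alt", "cumulative_lod", "theta", "classification"],
    )
    return ComparisonReport(
        n_rvis=len(rvis_keys),
        n_csv=n_csv,
        n_overlap=len(overlap),
        lod_threshold=lod_threshold,
        fraction_rvis_with_lod_ge=frac_rvis_lod,
        fraction_csv_common=frac_common,
        fraction_csv_without_informatics=frac_no_info,
        per_chromosome_csv=chromosome_distribution(sorted(csv_keys)),
        top_csv=top_df,
    )


def _chrom_sort_key(chrom: str):
    name = chrom[3:] if chrom.lower().startswith("chr") else chrom
    return (0, int(name)) if name.isdigit() else (1, name)


def chromosome_distribution(keys: Sequence[tuple]) -> dict[str, int]:
    """Per-chromosome counts in natural chromosome order; sums to len(keys)."""
    counts: dict[str, int] = {}
    for key in keys:
        counts[str(key[0])] = counts.get(str(key[0]), 0) + 1
    return {c: counts[c] for c in sorted(counts, key=_chrom_sort_key)}


def plot_chromosome_distribution(counts: Mapping[str, int], path) -> None:
    """Bar chart of per-chromosome C-SV counts (optional output)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3))
    chroms = list(counts)
    ax.bar(range(len(chroms)), [counts[c] for c in chroms], color="#356a9e")
    ax.set_xticks(range(len(chroms)), chroms)
    ax.set_xlabel("chromosome")
    ax.set_ylabel("co-segregating variants")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
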