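"""End-to-end orchestration: simulate -> qc -> rvis -> linkage -> compare.

Each stage writes its outputs under one run directory and appends them to a
checksummed manifest, so a fixed seed and configuration reproduce the run
byte-for-byte.  A stage failure halts downstream stages but the partial
manifest is retained.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .compare import compare_sets
from .errors import ConfigError
from .linkage import (
    DEFAULT_THETA_GRID,
    DiseaseModel,
    LodThresholds,
    linkage_scan,
)
from .pedigree import read_ped
from .qc import QcThresholds, proband_carrier_set, qc_pipeline
from .rvis import RvisCriteria, proband_sharing, rvis_table, subset_reports
from .simulate import SimulationConfig, simulate_cohort
from .vcfio import annotations_by_key, read_annotations

logger = logging.getLogger("famseg")

__all__ = ["RunConfig", "run_all", "read_probands_file", "linkage_results_frame"]


@dataclass
class RunConfig:
    out_dir: Path
    vcf: Path | None = None
    ped: Path | None = None
    annotations: Path | None = None
    probands: list[str] = field(default_factory=list)
    simulate: bool = False
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    qc_thresholds: QcThresholds = field(default_factory=QcThresholds)
    rvis_criteria: RvisCriteria = field(default_factory=RvisCriteria)
    disease: DiseaseModel = field(default_factory=DiseaseModel)
    theta_grid: tuple[float, ...] = DEFAULT_THETA_GRID
    lod_thresholds: LodThresholds = field(default_factory=LodThresholds)
    marker_freq_source: str = "founder"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict = {}
        if "out_dir" not in raw:
            raise ConfigError("config must set out_dir")
        kwargs["out_dir"] = Path(raw["out_dir"])
        for key in ("vcf", "ped", "annotations"):
            if raw.get(key):
                kwargs[key] = Path(raw[key])
        for key in ("probands", "simulate", "marker_freq_source", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        if "theta_grid" in raw:
            kwargs["theta_grid"] = tuple(raw["theta_grid"])
        for key, klass in (
            ("qc_thresholds", QcThresholds),
            ("rvis_criteria", RvisCriteria),
            ("disease", DiseaseModel),
            ("lod_thresholds", LodThresholds),
        ):
            if key in raw:
                kwargs[key] = klass(**raw[key])
        if "simulation" in raw:
            kwargs["simulation"] = SimulationConfig(**raw["simulation"])
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def read_probands_file(path: str | Path) -> list[tuple[str, str]]:
    """Two-column sidecar: family id, individual id (tab/space separated)."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) == 1:
            out.append(parts[0])
        else:
            out.append((parts[0], parts[1]))
    return out


def linkage_results_frame(results, skipped) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {
            "chrom": r.variant_key[0],
            "pos": r.variant_key[1],
            "ref": r.variant_key[2],
            "alt": r.variant_key[3],
            "cumulative_lod": r.cumulative_lod,
            "cumulative_theta": r.cumulative_theta,
            "cumulative_lod_theta0": r.cumulative_lod_at_zero,
            "classification": r.classification,
            "skip_reason": "",
        }
        for fid, lod in r.family_max_lod.items():
            row[f"max_lod:{fid}"] = lod
            row[f"theta_at_max:{fid}"] = r.family_theta_at_max[fid]
        rows.append(row)
    for s in skipped:
        rows.append(
            {
                "chrom": s["variant_key"][0],
                "pos": s["variant_key"][1],
                "ref": s["variant_key"][2],
                "alt": s["variant_key"][3],
                "skip_reason": s["reason"] + ":" + ",".join(s["families"]),
            }
        )
    return pd.DataFrame(rows)


def run_all(cfg: RunConfig) -> dict:
    """Run every stage; returns the manifest (also written to manifest.json)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": [], "status": "ok"}
    manifest_path = out / "manifest.json"

    def record(stage: str, *paths: Path) -> None:
        for p in paths:
            manifest["stages"].append(
                {"stage": stage, "file": str(p), "sha256": _sha256(p)}
            )
        manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")

    stage = "setup"
    try:
        vcf, ped_path, ann_path = cfg.vcf, cfg.ped, cfg.annotations
        probands = list(cfg.probands)
        if cfg.simulate:
            stage = "simulate"
            logger.info("simulating cohort (seed=%s)", cfg.simulation.seed)
            cohort = simulate_cohort(cfg.simulation, out / "cohort")
            vcf, ped_path, ann_path = cohort.vcf, cohort.ped, cohort.annotations
            probands = list(cohort.probands.values())
            record(stage, cohort.vcf, cohort.ped, cohort.annotations,
                   cohort.truth, cohort.probands_file, cohort.config_file)
        for name, p in (("vcf", vcf), ("ped", ped_path)):
            if p is None:
                raise ConfigError(f"{name} path required (or set simulate: true)")

        stage = "qc"
        pedigrees = read_ped(ped_path, probands=probands or None)
        qc_vcf = out / "qc.vcf"
        qc_tsv = out / "qc_sites.tsv"
        records, report = qc_pipeline(
            vcf, pedigrees, cfg.qc_thresholds, out_vcf=qc_vcf, out_report_tsv=qc_tsv
        )
        summary_path = out / "qc_summary.json"
        summary_path.write_text(json.dumps(report.to_dict(), indent=2) + "\n")
        logger.info(
            "qc: %d sites in, %d kept, dropped=%s, %d genotypes blanked",
            report.n_input, report.n_kept, report.dropped, report.n_genotypes_blanked,
        )
        record(stage, qc_vcf, qc_tsv, summary_path)

        stage = "rvis"
        if ann_path is None:
            raise ConfigError("annotations path required for the rvis stage")
        if not probands:
            probands = [m.individual_id for p in pedigrees for m in p.probands]
        if not probands:
            raise ConfigError("no probands given (config, sidecar, or simulation)")
        annotations = annotations_by_key(read_annotations(ann_path))
        carriers = proband_carrier_set(records, probands)
        logger.info("%d of %d QC-passed sites carried by >=1 proband",
                    len(carriers), len(records))
        rvis = rvis_table(carriers, annotations, cfg.rvis_criteria, probands)
        rvis_path = out / "rvis.tsv"
        rvis.to_csv(rvis_path, sep="\t", index=False)
        family_of = {
            m.individual_id: p.family_id for p in pedigrees for m in p.members
        }
        outputs = [rvis_path]
        if len(probands) >= 2:
            sharing = proband_sharing(rvis, probands, family_of)
            for name in ("variant_table", "gene_table"):
                p = out / f"rvis_sharing_{name}.tsv"
                sharing[name].to_csv(p, sep="\t", index=False)
                outputs.append(p)
        records_by_key = {r.key: r for r in carriers}
        for name, df in subset_reports(rvis, records_by_key, probands).items():
            p = out / f"rvis_{name}.tsv"
            df.to_csv(p, sep="\t", index=False)
            outputs.append(p)
        record(stage, *outputs)

        stage = "linkage"
        scan = linkage_scan(
            carriers,
            pedigrees,
            cfg.disease,
            theta_grid=cfg.theta_grid,
            marker_freq_source=cfg.marker_freq_source,
            annotations=annotations,
            thresholds=cfg.lod_thresholds,
        )
        linkage_path = out / "linkage.tsv"
        linkage_results_frame(scan.results, scan.skipped).to_csv(
            linkage_path, sep="\t", index=False
        )
        logger.info("linkage: %d results, %d skipped", len(scan.results),
                    len(scan.skipped))
        record(stage, linkage_path)

        stage = "compare"
        report_cmp = compare_sets(
            rvis, scan.results, annotations,
            lod_threshold=cfg.lod_thresholds.cosegregating,
            max_maf_rare=cfg.rvis_criteria.max_maf,
            min_cadd=cfg.rvis_criteria.min_cadd,
        )
        cmp_path = out / "comparison.json"
        cmp_path.write_text(json.dumps(report_cmp.to_dict(), indent=2) + "\n")
        top_path = out / "top_csv.tsv"
        report_cmp.top_csv.to_csv(top_path, sep="\t", index=False)
        record(stage, cmp_path, top_path)
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
        raise
    return manifest
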