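"""End-to-end orchestration: load or simulate a cohort, harmonize,
compute metrics and architecture features, run the statistical layer
and the clustering, and emit a manifest of every artifact with content
hashes so a run is verifiable and reproducible from its seed."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from . import architecture as arch
from . import cluster as cl
from . import io as ptm_io
from . import metrics as met
from . import stats as st
from .synthetic import Cohort, SyntheticConfig, cohort_to_files, generate_cohort


@dataclass
class PipelineConfig:
    """Single config object driving every stage."""

    # either a directory of input files (fasta + tsv tables) ...
    input_dir: Optional[str] = None
    # ... or a synthetic cohort specification
    synthetic: Optional[dict] = None
    predominant_threshold: float = 0.60
    sensitivity_thresholds: tuple[float, ...] = (0.50, 0.60, 0.70)
    hotspot_half_window: int = 7
    hotspot_min_neighbors: int = 5
    crosstalk_mode: str = "residue"
    sparsity_threshold: float = 0.01
    k_min: int = 2
    k_max: int = 10
    cluster_method: str = "agglomerative_ward"
    q_threshold: float = 0.05
    seed: int = 0
    out_dir: str = "ptmatlas_run"

    def validate(self) -> None:
        if self.input_dir is None and self.synthetic is None:
            raise ValueError("config needs either input_dir or a synthetic section")
        if not (0.0 < self.predominant_threshold <= 1.0):
            raise ValueError("predominant_threshold must lie in (0, 1]")
        for t in self.sensitivity_thresholds:
            if not (0.0 < t <= 1.0):
                raise ValueError(f"sensitivity threshold {t} outside (0, 1]")
        if self.hotspot_half_window < 1:
            raise ValueError("hotspot_half_window must be >= 1")
        if self.hotspot_min_neighbors < 1:
            raise ValueError("hotspot_min_neighbors must be >= 1")
        if self.crosstalk_mode not in ("residue", "window"):
            raise ValueError(f"unknown crosstalk mode {self.crosstalk_mode!r}")
        if not (0.0 <= self.sparsity_threshold < 1.0):
            raise ValueError("sparsity_threshold must lie in [0, 1)")
        if self.k_min < 2 or self.k_max < self.k_min:
            raise ValueError("k range must satisfy 2 <= k_min <= k_max")
        if self.cluster_method not in ("agglomerative_ward", "kmeans"):
            raise ValueError(f"unknown cluster method {self.cluster_method!r}")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        if isinstance(cfg.sensitivity_thresholds, list):
            cfg.sensitivity_thresholds = tuple(cfg.sensitivity_thresholds)
        return cfg


@dataclass
class RunReport:
    out_dir: str
    manifest: dict[str, str]            # relative path -> sha256
    summary: dict
    config: dict = field(default_factory=dict)


def compute_metrics(
    cohort: Cohort,
    predominant_threshold: float = 0.60,
    half_window: int = 7,
    min_neighbors: int = 5,
    crosstalk_mode: str = "residue",
) -> pd.DataFrame:
    """Metrics table with architecture counts merged in — the
    per-enzyme row used by the statistics and clustering stages."""
    eligibility = met.EligibilityMap().fit_fallback(cohort.sites)
    table = met.enzyme_metrics_table(
        cohort.enzymes, cohort.sites, eligibility, predominant_threshold
    )
    counts = arch.architecture_counts(
        cohort.enzymes, cohort.sites, cohort.regions, cohort.variants,
        half_window, min_neighbors, crosstalk_mode,
    )
    return table.join(counts)


def _write(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run(config: PipelineConfig) -> RunReport:
    """Execute every stage in order and write all artifacts.

    Stage order: load/generate -> harmonize -> metrics -> architecture
    -> statistics -> clustering -> characterization.  Any stage error
    aborts with the stage name attached.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "events.jsonl"
    log_fh = open(log_path, "w")

    def log(stage: str, **payload) -> None:
        log_fh.write(json.dumps({"stage": stage, **payload}) + "\n")

    summary: dict = {}
    stage = "load"
    try:
        if config.synthetic is not None:
            syn = SyntheticConfig(**{**config.synthetic, "seed": config.seed})
            cohort = generate_cohort(syn)
            cohort_to_files(cohort, out / "cohort")
        else:
            from .synthetic import load_cohort

            cohort = load_cohort(config.input_dir)
        log(stage, n_enzymes=len(cohort.enzymes), n_sites=len(cohort.sites))

        stage = "harmonize"
        sites, report = ptm_io.harmonize_sites(cohort.sites, cohort.enzymes)
        cohort = Cohort(cohort.enzymes, sites, cohort.regions, cohort.variants,
                        cohort.truth)
        ptm_io.write_catalog(sites, out / "catalog.tsv")
        report.to_json(out / "harmonization_report.json")
        log(stage, n_sites=report.n_sites, n_rejected=len(report.rejections))

        stage = "metrics"
        metrics = compute_metrics(
            cohort, config.predominant_threshold, config.hotspot_half_window,
            config.hotspot_min_neighbors, config.crosstalk_mode,
        )
        _write(metrics, out / "metrics.tsv")
        _write(met.predominant_table(sites, config.predominant_threshold),
               out / "predominant_sites.tsv", index=False)
        scan = met.sensitivity_scan(sites, config.sensitivity_thresholds)
        _write(scan.counts, out / "predominant_sensitivity.tsv")
        summary["median_ptm_density"] = float(metrics["ptm_density"].median())
        log(stage, n_rows=len(metrics))

        stage = "architecture"
        hotspots = []
        crosstalk = []
        by_enzyme: dict[str, list] = {acc: [] for acc in cohort.enzymes}
        for s in sites:
            by_enzyme[s.accession].append(s)
        for acc, enzyme in cohort.enzymes.items():
            esites = by_enzyme[acc]
            hotspots.extend(
                arch.detect_hotspots(esites, enzyme.length,
                                     config.hotspot_half_window,
                                     config.hotspot_min_neighbors)
            )
            crosstalk.extend(arch.detect_crosstalk(esites, config.crosstalk_mode,
                                                   config.hotspot_half_window))
        _write(arch.hotspot_table(hotspots), out / "hotspots.tsv", index=False)
        _write(arch.crosstalk_table(crosstalk), out / "crosstalk.tsv", index=False)
        locs, enrichment_table = arch.localize_sites(sites, cohort.regions,
                                                     cohort.enzymes)
        _write(enrichment_table, out / "region_enrichment.tsv", index=False)
        overlaps, overlap_summary = arch.overlap_variants(sites, cohort.variants)
        (out / "mutation_overlap.json").write_text(json.dumps(overlap_summary, indent=2))
        summary["n_hotspot_regions"] = len(hotspots)
        summary["n_crosstalk_residues"] = len(crosstalk)
        log(stage, n_hotspots=len(hotspots), n_crosstalk=len(crosstalk))

        stage = "stats"
        corr_features = ["ptm_density", "ppr_mean", "n_predominant_total",
                         "n_hotspot_regions", "n_crosstalk_residues",
                         "n_mutated_ptm_sites"]
        corr_features = [c for c in corr_features if c in metrics.columns]
        correlations = st.spearman_matrix(metrics[corr_features])
        _write(st.correlation_table(correlations), out / "correlations.tsv",
               index=False)
        for flag, family in st.standard_contrasts(metrics).items():
            _write(st.contrast_frame(family), out / f"contrasts_{flag}.tsv",
                   index=False)
        log(stage, n_correlation_pairs=len(correlations))

        stage = "clustering"
        fm = cl.build_feature_matrix(metrics, cohort.enzymes)
        fm = cl.filter_and_normalize(fm, config.sparsity_threshold)
        scan_result = cl.silhouette_scan(
            fm, range(config.k_min, config.k_max + 1), config.cluster_method,
            config.seed,
        )
        k = scan_result.selected_k
        result = (
            cl.agglomerative_cluster(fm, k)
            if config.cluster_method == "agglomerative_ward"
            else cl.kmeans_cluster(fm, k, config.seed)
        )
        result.labels.rename("cluster").to_frame().to_csv(
            out / "cluster_assignments.tsv", sep="\t"
        )
        (out / "silhouette_scan.json").write_text(
            json.dumps(
                {
                    "selected_k": scan_result.selected_k,
                    "method": scan_result.selected_method,
                    "per_k": {
                        str(kk): {m: (None if pd.isna(v) else float(v))
                                  for m, v in row.items()}
                        for kk, row in scan_result.per_k.iterrows()
                    },
                },
                indent=2,
            )
        )
        if result.linkage_tree is not None:
            pd.DataFrame(
                result.linkage_tree,
                columns=["child_a", "child_b", "distance", "n_members"],
            ).to_csv(out / "linkage_tree.tsv", sep="\t", index=False)
        scores, evr = cl.pca_project(fm, 2, config.seed)
        _write(scores, out / "pca_scores.tsv")
        summary["selected_k"] = k
        summary["silhouette"] = result.silhouette
        log(stage, selected_k=k, silhouette=result.silhouette)

        stage = "characterization"
        pathway_sets: dict[str, set] = {}
        for acc, enzyme in cohort.enzymes.items():
            for p in enzyme.pathways:
                pathway_sets.setdefault(p, set()).add(acc)
        character = cl.characterize_clusters(result, metrics, pathway_sets,
                                             q_threshold=config.q_threshold)
        _write(st.contrast_frame(character["contrasts"]),
               out / "cluster_contrasts.tsv", index=False)
        enrich_frames = []
        for cid, results in character["enrichment"].items():
            frame = st.enrichment_frame(results)
            frame.insert(0, "cluster", cid)
            enrich_frames.append(frame)
        _write(pd.concat(enrich_frames, ignore_index=True)
               if enrich_frames else pd.DataFrame(),
               out / "cluster_enrichment.tsv", index=False)
        summary["cluster_sizes"] = character["cluster_sizes"]
        summary["rate_limiting_fraction"] = character["rate_limiting_fraction"]
        log(stage, cluster_sizes=character["cluster_sizes"])
    except Exception as exc:
        log_fh.close()
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    log_fh.close()

    manifest = {
        str(p.relative_to(out)): _sha256(p)
        for p in sorted(out.rglob("*"))
        if p.is_file() and p.name != "events.jsonl"
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    report = RunReport(str(out), manifest, summary, dataclasses.asdict(config))
    (out / "run_report.json").write_text(
        json.dumps({"summary": summary, "config": dataclasses.asdict(config),
                    "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S")}, indent=2)
    )
    return report
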