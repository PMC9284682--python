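"""End-to-end orchestration: detect, correct (all variants), evaluate, summarize.

One run produces, for a single dataset:

* a batch report (Kruskal-Wallis of p_low by batch, design bias),
* eight correction runs — {uncorrected, batch, plow, both} confounders
  crossed with {outliers kept, outliers removed} — each an adjusted PCA
  with automatically selected penalty weight plus cluster metrics,
* metric deltas of every corrected variant against the uncorrected,
  outliers-kept baseline,
* a JSON summary and per-variant score tables on disk.

Everything is deterministic given the inputs and the config seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from plowbatch.cluster_eval import ClusterMetrics, MetricsDelta, evaluate_clustering, metrics_delta
from plowbatch.correction import (
    ACPCAResult,
    OutlierResult,
    acpca,
    build_confounder,
    detect_quality_outliers,
    select_lambda,
)
from plowbatch.io_core import (
    CountMatrix,
    PipelineConfig,
    SampleTable,
    ValidationError,
    join_counts_samples,
    read_counts,
    read_sample_table,
)
from plowbatch.normalize import differential_expression, log_normalize, regress_out_confounder, NormalizedMatrix
from plowbatch.quality_stats import BatchReport, batch_report

logger = logging.getLogger("plowbatch")

CONFOUNDER_VARIANTS = ("uncorrected", "batch", "plow", "both")
_CONF_USE = {"batch": {"batch"}, "plow": {"p_low"}, "both": {"batch", "p_low"}}


@dataclass
class CorrectionRun:
    variant: str  # e.g. "plow" or "plow_no_outlier"
    confounder: str  # uncorrected | batch | plow | both
    outliers_removed: bool
    result: ACPCAResult
    metrics: ClusterMetrics
    outliers: OutlierResult
    lambda_converged: bool
    deg_count: int | None = None

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "confounder": self.confounder,
            "outliers_removed": self.outliers_removed,
            "lambda": self.result.lam,
            "lambda_converged": self.lambda_converged,
            "penalty_ratios": [float(r) for r in self.result.penalty_ratios],
            "outlier_sample_ids": self.outliers.outlier_sample_ids,
            "metrics": self.metrics.to_dict(),
            "deg_count": self.deg_count,
        }


@dataclass
class DatasetSummary:
    report: BatchReport
    runs: list[CorrectionRun]
    deltas: list[MetricsDelta]
    config: PipelineConfig

    @property
    def baseline(self) -> CorrectionRun:
        matches = [r for r in self.runs if r.variant == "uncorrected"]
        if len(matches) != 1:
            raise ValidationError("summary must contain the uncorrected baseline exactly once")
        return matches[0]

    def to_dict(self) -> dict:
        return {
            "batch_report": self.report.to_dict(),
            "runs": [r.to_dict() for r in self.runs],
            "deltas": [d.to_dict() for d in self.deltas],
            "config": {
                "pseudocount": self.config.pseudocount,
                "de_alpha": self.config.de_alpha,
                "n_components": self.config.n_components,
                "penalty_tol": self.config.penalty_tol,
                "outlier_min_gap": self.config.outlier_min_gap,
                "outlier_threshold": self.config.outlier_threshold,
                "seed": self.config.seed,
            },
        }


def _stage(name: str, t0: float) -> float:
    t1 = time.perf_counter()
    logger.info("stage %-22s %6.2fs", name, t1 - t0)
    return t1


def correct_variant(
    norm: NormalizedMatrix,
    table: SampleTable,
    confounder: str,
    config: PipelineConfig,
) -> tuple[ACPCAResult, bool]:
    """Adjusted PCA for one confounder variant on (already subset) data."""
    X = norm.samples_by_genes()
    X = X - X.mean(axis=0, keepdims=True)
    if confounder == "uncorrected":
        # plain PCA; a batch design is still attached so penalty diagnostics exist
        conf = build_confounder(table, {"batch"})
        return acpca(X, conf, 0.0, k=config.n_components, sample_ids=norm.sample_ids), True
    conf = build_confounder(table, _CONF_USE[confounder])
    lam, converged = select_lambda(X, conf, config.lambda_grid, tol=config.penalty_tol, k=config.n_components)
    return acpca(X, conf, lam, k=config.n_components, sample_ids=norm.sample_ids), converged


def run_pipeline(
    counts: CountMatrix | str | Path,
    samples: SampleTable | str | Path,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> DatasetSummary:
    """Execute normalize -> detect -> correct x 8 -> evaluate -> summarize."""
    config = config or PipelineConfig()
    t0 = time.perf_counter()
    if not isinstance(counts, CountMatrix):
        counts = read_counts(counts)
    if not isinstance(samples, SampleTable):
        samples = read_sample_table(samples)
    table = join_counts_samples(counts, samples)
    t0 = _stage("load", t0)

    norm = log_normalize(counts, config.pseudocount)
    t0 = _stage("normalize", t0)

    report = batch_report(table)
    t0 = _stage("batch_report", t0)

    outliers = detect_quality_outliers(
        table, min_gap=config.outlier_min_gap, fixed_threshold=config.outlier_threshold
    )
    keep_ids = [s for s in table.sample_ids if s not in set(outliers.outlier_sample_ids)]
    if len(keep_ids) < 4:
        raise ValidationError("outlier removal would leave fewer than 4 samples")
    norm_sub = norm.subset_samples(keep_ids)
    table_sub = table.subset(keep_ids)
    t0 = _stage("outliers", t0)

    runs: list[CorrectionRun] = []
    for confounder in CONFOUNDER_VARIANTS:
        for removed in (False, True):
            nm, tb = (norm_sub, table_sub) if removed else (norm, table)
            res, converged = correct_variant(nm, tb, confounder, config)
            metrics = evaluate_clustering(res.scores, tb, n_components=config.n_components)
            deg = None
            if config.compute_de:
                deg = _deg_count(nm, tb, confounder, config)
            variant = confounder + ("_no_outlier" if removed else "")
            runs.append(CorrectionRun(variant, confounder, removed, res, metrics, outliers, converged, deg))
    t0 = _stage("corrections", t0)

    baseline = runs[0].metrics
    deltas = [metrics_delta(baseline, r.metrics, r.variant) for r in runs if r.variant != "uncorrected"]

    summary = DatasetSummary(report, runs, deltas, config)
    if out_dir is not None:
        _write_outputs(summary, Path(out_dir))
        t0 = _stage("write", t0)
    return summary


def _deg_count(norm: NormalizedMatrix, table: SampleTable, confounder: str, config: PipelineConfig) -> int | None:
    groups = sorted(set(str(g) for g in table.groups))
    if len(groups) != 2:
        return None
    if confounder != "uncorrected":
        conf = build_confounder(table, _CONF_USE[confounder])
        values = regress_out_confounder(norm.samples_by_genes(), conf.design).T
        norm = NormalizedMatrix(norm.gene_ids, norm.sample_ids, values, norm.size_factors, norm.pseudocount)
    counts_ok = all((np.asarray(table.groups) == g).sum() >= 2 for g in groups)
    if not counts_ok:
        return None
    de = differential_expression(norm, table, groups[0], groups[1], alpha=config.de_alpha)
    return de.deg_count


def _write_outputs(summary: DatasetSummary, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    for run in summary.runs:
        df = pd.DataFrame(
            run.result.scores,
            index=run.result.sample_ids,
            columns=[f"PC{i + 1}" for i in range(run.result.scores.shape[1])],
        )
        df.index.name = "sample_id"
        df.to_csv(out_dir / f"scores_{run.variant}.tsv", sep="\t")
    compare_corrections(summary).to_csv(out_dir / "metrics.tsv", sep="\t", index=False)


def compare_corrections(summary: DatasetSummary) -> pd.DataFrame:
    """Per-variant metric deltas, sorted by Pearson-gamma delta descending.

    Variants whose sample count differs from the baseline are flagged: the
    metrics are sensitive to sample removal and not directly comparable.
    """
    baseline = summary.baseline  # raises when absent
    if len(summary.deltas) < 1:
        raise ValidationError("summary contains no corrected runs to compare")
    rows = []
    for d in summary.deltas:
        rows.append(
            {
                "variant": d.label,
                "d_pearson_gamma": d.d_pearson_gamma,
                "d_dunn1": d.d_dunn1,
                "d_wb_ratio": d.d_wb_ratio,
                "n_before": d.n_before,
                "n_after": d.n_after,
                "n_changed": d.n_after != baseline.metrics.n_samples,
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values("d_pearson_gamma", ascending=False, kind="stable").reset_index(drop=True)
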