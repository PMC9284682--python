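"""Cluster-quality metrics on an embedding with biological groups as clusters.

Three indices, all on Euclidean distances of the first components of an
(adjusted) PCA embedding:

* ``pearson_gamma`` — correlation of pairwise distances with the 0/1
  different-cluster indicator (higher is better);
* ``dunn1`` — minimum between-cluster separation over maximum within-cluster
  diameter, a worst-case index (higher is better);
* ``wb_ratio`` — mean within-cluster distance over mean between-cluster
  distance (lower is better).

Before/after-correction deltas of the three metrics quantify what a
correction bought, with sample counts on both sides since outlier removal
changes n.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from plowbatch.io_core import SampleTable, ValidationError
from plowbatch.quality_stats import DegenerateMetricError, pearson_gamma


@dataclass
class ClusterMetrics:
    pearson_gamma: float
    dunn1: float
    wb_ratio: float
    n_samples: int
    n_clusters: int
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "pearson_gamma": self.pearson_gamma,
            "dunn1": self.dunn1,
            "wb_ratio": self.wb_ratio,
            "n_samples": self.n_samples,
            "n_clusters": self.n_clusters,
            "degenerate": self.degenerate,
        }


@dataclass
class MetricsDelta:
    """corrected minus uncorrected, per metric."""

    label: str
    d_pearson_gamma: float
    d_dunn1: float
    d_wb_ratio: float
    n_before: int
    n_after: int

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "d_pearson_gamma": self.d_pearson_gamma,
            "d_dunn1": self.d_dunn1,
            "d_wb_ratio": self.d_wb_ratio,
            "n_before": self.n_before,
            "n_after": self.n_after,
        }


def _check_labels(points: np.ndarray, labels: np.ndarray) -> None:
    if points.shape[0] != len(labels):
        raise ValidationError("points and labels disagree in length")
    if len(np.unique(labels)) < 2:
        raise ValidationError("need at least 2 clusters")


def dunn_index(points, labels) -> float:
    """min between-cluster distance / max within-cluster diameter.

    All-singleton clusterings have zero diameter and return +inf; identical
    points return 0.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[0] == 1:
        points = points.T
    labels = np.asarray(labels)
    _check_labels(points, labels)
    D = squareform(pdist(points))
    uniq = np.unique(labels)
    diameters = [D[np.ix_(labels == u, labels == u)].max() for u in uniq]
    max_diam = max(diameters)
    separations = [
        D[np.ix_(labels == a, labels == b)].min()
        for i, a in enumerate(uniq)
        for b in uniq[i + 1 :]
    ]
    min_sep = min(separations)
    if max_diam == 0:
        return float("inf") if min_sep > 0 else 0.0
    return float(min_sep / max_diam)


def wb_ratio(points, labels) -> float:
    """mean within-cluster pairwise distance / mean between-cluster distance."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[0] == 1:
        points = points.T
    labels = np.asarray(labels)
    _check_labels(points, labels)
    n = points.shape[0]
    d = pdist(points)
    iu = np.triu_indices(n, k=1)
    same = labels[iu[0]] == labels[iu[1]]
    if not same.any():
        raise DegenerateMetricError("no within-cluster pair (all clusters singleton)")
    between = d[~same]
    if between.size == 0 or between.mean() == 0:
        raise DegenerateMetricError("between-cluster mean distance is zero")
    return float(d[same].mean() / between.mean())


def evaluate_clustering(
    scores: np.ndarray,
    table: SampleTable,
    n_components: int = 2,
    cluster_by: str = "group",
) -> ClusterMetrics:
    """All three metrics on the first ``n_components`` score columns.

    Clusters are the biological groups.  Fully degenerate embeddings
    (identical points) report gamma 0 / dunn 0 with ``degenerate=True``
    instead of NaN, keeping report JSON machine-readable.
    """
    if cluster_by != "group":
        raise ValidationError("cluster_by must be 'group'")
    scores = np.asarray(scores, dtype=float)
    if scores.shape[1] < n_components:
        raise ValidationError(f"need {n_components} components, have {scores.shape[1]}")
    pts = scores[:, :n_components]
    labels = np.asarray(table.groups)
    _check_labels(pts, labels)
    n = pts.shape[0]
    d = pdist(pts)
    iu = np.triu_indices(n, k=1)
    same = labels[iu[0]] == labels[iu[1]]
    degenerate = False
    try:
        gamma = pearson_gamma(d, same)
    except DegenerateMetricError:
        gamma = 0.0
        degenerate = True
    dunn = dunn_index(pts, labels)
    try:
        wb = wb_ratio(pts, labels)
    except DegenerateMetricError:
        wb = float("nan")
        degenerate = True
    return ClusterMetrics(gamma, dunn, wb, n, len(np.unique(labels)), degenerate)


def metrics_delta(before: ClusterMetrics, after: ClusterMetrics, label: str) -> MetricsDelta:
    """Per-metric subtraction (after - before), recording both sample counts."""
    if before.n_clusters != after.n_clusters:
        raise ValidationError("metrics computed on different clusterings are not comparable")
    return MetricsDelta(
        label=label,
        d_pearson_gamma=after.pearson_gamma - before.pearson_gamma,
        d_dunn1=after.dunn1 - before.dunn1,
        d_wb_ratio=after.wb_ratio - before.wb_ratio,
        n_before=before.n_samples,
        n_after=after.n_samples,
    )
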