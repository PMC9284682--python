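"""Batch detection from quality scores and the design-bias statistic.

Two questions are answered from the sample table alone:

* do p_low values differ between batches?  (Kruskal-Wallis rank test, H
  compared to a chi-square with k-1 degrees of freedom)
* does quality align with the biological groups?  (design bias: Pearson
  gamma of |p_low_i - p_low_j| against the different-group indicator,
  mapped from [-1, 1] to [0, 1] via (gamma + 1) / 2)

A high design bias warns that correcting by quality may strip biological
signal, because quality itself separates the groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from plowbatch.io_core import SampleTable, ValidationError


@dataclass
class BatchReport:
    """Machine-readable summary of quality-vs-batch structure in one dataset."""

    kw_statistic: float
    df: int
    p_value: float
    design_bias: float
    per_batch_mean_plow: dict[str, float]
    n_per_batch: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "kw_statistic": self.kw_statistic,
            "df": self.df,
            "p_value": self.p_value,
            "design_bias": self.design_bias,
            "per_batch_mean_plow": self.per_batch_mean_plow,
            "n_per_batch": self.n_per_batch,
        }


def kruskal_wallis(values, labels) -> tuple[float, int, float]:
    """Tie-corrected Kruskal-Wallis H with chi-square p-value.

    Returns ``(H, df, p)`` with df = k - 1.  All-identical observations are a
    defined degenerate case returning ``(0.0, df, 1.0)`` — a constant score
    carries no batch signal and should not abort a pipeline.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape or values.ndim != 1:
        raise ValidationError("values and labels must be 1-D and equally long")
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValidationError("Kruskal-Wallis needs at least 2 labels")
    if len(values) < 3:
        raise ValidationError("Kruskal-Wallis needs at least 3 observations")
    df = len(uniq) - 1
    if np.ptp(values) == 0:
        return 0.0, df, 1.0
    groups = [values[labels == u] for u in uniq]
    h, p = stats.kruskal(*groups)
    return float(h), df, float(p)


def kruskal_wallis_permutation_p(
    values, labels, seed: int = 0, n_perm: int | None = None, mid_p: bool = False
) -> float:
    """Exact (or Monte-Carlo) permutation p-value of the KW statistic.

    Enumerates all distinct label permutations when feasible (N <= 9),
    otherwise samples ``n_perm`` random permutations.  With ``mid_p`` the
    observed value carries half weight — the appropriate convention when
    comparing the discrete permutation null to a continuous approximation
    such as the chi-square tail.  Intended as a small-sample cross-check.
    """
    from itertools import permutations

    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    h_obs, _, _ = kruskal_wallis(values, labels)
    uniq = np.unique(labels)

    def h_of(perm_labels) -> float:
        pl = np.asarray(perm_labels)
        if np.ptp(values) == 0:
            return 0.0
        h, _ = stats.kruskal(*[values[pl == u] for u in uniq])
        return h

    def tail(hs: np.ndarray) -> float:
        hs = np.asarray(hs)
        greater = (hs > h_obs + 1e-12).mean()
        equal = (np.abs(hs - h_obs) <= 1e-12).mean()
        return greater + (0.5 * equal if mid_p else equal)

    n = len(values)
    if n_perm is None and n <= 9:
        seen = set()
        hs = []
        for perm in permutations(labels):
            if perm in seen:
                continue
            seen.add(perm)
            hs.append(h_of(perm))
        return tail(np.array(hs))
    rng = np.random.default_rng(seed)
    n_perm = n_perm or 2000
    hs = np.array([h_of(rng.permutation(labels)) for _ in range(n_perm)])
    return (tail(hs) * n_perm + 1) / (n_perm + 1)


def pearson_gamma(distances, same_cluster) -> float:
    """Pearson correlation of pairwise distances with the different-cluster indicator.

    ``same_cluster`` is boolean per unordered pair (True = same cluster); the
    correlated indicator is 0 for same-cluster pairs and 1 for
    different-cluster pairs, so tight well-separated clusters give values
    near +1.  Raises ``DegenerateMetricError`` when either vector is
    constant (correlation undefined); callers decide the fallback.
    """
    d = np.asarray(distances, dtype=float)
    same = np.asarray(same_cluster, dtype=bool)
    if d.shape != same.shape or d.ndim != 1:
        raise ValidationError("distances and same_cluster must be 1-D and equally long")
    if len(d) < 2:
        raise ValidationError("pearson_gamma needs at least 2 pairs")
    indicator = (~same).astype(float)
    if np.ptp(d) == 0 or np.ptp(indicator) == 0:
        raise DegenerateMetricError("constant distances or one-sided pair pattern")
    return float(np.corrcoef(d, indicator)[0, 1])


class DegenerateMetricError(ValueError):
    """A metric is undefined on this input (zero variance in a correlate)."""


def design_bias(table: SampleTable) -> float:
    """Normalized gamma of p_low distances against the biological grouping.

    gamma is the Pearson correlation between |p_low_i - p_low_j| and the
    different-group indicator over all unordered sample pairs; the returned
    value is (gamma + 1) / 2, in [0, 1].  Constant p_low (gamma undefined)
    returns 0.5: quality carries no group information either way.
    """
    groups = np.asarray(table.groups)
    if len(np.unique(groups)) < 2:
        raise ValidationError("design_bias needs at least 2 groups")
    if table.n_samples < 3:
        raise ValidationError("design_bias needs at least 3 samples")
    p = table.require_p_low()
    n = len(p)
    iu = np.triu_indices(n, k=1)
    dist = np.abs(p[iu[0]] - p[iu[1]])
    same = groups[iu[0]] == groups[iu[1]]
    try:
        gamma = pearson_gamma(dist, same)
    except DegenerateMetricError:
        return 0.5
    return (gamma + 1.0) / 2.0


def batch_report(table: SampleTable) -> BatchReport:
    """Assemble KW on (p_low, batch), design bias on (p_low, group), batch means."""
    batches = np.asarray(table.batches)
    uniq = np.unique(batches)
    if len(uniq) < 2:
        raise ValidationError("batch_report needs at least 2 batches")
    p = table.require_p_low()
    h, df, pval = kruskal_wallis(p, batches)
    bias = design_bias(table)
    means = {str(b): float(p[batches == b].mean()) for b in uniq}
    counts = {str(b): int((batches == b).sum()) for b in uniq}
    return BatchReport(h, df, pval, bias, means, counts)
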