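"""Size-factor normalization, log transform and a rank-based DE stage.

The normalization is the median-of-ratios size factor followed by
``log2(count / sf + pseudocount)``.  This deliberately replaces the
regularized-log transform of NB-GLM pipelines: the downstream correction and
clustering metrics only need a variance-stabilized log scale, not the exact
ridge-shrunken values.  Likewise the differential-expression stage is a
per-gene two-sided Wilcoxon rank-sum test with Benjamini-Hochberg adjustment
— a distribution-free substitute for an NB Wald test, intended as a soft
indicator of correction quality, not as a publication-grade DE method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from plowbatch.io_core import CountMatrix, SampleTable, ValidationError


@dataclass
class NormalizedMatrix:
    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # genes x samples, log2 scale
    size_factors: np.ndarray  # per sample, > 0
    pseudocount: float

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def samples_by_genes(self) -> np.ndarray:
        """Samples x genes view for the statistics modules."""
        return self.values.T

    def subset_samples(self, sample_ids: list[str]) -> "NormalizedMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return NormalizedMatrix(
            list(self.gene_ids),
            list(sample_ids),
            self.values[:, idx].copy(),
            self.size_factors[idx].copy(),
            self.pseudocount,
        )


@dataclass
class DEResult:
    gene_ids: list[str]
    p_values: np.ndarray
    p_adjusted: np.ndarray
    log2_fold_change: np.ndarray  # group_b minus group_a on the log2 scale
    deg_count: int
    alpha: float


def size_factors(counts: CountMatrix) -> np.ndarray:
    """Median-of-ratios size factors.

    s_j = median over genes g of counts_gj / geomean_g, taken only over genes
    whose counts are positive in every sample (zero anywhere removes the gene
    from the median — its geometric mean would be zero).
    """
    c = counts.counts.astype(float)
    all_positive = (c > 0).all(axis=1)
    if not all_positive.any():
        raise ValidationError(
            "no gene has positive counts in every sample; size factors are "
            "undefined (pseudo-reference fallback is disabled)"
        )
    cc = c[all_positive]
    log_geomean = np.log(cc).mean(axis=1)
    ratios = np.log(cc) - log_geomean[:, None]
    return np.exp(np.median(ratios, axis=0))


def log_normalize(counts: CountMatrix, pseudocount: float = 1.0) -> NormalizedMatrix:
    """values = log2(count / size_factor + pseudocount), shape preserved."""
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be positive")
    sf = size_factors(counts)
    values = np.log2(counts.counts / sf[None, :] + pseudocount)
    return NormalizedMatrix(list(counts.gene_ids), list(counts.sample_ids), values, sf, pseudocount)


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def differential_expression(
    norm: NormalizedMatrix,
    table: SampleTable,
    group_a: str,
    group_b: str,
    alpha: float = 0.05,
) -> DEResult:
    """Per-gene two-sided Wilcoxon rank-sum between two groups, BH-adjusted.

    Genes with zero variance across all samples get p = 1.  Fold change is
    mean(group_b) - mean(group_a) of the log2 values.  Small tie-free groups
    use the exact null, otherwise the normal approximation with tie
    correction (scipy's ``mannwhitneyu`` default policy).
    """
    table = table.aligned_to(norm.sample_ids)
    groups = table.groups
    a_idx = np.where(groups == group_a)[0]
    b_idx = np.where(groups == group_b)[0]
    if len(a_idx) < 2 or len(b_idx) < 2:
        raise ValidationError(
            f"both groups need >= 2 samples (got {group_a}: {len(a_idx)}, {group_b}: {len(b_idx)})"
        )
    X = norm.values
    n_genes = X.shape[0]
    p_values = np.ones(n_genes)
    lfc = X[:, b_idx].mean(axis=1) - X[:, a_idx].mean(axis=1)
    both = np.concatenate([a_idx, b_idx])
    nonconstant = X[:, both].std(axis=1) > 0
    if nonconstant.any():
        res = stats.mannwhitneyu(
            X[np.ix_(nonconstant, a_idx)],
            X[np.ix_(nonconstant, b_idx)],
            axis=1,
            alternative="two-sided",
            method="auto",
        )
        p_values[nonconstant] = np.minimum(res.pvalue, 1.0)
    p_adj = benjamini_hochberg(p_values)
    deg_count = int((p_adj < alpha).sum())
    return DEResult(list(norm.gene_ids), p_values, p_adj, lfc, deg_count, alpha)


def regress_out_confounder(values_samples_by_genes: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Residualize expression against confounder columns (for DE on corrected data).

    Least-squares projection of each gene onto the centered design is removed;
    the per-gene mean is added back so values stay on the original scale.
    """
    X = np.asarray(values_samples_by_genes, dtype=float)
    mean = X.mean(axis=0, keepdims=True)
    Xc = X - mean
    D = np.asarray(design, dtype=float)
    coef, *_ = np.linalg.lstsq(D, Xc, rcond=None)
    return Xc - D @ coef + mean
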