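"""Confounder-adjusted PCA and quality-based outlier removal.

Standard PCA extracts the top eigenvectors of X'X.  When a confounding
variable Y (batch labels, a quality score, or both) drives part of the
variance, the adjusted decomposition penalizes components aligned with the
confounder: with kernel K = YY' (trace-normalized to n) the components are
the top eigenvectors v of

    X' (I - lambda K) X

so variance explained through the confounder subspace is discounted by the
penalty weight lambda.  At lambda = 0 this is exactly PCA.  For wide
matrices (p >> n) the eigenproblem is solved in the n-dimensional row space
of X, which is exact for all nonzero eigenvalues.

The penalty weight is selected as the smallest value on a grid for which no
retained component keeps more than ``tol`` of its variance in the confounder
subspace; the per-component diagnostic is the fraction of score variance
explained by the confounder columns (an R-squared, in [0, 1]).

Outlier removal follows a sudden-increase rule on sorted p_low: the largest
consecutive gap in the upper half of the sorted values, if at least
``min_gap`` wide, splits off the high-quality-risk samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from plowbatch.io_core import SampleTable, ValidationError


@dataclass
class ConfounderSpec:
    """Centered samples x q design matrix built from batch and/or p_low columns."""

    design: np.ndarray
    provenance: list[str]

    def __post_init__(self) -> None:
        D = np.asarray(self.design, dtype=float)
        if D.ndim != 2 or D.shape[1] < 1:
            raise ValidationError("confounder design must be samples x q with q >= 1")
        if D.shape[1] != len(self.provenance):
            raise ValidationError("provenance labels must match design columns")
        norms = np.linalg.norm(D, axis=0)
        if np.any(norms == 0):
            raise ValidationError("confounder design contains an all-zero column")
        self.design = D

    def kernel(self) -> np.ndarray:
        """Penalty kernel K = YY' scaled so trace(K) = n."""
        K = self.design @ self.design.T
        tr = np.trace(K)
        n = K.shape[0]
        return K * (n / tr)

    def projection(self) -> np.ndarray:
        """Orthogonal projector onto the confounder column space.

        Used for the per-component diagnostic ratio, which is then the
        fraction of a component's variance explained by the confounder —
        a quantity in [0, 1], so tolerances are on an absolute scale.
        """
        return self.design @ np.linalg.pinv(self.design)


@dataclass
class ACPCAResult:
    loadings: np.ndarray  # genes x k, orthonormal
    scores: np.ndarray  # samples x k  (X @ loadings)
    lam: float
    penalty_ratios: np.ndarray  # per component: v'X'KXv / v'X'Xv
    eigenvalues: np.ndarray
    sample_ids: list[str] | None = None


@dataclass
class OutlierResult:
    outlier_sample_ids: list[str]
    threshold_used: float
    gap: float
    method: str  # largest_gap | fixed_threshold | manual_list


def build_confounder(
    table: SampleTable,
    use: set[str] | frozenset[str],
    extra_columns: np.ndarray | None = None,
) -> ConfounderSpec:
    """One-hot batch block and/or standardized p_low column, all centered.

    ``extra_columns`` (e.g. externally computed surrogate variables) are
    standardized and appended, row-aligned to the table.
    """
    use = set(use)
    unknown = use - {"batch", "p_low"}
    if unknown:
        raise ValidationError(f"unknown confounder(s): {sorted(unknown)}")
    if not use and extra_columns is None:
        raise ValidationError("at least one confounder column is required")
    blocks: list[np.ndarray] = []
    provenance: list[str] = []
    n = table.n_samples
    if "batch" in use:
        batches = np.asarray(table.batches)
        levels = sorted(set(str(b) for b in batches))
        if len(levels) < 2:
            raise ValidationError("confounder column 'batch' is constant")
        onehot = np.stack([(batches.astype(str) == lv).astype(float) for lv in levels], axis=1)
        blocks.append(onehot - onehot.mean(axis=0, keepdims=True))
        provenance += [f"batch={lv}" for lv in levels]
    if "p_low" in use:
        p = table.require_p_low()
        sd = p.std()
        if sd == 0:
            raise ValidationError("confounder column 'p_low' is constant")
        blocks.append(((p - p.mean()) / sd)[:, None])
        provenance.append("p_low")
    if extra_columns is not None:
        E = np.asarray(extra_columns, dtype=float)
        if E.ndim == 1:
            E = E[:, None]
        if E.shape[0] != n:
            raise ValidationError("extra_columns not row-aligned to samples")
        sds = E.std(axis=0)
        if np.any(sds == 0):
            raise ValidationError("extra confounder column is constant")
        blocks.append((E - E.mean(axis=0, keepdims=True)) / sds)
        provenance += [f"extra{i}" for i in range(E.shape[1])]
    return ConfounderSpec(np.concatenate(blocks, axis=1), provenance)


def _fix_signs(loadings: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # sign convention: largest-|.| loading entry positive, for reproducible output
    for i in range(loadings.shape[1]):
        j = np.argmax(np.abs(loadings[:, i]))
        if loadings[j, i] < 0:
            loadings[:, i] *= -1
            scores[:, i] *= -1
    return loadings, scores


def acpca(
    X: np.ndarray,
    conf: ConfounderSpec,
    lam: float,
    k: int = 2,
    sample_ids: list[str] | None = None,
) -> ACPCAResult:
    """Top-k components of X'(I - lambda K)X for column-centered X.

    Solved in the row space of X when p > n (exact for nonzero eigenvalues);
    the loadings are orthonormal and sign-fixed so the largest-magnitude
    loading entry of each component is positive.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if k > min(n - 1, p):
        raise ValidationError(f"k={k} too large for {n} samples x {p} features")
    if lam < 0:
        raise ValidationError("lambda must be >= 0")
    scale = max(np.abs(X).max(), 1.0)
    if np.abs(X.mean(axis=0)).max() > 1e-6 * scale:
        raise ValidationError("X must be column-centered")
    K = conf.kernel()
    M = np.eye(n) - lam * K

    if p > n:
        # row-space solve: X = U S V', restrict X'MX to span(V)
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        pos = s > s[0] * 1e-12 if s.size else s > 0
        U, s, Vt = U[:, pos], s[pos], Vt[pos]
        B = (U * s).T @ M @ (U * s)  # r x r, equals V' X'MX V
        B = (B + B.T) / 2
        evals, evecs = np.linalg.eigh(B)
        order = np.argsort(evals)[::-1][:k]
        eigenvalues = evals[order]
        loadings = Vt.T @ evecs[:, order]
    else:
        A = X.T @ M @ X
        A = (A + A.T) / 2
        evals, evecs = np.linalg.eigh(A)
        order = np.argsort(evals)[::-1][:k]
        eigenvalues = evals[order]
        loadings = evecs[:, order]

    scores = X @ loadings
    loadings, scores = _fix_signs(loadings, scores)

    P = conf.projection()
    ratios = np.full(k, np.nan)
    for i in range(k):
        xv = scores[:, i]
        total = float(xv @ xv)
        if total > 0:
            ratios[i] = float(xv @ P @ xv) / total
    return ACPCAResult(loadings, scores, float(lam), ratios, eigenvalues, sample_ids)


def select_lambda(
    X: np.ndarray,
    conf: ConfounderSpec,
    grid,
    tol: float = 0.05,
    k: int = 2,
) -> tuple[float, bool]:
    """Smallest grid value whose components keep <= tol confounder variance.

    Returns ``(lambda, converged)``; when no grid value reaches the
    tolerance, returns the minimizer of the worst per-component ratio with
    ``converged = False``.
    """
    grid = [float(g) for g in grid]
    if not grid or grid[0] != 0.0 or any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValidationError("grid must be nonempty, strictly increasing, starting at 0")
    best_lam, best_max = None, np.inf
    for lam in grid:
        res = acpca(X, conf, lam, k=k)
        with np.errstate(invalid="ignore"):
            worst = np.nanmax(res.penalty_ratios)
        if worst <= tol:
            return lam, True
        if worst < best_max:
            best_lam, best_max = lam, worst
    return best_lam, False


def detect_quality_outliers(
    table: SampleTable,
    min_gap: float = 0.3,
    fixed_threshold: float | None = None,
    manual_list: list[str] | None = None,
) -> OutlierResult:
    """Flag quality outliers by a sudden increase in sorted p_low.

    largest_gap mode (default): sort p_low ascending and scan consecutive
    gaps in the upper half of the sorted values; if the largest such gap is
    >= ``min_gap``, every sample above it is an outlier.  The scan never
    looks at the lower half, so spread among good-quality samples cannot
    flag them.  ``fixed_threshold`` flags samples with p_low > threshold;
    ``manual_list`` passes an explicit id list through (for reproducing
    removals chosen by eye).  An empty outlier set is a valid result.
    """
    if manual_list is not None:
        have = set(table.sample_ids)
        missing = [s for s in manual_list if s not in have]
        if missing:
            raise ValidationError(f"manual outlier id(s) not in table: {missing}")
        return OutlierResult(list(manual_list), float("nan"), 0.0, "manual_list")
    p = table.require_p_low()
    ids = np.asarray(table.sample_ids)
    if fixed_threshold is not None:
        mask = p > fixed_threshold
        return OutlierResult(ids[mask].tolist(), float(fixed_threshold), 0.0, "fixed_threshold")
    n = len(p)
    if n < 3:
        raise ValidationError("largest_gap mode needs at least 3 samples")
    order = np.argsort(p, kind="stable")
    sp = p[order]
    start = n // 2  # gaps sp[i+1]-sp[i] for i >= floor(n/2): upper half only
    gaps = np.diff(sp)
    upper = gaps[start:]
    if upper.size == 0:
        return OutlierResult([], float("nan"), 0.0, "largest_gap")
    rel = int(np.argmax(upper[::-1]))  # ties -> topmost gap
    i = start + (len(upper) - 1 - rel)
    gap = float(gaps[i])
    if gap >= min_gap:
        cut = (sp[i] + sp[i + 1]) / 2
        out_ids = ids[order[i + 1 :]].tolist()
        return OutlierResult(out_ids, float(cut), gap, "largest_gap")
    return OutlierResult([], float("nan"), gap, "largest_gap")
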