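import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from plowbatch.correction import (
    ConfounderSpec,
    acpca,
    build_confounder,
    detect_quality_outliers,
    select_lambda,
)
from plowbatch.io_core import ValidationError
from plowbatch.normalize import log_normalize
from plowbatch.simulate import SimulationConfig, inject_outliers, simulate_dataset
from tests.conftest import cells16, make_table


def random_instance(seed, n=10, p=40, q=1):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    X -= X.mean(axis=0, keepdims=True)
    Y = rng.normal(size=(n, q))
    Y -= Y.mean(axis=0, keepdims=True)
    Y /= Y.std(axis=0, keepdims=True)
    return X, ConfounderSpec(Y, [f"c{i}" for i in range(q)])


def dense_eig_oracle(X, conf, lam, k):
    n = X.shape[0]
    A = X.T @ (np.eye(n) - lam * conf.kernel()) @ X
    A = (A + A.T) / 2
    evals = np.linalg.eigvalsh(A)
    return np.sort(evals)[::-1][:k]


class TestBuildConfounder:
    def test_two_level_batch_centers_to_rank_one(self):
        t = make_table([0.1] * 4, ["A", "A", "B", "B"], ["b1", "b1", "b2", "b2"])
        conf = build_confounder(t, {"batch"})
        assert conf.design.shape == (4, 2)
        assert np.allclose(conf.design.mean(axis=0), 0)
        assert np.linalg.matrix_rank(conf.design) == 1
        assert np.allclose(np.abs(conf.design), 0.5)

    def test_p_low_standardized(self):
        t = make_table([0.1, 0.1, 0.9, 0.9], ["A", "B", "A", "B"], ["b1", "b1", "b2", "b2"])
        conf = build_confounder(t, {"p_low"})
        col = conf.design[:, 0]
        expected = np.array([-1, -1, 1, 1]) / np.std([-1, -1, 1, 1])
        assert col == pytest.approx(expected / np.std(expected) * col.std())
        assert col == pytest.approx([-1.0, -1.0, 1.0, 1.0], abs=1e-12)

    def test_combined_design_width(self):
        t = make_table([0.1, 0.2, 0.8, 0.9], ["A", "B", "A", "B"], ["b1", "b1", "b2", "b2"])
        conf = build_confounder(t, {"batch", "p_low"})
        assert conf.design.shape[1] == 3  # 2 batch levels + 1 p_low column
        assert any(p.startswith("batch=") for p in conf.provenance)
        assert "p_low" in conf.provenance

    def test_constant_column_errors(self):
        t = make_table([0.5] * 4, ["A", "B", "A", "B"], ["b1", "b1", "b2", "b2"])
        with pytest.raises(ValidationError):
            build_confounder(t, {"p_low"})

    def test_extra_columns_appended(self):
        t = make_table([0.1, 0.2, 0.8, 0.9], ["A", "B", "A", "B"], ["b1", "b1", "b2", "b2"])
        sv = np.array([1.0, 2.0, 3.0, 4.0])
        conf = build_confounder(t, set(), extra_columns=sv)
        assert conf.design.shape == (4, 1)
        assert np.allclose(conf.design.mean(axis=0), 0)


class TestACPCA:
    def test_lambda_zero_reduces_to_pca(self):
        from sklearn.decomposition import PCA

        for seed in range(10):
            X, conf = random_instance(seed, n=12, p=30)
            res = acpca(X, conf, 0.0, k=3)
            ref = PCA(n_components=3).fit_transform(X)
            for i in range(3):
                r = np.corrcoef(res.scores[:, i], ref[:, i])[0, 1]
                assert abs(r) > 0.999999

    def test_rowspace_matches_dense_oracle_wide(self):
        for seed in range(10):
            X, conf = random_instance(seed, n=8, p=120)
            for lam in (0.0, 0.7, 3.0):
                res = acpca(X, conf, lam, k=4)
                expected = dense_eig_oracle(X, conf, lam, 4)
                assert res.eigenvalues == pytest.approx(expected, abs=1e-8)

    def test_explicit_small_matrix_oracle(self):
        X = np.array([[1.0, 2.0, 0.0], [-1.0, 0.0, 1.0], [0.0, -2.0, -1.0], [0.0, 0.0, 0.0]])
        X -= X.mean(axis=0, keepdims=True)
        y = np.array([[1.0], [-1.0], [1.0], [-1.0]])
        conf = ConfounderSpec(y, ["c"])
        res = acpca(X, conf, 0.5, k=2)
        assert res.eigenvalues == pytest.approx(dense_eig_oracle(X, conf, 0.5, 2), abs=1e-8)

    def test_loadings_orthonormal(self):
        X, conf = random_instance(3, n=10, p=50)
        res = acpca(X, conf, 1.3, k=4)
        assert res.loadings.T @ res.loadings == pytest.approx(np.eye(4), abs=1e-8)

    def test_non_centered_input_rejected(self):
        X, conf = random_instance(0)
        with pytest.raises(ValidationError):
            acpca(X + 5.0, conf, 0.0, k=2)

    def test_k_too_large_rejected(self):
        X, conf = random_instance(0, n=5, p=20)
        with pytest.raises(ValidationError):
            acpca(X, conf, 0.0, k=5)

    def test_gene_permutation_equivariance(self):
        X, conf = random_instance(4, n=10, p=60)
        rng = np.random.default_rng(0)
        perm = rng.permutation(60)
        res1 = acpca(X, conf, 0.8, k=2)
        res2 = acpca(X[:, perm], conf, 0.8, k=2)
        assert res2.scores == pytest.approx(res1.scores, abs=1e-8)
        assert res2.loadings == pytest.approx(res1.loadings[perm], abs=1e-8)

    def test_sample_reorder_invariance(self):
        X, conf = random_instance(5, n=10, p=60)
        rng = np.random.default_rng(1)
        perm = rng.permutation(10)
        res1 = acpca(X, conf, 0.8, k=2)
        conf2 = ConfounderSpec(conf.design[perm], conf.provenance)
        res2 = acpca(X[perm], conf2, 0.8, k=2)
        assert res2.scores == pytest.approx(res1.scores[perm], abs=1e-8)

    def test_simulated_batch_effect_removed_by_plow_confounder(self):
        cfg = SimulationConfig(seed=2, n_genes=1000, samples_per_cell=cells16())
        cm, table, _ = simulate_dataset(cfg)
        X = log_normalize(cm).samples_by_genes()
        X = X - X.mean(axis=0, keepdims=True)
        batch = (np.asarray(table.batches) == "b2").astype(float)
        group = (np.asarray(table.groups) == "g2").astype(float)
        base = acpca(X, build_confounder(table, {"batch"}), 0.0, k=2)
        assert abs(np.corrcoef(base.scores[:, 0], batch)[0, 1]) > 0.7
        conf = build_confounder(table, {"p_low"})
        lam, converged = select_lambda(X, conf, np.linspace(0, 20, 41), tol=0.05, k=2)
        assert converged
        res = acpca(X, conf, lam, k=2)
        assert abs(np.corrcoef(res.scores[:, 0], batch)[0, 1]) < 0.3
        assert max(
            abs(np.corrcoef(res.scores[:, i], group)[0, 1]) for i in range(2)
        ) > 0.6


class TestSelectLambda:
    def test_orthogonal_confounder_returns_zero(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(8, 30))
        X -= X.mean(axis=0, keepdims=True)
        # build a confounder orthogonal to every data column
        y = rng.normal(size=8)
        y -= y.mean()
        proj = X.T @ y / (y @ y)
        X = X - np.outer(y, proj)  # now X'y = 0
        X -= X.mean(axis=0, keepdims=True)
        conf = ConfounderSpec((y / y.std())[:, None], ["c"])
        lam, converged = select_lambda(X, conf, [0.0, 1.0, 2.0], tol=0.05, k=2)
        assert lam == 0.0 and converged

    def test_vacuous_tolerance_returns_zero(self):
        X, conf = random_instance(7)
        lam, converged = select_lambda(X, conf, [0.0, 1.0], tol=0.999, k=2)
        assert lam == 0.0 and converged

    def test_confounded_instance_selects_positive_lambda(self, coupled_dataset):
        cm, table, _ = coupled_dataset
        X = log_normalize(cm).samples_by_genes()
        X = X - X.mean(axis=0, keepdims=True)
        conf = build_confounder(table, {"batch"})
        lam, converged = select_lambda(X, conf, np.linspace(0, 20, 41), tol=0.05, k=2)
        assert lam > 0 and converged
        res = acpca(X, conf, lam, k=2)
        assert np.nanmax(res.penalty_ratios) <= 0.05

    def test_invalid_grid_rejected(self):
        X, conf = random_instance(0)
        with pytest.raises(ValidationError):
            select_lambda(X, conf, [1.0, 2.0], tol=0.05)

    def test_leading_ratio_nonincreasing_in_lambda(self):
        # allow rare non-monotone residual cases, assert over >= 95%
        grid = [0.0, 0.5, 1.0, 2.0, 4.0]
        ok = 0
        n_instances = 60
        for seed in range(n_instances):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(12, 40))
            y = rng.normal(size=12)
            X[:, :10] += np.outer(y, rng.normal(size=10))  # confounded block
            X -= X.mean(axis=0, keepdims=True)
            y -= y.mean()
            conf = ConfounderSpec((y / y.std())[:, None], ["c"])
            ratios = [np.nanmax(acpca(X, conf, lam, k=1).penalty_ratios) for lam in grid]
            ok += all(b <= a + 1e-9 for a, b in zip(ratios, ratios[1:]))
        assert ok >= 0.95 * n_instances


class TestOutlierDetection:
    def test_clear_gap_example(self):
        t = make_table([0.1, 0.12, 0.15, 0.8, 0.85], ["A"] * 3 + ["B"] * 2, ["b1"] * 5)
        res = detect_quality_outliers(t, min_gap=0.3)
        assert set(res.outlier_sample_ids) == {"s3", "s4"}
        assert res.gap == pytest.approx(0.65)
        assert res.method == "largest_gap"

    def test_even_spacing_no_outliers(self):
        t = make_table([0.1, 0.2, 0.3, 0.4, 0.5], ["A"] * 3 + ["B"] * 2, ["b1"] * 5)
        res = detect_quality_outliers(t, min_gap=0.3)
        assert res.outlier_sample_ids == []

    def test_fixed_threshold(self):
        t = make_table([0.2, 0.6, 0.7], ["A", "B", "B"], ["b1"] * 3)
        res = detect_quality_outliers(t, fixed_threshold=0.5)
        assert set(res.outlier_sample_ids) == {"s1", "s2"}
        assert res.method == "fixed_threshold"

    def test_gap_in_lower_half_never_flags(self):
        # large spread among good-quality samples must not trigger
        t = make_table([0.0, 0.5, 0.55, 0.58, 0.6, 0.62], ["A"] * 3 + ["B"] * 3, ["b1"] * 6)
        res = detect_quality_outliers(t, min_gap=0.3)
        assert res.outlier_sample_ids == []

    def test_manual_list_passthrough(self):
        t = make_table([0.1, 0.2, 0.3], ["A", "B", "B"], ["b1"] * 3)
        res = detect_quality_outliers(t, manual_list=["s2"])
        assert res.outlier_sample_ids == ["s2"] and res.method == "manual_list"
        with pytest.raises(ValidationError):
            detect_quality_outliers(t, manual_list=["nope"])

    def test_recovers_injected_outliers(self):
        # quality-uniform base: the +0.5 shift is then a clean sudden increase
        hits = 0
        n_seeds = 25
        for seed in range(n_seeds):
            cfg = SimulationConfig(
                seed=seed, n_genes=50, samples_per_cell=cells16(), plow_batch_shift=0.0
            )
            cm, table, _ = simulate_dataset(cfg)
            _, t2, ids = inject_outliers(cm, table, 2, seed=seed + 1000)
            res = detect_quality_outliers(t2, min_gap=0.3)
            hits += set(res.outlier_sample_ids) == set(ids)
        assert hits >= 0.9 * n_seeds

    def test_subset_then_correct_commutes(self):
        # removing outliers then correcting == correcting the submatrix,
        # when the confounder is rebuilt on the subset
        cfg = SimulationConfig(seed=7, n_genes=400, samples_per_cell=cells16(), plow_batch_shift=0.0)
        cm, table, _ = simulate_dataset(cfg)
        cm2, t2, ids = inject_outliers(cm, table, 2, seed=5)
        res = detect_quality_outliers(t2, min_gap=0.3)
        keep = [s for s in cm2.sample_ids if s not in set(res.outlier_sample_ids)]
        assert len(keep) < cm2.n_samples
        norm = log_normalize(cm2)
        ta = t2.subset(keep)
        # route 1: subset the normalized matrix object, then correct
        Xa = norm.subset_samples(keep).samples_by_genes()
        Xa = Xa - Xa.mean(axis=0, keepdims=True)
        ra = acpca(Xa, build_confounder(ta, {"batch"}), 1.0, k=2)
        # route 2: slice the raw value array directly, then correct
        idx = [norm.sample_ids.index(s) for s in keep]
        Xb = norm.values[:, idx].T
        Xb = Xb - Xb.mean(axis=0, keepdims=True)
        rb = acpca(Xb, build_confounder(ta, {"batch"}), 1.0, k=2)
        assert ra.scores == pytest.approx(rb.scores, abs=1e-10)
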