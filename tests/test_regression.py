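"""Feature filtering, LOOCV, combination search and permutation analysis."""

import numpy as np
import pandas as pd
import pytest

from curvmap.errors import EmptySelectionError, ParameterError
from curvmap.regression import (
    ModelSpec,
    StudyDataset,
    brute_force_loocv_predictions,
    combination_search,
    filter_features,
    generate_permuted_responses,
    linear_loocv_predictions,
    loocv_evaluate,
    permutation_analysis,
)


def _dataset(n=20, p=6, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    beta = np.zeros(p)
    beta[:3] = [1.0, -0.8, 0.6]
    y = X @ beta + noise * rng.standard_normal(n)
    cols = [f"f{i}" for i in range(p)]
    return StudyDataset(X=pd.DataFrame(X, columns=cols), y=y)


class TestFilterFeatures:
    def test_self_correlated_column_retained(self):
        ds = _dataset()
        ds.X["copy_of_y"] = ds.y
        retained = filter_features(ds)
        assert "copy_of_y" in retained

    def test_constant_column_dropped(self):
        ds = _dataset()
        ds.X["const"] = 1.0
        assert "const" not in filter_features(ds)

    def test_outlier_column_dropped(self):
        ds = _dataset()
        spiked = ds.y.copy()
        spiked[0] = spiked.mean() + 50 * spiked.std()  # one entry at +5σ of the rest
        ds.X["spiked"] = spiked
        assert "spiked" not in filter_features(ds)

    def test_all_dropped_raises(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"a": np.ones(10), "b": np.ones(10)})
        ds = StudyDataset(X=X, y=rng.standard_normal(10))
        with pytest.raises(EmptySelectionError):
            filter_features(ds)

    def test_response_outlier_prefilter(self):
        ds = _dataset()
        y = ds.y.copy()
        y[3] = y.mean() + 10 * y.std()
        spiked = StudyDataset(ds.X, y)
        trimmed = spiked.drop_response_outliers()
        assert len(trimmed.y) == len(y) - 1


class TestLoocv:
    def test_noiseless_linear_law_is_interpolated(self):
        ds = _dataset(noise=0.0)
        res = loocv_evaluate(ds, ("f0", "f1", "f2"), ModelSpec("Linear"))
        assert res.r == pytest.approx(1.0, abs=1e-9)
        assert res.r2 == pytest.approx(1.0, abs=1e-9)
        assert res.mse == pytest.approx(0.0, abs=1e-12)

    def test_hat_matrix_matches_brute_force(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            X = rng.standard_normal((20, 3))
            y = rng.standard_normal(20)
            fast = linear_loocv_predictions(X, y)
            slow = brute_force_loocv_predictions(X, y, ModelSpec("Linear"))
            assert np.abs(fast - slow).max() < 1e-10

    def test_row_permutation_equivariance(self):
        ds = _dataset(noise=0.3)
        combo = ("f0", "f1", "f2")
        base = loocv_evaluate(ds, combo, ModelSpec("Linear")).predictions
        perm = np.random.default_rng(3).permutation(len(ds.y))
        shuffled = StudyDataset(ds.X.iloc[perm], ds.y[perm])
        res = loocv_evaluate(shuffled, combo, ModelSpec("Linear")).predictions
        np.testing.assert_allclose(res, base[perm], atol=1e-10)

    def test_pure_noise_gives_nonpositive_r2(self):
        # Monte-Carlo: with y independent of X, out-of-fold R² ≤ 0 on average
        rng = np.random.default_rng(4)
        r2s = []
        for _ in range(200):
            X = rng.standard_normal((20, 3))
            y = rng.standard_normal(20)
            ds = StudyDataset(pd.DataFrame(X, columns=["a", "b", "c"]), y)
            r2s.append(loocv_evaluate(ds, ("a", "b", "c"), ModelSpec("Linear")).r2)
        assert np.mean(r2s) < 0

    def test_out_of_sample_below_in_sample(self):
        rng = np.random.default_rng(5)
        diffs = []
        for _ in range(50):
            X = rng.standard_normal((20, 3))
            y = X @ np.array([1.0, 0.5, -0.5]) + rng.standard_normal(20)
            ds = StudyDataset(pd.DataFrame(X, columns=["a", "b", "c"]), y)
            res = loocv_evaluate(ds, ("a", "b", "c"), ModelSpec("Linear"))
            diffs.append(res.r2_in - res.r2)
        assert np.median(diffs) > 0

    def test_nonlinear_models_produce_finite_metrics(self):
        ds = _dataset(n=12, noise=0.2)
        for kind in ("KNN", "SVM", "RF", "GRB"):
            res = loocv_evaluate(ds, ("f0", "f1", "f2"), ModelSpec(kind))
            assert np.isfinite([res.r, res.r2, res.mse]).all()
            assert res.mse >= 0

    def test_too_few_molecules_rejected(self):
        ds = _dataset(n=2)
        with pytest.raises(ParameterError):
            loocv_evaluate(ds, ("f0", "f1", "f2"), ModelSpec("Linear"))


class TestCombinationSearch:
    def test_binomial_combination_count(self):
        ds = _dataset(p=5, noise=0.5)
        results = combination_search(ds, [f"f{i}" for i in range(5)], ModelSpec("Linear"))
        assert len(results) == 10  # C(5,3)

    def test_duplicate_columns_duplicate_results(self):
        ds = _dataset(p=4, noise=0.5)
        ds.X["f0_dup"] = ds.X["f0"]
        results = combination_search(
            ds, ["f0", "f0_dup", "f1", "f2"], ModelSpec("Linear")
        )
        by_combo = {res.combo: res for res in results}
        a = by_combo[("f0", "f1", "f2")]
        b = by_combo[("f0_dup", "f1", "f2")]
        assert a.r == pytest.approx(b.r, abs=1e-12)
        assert a.mse == pytest.approx(b.mse, abs=1e-12)

    def test_batched_linear_matches_single_evaluations(self):
        ds = _dataset(p=6, noise=0.4, seed=7)
        names = [f"f{i}" for i in range(6)]
        results = combination_search(ds, names, ModelSpec("Linear"))
        for res in results[:5]:
            single = loocv_evaluate(ds, res.combo, ModelSpec("Linear"))
            assert res.r == pytest.approx(single.r, abs=1e-10)
            assert res.mse == pytest.approx(single.mse, abs=1e-10)

    def test_ranking_descends_in_r(self):
        ds = _dataset(p=6, noise=0.4)
        results = combination_search(ds, [f"f{i}" for i in range(6)], ModelSpec("Linear"))
        rs = [res.r for res in results]
        assert rs == sorted(rs, reverse=True)

    def test_too_few_features_rejected(self):
        ds = _dataset(p=3)
        with pytest.raises(ParameterError):
            combination_search(ds, ["f0", "f1"], ModelSpec("Linear"))


class TestPermutation:
    def test_identity_reference_reproduces_unpermuted_metrics(self):
        ds = _dataset(noise=0.3)
        combo = ("f0", "f1", "f2")
        base = loocv_evaluate(ds, combo, ModelSpec("Linear"))
        perm = permutation_analysis(ds, combo, ModelSpec("Linear"), seed=9)
        ident = perm.table[perm.table.is_identity].iloc[0]
        assert ident.degree == pytest.approx(1.0, abs=1e-12)
        assert ident.r2_oof == pytest.approx(base.r2, abs=1e-12)
        assert ident.r2_in == pytest.approx(base.r2_in, abs=1e-12)

    def test_generated_vectors_are_permutations(self):
        rng = np.random.default_rng(10)
        y = rng.standard_normal(20)
        vectors = generate_permuted_responses(y, 100, rng)
        assert len(vectors) == 100
        np.testing.assert_array_equal(vectors[0], y)
        for v in vectors:
            np.testing.assert_array_equal(np.sort(v), np.sort(y))

    def test_degree_coverage(self):
        rng = np.random.default_rng(11)
        y = rng.standard_normal(20)
        vectors = generate_permuted_responses(y, 100, rng)
        degrees = np.array([np.corrcoef(y, v)[0, 1] for v in vectors])
        assert degrees.max() == pytest.approx(1.0)
        assert degrees.min() < 0.2
        assert ((degrees > 0.5) & (degrees < 1.0)).sum() >= 10

    def test_anti_sorted_vector_has_degree_minus_one(self):
        y = np.arange(10, dtype=float)  # distinct values
        assert np.corrcoef(y, y[::-1])[0, 1] == pytest.approx(-1.0)
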