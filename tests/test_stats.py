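"""Tests of the inference layer: Spearman, bootstrap CI, BH-FDR,
standardized regression, and Boruta with shadow features."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sstats

from gatebeat.stats import (
    boruta,
    boruta_consensus,
    bootstrap_ci,
    fdr_bh,
    spearman,
    standardized_regression,
)


def fdr_reference(p):
    """BH step-up by definition: for each i, min over j with p_(j) >= p_i
    of p_(j) * m / rank(j)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    sorted_p = p[order]
    for k in range(m):
        candidates = [sorted_p[j] * m / (j + 1) for j in range(k, m)]
        adj[order[k]] = min(1.0, min(candidates))
    return adj


class TestSpearman:
    def test_monotone_pairs(self):
        assert spearman([1, 2, 3, 4], [2, 4, 6, 8])[0] == pytest.approx(1.0)
        assert spearman([1, 2, 3, 4], [8, 6, 4, 2])[0] == pytest.approx(-1.0)

    def test_matches_rank_pearson_oracle_with_ties(self, rng):
        for _ in range(200):
            n = int(rng.integers(5, 60))
            x = rng.integers(0, 6, n).astype(float)
            y = rng.integers(0, 6, n).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            rho, p = spearman(x, y)
            rx = sstats.rankdata(x)
            ry = sstats.rankdata(y)
            oracle = np.corrcoef(rx, ry)[0, 1]
            assert abs(rho - oracle) < 1e-12
            assert abs(rho - sstats.spearmanr(x, y).statistic) < 1e-12

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            spearman([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            spearman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    @given(st.integers(0, 1000))
    @settings(max_examples=25, deadline=None)
    def test_invariant_under_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(20)
        y = rng.standard_normal(20)
        rho, _ = spearman(x, y)
        rho_t, _ = spearman(np.exp(x), y**3)  # strictly increasing transforms
        assert rho_t == pytest.approx(rho, abs=1e-12)


class TestBootstrapCI:
    def test_perfectly_monotone_data_degenerate_interval(self):
        x = np.arange(20.0)
        lo, hi = bootstrap_ci(x, 2.0 * x + 1.0, seed=0)
        assert (lo, hi) == (1.0, 1.0)

    def test_seed_determinism(self, rng):
        x = rng.standard_normal(40)
        y = 0.5 * x + rng.standard_normal(40)
        assert bootstrap_ci(x, y, seed=5) == bootstrap_ci(x, y, seed=5)
        assert bootstrap_ci(x, y, seed=5) != bootstrap_ci(x, y, seed=6)

    def test_interval_brackets_sample_rho(self, rng):
        x = rng.standard_normal(60)
        y = 0.6 * x + 0.8 * rng.standard_normal(60)
        rho, _ = spearman(x, y)
        lo, hi = bootstrap_ci(x, y, seed=1)
        assert lo <= rho <= hi

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ci(np.arange(5.0), np.arange(5.0))


class TestFDR:
    def test_hand_computed_step_up(self):
        out = fdr_bh(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert fdr_bh(np.array([0.37]))[0] == pytest.approx(0.37)

    def test_matches_brute_force_reference(self, rng):
        for _ in range(100):
            p = rng.random(int(rng.integers(1, 25)))
            assert np.allclose(fdr_bh(p), fdr_reference(p), atol=1e-15)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(50):
            p = rng.random(12)
            assert np.allclose(fdr_bh(p), multipletests(p, method="fdr_bh")[1])

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_monotone_capped_and_reapplication_never_decreases(self, seed):
        # step-up adjustment is monotone in sorted order and bounded by 1;
        # it is not idempotent in general, but a second pass can only grow
        rng = np.random.default_rng(seed)
        p = rng.random(15)
        adj = fdr_bh(p)
        order = np.argsort(p, kind="stable")
        assert (np.diff(adj[order]) >= -1e-15).all()
        assert (adj <= 1.0).all() and (adj >= p - 1e-12).all()
        assert (fdr_bh(adj) >= adj - 1e-15).all()

    def test_constant_vector_is_fixed_point(self):
        p = np.full(8, 0.2)
        assert np.allclose(fdr_bh(p), p)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh(np.array([0.5, 1.2]))


class TestStandardizedRegression:
    def test_single_predictor_equals_pearson_r(self, rng):
        x = rng.standard_normal(50)
        y = 0.4 * x + rng.standard_normal(50)
        res = standardized_regression(pd.DataFrame({"x": x}), y)
        assert res.loc["x", "beta"] == pytest.approx(np.corrcoef(x, y)[0, 1])

    def test_orthogonal_predictors_recover_marginals(self):
        n = 64
        t = np.arange(n)
        x1 = np.sin(2 * np.pi * t / n)
        x2 = np.cos(2 * np.pi * t / n)  # exactly orthogonal, zero-mean
        y = 0.7 * x1 - 0.2 * x2
        res = standardized_regression(pd.DataFrame({"a": x1, "b": x2}), y)
        zy = (y - y.mean()) / y.std(ddof=1)
        za = (x1 - x1.mean()) / x1.std(ddof=1)
        zb = (x2 - x2.mean()) / x2.std(ddof=1)
        r_a = (za * zy).sum() / (n - 1)
        r_b = (zb * zy).sum() / (n - 1)
        assert res.loc["a", "beta"] == pytest.approx(r_a, abs=1e-9)
        assert res.loc["b", "beta"] == pytest.approx(r_b, abs=1e-9)

    def test_affine_rescaling_leaves_betas_unchanged(self, rng):
        X = pd.DataFrame(rng.standard_normal((60, 3)), columns=list("abc"))
        y = X["a"] - 0.5 * X["b"] + rng.standard_normal(60)
        base = standardized_regression(X, y)
        X2 = X.copy()
        X2["a"] = 100.0 * X2["a"] - 7.0
        X2["c"] = -0.01 * X2["c"]
        rescaled = standardized_regression(X2, y)
        assert np.allclose(base["beta"].abs(), rescaled["beta"].abs(), atol=1e-9)

    def test_collinear_columns_named_in_error(self, rng):
        x = rng.standard_normal(30)
        X = pd.DataFrame({"a": x, "b": 2.0 * x, "c": rng.standard_normal(30)})
        with pytest.raises(ValueError, match="a.*b"):
            standardized_regression(X, rng.standard_normal(30))

    def test_constant_column_rejected(self, rng):
        X = pd.DataFrame({"a": np.ones(30), "b": rng.standard_normal(30)})
        with pytest.raises(ValueError, match="constant"):
            standardized_regression(X, rng.standard_normal(30))

    def test_cohort_effect_sizes_recovered(self):
        from gatebeat.synth import CohortSpec, generate_cohort

        tab = generate_cohort(CohortSpec(n_subjects=500, seed=5)).table
        res = standardized_regression(
            tab[["log_lf", "edr_hz", "smoker"]], tab["ratio"]
        )
        for name, target in (("log_lf", -0.5), ("edr_hz", -0.4), ("smoker", -0.45)):
            assert res.loc[name, "beta"] == pytest.approx(target, abs=0.1)


def _noise_problem(rng, n=200, p=20):
    X = pd.DataFrame(
        rng.standard_normal((n, p)), columns=[f"f{i}" for i in range(p)]
    )
    return X, rng.standard_normal(n)


class TestBoruta:
    def test_planted_signal_confirmed_every_seed(self, rng):
        X, _ = _noise_problem(rng)
        y = X["f0"].to_numpy() + 0.3 * rng.standard_normal(len(X))
        for seed in (1, 2, 3):
            res = boruta(X, y, seed=seed, max_iter=25, n_estimators=200)
            assert "f0" in res.confirmed

    def test_pure_noise_confirms_nothing(self):
        # the null guarantee is over data draws: a fresh cohort per seed
        for data_seed in (901, 902, 903):
            X, y = _noise_problem(np.random.default_rng(data_seed))
            res = boruta(X, y, seed=1, max_iter=20, n_estimators=200)
            assert res.confirmed == []

    def test_stricter_alpha_confirms_subset(self, rng):
        X, _ = _noise_problem(rng)
        y = (X["f0"] + 0.8 * X["f1"]).to_numpy() + 0.5 * rng.standard_normal(len(X))
        loose = boruta(X, y, seed=4, max_iter=25, n_estimators=200, alpha=0.01)
        strict = boruta(X, y, seed=4, max_iter=25, n_estimators=200, alpha=0.001)
        assert set(strict.confirmed) <= set(loose.confirmed)

    def test_deterministic_given_seed(self, rng):
        X, _ = _noise_problem(rng, n=60, p=8)
        y = X["f0"].to_numpy() + 0.5 * rng.standard_normal(60)
        a = boruta(X, y, seed=9, max_iter=15, n_estimators=100)
        b = boruta(X, y, seed=9, max_iter=15, n_estimators=100)
        pd.testing.assert_frame_equal(a.decisions, b.decisions)

    def test_constant_outcome_rejected(self, rng):
        X, _ = _noise_problem(rng, n=30, p=4)
        with pytest.raises(ValueError):
            boruta(X, np.ones(30))

    def test_missing_values_rejected(self, rng):
        X, y = _noise_problem(rng, n=30, p=4)
        X.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            boruta(X, y)

    def test_consensus_is_intersection_of_confirmed_sets(self, rng):
        X, _ = _noise_problem(rng, n=150, p=10)
        y = X["f0"].to_numpy() + 0.4 * rng.standard_normal(150)
        cons = boruta_consensus(X, y, seeds=(1, 2, 3), max_iter=20,
                                n_estimators=150)
        per_seed = [
            set(cons.index[cons[f"status_seed{s}"] == "confirmed"])
            for s in (1, 2, 3)
        ]
        assert set(cons.index[cons["consensus"]]) == set.intersection(*per_seed)
        assert "f0" in set(cons.index[cons["consensus"]])
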