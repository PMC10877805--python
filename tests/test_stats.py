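"""W-scores, partial correlation, ordinal models, FDR, group comparison,
continuum curve."""

import numpy as np
import pandas as pd
import pytest

from glymph import (
    continuum_curve,
    fdr_adjust,
    fit_wscore_model,
    group_compare,
    ordinal_fit,
    partial_corr,
    w_score,
)


def _reference_frame(rng, n=200):
    age = rng.normal(75, 8, n)
    sex = rng.integers(0, 2, n)
    tiv = rng.normal(1450, 150, n)
    marker = 1.4 - 0.01 * (age - 75) + 0.05 * sex + rng.normal(0, 0.1, n)
    return pd.DataFrame({"age": age, "sex": sex, "tiv": tiv, "marker": marker})


class TestWScore:
    def test_constant_marker_flagged_degenerate(self, rng):
        df = _reference_frame(rng)
        df["marker"] = 3.0
        model = fit_wscore_model(df, "marker")
        assert model.degenerate
        assert model.coef[0] == pytest.approx(3.0)
        assert np.allclose(model.coef[1:], 0.0, atol=1e-10)
        with pytest.raises(ValueError, match="degenerate"):
            w_score(model, df.iloc[0])

    def test_sign_flip_maps_low_marker_to_high_deviation(self, rng):
        df = _reference_frame(rng)
        model = fit_wscore_model(df, "marker", sign_flip=True)
        low = df.iloc[0].copy()
        high = df.iloc[0].copy()
        low["marker"] = 1.0
        high["marker"] = 1.8
        assert w_score(model, low) > w_score(model, high)

    def test_parameter_recovery(self, rng):
        n = 5000
        age = rng.normal(75, 8, n)
        df = pd.DataFrame(
            {
                "age": age,
                "sex": rng.integers(0, 2, n),
                "tiv": rng.normal(1450, 150, n),
                "marker": 2.0 * age + rng.normal(0, 1.0, n),
            }
        )
        model = fit_wscore_model(df, "marker")
        assert model.coef[1] == pytest.approx(2.0, abs=0.05)
        assert model.residual_sd == pytest.approx(1.0, abs=0.05)

    def test_reference_scores_mean_zero_sd_one(self, rng):
        df = _reference_frame(rng, n=2000)
        model = fit_wscore_model(df, "marker")
        scores = np.array([w_score(model, row) for _, row in df.iterrows()])
        assert abs(scores.mean()) <= 1e-10
        assert scores.std(ddof=1) == pytest.approx(1.0, abs=0.01)

    def test_one_residual_sd_scores_one(self, rng):
        df = _reference_frame(rng)
        model = fit_wscore_model(df, "marker")
        rec = df.iloc[3].copy()
        rec["marker"] = model.predict(rec) + model.residual_sd
        assert w_score(model, rec) == pytest.approx(1.0, abs=1e-10)

    def test_too_few_reference_records(self, rng):
        df = _reference_frame(rng, n=5)
        with pytest.raises(ValueError, match="reference records"):
            fit_wscore_model(df, "marker")


class TestPartialCorr:
    def test_identity_without_covariates(self, rng):
        x = rng.normal(size=50)
        df = pd.DataFrame({"x": x, "y": x})
        res = partial_corr(df, "x", "y")
        assert res.r == pytest.approx(1.0)

    def test_conditional_independence_null(self, rng):
        n = 10000
        z = rng.normal(size=n)
        df = pd.DataFrame(
            {"z": z, "x": z + rng.normal(size=n), "y": z + rng.normal(size=n)}
        )
        res = partial_corr(df, "x", "y", covariates=["z"])
        assert abs(res.r) < 0.03
        # and strong marginal dependence confirms the adjustment did the work
        assert partial_corr(df, "x", "y").r > 0.3

    def test_matches_independent_oracle(self, rng):
        """Equivalence with pingouin's precision-matrix implementation."""
        pingouin = pytest.importorskip("pingouin")
        n = 300
        df = pd.DataFrame(
            rng.normal(size=(n, 4)), columns=["x", "y", "c1", "c2"]
        )
        df["y"] += 0.4 * df["x"] + 0.3 * df["c1"]
        res = partial_corr(df, "x", "y", covariates=["c1", "c2"])
        oracle = pingouin.partial_corr(df, x="x", y="y", covar=["c1", "c2"])
        p_col = "p_val" if "p_val" in oracle.columns else "p-val"
        assert res.r == pytest.approx(float(oracle["r"].iloc[0]), abs=1e-12)
        assert res.p == pytest.approx(float(oracle[p_col].iloc[0]), rel=1e-8)
        assert res.n == int(oracle["n"].iloc[0])

    def test_spearman_is_rank_invariant_in_xy(self, rng):
        n = 500
        df = pd.DataFrame({"c": rng.normal(size=n)})
        df["x"] = df["c"] + rng.normal(size=n)
        df["y"] = df["x"] + rng.normal(size=n)
        res = partial_corr(df, "x", "y", covariates=["c"], method="spearman")
        df2 = df.copy()
        df2["x"] = np.exp(df2["x"])  # monotone transform of x only
        res2 = partial_corr(df2, "x", "y", covariates=["c"], method="spearman")
        assert res.r == pytest.approx(res2.r, abs=1e-12)

    def test_insufficient_n_raises(self, rng):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0], "y": [1.0, 2.0, 3.0], "c": [0.0, 1.0, 0.5]})
        with pytest.raises(ValueError, match="complete cases"):
            partial_corr(df, "x", "y", covariates=["c"])

    def test_zero_variance_raises(self):
        df = pd.DataFrame({"x": np.ones(30), "y": np.arange(30.0)})
        with pytest.raises(ValueError, match="zero-variance"):
            partial_corr(df, "x", "y")


class TestOrdinalFit:
    @staticmethod
    def _latent_frame(rng, n, beta=1.0, cuts=(-1.0, 0.0, 1.0)):
        w = rng.normal(size=n)
        latent = beta * w + rng.logistic(size=n)
        grade = 1 + (latent[:, None] > np.asarray(cuts)[None, :]).sum(axis=1)
        return pd.DataFrame({"grade": grade, "w": w})

    def test_slope_recovery(self, rng):
        df = self._latent_frame(rng, 5000)
        fit = ordinal_fit(df, "grade", exposures=["w"])
        assert fit.converged
        assert fit.coef["w"] == pytest.approx(1.0, abs=0.15)
        assert np.all(np.diff(fit.cutpoints) > 0)
        assert fit.cutpoints == pytest.approx([-1.0, 0.0, 1.0], abs=0.15)

    def test_null_slope_small(self, rng):
        df = self._latent_frame(rng, 5000, beta=0.0)
        fit = ordinal_fit(df, "grade", exposures=["w"])
        assert abs(fit.coef["w"]) < 0.1
        assert fit.pvalues["w"] > 0.01

    def test_single_grade_outcome_raises(self, rng):
        df = pd.DataFrame({"grade": np.ones(100, dtype=int), "w": rng.normal(size=100)})
        with pytest.raises(ValueError, match="fewer than 2"):
            ordinal_fit(df, "grade", exposures=["w"])


class TestFdrAdjust:
    @staticmethod
    def _brute_force_bh(pvals):
        """Definitional BH step-up: adjusted p = min over j>=rank of
        n*p_(j)/j, capped at 1."""
        p = np.asarray(pvals, dtype=float)
        n = len(p)
        order = np.argsort(p, kind="stable")
        adj = np.empty(n)
        running = 1.0
        for rank_from_end, idx in enumerate(order[::-1]):
            j = n - rank_from_end
            running = min(running, n * p[idx] / j)
            adj[idx] = running
        return adj

    def test_hand_computed_example(self):
        got = fdr_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(got, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert fdr_adjust([0.37])[0] == pytest.approx(0.37)

    def test_all_ones(self):
        assert np.allclose(fdr_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_matches_brute_force_on_permutations(self):
        """All 720 orderings of six p-values agree with the definition."""
        import itertools

        base = [0.001, 0.008, 0.039, 0.041, 0.042, 0.6]
        for perm in itertools.permutations(base):
            assert np.allclose(fdr_adjust(perm), self._brute_force_bh(perm), atol=1e-12)

    def test_random_sets_match_brute_force(self, rng):
        for size in (1, 2, 3, 4, 5, 6):
            for _ in range(20):
                p = rng.uniform(size=size)
                assert np.allclose(fdr_adjust(p), self._brute_force_bh(p), atol=1e-12)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            fdr_adjust([-0.1])


class TestGroupCompare:
    def test_shifted_group_detected(self, rng):
        n = 200
        df = pd.DataFrame(
            {
                "group": ["A"] * n + ["B"] * n,
                "v": np.concatenate([rng.normal(0, 1, n), rng.normal(3, 1, n)]),
                "flag": np.concatenate([rng.integers(0, 2, n), rng.integers(0, 2, n)]),
            }
        )
        table = group_compare(df, continuous=["v"], categorical=["flag"])
        assert table.loc[table.variable == "v", "p"].iloc[0] < 0.001

    def test_identical_categorical_tables_give_zero_statistic(self):
        df = pd.DataFrame(
            {
                "group": ["A"] * 40 + ["B"] * 40,
                "flag": ([0] * 20 + [1] * 20) * 2,
            }
        )
        table = group_compare(df, categorical=["flag"])
        assert table["statistic"].iloc[0] == pytest.approx(0.0)

    def test_empty_group_raises(self):
        df = pd.DataFrame({"group": ["A"] * 10, "v": np.arange(10.0)})
        with pytest.raises(ValueError, match="at least 2 groups"):
            group_compare(df, continuous=["v"])


class TestContinuumCurve:
    @staticmethod
    def _scores(means, per_stage=25, seed=0):
        rng = np.random.default_rng(seed)
        stages = []
        w = []
        for stage, mu in zip(("CN-", "CN+", "MCI+", "AD+"), means):
            stages += [stage] * per_stage
            w += list(mu + 0.1 * rng.normal(size=per_stage))
        return np.array(w), np.array(stages)

    def test_constant_scores_give_flat_curve(self):
        w, stages = self._scores([1.0, 1.0, 1.0, 1.0])
        w = np.full_like(w, 1.0)
        curve = continuum_curve(w, stages, seed=1)
        assert np.allclose(curve.grid_y, 1.0)

    def test_monotone_means_stay_monotone_at_stages(self):
        w, stages = self._scores([0.0, 0.5, 1.2, 2.0])
        curve = continuum_curve(w, stages, seed=1)
        assert np.all(np.diff(curve.stage_means) > 0)
        fitted_at_stages = np.interp(curve.stage_x, curve.grid_x, curve.grid_y)
        assert np.allclose(fitted_at_stages, curve.stage_means, atol=1e-10)

    def test_band_contains_fit(self):
        w, stages = self._scores([0.0, 0.4, 1.0, 1.8])
        curve = continuum_curve(w, stages, seed=2)
        assert np.all(curve.band_lo <= curve.band_hi)

    def test_band_deterministic_given_seed(self):
        w, stages = self._scores([0.0, 0.4, 1.0, 1.8])
        c1 = continuum_curve(w, stages, seed=5)
        c2 = continuum_curve(w, stages, seed=5)
        assert np.array_equal(c1.band_lo, c2.band_lo)

    def test_too_few_per_stage_raises(self):
        w = np.array([0.0, 1.0, 2.0, 0.1, 1.1, 2.1, 0.2, 1.2])
        stages = np.array(["CN-", "CN+", "MCI+"] * 2 + ["CN-", "CN+"])
        with pytest.raises(ValueError, match=">= 4 observations"):
            continuum_curve(w, stages)
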