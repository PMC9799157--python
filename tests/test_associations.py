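"""Correlation CIs, regression importance/VIF, residualization, extreme-trial
contrasts, Welch subset tests, and the dissociation summary."""

from __future__ import annotations

from itertools import permutations

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from trialnet.associations import (
    ContrastSpec,
    compute_contrast_map,
    correlate_pair,
    correlate_predictors_networks,
    dissociation_report,
    extreme_quadrant_subsets,
    fisher_ci,
    fit_network_model,
    lmg_importance,
    residualize_composites,
    rt_validation,
    select_extreme_trials,
    subset_t_test,
    vif,
)


def lmg_by_ordering_enumeration(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Oracle: explicit average of incremental R^2 over all p! entry orders."""
    p = x.shape[1]
    shares = np.zeros(p)
    n_perm = 0
    for perm in permutations(range(p)):
        n_perm += 1
        prev = 0.0
        for pos in range(p):
            idx = list(perm[: pos + 1])
            r2 = sm.OLS(y, sm.add_constant(x[:, idx])).fit().rsquared
            shares[perm[pos]] += r2 - prev
            prev = r2
    return shares / n_perm


class TestFisherCI:
    @pytest.mark.parametrize(
        "r,expected",
        [
            (0.61, (0.51, 0.69)),
            (0.70, (0.62, 0.77)),
            (0.65, (0.56, 0.73)),
        ],
    )
    def test_printed_worked_examples_at_n180(self, r, expected):
        lo, hi = fisher_ci(r, 180)
        assert (round(lo, 2), round(hi, 2)) == expected

    def test_zero_r_gives_symmetric_interval(self):
        lo, hi = fisher_ci(0.0, 100)
        assert lo == pytest.approx(-hi)

    def test_tiny_sample_rejected(self):
        with pytest.raises(ValueError, match="n >= 4"):
            fisher_ci(0.5, 3)

    @given(st.floats(-0.95, 0.95), st.integers(10, 500))
    @settings(max_examples=50, deadline=None)
    def test_interval_contains_point_estimate(self, r, n):
        lo, hi = fisher_ci(r, n)
        assert lo <= r <= hi

    def test_null_coverage_near_95_percent(self):
        # 1,000 independent null samples at n=180
        rng = np.random.default_rng(23)
        covered = 0
        for _ in range(1000):
            x, y = rng.normal(0, 1, (2, 180))
            res = correlate_pair(x, y, "x", "y")
            covered += res.ci_low <= 0.0 <= res.ci_high
        assert 0.935 <= covered / 1000 <= 0.965


class TestLMG:
    def test_orthogonal_regressors_get_marginal_r2(self):
        rng = np.random.default_rng(0)
        n = 4000
        x = rng.normal(0, 1, (n, 2))
        x = np.linalg.qr(x)[0] * np.sqrt(n)  # exactly orthonormal columns
        y = np.sqrt(0.3) * x[:, 0] + np.sqrt(0.2) * x[:, 1] + np.sqrt(0.5) * rng.normal(0, 1, n)
        shares = lmg_importance(y, x, ["a", "b"])
        assert shares["a"] == pytest.approx(0.3, abs=0.03)
        assert shares["b"] == pytest.approx(0.2, abs=0.03)

    def test_duplicated_regressor_splits_share_equally(self):
        rng = np.random.default_rng(1)
        n = 500
        base = rng.normal(0, 1, n)
        x = np.column_stack([base, base + rng.normal(0, 1e-6, n)])
        y = base + rng.normal(0, 1, n)
        shares = lmg_importance(y, x, ["a", "b"])
        assert shares["a"] == pytest.approx(shares["b"], abs=1e-3)

    def test_single_regressor_share_equals_r2(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, (200, 1))
        y = x[:, 0] + rng.normal(0, 1, 200)
        r2 = sm.OLS(y, sm.add_constant(x)).fit().rsquared
        assert lmg_importance(y, x, ["a"])["a"] == pytest.approx(r2, abs=1e-12)

    @pytest.mark.parametrize("p", [2, 3, 4, 5])
    def test_subset_weighting_equals_ordering_enumeration(self, p):
        rng = np.random.default_rng(p)
        n = 120
        cov = rng.normal(0, 1, (p, p))
        x = rng.normal(0, 1, (n, p)) @ cov
        y = x @ rng.normal(0, 1, p) + rng.normal(0, 2, n)
        got = lmg_importance(y, x, [f"v{i}" for i in range(p)]).to_numpy()
        expected = lmg_by_ordering_enumeration(y, x)
        np.testing.assert_allclose(got, expected, atol=1e-10)
        full = sm.OLS(y, sm.add_constant(x)).fit().rsquared
        assert got.sum() == pytest.approx(full, abs=1e-10)

    def test_exact_collinearity_rejected(self):
        x = np.column_stack([np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(ValueError, match="collinear"):
            lmg_importance(np.arange(10.0), x, ["a", "b"])


class TestVIF:
    def test_orthogonal_regressors_all_unit(self):
        rng = np.random.default_rng(3)
        # columns orthogonal to each other AND to the intercept
        q = np.linalg.qr(
            np.column_stack([np.ones(100), rng.normal(0, 1, (100, 3))])
        )[0][:, 1:]
        out = vif(pd.DataFrame(q, columns=["a", "b", "c"]))
        np.testing.assert_allclose(out, 1.0, atol=1e-10)

    def test_pairwise_r_0866_gives_vif_4(self):
        # r^2 = 0.75 -> VIF = 1/(1-0.75) = 4
        rng = np.random.default_rng(4)
        n = 200000
        a = rng.normal(0, 1, n)
        b = np.sqrt(0.75) * a + np.sqrt(0.25) * rng.normal(0, 1, n)
        out = vif(pd.DataFrame({"a": a, "b": b}))
        assert out["a"] == pytest.approx(4.0, abs=0.07)

    def test_duplicated_regressor_is_infinite(self):
        a = np.arange(20.0)
        out = vif(pd.DataFrame({"a": a, "b": a}))
        assert np.isinf(out).all()

    def test_single_regressor_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            vif(pd.DataFrame({"a": np.arange(5.0)}))


class TestNetworkModel:
    def test_single_regressor_r2_is_squared_correlation(self):
        rng = np.random.default_rng(5)
        x = pd.DataFrame({"c": rng.normal(0, 1, 100)}, index=range(100))
        y = pd.Series(x["c"] + rng.normal(0, 1, 100), index=x.index, name="DN-A")
        fit = fit_network_model(y, x)
        r = np.corrcoef(x["c"], y)[0, 1]
        assert fit.r2 == pytest.approx(r**2, abs=1e-12)

    def test_exactly_linear_response_r2_one(self):
        x = pd.DataFrame(
            {"a": np.arange(30.0), "b": np.arange(30.0) ** 2}, index=range(30)
        )
        y = pd.Series(2 * x["a"] - x["b"] + 1, index=x.index, name="n")
        assert fit_network_model(y, x).r2 == pytest.approx(1.0)

    def test_orthogonal_marginal_r2_adds_up(self):
        rng = np.random.default_rng(6)
        n = 5000
        q = np.linalg.qr(rng.normal(0, 1, (n, 2)))[0] * np.sqrt(n)
        y_arr = np.sqrt(0.3) * q[:, 0] + np.sqrt(0.2) * q[:, 1] + np.sqrt(0.5) * rng.normal(0, 1, n)
        x = pd.DataFrame(q, columns=["a", "b"], index=range(n))
        fit = fit_network_model(pd.Series(y_arr, index=x.index, name="n"), x)
        assert fit.r2 == pytest.approx(0.5, abs=0.03)
        assert fit.lmg.sum() == pytest.approx(fit.r2, abs=1e-10)


class TestResidualization:
    def test_composite_identical_to_covariate_zeroes_out(self):
        s = pd.DataFrame({"Difficulty": [1.0, 2, 3], "Copy": [1.0, 2, 3]})
        out = residualize_composites(s, "Difficulty")
        np.testing.assert_allclose(out["Copy"], 0.0, atol=1e-12)

    def test_orthogonal_composite_only_mean_centered(self):
        s = pd.DataFrame(
            {"Difficulty": [-1.0, 1, -1, 1], "Other": [1.0, 1, -1, -1]}
        )
        out = residualize_composites(s, "Difficulty")
        np.testing.assert_allclose(out["Other"], s["Other"] - s["Other"].mean(), atol=1e-12)

    def test_residuals_orthogonal_to_covariate(self):
        rng = np.random.default_rng(7)
        s = pd.DataFrame(rng.normal(0, 1, (180, 4)), columns=["Difficulty", "a", "b", "c"])
        s["a"] += 0.8 * s["Difficulty"]
        out = residualize_composites(s, "Difficulty")
        for col in out:
            assert abs(np.corrcoef(out[col], s["Difficulty"])[0, 1]) < 1e-10

    def test_zero_variance_covariate_rejected(self):
        s = pd.DataFrame({"Difficulty": [1.0, 1, 1], "a": [1.0, 2, 3]})
        with pytest.raises(ValueError, match="zero-variance"):
            residualize_composites(s, "Difficulty")


class TestRTValidation:
    def test_outlier_trials_dropped_before_means(self):
        rts = pd.DataFrame(
            {"trial_id": [1, 1, 2, 2, 3, 3, 4, 4], "response_time": [5, 100.0, 6, 6, 7, 7, 8, 8]}
        )
        diff = pd.Series([1.0, 2, 3, 4], index=pd.Index([1, 2, 3, 4], name="trial_id"))
        res = rt_validation(rts, diff)
        assert res.n == 4
        # trial 1 mean is 5 (outlier removed), so correlation is near-perfect
        assert res.r > 0.95

    def test_all_outliers_rejected(self):
        rts = pd.DataFrame({"trial_id": [1, 2, 3, 4], "response_time": [70.0] * 4})
        diff = pd.Series([1.0, 2, 3, 4], index=pd.Index([1, 2, 3, 4], name="trial_id"))
        with pytest.raises(ValueError, match="excluded"):
            rt_validation(rts, diff)


class TestExtremeTrials:
    def test_argmax_and_argmin_at_n1(self):
        scores = pd.DataFrame(
            {"c": [0.3, -1.0, 2.0, 0.1]}, index=pd.Index([1, 2, 3, 4], name="trial_id")
        )
        spec = select_extreme_trials(scores, "c", 1)
        assert spec.high == (3,) and spec.low == (2,)

    def test_all_equal_scores_tie_break_by_trial_id(self):
        scores = pd.DataFrame(
            {"c": [1.0] * 6}, index=pd.Index([10, 11, 12, 13, 14, 15], name="trial_id")
        )
        spec = select_extreme_trials(scores, "c", 2)
        assert spec.low == (10, 11) and spec.high == (14, 15)

    def test_role_filter_restricts_eligibility(self):
        scores = pd.DataFrame(
            {"c": [5.0, 4.0, 3.0, 2.0]}, index=pd.Index([1, 2, 3, 4], name="trial_id")
        )
        meta = pd.DataFrame(
            {"trial_id": [1, 2, 3, 4], "role": ["target", "control", "control", "control"]}
        )
        spec = select_extreme_trials(scores, "c", 1, meta, role="control")
        assert spec.high == (2,) and spec.low == (4,)

    def test_insufficient_trials_rejected(self):
        scores = pd.DataFrame({"c": [1.0, 2.0]}, index=pd.Index([1, 2], name="trial_id"))
        with pytest.raises(ValueError, match="not enough"):
            select_extreme_trials(scores, "c", 2)

    def test_generator_controls_high_set_mean_exceeds_low(self, default_study):
        lat = default_study.trial_latents
        scores = lat[["SceneConstruction"]]
        spec = select_extreme_trials(
            scores, "SceneConstruction", 10, default_study.metadata, role="control"
        )
        assert (
            lat.loc[list(spec.high), "SceneConstruction"].mean()
            > lat.loc[list(spec.low), "SceneConstruction"].mean()
        )


class TestContrastMaps:
    def test_identical_high_low_sets_give_zero_map(self):
        rng = np.random.default_rng(8)
        betas = rng.normal(0, 1, (6, 10))
        labels = np.array(["DN-A"] * 5 + ["DN-B"] * 5)
        spec = ContrastSpec("c", 2, high=(1, 2), low=(1, 2))
        cmap = compute_contrast_map(betas, np.arange(1, 7), spec, labels, "DN-A")
        np.testing.assert_allclose(cmap.values, 0.0)

    def test_scene_contrast_lands_inside_dna_for_most_subjects(self, default_study):
        lat = default_study.trial_latents
        spec = select_extreme_trials(
            lat[["SceneConstruction"]], "SceneConstruction", 10,
            default_study.metadata, role="control",
        )
        trial_ids = default_study.metadata["trial_id"].to_numpy()
        wins = sum(
            compute_contrast_map(
                default_study.betas[s], trial_ids, spec, default_study.labels[s], "DN-A", s
            ).mean_inside
            > compute_contrast_map(
                default_study.betas[s], trial_ids, spec, default_study.labels[s], "DN-A", s
            ).mean_outside
            for s in default_study.betas
        )
        assert wins >= 9

    def test_shuffled_labels_dice_near_chance(self, default_study):
        rng = np.random.default_rng(9)
        lat = default_study.trial_latents
        spec = select_extreme_trials(lat[["Difficulty"]], "Difficulty", 10)
        sid = sorted(default_study.betas)[0]
        labels = default_study.labels[sid].copy()
        rng.shuffle(labels)
        cmap = compute_contrast_map(
            default_study.betas[sid],
            default_study.metadata["trial_id"].to_numpy(),
            spec,
            labels,
            "FPN-B",
            sid,
        )
        chance = (labels == "FPN-B").mean()
        assert cmap.dice == pytest.approx(chance, abs=0.12)

    def test_missing_spec_trial_rejected(self):
        spec = ContrastSpec("c", 1, high=(99,), low=(1,))
        with pytest.raises(ValueError, match="missing"):
            compute_contrast_map(
                np.ones((2, 4)), np.array([1, 2]), spec, np.array(["DN-A"] * 4), "DN-A"
            )


class TestSubsetTest:
    def test_identical_groups_give_zero_t(self):
        res = subset_t_test([1.0, 2, 3], [1.0, 2, 3])
        assert res.t == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_welch_example(self):
        # {0,1,2} vs {10,11,12}: t = -10/sqrt(2/3) = -12.2474, df = 4
        res = subset_t_test([0.0, 1, 2], [10.0, 11, 12])
        assert res.t == pytest.approx(-12.2474487, abs=1e-6)
        assert res.df == pytest.approx(4.0)

    def test_equal_variance_equal_n_df_is_pooled(self):
        rng = np.random.default_rng(10)
        a = rng.normal(0, 1, 30)
        b = rng.normal(0, 1, 30) * np.std(a) / np.std(rng.normal(0, 1, 30))
        res = subset_t_test(a, a + 1.0)  # exactly equal variances
        assert res.df == pytest.approx(58.0)

    def test_welch_df_never_exceeds_pooled_df(self):
        rng = np.random.default_rng(11)
        a, b = rng.normal(0, 1, 12), rng.normal(0, 5, 20)
        res = subset_t_test(a, b)
        assert res.df <= 30.0

    def test_quadrant_subsets_lean_the_right_way(self):
        rng = np.random.default_rng(12)
        scores = pd.DataFrame(
            {"A": rng.normal(0, 1, 60), "B": rng.normal(0, 1, 60)},
            index=pd.Index(range(1, 61), name="trial_id"),
        )
        side_a, side_b = extreme_quadrant_subsets(scores, "A", "B", 7)
        za = (scores["A"] - scores["A"].mean()) / scores["A"].std(ddof=1)
        zb = (scores["B"] - scores["B"].mean()) / scores["B"].std(ddof=1)
        delta = za - zb
        assert delta.loc[list(side_a)].min() > delta.loc[list(side_b)].max()


class TestGridAndDissociation:
    @staticmethod
    def toy_grid():
        rng = np.random.default_rng(13)
        idx = pd.Index(range(1, 101), name="trial_id")
        pred = pd.DataFrame(
            {"Scene": rng.normal(0, 1, 100), "Diff": rng.normal(0, 1, 100)}, index=idx
        )
        resp = pd.DataFrame(
            {
                "DN-A": pred["Scene"] + rng.normal(0, 0.8, 100),
                "FPN-B": pred["Diff"] + rng.normal(0, 0.8, 100),
            },
            index=idx,
        )
        return correlate_predictors_networks(pred, resp)

    def test_grid_has_all_pairs_with_valid_cis(self):
        grid = self.toy_grid()
        assert len(grid) == 4
        assert ((grid["ci_low"] <= grid["r"]) & (grid["r"] <= grid["ci_high"])).all()

    def test_diagonal_structure_flagged_selective(self):
        table = dissociation_report(self.toy_grid(), ("Scene", "Diff"), ("DN-A", "FPN-B"))
        assert table.attrs["selective"]

    def test_swapped_predictors_transpose_the_table(self):
        grid = self.toy_grid()
        a = dissociation_report(grid, ("Scene", "Diff"), ("DN-A", "FPN-B"))
        b = dissociation_report(grid, ("Diff", "Scene"), ("DN-A", "FPN-B"))
        assert set(map(tuple, a[["predictor", "network"]].to_numpy())) == set(
            map(tuple, b[["predictor", "network"]].to_numpy())
        )

    def test_identical_predictors_not_flagged(self):
        rng = np.random.default_rng(14)
        idx = pd.Index(range(1, 51), name="trial_id")
        same = rng.normal(0, 1, 50)
        pred = pd.DataFrame({"P1": same, "P2": same}, index=idx)
        resp = pd.DataFrame(
            {"N1": same + rng.normal(0, 1, 50), "N2": rng.normal(0, 1, 50)}, index=idx
        )
        grid = correlate_predictors_networks(pred, resp)
        table = dissociation_report(grid, ("P1", "P2"), ("N1", "N2"))
        assert not table.attrs["selective"]

    def test_missing_cell_rejected(self):
        grid = self.toy_grid()
        with pytest.raises(ValueError, match="missing cell"):
            dissociation_report(grid, ("Scene", "Nope"), ("DN-A", "FPN-B"))
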