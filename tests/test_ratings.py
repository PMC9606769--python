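"""Rating analyses: aggregation, standardized β, Kruskal–Dunn, curves."""

import numpy as np
import pandas as pd
import pytest

import oracles
from sipscape.ratings import (
    aggregate_ratings,
    effect_band,
    fit_quadratic,
    inter_rating_correlations,
    kruskal_dunn,
    significance_stars,
    slope_preference_curves,
    standardized_regression,
    validate_rating_table,
)


def _toy_ratings():
    rows = []
    for p in ["P0", "P1"]:
        for i, img in enumerate(["a", "b", "c"]):
            for d in ["Pleasing", "Harmonious", "Interesting"]:
                rows.append(
                    {
                        "participant_id": p,
                        "image_id": img,
                        "category": "style_transferred",
                        "dimension": d,
                        "rating": 0.2 + 0.1 * i + (0.05 if p == "P1" else 0.0),
                    }
                )
    return pd.DataFrame(rows)


class TestSchemaAndAggregation:
    def test_validation_catches_bad_rows(self):
        df = _toy_ratings()
        validate_rating_table(df)
        bad = df.copy()
        bad.loc[0, "rating"] = 1.5
        with pytest.raises(ValueError):
            validate_rating_table(bad)
        with pytest.raises(ValueError):
            validate_rating_table(pd.concat([df, df.iloc[[0]]]))

    def test_means_match_hand_arithmetic(self):
        agg = aggregate_ratings(_toy_ratings(), by="image")
        row = agg[(agg.image_id == "b") & (agg.dimension == "Pleasing")]
        assert row["rating"].item() == pytest.approx((0.3 + 0.35) / 2)
        assert row["n"].item() == 2

    def test_unknown_grouping_rejected(self):
        with pytest.raises(ValueError):
            aggregate_ratings(_toy_ratings(), by="nonsense")


class TestStandardizedRegression:
    def test_single_perfect_predictor(self, rng):
        X = pd.DataFrame(rng.standard_normal((50, 3)), columns=list("abc"))
        res = standardized_regression(X, 3.0 + 2.0 * X["b"].to_numpy())
        assert res.beta_star[1] == pytest.approx(1.0, abs=1e-8)
        assert abs(res.beta_star[0]) < 1e-8 and abs(res.beta_star[2]) < 1e-8
        assert res.r2_adj == pytest.approx(1.0, abs=1e-10)
        assert res.effect_bands[1] == "strong"

    @pytest.mark.parametrize(
        "value,band",
        [(0.19, "weak"), (0.2, "moderate"), (-0.49, "moderate"), (0.5, "strong")],
    )
    def test_effect_band_boundaries(self, value, band):
        assert effect_band(value) == band

    def test_affine_invariance(self, rng):
        X = pd.DataFrame(rng.standard_normal((60, 4)), columns=list("abcd"))
        y = X.to_numpy() @ [0.5, -0.3, 0.0, 0.2] + rng.standard_normal(60)
        a = standardized_regression(X, y)
        X2 = X * [10.0, -0.2, 3.0, 100.0] + [5, -2, 0, 7]
        b = standardized_regression(X2, 0.01 * y + 42.0)
        signs = np.sign([10.0, -0.2, 3.0, 100.0])
        np.testing.assert_allclose(a.beta_star * signs, b.beta_star, atol=1e-10)
        np.testing.assert_allclose(a.p_values, b.p_values, atol=1e-10)

    def test_planted_coefficients_recovered(self, rng):
        n, beta = 150, np.array([-0.4, 0.3, 0.0, 0.0])
        X = pd.DataFrame(rng.standard_normal((n, 4)), columns=list("abcd"))
        sd_lat = np.sqrt(beta @ beta + 0.3**2)
        errs = []
        for _ in range(20):
            y = X.to_numpy() @ beta + rng.normal(0, 0.3, n)
            res = standardized_regression(X, y)
            errs.append(np.abs(res.beta_star - beta / sd_lat))
        assert np.mean(errs) < 0.05

    def test_constant_predictor_rejected(self, rng):
        X = pd.DataFrame({"a": rng.standard_normal(20), "c": np.ones(20)})
        with pytest.raises(ValueError):
            standardized_regression(X, rng.standard_normal(20))

    def test_collinearity_warns_with_vif(self, rng):
        x = rng.standard_normal(40)
        X = pd.DataFrame({"a": x, "b": x + 1e-8 * rng.standard_normal(40)})
        with pytest.warns(UserWarning, match="VIF"):
            standardized_regression(X, rng.standard_normal(40))


class TestKruskalDunn:
    def test_identical_groups_h_zero(self):
        vals = np.tile([1.0, 2.0, 3.0, 4.0, 5.0], 3)
        groups = np.repeat(["a", "b", "c"], 5)
        res = kruskal_dunn(vals, groups)
        assert res.h_statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value > 0.99

    def test_matches_hand_rank_arithmetic(self):
        groups = [[3, 1, 4, 1], [5, 9, 2, 6], [5, 3, 5, 8]]
        vals = np.concatenate([np.asarray(g, float) for g in groups])
        labels = np.repeat(["g1", "g2", "g3"], 4)
        res = kruskal_dunn(vals, labels)
        assert res.h_statistic == pytest.approx(oracles.kruskal_h(groups), abs=1e-9)

    def test_monotone_invariance(self, rng):
        vals = rng.uniform(size=30)
        labels = np.repeat(list("abc"), 10)
        a = kruskal_dunn(vals, labels).h_statistic
        b = kruskal_dunn(np.exp(5 * vals), labels).h_statistic
        assert a == pytest.approx(b, abs=1e-9)

    def test_adjusted_p_dominates_raw_and_stars(self, rng):
        vals = np.concatenate(
            [rng.normal(0, 1, 20), rng.normal(2, 1, 20), rng.normal(4, 1, 20)]
        )
        labels = np.repeat(list("abc"), 20)
        res = kruskal_dunn(vals, labels)
        assert len(res.comparisons) == 3
        for c in res.comparisons:
            assert c.p_adjusted >= c.p_raw - 1e-15
        assert significance_stars(0.03) == "*"
        assert significance_stars(4e-5) == "****"
        assert significance_stars(0.2) == "n.s."

    def test_small_group_dropped(self, rng):
        vals = np.array([1.0, 2.0, 3.0, 4.0, 9.0])
        labels = np.array(["a", "a", "b", "b", "tiny"])
        with pytest.warns(UserWarning, match="tiny"):
            res = kruskal_dunn(vals, labels)
        assert res.groups == ("a", "b")

    def test_bonferroni_switch(self, rng):
        vals = rng.uniform(size=30)
        labels = np.repeat(list("abc"), 10)
        res = kruskal_dunn(vals, labels, adjustment="bonferroni")
        for c in res.comparisons:
            assert c.p_adjusted == pytest.approx(min(1.0, 3 * c.p_raw))


class TestQuadraticFits:
    def test_exact_parabola_recovered(self):
        x = np.array([-5.0, -4.0, -3.0, -2.0, -1.0, 0.0])
        y = 0.8 - 0.1 * (x + 2.5) ** 2
        fit = fit_quadratic(x, y)
        assert fit.vertex == pytest.approx(-2.5, abs=1e-9)
        assert fit.curvature_sign == -1 and fit.inverted_u
        assert fit.r2 == pytest.approx(1.0)

    def test_three_points_interpolated_exactly(self):
        fit = fit_quadratic(np.array([0.0, 1.0, 2.0]), np.array([1.0, 0.0, 3.0]))
        for x, y in [(0, 1), (1, 0), (2, 3)]:
            assert fit.a + fit.b * x + fit.c * x**2 == pytest.approx(y, abs=1e-9)

    def test_requires_three_levels(self):
        with pytest.raises(ValueError):
            fit_quadratic(np.array([1.0, 1.0, 2.0]), np.array([1.0, 2.0, 3.0]))

    def test_slope_preference_curves_on_planted_parabola(self, rng):
        slopes = [-5.0, -4.0, -3.0, -2.0, -1.0, 0.0]
        rows = []
        set_slopes = {}
        for si, s in enumerate(slopes):
            for i in range(4):
                img = f"rp{si}_{i}"
                set_slopes[img] = s
                for p in range(6):
                    for d in ["Pleasing", "Harmonious", "Interesting"]:
                        base = 0.8 - 0.05 * (s + 2.5) ** 2
                        rows.append(
                            {
                                "participant_id": f"P{p}",
                                "image_id": img,
                                "category": "random_phase",
                                "dimension": d,
                                "rating": np.clip(base + rng.normal(0, 0.02), 0, 1),
                            }
                        )
        out = slope_preference_curves(pd.DataFrame(rows), set_slopes)
        for d in ["Pleasing", "Harmonious", "Interesting"]:
            fit = out[d]["quadratic"]
            assert fit.inverted_u
            assert -3.0 < fit.vertex < -2.0
            assert out[d]["group_test"].p_value < 0.01


class TestInterRatingCorrelations:
    def test_identical_dimensions_rho_one(self):
        df = _toy_ratings()  # all three dimensions generated identically
        pooled = inter_rating_correlations(df, scope="pooled")
        np.testing.assert_allclose(pooled.iloc[0].to_numpy(), 1.0)

    def test_pooled_matches_brute_force_ranks(self, rng):
        rows = []
        p_vals = rng.uniform(size=10)
        h_vals = rng.uniform(size=10)
        for i in range(10):
            for d, v in [("Pleasing", p_vals[i]), ("Harmonious", h_vals[i]),
                         ("Interesting", rng.uniform())]:
                rows.append(
                    {
                        "participant_id": "P0",
                        "image_id": f"img{i}",
                        "category": "original",
                        "dimension": d,
                        "rating": v,
                    }
                )
        pooled = inter_rating_correlations(pd.DataFrame(rows), scope="pooled")
        rp = pd.Series(p_vals).rank()
        rh = pd.Series(h_vals).rank()
        assert pooled["rho_PH"].item() == pytest.approx(np.corrcoef(rp, rh)[0, 1])

    def test_anticorrelated_rater_detected(self, rng):
        rows = []
        for i in range(20):
            h = rng.uniform()
            for d, v in [("Pleasing", rng.uniform()), ("Harmonious", h),
                         ("Interesting", 1.0 - h)]:
                rows.append(
                    {
                        "participant_id": "P9",
                        "image_id": f"img{i}",
                        "category": "original",
                        "dimension": d,
                        "rating": v,
                    }
                )
        per = inter_rating_correlations(pd.DataFrame(rows), scope="per_participant")
        assert per.loc["P9", "rho_HI"] == pytest.approx(-1.0)

    def test_sparse_participant_excluded(self, rng):
        df = _toy_ratings()  # only 3 common images per participant
        with pytest.warns(UserWarning):
            per = inter_rating_correlations(df, scope="per_participant", min_common=5)
        assert per.empty
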