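"""ilr linear models, MANOVA, logit cross-checks, influence, target bands."""

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import qr

from macroniche.compositional import (
    PCL,
    CompositionSet,
    closure,
    geometric_mean_composition,
    helmert_basis,
    ilr_rows,
)
from macroniche.models import (
    DesignSpec,
    IntakeTarget,
    anova_global,
    compare_to_target,
    cooks_influence,
    fit_compositional_lm,
    fit_logit_lm,
    group_geometric_means,
)
from macroniche.simulate import sample_logistic_normal


def two_group_set(mean_a, mean_b, n, cov, seed):
    rng = np.random.default_rng(seed)
    a = sample_logistic_normal(closure(mean_a), cov, n, rng)
    b = sample_logistic_normal(closure(mean_b), cov, n, rng)
    s = CompositionSet(PCL, np.vstack([a.values, b.values]),
                       {"subsidy": ["natural"] * n + ["anthropogenic"] * n})
    return s


def seasonal_set(means_by_season, n_per, cov, seed):
    rng = np.random.default_rng(seed)
    rows, seasons = [], []
    for season, mean in means_by_season.items():
        x = sample_logistic_normal(closure(mean), cov, n_per, rng)
        rows.append(x.values)
        seasons += [season] * n_per
    return CompositionSet(PCL, np.vstack(rows), {"season": seasons})


class TestCompositionalLm:
    def test_intercept_only_fits_geometric_mean(self, random_set):
        random_set.metadata["season"] = ["spring"] * len(random_set)
        spec = DesignSpec(random_set, ())
        fit = fit_compositional_lm(spec)
        g = geometric_mean_composition(random_set)
        fitted = fit.fitted_compositions()
        for c in fitted:
            assert np.allclose(c.values, g.values, atol=1e-9)

    def test_group_mean_recovery(self):
        cov = 0.2 * np.eye(2)
        s = two_group_set((0.45, 0.25, 0.30), (0.25, 0.45, 0.30), 200, cov, 42)
        fit = fit_compositional_lm(DesignSpec(s, ("subsidy",)))
        fitted = fit.fitted_compositions()
        for truth, lev in [((0.45, 0.25, 0.30), "natural"),
                           ((0.25, 0.45, 0.30), "anthropogenic")]:
            idx = [i for i, g in enumerate(s.metadata["subsidy"]) if g == lev][0]
            assert np.allclose(fitted.row(idx).values, closure(truth).values,
                               atol=0.01)

    def test_group_fitted_values_equal_per_group_geometric_means(self):
        s = two_group_set((0.4, 0.3, 0.3), (0.3, 0.3, 0.4), 15, 0.3 * np.eye(2), 3)
        fit = fit_compositional_lm(DesignSpec(s, ("subsidy",)))
        fitted = fit.fitted_compositions()
        means = group_geometric_means(s, "subsidy")
        for i, lev in enumerate(s.metadata["subsidy"]):
            assert np.allclose(fitted.row(i).values, means[lev].values, atol=1e-9)

    def test_perfect_fit_zero_residuals(self):
        vals = np.vstack([np.tile(closure((0.5, 0.3, 0.2)).values, (5, 1)),
                          np.tile(closure((0.2, 0.4, 0.4)).values, (5, 1))])
        s = CompositionSet(PCL, vals,
                           {"subsidy": ["natural"] * 5 + ["anthropogenic"] * 5})
        fit = fit_compositional_lm(DesignSpec(s, ("subsidy",)))
        assert np.allclose(fit.residuals_ilr, 0.0, atol=1e-12)

    def test_winter_rows_dropped_before_fitting(self):
        s = seasonal_set(
            {"spring": (0.4, 0.3, 0.3), "summer": (0.35, 0.35, 0.3),
             "autumn": (0.3, 0.4, 0.3)}, 6, 0.2 * np.eye(2), 8)
        winter = sample_logistic_normal(closure((0.2, 0.3, 0.5)), 0.2 * np.eye(2), 3, 9)
        full = CompositionSet(PCL, np.vstack([s.values, winter.values]),
                              {"season": s.metadata["season"] + ["winter"] * 3})
        fit = fit_compositional_lm(DesignSpec(full, ("season",)))
        assert fit.X.shape[0] == len(s)


class TestAnovaGlobal:
    def test_matches_statsmodels_manova(self):
        from statsmodels.multivariate.manova import MANOVA

        s = seasonal_set(
            {"spring": (0.4, 0.3, 0.3), "summer": (0.3, 0.4, 0.3),
             "autumn": (0.25, 0.45, 0.3)}, 10, 0.3 * np.eye(2), 21)
        fit = fit_compositional_lm(DesignSpec(s, ("season",)))
        ours = anova_global(fit, "season")
        Y = ilr_rows(s)
        df = pd.DataFrame({"y1": Y[:, 0], "y2": Y[:, 1],
                           "season": s.metadata["season"]})
        ref = MANOVA.from_formula("y1 + y2 ~ C(season)", data=df).mv_test()
        row = ref.results["C(season)"]["stat"].loc["Wilks' lambda"]
        assert ours.statistic == pytest.approx(float(row["Value"]), abs=1e-10)
        assert ours.p_value == pytest.approx(float(row["Pr > F"]), abs=1e-10)

    def test_basis_invariance(self):
        s = two_group_set((0.4, 0.3, 0.3), (0.3, 0.4, 0.3), 12, 0.25 * np.eye(2), 5)
        Q = qr(np.array([[0.3, 0.9], [1.0, -0.2]]))[0]
        p1 = anova_global(
            fit_compositional_lm(DesignSpec(s, ("subsidy",))), "subsidy"
        ).p_value
        p2 = anova_global(
            fit_compositional_lm(DesignSpec(s, ("subsidy",)),
                                 basis=Q @ helmert_basis(3)),
            "subsidy",
        ).p_value
        assert p1 == pytest.approx(p2, abs=1e-9)

    def test_type_one_error_calibration(self):
        rng = np.random.default_rng(123)
        mean = closure((0.35, 0.35, 0.30))
        groups = ["natural"] * 20 + ["anthropogenic"] * 20
        rejections = 0
        reps = 600
        for _ in range(reps):
            x = sample_logistic_normal(mean, 0.3 * np.eye(2), 40, rng)
            x.metadata["subsidy"] = groups
            fit = fit_compositional_lm(DesignSpec(x, ("subsidy",)))
            if anova_global(fit, "subsidy").p_value < 0.05:
                rejections += 1
        assert rejections / reps == pytest.approx(0.05, abs=0.02)

    def test_power_under_strong_separation(self):
        # group means ~3 Aitchison units apart
        a = closure((1, 1, 1))
        b = np.exp(helmert_basis(3).T @ np.array([3.0, 0.0]))
        s = two_group_set(a.values, b / b.sum(), 20, 0.3 * np.eye(2), 77)
        fit = fit_compositional_lm(DesignSpec(s, ("subsidy",)))
        assert anova_global(fit, "subsidy").p_value < 0.001

    def test_absent_term_rejected(self):
        s = two_group_set((0.4, 0.3, 0.3), (0.3, 0.4, 0.3), 10, 0.2 * np.eye(2), 1)
        fit = fit_compositional_lm(DesignSpec(s, ("subsidy",)))
        with pytest.raises(ValueError, match="season"):
            anova_global(fit, "season")


class TestLogitLm:
    def test_season_constant_data_zero_trend(self):
        vals = np.tile(closure((0.3, 0.3, 0.4)).values, (9, 1))
        s = CompositionSet(PCL, vals,
                           {"season": ["spring", "summer", "autumn"] * 3})
        fits = fit_logit_lm(s)
        for f in fits.values():
            assert f.linear_contrast == pytest.approx(0.0, abs=1e-12)

    def test_boundary_fractions_rejected(self):
        vals = np.array([[0.5, 0.5, 0.0], [0.4, 0.3, 0.3], [0.2, 0.4, 0.4]])
        s = CompositionSet(PCL, vals, {"season": ["spring", "summer", "autumn"]})
        with pytest.raises(ValueError, match="replace_zeros"):
            fit_logit_lm(s)

    def test_monotone_protein_decline_detected_and_consistent(self):
        s = seasonal_set(
            {"spring": (0.45, 0.2, 0.35), "summer": (0.35, 0.3, 0.35),
             "autumn": (0.2, 0.45, 0.35)}, 12, 0.1 * np.eye(2), 99)
        fits = fit_logit_lm(s)
        assert fits["P"].linear_contrast < 0 and fits["P"].linear_p < 0.01
        assert fits["C"].linear_contrast > 0
        fit = fit_compositional_lm(DesignSpec(s, ("season",)))
        assert anova_global(fit, "season").p_value < 0.001

    def test_sign_agreement_under_strong_trend(self):
        rng = np.random.default_rng(7)
        agree = 0
        reps = 60
        for _ in range(reps):
            s = seasonal_set(
                {"spring": (0.45, 0.2, 0.35), "summer": (0.35, 0.3, 0.35),
                 "autumn": (0.2, 0.45, 0.35)}, 8, 0.15 * np.eye(2),
                rng.integers(2**31))
            lf = fit_logit_lm(s)["P"]
            fit = fit_compositional_lm(DesignSpec(s, ("season",)))
            gm = group_geometric_means(fit.spec.response, "season")
            comp_declines = gm["autumn"]["P"] < gm["spring"]["P"]
            if (lf.linear_contrast < 0) == comp_declines:
                agree += 1
        assert agree / reps > 0.95


class TestInfluence:
    def test_balanced_duplicated_data_equal_distances(self):
        base = np.array([[0.5, 0.3, 0.2], [0.2, 0.5, 0.3], [0.3, 0.2, 0.5]])
        vals = np.vstack([base, base])
        s = CompositionSet(PCL, vals, {"subsidy": ["natural"] * 6})
        fit = fit_compositional_lm(DesignSpec(s, ()))
        d = cooks_influence(fit)
        # leverage equal for all; distance depends only on residual magnitude,
        # which is symmetric across the two copies
        assert np.allclose(d[:3], d[3:], atol=1e-12)

    def test_outlier_attains_max_distance(self):
        rng = np.random.default_rng(13)
        tight = sample_logistic_normal(closure((0.35, 0.35, 0.3)),
                                       0.01 * np.eye(2), 12, rng)
        outlier = closure((0.02, 0.98 - 1e-3, 0.01 + 1e-3))
        vals = np.vstack([tight.values, outlier.values])
        s = CompositionSet(PCL, vals, {"subsidy": ["natural"] * 13})
        fit = fit_compositional_lm(DesignSpec(s, ()))
        d = cooks_influence(fit)
        assert np.argmax(d) == 12

    def test_refit_without_outlier_shifts_mean_back(self):
        rng = np.random.default_rng(14)
        tight = sample_logistic_normal(closure((0.35, 0.35, 0.3)),
                                       0.01 * np.eye(2), 12, rng)
        outlier = closure((0.02, 0.97, 0.01))
        s = CompositionSet(PCL, np.vstack([tight.values, outlier.values]))
        g_with = geometric_mean_composition(s)
        g_without = geometric_mean_composition(s.select(np.arange(12)))
        g_tight = geometric_mean_composition(tight)
        from macroniche.compositional import aitchison_distance

        assert aitchison_distance(g_without, g_tight) < aitchison_distance(
            g_with, g_tight
        )


class TestIntakeTarget:
    @pytest.mark.parametrize(
        "comp,expected_cls,expected_gap",
        [
            ((0.17, 0.40, 0.43), "within", 0.0),
            ((0.208, 0.474, 0.318), "within", 0.038),
            ((0.493, 0.159, 0.348), "above", 0.323),
            ((0.12, 0.50, 0.38), "below", -0.05),
        ],
    )
    def test_classification_and_gap(self, comp, expected_cls, expected_gap):
        cls, gap = compare_to_target(closure(comp))
        assert cls == expected_cls
        assert gap == pytest.approx(expected_gap, abs=1e-9)

    def test_band_must_stay_inside_simplex(self):
        with pytest.raises(ValueError):
            IntakeTarget(protein_fraction=0.02, band_halfwidth=0.04)
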