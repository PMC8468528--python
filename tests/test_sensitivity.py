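"""Sensitivity regressions: pooled slopes, per-subject fits, cross-fit R^2,
and the stiffness-by-incline interaction."""

import numpy as np
import pandas as pd
import pytest

from dmama import (
    SensitivityFit,
    SessionConfig,
    crossfit_r2,
    draw_stride_table,
    fit_interaction,
    fit_subject_dependent,
    fit_subject_independent,
)


def exact_table(intercepts, slope, codes=(0, 1, 2), reps=4):
    rows = []
    for s, b0 in enumerate(intercepts):
        for c in codes:
            for _ in range(reps):
                rows.append(
                    {"subject": s, "stiffness_code": c, "incline_deg": 0.0,
                     "dmama_pct_foot": b0 + slope * c}
                )
    return pd.DataFrame(rows)


class TestSubjectIndependent:
    def test_exact_linear_data_recovered(self):
        table = exact_table([10.0, 14.0, 8.0], 3.0)
        fit = fit_subject_independent(table, "stiffness_code")
        assert fit.slope == pytest.approx(3.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)
        assert fit.intercepts[0] == pytest.approx(10.0, abs=1e-9)

    def test_offset_intercepts_absorbed(self):
        # equal slopes, different intercepts: pooled slope exact
        table = exact_table([0.0, 25.0], 2.299)
        fit = fit_subject_independent(table, "stiffness_code")
        assert fit.slope == pytest.approx(2.299, abs=1e-9)

    def test_slope_ci_covers_generating_value(self):
        """Parameter recovery at the down-ramp sensitivity under stride noise."""
        hits = 0
        for rep in range(50):
            cfg = SessionConfig(
                subjects=4, modes=("down_ramp",),
                strides_per_condition={"down_ramp": 11},
                beta_stiffness=3.749, beta_incline=0.0, beta_interaction=0.0,
                stride_noise_sd=3.0, seed=40_000 + rep,
            )
            fit = fit_subject_independent(draw_stride_table(cfg), "stiffness_code")
            hits += abs(fit.slope - 3.749) <= fit.slope_ci_half
        assert hits >= 45  # ~95% nominal coverage

    def test_frisch_waugh_identity(self, rng):
        """Pooled slope equals the per-subject-demeaned regression slope on
        condition means."""
        table = exact_table([10.0, 14.0, 8.0], 3.0)
        table["dmama_pct_foot"] += 0.5 * rng.standard_normal(len(table))
        fit = fit_subject_independent(table, "stiffness_code")
        means = table.groupby(["subject", "stiffness_code"], as_index=False)[
            "dmama_pct_foot"
        ].mean()
        demeaned = means.copy()
        for col in ("dmama_pct_foot", "stiffness_code"):
            demeaned[col] = demeaned[col] - demeaned.groupby("subject")[col].transform("mean")
        x, y = demeaned["stiffness_code"], demeaned["dmama_pct_foot"]
        slope = float((x * y).sum() / (x * x).sum())
        assert fit.slope == pytest.approx(slope, rel=1e-9)

    def test_single_level_subject_warns(self):
        table = exact_table([10.0, 14.0], 3.0)
        table = pd.concat(
            [table, pd.DataFrame([{"subject": 2, "stiffness_code": 1,
                                   "incline_deg": 0.0, "dmama_pct_foot": 12.0}])],
            ignore_index=True,
        )
        with pytest.warns(UserWarning, match="single"):
            fit_subject_independent(table, "stiffness_code")

    def test_mixed_variant_agrees_on_slope(self, rng):
        table = exact_table([10.0, 14.0, 8.0, 12.0], 3.0, reps=10)
        table["dmama_pct_foot"] += 0.8 * rng.standard_normal(len(table))
        means_fit = fit_subject_independent(table, "stiffness_code")
        mixed_fit = fit_subject_independent(table, "stiffness_code", method="mixed")
        assert mixed_fit.slope == pytest.approx(means_fit.slope, abs=0.2)

    def test_too_few_subjects_or_levels(self):
        one = exact_table([10.0], 3.0)
        with pytest.raises(ValueError):
            fit_subject_independent(one, "stiffness_code")
        flat = exact_table([10.0, 12.0], 3.0, codes=(1,))
        with pytest.raises(ValueError):
            fit_subject_independent(flat, "stiffness_code")


class TestSubjectDependent:
    def test_perfectly_linear_r2_one(self):
        table = exact_table([10.0], 2.5)
        fit = fit_subject_dependent(table, "stiffness_code")
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.slope == pytest.approx(2.5, abs=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        x = rng.integers(0, 3, 60).astype(float)
        y = 9.0 + 1.7 * x + rng.standard_normal(60)
        table = pd.DataFrame({"subject": 0, "stiffness_code": x, "dmama_pct_foot": y})
        fit = fit_subject_dependent(table, "stiffness_code")
        X = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.intercepts[0] == pytest.approx(beta[0], rel=1e-9)
        assert fit.slope == pytest.approx(beta[1], rel=1e-9)

    def test_null_slope_p_values_roughly_uniform(self):
        ps = []
        for rep in range(150):
            rng = np.random.default_rng(rep)
            x = np.tile([0.0, 1.0, 2.0], 15)
            y = 10.0 + rng.standard_normal(len(x))
            table = pd.DataFrame({"subject": 0, "stiffness_code": x,
                                  "dmama_pct_foot": y})
            ps.append(fit_subject_dependent(table, "stiffness_code").p_value)
        ps = np.asarray(ps)
        assert 0.35 < ps.mean() < 0.65  # coarse uniformity check
        assert (ps < 0.05).mean() < 0.15

    def test_too_few_strides(self):
        table = pd.DataFrame({"subject": 0, "stiffness_code": [0.0, 1.0],
                              "dmama_pct_foot": [1.0, 2.0]})
        with pytest.raises(ValueError):
            fit_subject_dependent(table, "stiffness_code")


def manual_fit(slope, intercepts, driver="stiffness_code"):
    return SensitivityFit(
        driver=driver, scope="subject_independent", slope=slope,
        intercepts=intercepts, p_value=0.0, r_squared=1.0, n_obs=0,
    )


class TestCrossfitR2:
    def strides(self, y, x=None):
        x = np.zeros(len(y)) if x is None else np.asarray(x, float)
        return pd.DataFrame({"subject": 0, "stiffness_code": x,
                             "dmama_pct_foot": np.asarray(y, float)})

    def test_predicting_subject_mean_gives_zero(self):
        y = np.array([9.0, 10.0, 11.0, 10.0])
        fit = manual_fit(0.0, {0: y.mean()})  # prediction == subject mean
        assert crossfit_r2(self.strides(y), fit) == pytest.approx(0.0, abs=1e-12)

    def test_perfect_prediction_gives_one(self):
        x = np.array([0.0, 1.0, 2.0, 0.0, 1.0, 2.0])
        y = 10.0 + 3.0 * x
        fit = manual_fit(3.0, {0: 10.0})
        assert crossfit_r2(self.strides(y, x), fit) == pytest.approx(1.0, abs=1e-12)

    def test_counter_sloped_prediction_negative(self):
        x = np.array([0.0, 1.0, 2.0] * 4)
        y = 10.0 + 3.0 * x
        fit = manual_fit(-3.0, {0: 10.0 + 3.0})  # wrong sign, centred
        assert crossfit_r2(self.strides(y, x), fit) < 0.0

    def test_random_effect_adjustment(self):
        # subject offset above the grand intercept must be removed
        x = np.array([0.0, 1.0, 2.0] * 4)
        y = 15.0 + 3.0 * x  # subject intercept 15, grand 10
        fit = manual_fit(3.0, {0: 15.0, 1: 5.0})
        assert crossfit_r2(self.strides(y, x), fit) == pytest.approx(1.0, abs=1e-12)

    def test_never_exceeds_own_fit_r2(self, rng):
        x = np.tile([0.0, 1.0, 2.0], 20)
        y = 10.0 + 2.0 * x + rng.standard_normal(len(x))
        table = self.strides(y, x)
        own = fit_subject_dependent(table, "stiffness_code")
        pooled = manual_fit(1.5, {0: 11.0, 1: 9.0})
        assert crossfit_r2(table, pooled) <= own.r_squared + 1e-12

    def test_constant_data_flagged_nan(self):
        fit = manual_fit(1.0, {0: 10.0})
        with pytest.warns(UserWarning, match="constant"):
            out = crossfit_r2(self.strides([5.0, 5.0, 5.0]), fit)
        assert np.isnan(out)


class TestInteraction:
    def draw(self, seed, noise=1.0):
        cfg = SessionConfig(
            subjects=4, modes=("down_ramp", "level", "up_ramp"),
            strides_per_condition={"down_ramp": 11, "level": 50, "up_ramp": 11},
            beta0_subject=(10.0,) * 4, stride_noise_sd=noise, seed=seed,
        )
        return draw_stride_table(cfg)

    def test_matches_pseudoinverse_oracle(self):
        table = self.draw(1)
        fit = fit_interaction(table)
        s = table["stiffness_code"].to_numpy(float)
        i = table["incline_deg"].to_numpy(float)
        X = np.column_stack([np.ones_like(s), s, i, s * i])
        beta = np.linalg.pinv(X) @ table["dmama_pct_foot"].to_numpy()
        assert fit.coef_stiffness == pytest.approx(beta[1], rel=1e-9)
        assert fit.coef_incline == pytest.approx(beta[2], rel=1e-9)
        assert fit.coef_interaction == pytest.approx(beta[3], rel=1e-9)

    def test_recovers_generating_coefficients(self):
        covered = np.zeros(3)
        signs = 0
        for rep in range(30):
            fit = fit_interaction(self.draw(50_000 + rep))
            est = np.array([fit.coef_stiffness, fit.coef_incline, fit.coef_interaction])
            ci = np.array([fit.ci_stiffness, fit.ci_incline, fit.ci_interaction])
            truth = np.array([3.01, 0.413, -0.145])
            covered += np.abs(est - truth) <= ci
            signs += np.all(np.sign(est) == np.sign(truth))
        assert (covered >= 25).all()  # ~95% nominal per coefficient
        assert signs == 30

    def test_zero_interaction_ci_covers_zero(self):
        cfg = SessionConfig(
            subjects=4, modes=("down_ramp", "level", "up_ramp"),
            strides_per_condition={"down_ramp": 11, "level": 50, "up_ramp": 11},
            beta0_subject=(10.0,) * 4, beta_interaction=0.0,
            stride_noise_sd=1.0, seed=77,
        )
        fit = fit_interaction(draw_stride_table(cfg))
        assert abs(fit.coef_interaction) <= fit.ci_interaction

    def test_stairs_excluded_from_fit(self):
        cfg = SessionConfig(subjects=2, stride_noise_sd=0.0, seed=5)
        table = draw_stride_table(cfg)
        fit = fit_interaction(table)
        ramps = table[table["mode"].isin(("down_ramp", "level", "up_ramp"))]
        assert fit.n_obs == len(ramps)

    def test_rank_deficiency_reported(self):
        table = self.draw(1)
        flat = table[table["mode"] == "level"]  # incline does not vary
        with pytest.raises(ValueError, match="incline"):
            fit_interaction(flat)

    def test_confidence_half_widths_positive(self):
        fit = fit_interaction(self.draw(2))
        assert fit.ci_stiffness > 0 and fit.ci_incline > 0 and fit.ci_interaction > 0
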