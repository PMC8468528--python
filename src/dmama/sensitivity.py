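"""Sensitivity of DMAMA to forefoot stiffness and ground incline.

Subject-independent sensitivity is the common slope of a linear model with
one intercept per subject (the fixed-intercept realisation of a mixed
model with participants as random effects), fitted to per-subject
condition means; subject-dependent sensitivity is an ordinary per-stride
regression within one subject.  How well the pooled trend explains one
subject's stride-by-stride data is scored by a cross-fit
R^2 = 1 - RSS/TSS computed on strides adjusted for the subject's intercept
offset — this R^2 may be negative when the pooled trend fits worse than
the subject's own mean.  The stiffness-by-incline interaction is a
multiple regression on [1, stiffness, incline, stiffness*incline] over the
three incline conditions (stairs excluded).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

DRIVERS = {"stiffness_code", "incline_deg"}
ALPHA = 0.05  # significance level for slope tests

RAMP_MODES = ("down_ramp", "level", "up_ramp")


@dataclass
class SensitivityFit:
    """Slope of DMAMA (% foot length) versus one driver variable."""

    driver: str
    scope: str                      # "subject_independent" | "subject_dependent"
    slope: float                    # % foot length per driver unit
    intercepts: dict                # subject -> intercept (% foot length)
    p_value: float
    r_squared: float
    n_obs: int
    slope_ci_half: float = float("nan")  # 95% confidence half-width
    subject: int | None = None

    @property
    def grand_intercept(self) -> float:
        return float(np.mean(list(self.intercepts.values())))

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA

    def predict(self, x) -> np.ndarray:
        """Pooled-trend prediction at driver values ``x`` (grand intercept)."""
        return self.grand_intercept + self.slope * np.asarray(x, dtype=float)

    def to_dict(self) -> dict:
        return {
            "driver": self.driver,
            "scope": self.scope,
            "subject": self.subject,
            "slope": self.slope,
            "slope_ci_half": self.slope_ci_half,
            "intercepts": {str(k): v for k, v in self.intercepts.items()},
            "p_value": self.p_value,
            "r_squared": self.r_squared,
            "n_obs": self.n_obs,
            "significant": self.significant,
        }


@dataclass
class InteractionFit:
    """Multiple regression of DMAMA on stiffness, incline and their product."""

    intercept: float
    coef_stiffness: float
    coef_incline: float
    coef_interaction: float
    ci_stiffness: float      # 95% confidence half-widths
    ci_incline: float
    ci_interaction: float
    p_values: dict = field(default_factory=dict)
    r_squared: float = float("nan")
    n_obs: int = 0

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "coef_stiffness": self.coef_stiffness,
            "coef_incline": self.coef_incline,
            "coef_interaction": self.coef_interaction,
            "ci_stiffness": self.ci_stiffness,
            "ci_incline": self.ci_incline,
            "ci_interaction": self.ci_interaction,
            "p_values": self.p_values,
            "r_squared": self.r_squared,
            "n_obs": self.n_obs,
        }


def _check_driver(driver: str):
    if driver not in DRIVERS:
        raise ValueError(f"driver must be one of {sorted(DRIVERS)}")


def fit_subject_independent(
    table: pd.DataFrame,
    driver: str,
    value: str = "dmama_pct_foot",
    method: str = "means",
) -> SensitivityFit:
    """Pooled sensitivity with per-subject intercepts.

    ``method="means"`` (default) regresses per-subject condition means with
    fixed subject intercepts, the computation the headline sensitivities
    use.  ``method="mixed"`` fits a per-stride random-intercept mixed model
    instead (REML via statsmodels MixedLM) as a variant.

    ``table`` needs columns ``subject``, the driver, and ``value``.
    """
    _check_driver(driver)
    df = table.dropna(subset=[value])
    if df["subject"].nunique() < 2:
        raise ValueError("subject-independent fit needs at least 2 subjects")
    if df[driver].nunique() < 2:
        raise ValueError("driver must take at least 2 levels")

    single = df.groupby("subject")[driver].nunique()
    for subj in single[single < 2].index:
        warnings.warn(
            f"subject {subj} observed at a single {driver} level; "
            "contributes to its intercept only"
        )

    if method == "mixed":
        model = sm.MixedLM(
            df[value].to_numpy(),
            sm.add_constant(df[driver].to_numpy()),
            groups=df["subject"].to_numpy(),
        )
        res = model.fit(reml=True)
        intercepts = {
            subj: float(res.params[0] + re.iloc[0])
            for subj, re in res.random_effects.items()
        }
        fitted = res.fittedvalues
        resid = df[value].to_numpy() - fitted
        r2 = 1.0 - np.sum(resid**2) / np.sum((df[value] - df[value].mean()) ** 2)
        return SensitivityFit(
            driver=driver,
            scope="subject_independent",
            slope=float(res.params[1]),
            intercepts=intercepts,
            p_value=float(res.pvalues[1]),
            r_squared=float(r2),
            n_obs=len(df),
            slope_ci_half=float(1.96 * res.bse[1]),
        )
    if method != "means":
        raise ValueError("method must be 'means' or 'mixed'")

    means = (
        df.groupby(["subject", driver], as_index=False)[value].mean()
    )
    subjects = sorted(means["subject"].unique())
    dummies = np.stack(
        [(means["subject"] == s).to_numpy(float) for s in subjects], axis=1
    )
    exog = np.column_stack([dummies, means[driver].to_numpy(float)])
    res = sm.OLS(means[value].to_numpy(), exog).fit()
    intercepts = {s: float(res.params[i]) for i, s in enumerate(subjects)}
    half = (res.conf_int(alpha=0.05)[-1, 1] - res.conf_int(alpha=0.05)[-1, 0]) / 2.0
    return SensitivityFit(
        driver=driver,
        scope="subject_independent",
        slope=float(res.params[-1]),
        intercepts=intercepts,
        p_value=float(res.pvalues[-1]),
        r_squared=float(res.rsquared),
        n_obs=len(means),
        slope_ci_half=float(half),
    )


def fit_subject_dependent(
    table: pd.DataFrame,
    driver: str,
    value: str = "dmama_pct_foot",
) -> SensitivityFit:
    """Ordinary per-stride regression for a single subject."""
    _check_driver(driver)
    df = table.dropna(subset=[value])
    subjects = df["subject"].unique() if "subject" in df.columns else [None]
    if len(subjects) != 1:
        raise ValueError("fit_subject_dependent expects data from exactly one subject")
    if len(df) < 3:
        raise ValueError("need at least 3 strides for a per-subject fit")
    if df[driver].nunique() < 2:
        raise ValueError("driver must take at least 2 levels")
    res = sm.OLS(
        df[value].to_numpy(), sm.add_constant(df[driver].to_numpy(float))
    ).fit()
    subj = subjects[0]
    half = (res.conf_int(alpha=0.05)[1, 1] - res.conf_int(alpha=0.05)[1, 0]) / 2.0
    return SensitivityFit(
        driver=driver,
        scope="subject_dependent",
        slope=float(res.params[1]),
        intercepts={subj: float(res.params[0])},
        p_value=float(res.pvalues[1]),
        r_squared=float(res.rsquared),
        n_obs=len(df),
        slope_ci_half=float(half),
        subject=subj,
    )


def crossfit_r2(
    table: pd.DataFrame,
    fit: SensitivityFit,
    value: str = "dmama_pct_foot",
) -> float:
    """Cross-fit R^2 of the pooled trend on one subject's strides.

    Strides are adjusted for the random effect by removing the subject's
    intercept offset relative to the grand intercept; the pooled
    prediction is the grand-intercept line.  ``R^2 = 1 - RSS/TSS`` with
    TSS about the subject's mean adjusted value — negative whenever the
    pooled trend explains the strides worse than that mean does.
    """
    df = table.dropna(subset=[value])
    subjects = df["subject"].unique()
    if len(subjects) != 1:
        raise ValueError("crossfit_r2 expects strides from exactly one subject")
    subj = subjects[0]
    if subj not in fit.intercepts:
        raise KeyError(f"fit has no intercept for subject {subj!r}")
    adjusted = df[value].to_numpy() - (fit.intercepts[subj] - fit.grand_intercept)
    predicted = fit.predict(df[fit.driver].to_numpy())
    tss = float(np.sum((adjusted - adjusted.mean()) ** 2))
    if tss == 0.0:
        warnings.warn("constant subject data: cross-fit R^2 undefined")
        return float("nan")
    rss = float(np.sum((adjusted - predicted) ** 2))
    return 1.0 - rss / tss


def fit_interaction(
    table: pd.DataFrame,
    value: str = "dmama_pct_foot",
    stiffness: str = "stiffness_code",
    incline: str = "incline_deg",
    modes: tuple = RAMP_MODES,
) -> InteractionFit:
    """DMAMA ~ 1 + stiffness + incline + stiffness*incline, inclines only.

    Stairs are excluded (they carry no incline value); both drivers must
    vary.  Confidence half-widths are classical t-based 95% intervals.
    """
    df = table.dropna(subset=[value])
    if "mode" in df.columns:
        df = df[df["mode"].isin(modes)]
    s = df[stiffness].to_numpy(float)
    i = df[incline].to_numpy(float)
    for name, x in (("stiffness", s), ("incline", i)):
        if len(np.unique(x)) < 2:
            raise ValueError(f"{name} does not vary; interaction fit is rank deficient")
    exog = np.column_stack([np.ones_like(s), s, i, s * i])
    rank = np.linalg.matrix_rank(exog)
    if rank < 4:
        raise ValueError("design matrix rank deficient: interaction term collapsed")
    res = sm.OLS(df[value].to_numpy(), exog).fit()
    half = (res.conf_int(alpha=0.05)[:, 1] - res.conf_int(alpha=0.05)[:, 0]) / 2.0
    return InteractionFit(
        intercept=float(res.params[0]),
        coef_stiffness=float(res.params[1]),
        coef_incline=float(res.params[2]),
        coef_interaction=float(res.params[3]),
        ci_stiffness=float(half[1]),
        ci_incline=float(half[2]),
        ci_interaction=float(half[3]),
        p_values={
            "stiffness": float(res.pvalues[1]),
            "incline": float(res.pvalues[2]),
            "interaction": float(res.pvalues[3]),
        },
        r_squared=float(res.rsquared),
        n_obs=len(df),
    )


def sensitivity_by_stratum(
    table: pd.DataFrame,
    driver: str,
    stratum: str,
    value: str = "dmama_pct_foot",
) -> dict:
    """Subject-independent fits per stratum plus per-subject fits and
    cross-fit R^2, mirroring the tabulated layout of the analysis.

    For the stiffness driver, strata are locomotion modes; for the incline
    driver, strata are stiffness levels (ramp/level modes only).
    """
    _check_driver(driver)
    df = table.dropna(subset=[value])
    if driver == "incline_deg" and "mode" in df.columns:
        df = df[df["mode"].isin(RAMP_MODES)]
    out = {}
    for key, grp in df.groupby(stratum):
        entry = {"subject_independent": None, "subject_dependent": {}, "crossfit_r2": {}}
        try:
            ind = fit_subject_independent(grp, driver, value=value)
        except ValueError:
            continue
        entry["subject_independent"] = ind.to_dict()
        for subj, sub in grp.groupby("subject"):
            try:
                dep = fit_subject_dependent(sub, driver, value=value)
            except ValueError:
                continue
            entry["subject_dependent"][str(subj)] = dep.to_dict()
            entry["crossfit_r2"][str(subj)] = crossfit_r2(sub, ind, value=value)
        out[str(key)] = entry
    return out
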