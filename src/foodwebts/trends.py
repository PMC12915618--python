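"""Hierarchical random-slope trend models and cross-iteration pooling.

Each biodiversity metric is regressed on mean-centered year with random
intercepts and slopes for study and for spatial unit nested within study:

    metric ~ year_c + (year_c | study / unit)

with a Gaussian, Poisson (log link; counts such as richness) or binomial
(logit link; trophic-group counts out of classified species) response.
The model is fitted once per rarefaction iteration and the fixed slopes are
pooled across iterations into the headline estimate with percentile (or,
optionally, Rubin's-rules) intervals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.genmod.bayes_mixed_glm import (
    BinomialBayesMixedGLM,
    PoissonBayesMixedGLM,
)
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["TrendFit", "TrendEstimate", "fit_trend", "combine_iterations"]

FAMILIES = ("gaussian", "poisson", "binomial")

# random intercepts and slopes for study, and for unit nested in study;
# the Bayes GLMM is fitted on unit-variance year (year_s) for stability
_VC_FORMULAS = {
    "study": "0 + C(study_id)",
    "study_slope": "0 + C(study_id):year_s",
    "unit": "0 + C(unit_id)",
    "unit_slope": "0 + C(unit_id):year_s",
}


@dataclass
class TrendFit:
    """One model fit: fixed year slope and diagnostics."""

    metric: str
    family: str
    fixed_slope: float
    fixed_slope_se: float
    variance_components: dict[str, float] = field(default_factory=dict)
    converged: bool = True
    fallback: bool = False  # nested structure simplified to unit-level slopes
    iteration_index: int = 1


@dataclass
class TrendEstimate:
    """Pooled trend across rarefaction iterations."""

    metric: str
    mean_slope: float
    ci50: tuple[float, float]
    ci95: tuple[float, float]
    n_iterations_used: int
    slopes: list[float] = field(default_factory=list)
    method: str = "percentile"
    rubin_ci95: tuple[float, float] | None = None


def _prepare(panel: pd.DataFrame) -> pd.DataFrame:
    df = panel.copy()
    # global mean-centering of year over the fitted panel
    df["year_c"] = df["year"].astype(float) - df["year"].astype(float).mean()
    return df


def _fit_gaussian(df: pd.DataFrame, value_col: str) -> tuple[float, float, dict, bool, bool]:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            md = smf.mixedlm(
                f"{value_col} ~ year_c",
                df,
                groups=df["study_id"],
                re_formula="~year_c",
                vc_formula={"unit": "0 + C(unit_id)", "unit_slope": "0 + C(unit_id):year_c"},
            )
            res = None
            for opt in ("powell", "lbfgs"):
                res = md.fit(reml=True, method=opt, maxiter=500)
                if res.converged and np.isfinite(res.params["year_c"]):
                    break
            if res is not None and np.isfinite(res.params["year_c"]):
                vc = {
                    "study_intercept_var": float(res.cov_re.iloc[0, 0]),
                    "study_slope_var": float(res.cov_re.iloc[1, 1]),
                    "unit_intercept_var": float(res.vcomp[0]),
                    "unit_slope_var": float(res.vcomp[1]),
                }
                return (
                    float(res.params["year_c"]),
                    float(res.bse["year_c"]),
                    vc,
                    bool(res.converged),
                    False,
                )
        except Exception as exc:  # singular fit, separation, ...
            logger.warning("nested gaussian fit failed (%s); falling back", exc)
        # fallback: random slopes at the spatial-unit level only
        try:
            md = smf.mixedlm(
                f"{value_col} ~ year_c",
                df,
                groups=df["unit_id"],
                re_formula="~year_c",
            )
            res = md.fit(reml=True, method="lbfgs", maxiter=200)
            return (
                float(res.params["year_c"]),
                float(res.bse["year_c"]),
                {},
                bool(res.converged) and np.isfinite(res.params["year_c"]),
                True,
            )
        except Exception as exc:
            logger.error("gaussian trend fit failed entirely: %s", exc)
            return float("nan"), float("nan"), {}, False, True


def _fit_glmm_bayes(
    df: pd.DataFrame, family: str, value_col: str
) -> tuple[float, float, dict, bool, bool]:
    """Poisson/binomial GLMM via variational Bayes with weak priors.

    The year covariate is standardized for the optimizer and the fitted
    slope rescaled back to per-year units.
    """
    df = df.copy()
    sd_year = float(df["year_c"].std())
    if sd_year <= 0:
        return float("nan"), float("nan"), {}, False, False
    df["year_s"] = df["year_c"] / sd_year
    if family == "binomial":
        # expand (successes, trials) to Bernoulli rows for the logit GLMM
        if "successes" not in df.columns or "trials" not in df.columns:
            raise ValueError("binomial family requires successes and trials columns")
        reps = df["trials"].astype(int)
        expanded = df.loc[df.index.repeat(reps)].copy()
        ones = np.concatenate(
            [np.r_[np.ones(s), np.zeros(t - s)] for s, t in zip(df["successes"], df["trials"])]
        )
        expanded["y"] = ones
        data, endog_col, cls = expanded, "y", BinomialBayesMixedGLM
    else:
        data, endog_col, cls = df, value_col, PoissonBayesMixedGLM
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = cls.from_formula(
                f"{endog_col} ~ year_s", _VC_FORMULAS, data, vcp_p=3.0, fe_p=3.0
            )
            res = model.fit_vb()
            slope = float(res.fe_mean[1]) / sd_year
            se = float(res.fe_sd[1]) / sd_year
            vcp = dict(zip(("study", "study_slope", "unit", "unit_slope"),
                           np.asarray(res.vcp_mean, float)))
            return slope, se, vcp, np.isfinite(slope), False
        except Exception as exc:
            logger.warning("nested %s fit failed (%s); falling back", family, exc)
        try:
            vcf = {"unit": "0 + C(unit_id)", "unit_slope": "0 + C(unit_id):year_s"}
            model = cls.from_formula(
                f"{endog_col} ~ year_s", vcf, data, vcp_p=3.0, fe_p=3.0
            )
            res = model.fit_vb()
            slope = float(res.fe_mean[1]) / sd_year
            return slope, float(res.fe_sd[1]) / sd_year, {}, np.isfinite(slope), True
        except Exception as exc:
            logger.error("%s trend fit failed entirely: %s", family, exc)
            return float("nan"), float("nan"), {}, False, True


def fit_trend(
    panel: pd.DataFrame,
    family: str = "gaussian",
    value_col: str = "value",
    metric: str | None = None,
    iteration_index: int = 1,
) -> TrendFit:
    """Fit the random-slope trend model to one iteration's metric panel.

    ``panel`` needs columns ``study_id``, ``unit_id``, ``year`` and the
    response (``value_col`` for gaussian/poisson; ``successes``/``trials``
    for binomial). Year is mean-centered over the whole panel before
    fitting. Rows with missing responses are dropped. Non-convergence is
    flagged rather than raised so pooling can skip the fit.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family: {family!r}")
    needed = ["study_id", "unit_id", "year"]
    for col in needed:
        if col not in panel.columns:
            raise ValueError(f"panel lacks required column {col!r}")
    df = _prepare(panel)
    if family != "binomial":
        df = df[np.isfinite(pd.to_numeric(df[value_col], errors="coerce"))]
    if df["study_id"].nunique() < 2 or df["year"].nunique() < 2:
        logger.warning("degenerate panel (single study or year)")
    if family == "gaussian":
        slope, se, vc, ok, fb = _fit_gaussian(df, value_col)
    else:
        slope, se, vc, ok, fb = _fit_glmm_bayes(df, family, value_col)
    return TrendFit(
        metric=metric or value_col,
        family=family,
        fixed_slope=slope,
        fixed_slope_se=se,
        variance_components=vc,
        converged=ok,
        fallback=fb,
        iteration_index=iteration_index,
    )


def combine_iterations(
    fits: list[TrendFit], method: str = "percentile"
) -> TrendEstimate:
    """Pool fixed slopes across rarefaction iterations.

    Non-converged fits are excluded (logged). ``percentile`` (default)
    reports the 50% and 95% percentile intervals of the slope distribution
    across iterations; ``rubin`` combines within- and between-iteration
    variance (Rubin's rules) into normal-theory intervals. The Rubin 95%
    interval is attached to the result either way.
    """
    used = [f for f in fits if f.converged and np.isfinite(f.fixed_slope)]
    n_dropped = len(fits) - len(used)
    if n_dropped:
        logger.info("excluding %d non-converged fits from pooling", n_dropped)
    if not used:
        raise ValueError("no converged fits to pool")
    slopes = np.array([f.fixed_slope for f in used])
    mean = float(slopes.mean())
    # Rubin's rules: total variance = mean within + (1 + 1/m) between
    ses = np.array([f.fixed_slope_se for f in used])
    within = float(np.mean(ses[np.isfinite(ses)] ** 2)) if np.isfinite(ses).any() else 0.0
    between = float(slopes.var(ddof=1)) if len(slopes) > 1 else 0.0
    total_sd = np.sqrt(within + (1.0 + 1.0 / len(slopes)) * between)
    z95 = stats.norm.ppf(0.975)
    rubin95 = (mean - z95 * total_sd, mean + z95 * total_sd)
    if method == "percentile":
        ci50 = tuple(np.percentile(slopes, [25.0, 75.0]))
        ci95 = tuple(np.percentile(slopes, [2.5, 97.5]))
    elif method == "rubin":
        z50 = stats.norm.ppf(0.75)
        ci50 = (mean - z50 * total_sd, mean + z50 * total_sd)
        ci95 = rubin95
    else:
        raise ValueError(f"unknown pooling method: {method!r}")
    return TrendEstimate(
        metric=used[0].metric,
        mean_slope=mean,
        ci50=(float(ci50[0]), float(ci50[1])),
        ci95=(float(ci95[0]), float(ci95[1])),
        n_iterations_used=len(used),
        slopes=[float(s) for s in slopes],
        method=method,
        rubin_ci95=(float(rubin95[0]), float(rubin95[1])),
    )
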