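"""Allometric niche model: Gaussian feeding kernel, predation-window
calibration by quantile regression, and Boyce-index cross-validation.

The probability that a predator of log10 body size ``m_i`` feeds on a prey
of log10 size ``m_j`` is modelled as a Gaussian in the log size difference,

    P_ij = theta * exp(-(m_i - m_j - mu)^2 / (2 sigma^2)),

where ``mu`` is the optimal log10 predator:prey size ratio, ``sigma`` the
feeding range and ``theta`` the maximum feeding probability. Calibrating
quantile regressions of prey size on predator size at a low and a high
quantile yields a *predation window* — the prey-size band a predator of a
given size can exploit — from which (mu, sigma) follow by normal-quantile
arithmetic. Candidate windows are compared by the continuous Boyce index on
repeated 70/30 train/holdout splits.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf

logger = logging.getLogger(__name__)

__all__ = [
    "FeedingKernel",
    "WindowModel",
    "CrossValResult",
    "feeding_probability",
    "calibrate_window",
    "window_to_kernel",
    "boyce_index",
    "cross_validate",
]

#: The candidate predation windows evaluated in model selection.
DEFAULT_WINDOW_CANDIDATES = [
    (0.01, 0.99),
    (0.02, 0.98),
    (0.03, 0.97),
    (0.04, 0.96),
    (0.05, 0.95),
]


@dataclass(frozen=True)
class FeedingKernel:
    """Gaussian feeding kernel parameters (log10 size units).

    ``theta`` is unidentified by window calibration and fixed at 1 by
    default; the binary link rule downstream only compares probabilities to
    a window-equivalent threshold, so theta cancels.
    """

    mu: float
    sigma: float
    theta: float = 1.0

    def validate(self) -> "FeedingKernel":
        if not np.isfinite(self.mu):
            raise ValueError("mu must be finite")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if not 0.0 < self.theta <= 1.0:
            raise ValueError("theta must be in (0, 1]")
        return self


@dataclass
class WindowModel:
    """Predation window: affine lower/upper prey-size bounds vs predator size."""

    q_low: float
    q_high: float
    lower_intercept: float
    lower_slope: float
    upper_intercept: float
    upper_slope: float
    realm: str | None = None
    crossing: bool = False  # bounds crossed somewhere on the calibration range

    def lower(self, m_pred):
        return self.lower_intercept + self.lower_slope * np.asarray(m_pred, float)

    def upper(self, m_pred):
        return self.upper_intercept + self.upper_slope * np.asarray(m_pred, float)


@dataclass
class CrossValResult:
    """Per-candidate Boyce summaries over repeated splits, plus the winner."""

    candidates: list[tuple[float, float]]
    mean_boyce: list[float]
    sd_boyce: list[float]
    n_reps: list[int]
    selected: tuple[float, float]
    boyce_by_candidate: dict[tuple[float, float], list[float]] = field(
        default_factory=dict
    )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "q_low": [c[0] for c in self.candidates],
                "q_high": [c[1] for c in self.candidates],
                "mean_boyce": self.mean_boyce,
                "sd_boyce": self.sd_boyce,
                "n_reps": self.n_reps,
                "selected": [c == self.selected for c in self.candidates],
            }
        )


def feeding_probability(kernel: FeedingKernel, m_pred, m_prey):
    """Evaluate the Gaussian kernel; vectorized over predator/prey sizes."""
    kernel.validate()
    d = np.asarray(m_pred, float) - np.asarray(m_prey, float) - kernel.mu
    return kernel.theta * np.exp(-(d**2) / (2.0 * kernel.sigma**2))


def calibrate_window(
    records: pd.DataFrame,
    q_low: float,
    q_high: float,
    min_records: int = 50,
    realm: str | None = None,
) -> WindowModel:
    """Fit the predation window by quantile regression.

    Regresses prey log10 size on predator log10 size at tau = ``q_low``
    (lower bound) and tau = ``q_high`` (upper bound). Bounds are affine in
    predator size; if they cross anywhere over the observed predator size
    range the model is flagged (``crossing=True``) and a warning logged.
    """
    if not (0.0 < q_low < 0.5 < q_high < 1.0):
        raise ValueError("require 0 < q_low < 0.5 < q_high < 1")
    if len(records) < min_records:
        raise ValueError(
            f"too few records to calibrate ({len(records)} < {min_records})"
        )
    x = records["pred_log10_size"].to_numpy(float)
    if np.ptp(x) < 1e-8:
        raise ValueError("degenerate design: predator sizes are constant")
    df = pd.DataFrame(
        {"mp": x, "my": records["prey_log10_size"].to_numpy(float)}
    )
    model = smf.quantreg("my ~ mp", df)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lo = model.fit(q=q_low)
        hi = model.fit(q=q_high)
    window = WindowModel(
        q_low=q_low,
        q_high=q_high,
        lower_intercept=float(lo.params["Intercept"]),
        lower_slope=float(lo.params["mp"]),
        upper_intercept=float(hi.params["Intercept"]),
        upper_slope=float(hi.params["mp"]),
        realm=realm,
    )
    for m in (x.min(), x.max()):  # affine bounds: endpoints suffice
        if window.upper(m) < window.lower(m):
            window.crossing = True
            logger.warning(
                "predation-window bounds cross at predator size %.3f", m
            )
    return window


def window_to_kernel(window: WindowModel, m_pred: float) -> FeedingKernel:
    """Convert window bounds at one predator size to Gaussian kernel parameters.

    The window is read as the central (q_high - q_low) probability band of
    the prey-size distribution: mu(m) = m - midpoint, and sigma is the
    half-width divided by the standard normal quantile at ``q_high``.
    """
    lo = float(window.lower(m_pred))
    hi = float(window.upper(m_pred))
    if hi < lo:
        raise ValueError(f"window bounds cross at predator size {m_pred}")
    z = stats.norm.ppf(window.q_high)
    sigma = (hi - lo) / (2.0 * z)
    if sigma <= 0:
        raise ValueError("degenerate window: upper == lower gives sigma = 0")
    mu = m_pred - (lo + hi) / 2.0
    return FeedingKernel(mu=mu, sigma=sigma)


def boyce_index(
    presence_scores,
    background_scores,
    n_windows: int = 101,
    window_frac: float = 0.10,
) -> float:
    """Continuous Boyce index in [-1, 1].

    Moving windows of width ``window_frac`` times the background score range
    slide across that range; for each, P/E is the fraction of presence scores
    inside divided by the fraction of background scores inside (windows with
    empty background are skipped). The index is the Spearman rank correlation
    between P/E and the window midpoint: +1 means predicted suitability ranks
    observed interactions perfectly, 0 is indistinguishable from random, -1
    means the model ranks them backwards. Returns NaN when undefined (all
    scores identical, or fewer than two usable windows).
    """
    pres = np.asarray(presence_scores, float)
    back = np.asarray(background_scores, float)
    if pres.size == 0 or back.size == 0:
        raise ValueError("presence and background scores must be nonempty")
    if not (np.isfinite(pres).all() and np.isfinite(back).all()):
        raise ValueError("scores must be finite")
    lo, hi = back.min(), back.max()
    if hi - lo <= 0:
        logger.warning("all background scores identical; Boyce undefined")
        return float("nan")
    width = window_frac * (hi - lo)
    mids = np.linspace(lo + width / 2.0, hi - width / 2.0, n_windows)
    pe, used_mids = [], []
    for m in mids:
        in_p = np.mean((pres >= m - width / 2.0) & (pres <= m + width / 2.0))
        in_b = np.mean((back >= m - width / 2.0) & (back <= m + width / 2.0))
        if in_b == 0.0:
            continue
        pe.append(in_p / in_b)
        used_mids.append(m)
    if len(pe) < 2 or np.ptp(pe) == 0:
        logger.warning("degenerate P/E curve; Boyce undefined")
        return float("nan")
    rho = stats.spearmanr(used_mids, pe).statistic
    return float(rho)


def _background_scores(
    holdout: pd.DataFrame, window: WindowModel, rng: np.random.Generator,
    grid_cap: int = 100,
) -> np.ndarray:
    """Score all predator x prey size pairings on a holdout subsample grid."""
    mp = holdout["pred_log10_size"].to_numpy(float)
    my = holdout["prey_log10_size"].to_numpy(float)
    if mp.size > grid_cap:
        mp = rng.choice(mp, grid_cap, replace=False)
    if my.size > grid_cap:
        my = rng.choice(my, grid_cap, replace=False)
    mu = mp - (window.lower(mp) + window.upper(mp)) / 2.0
    z = stats.norm.ppf(window.q_high)
    sigma = (window.upper(mp) - window.lower(mp)) / (2.0 * z)
    sigma = np.maximum(sigma, 1e-12)
    d = mp[:, None] - my[None, :] - mu[:, None]
    return np.exp(-(d**2) / (2.0 * sigma[:, None] ** 2)).ravel()


def _presence_scores(holdout: pd.DataFrame, window: WindowModel) -> np.ndarray:
    mp = holdout["pred_log10_size"].to_numpy(float)
    my = holdout["prey_log10_size"].to_numpy(float)
    mu = mp - (window.lower(mp) + window.upper(mp)) / 2.0
    z = stats.norm.ppf(window.q_high)
    sigma = np.maximum((window.upper(mp) - window.lower(mp)) / (2.0 * z), 1e-12)
    d = mp - my - mu
    return np.exp(-(d**2) / (2.0 * sigma**2))


def cross_validate(
    records: pd.DataFrame,
    candidates: list[tuple[float, float]] | None = None,
    n_reps: int = 999,
    train_frac: float = 0.7,
    seed: int = 0,
    min_records: int = 50,
    background_grid_cap: int = 100,
    realm: str | None = None,
) -> CrossValResult:
    """Select a predation window by repeated-split cross-validation.

    Each repetition draws a random ``train_frac`` calibration split; every
    candidate window is fitted on it, holdout interactions are scored by the
    implied kernel, and a background of size-matched random pairings (all
    pairings of subsampled holdout predator and prey sizes) yields the Boyce
    index. The candidate with the highest mean Boyce across repetitions is
    selected. NaN Boyce values (degenerate splits) are dropped from the
    summaries.
    """
    if candidates is None:
        candidates = list(DEFAULT_WINDOW_CANDIDATES)
    if not candidates:
        raise ValueError("candidates must be nonempty")
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must be in (0, 1)")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    n = len(records)
    n_train = int(round(train_frac * n))
    if n_train < min_records or n - n_train < 2:
        raise ValueError("too few records for a train/holdout split")
    rng = np.random.default_rng(seed)
    boyce: dict[tuple[float, float], list[float]] = {c: [] for c in candidates}
    for _ in range(n_reps):
        perm = rng.permutation(n)
        train = records.iloc[perm[:n_train]]
        holdout = records.iloc[perm[n_train:]]
        for cand in candidates:
            try:
                window = calibrate_window(
                    train, *cand, min_records=min_records, realm=realm
                )
            except ValueError:
                boyce[cand].append(float("nan"))
                continue
            pres = _presence_scores(holdout, window)
            back = _background_scores(
                holdout, window, rng, grid_cap=background_grid_cap
            )
            boyce[cand].append(boyce_index(pres, back))
    means, sds, ns = [], [], []
    for cand in candidates:
        vals = np.asarray(boyce[cand])
        vals = vals[np.isfinite(vals)]
        means.append(float(vals.mean()) if vals.size else float("nan"))
        sds.append(float(vals.std(ddof=1)) if vals.size > 1 else float("nan"))
        ns.append(int(vals.size))
    best = int(np.nanargmax(means))
    return CrossValResult(
        candidates=list(candidates),
        mean_boyce=means,
        sd_boyce=sds,
        n_reps=ns,
        selected=candidates[best],
        boyce_by_candidate=boyce,
    )
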