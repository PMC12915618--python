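"""Seeded synthetic data generators.

Everything downstream of this module (standardization, window calibration,
web reconstruction, trend fitting) can be exercised on data whose generating
mechanism is fully known: a species pool with lognormal body sizes, feeding
links drawn from a Gaussian size-ratio kernel, assemblage time series with
size-selective turnover, and metric panels produced by the exact hierarchical
random-slope model the trend stage is meant to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .nichemodel import FeedingKernel

__all__ = [
    "TurnoverConfig",
    "TrendPanelConfig",
    "generate_species_pool",
    "generate_interaction_records",
    "generate_diet_records",
    "generate_assemblage_timeseries",
    "generate_trend_panel",
]

SURVEY_COLUMNS = [
    "study_id",
    "unit_id",
    "year",
    "season",
    "sample_id",
    "species_id",
    "abundance",
    "latitude",
    "longitude",
    "realm",
]

#: Item-level trophic levels used when building synthetic diet records.
#: Real analyses source these from taxonomic reference databases; the lookup
#: here only has to span the plausible TL range of fish diet items.
ITEM_TL_LOOKUP = {
    "detritus": 1.0,
    "algae": 1.0,
    "macrophytes": 1.0,
    "zooplankton": 2.0,
    "zoobenthos": 2.2,
    "insects": 2.3,
    "crustaceans": 2.5,
    "mollusks": 2.1,
    "small_fish": 3.0,
    "fish": 3.5,
    "large_fish": 4.0,
}


@dataclass(frozen=True)
class TurnoverConfig:
    """Controls for the assemblage time-series generator.

    ``turnover_rate`` is the per-year probability that a resident species is
    replaced by a colonist drawn from the regional pool; ``size_selectivity``
    is a log-odds penalty on colonization per unit log10 body size, so
    positive values shrink mean assemblage body size over time (0 = neutral).
    """

    n_studies: int = 3
    units_per_study: int = 4
    n_years: int = 10
    samples_per_year: int = 4
    turnover_rate: float = 0.10
    size_selectivity: float = 0.0
    abundance_dispersion: float = 0.8
    richness: int = 15
    mean_abundance: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_studies < 1 or self.units_per_study < 1:
            raise ValueError("n_studies and units_per_study must be >= 1")
        if self.n_years < 2:
            raise ValueError("n_years must be >= 2")
        if self.samples_per_year < 1:
            raise ValueError("samples_per_year must be >= 1")
        if not 0.0 <= self.turnover_rate <= 1.0:
            raise ValueError("turnover_rate must be in [0, 1]")
        if self.abundance_dispersion <= 0:
            raise ValueError("abundance_dispersion must be positive")


@dataclass(frozen=True)
class TrendPanelConfig:
    """Parameters of the hierarchical random-slope panel generator.

    The linear predictor for study s, unit u nested in s, centered year t is

        eta = intercept + b_s + b_su + (fixed_slope + g_s + g_su) * t

    with study/unit intercept deviations b and slope deviations g drawn
    normal with the configured SDs, mapped through the identity (gaussian),
    log (poisson) or logit (binomial) link.
    """

    fixed_slope: float = 0.0
    intercept: float = 3.0
    random_slope_sd: float = 0.001
    random_intercept_sd: float = 0.1
    residual_sd: float = 0.05
    family: str = "gaussian"
    n_studies: int = 20
    units_per_study: int = 5
    n_years: int = 20
    trials: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in {"gaussian", "poisson", "binomial"}:
            raise ValueError(f"unknown family: {self.family!r}")
        for name in ("random_slope_sd", "random_intercept_sd", "residual_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.family == "binomial" and self.trials < 1:
            raise ValueError("trials must be >= 1 for the binomial family")


def generate_species_pool(
    n_species: int,
    size_log10_mean: float = 1.2,
    size_log10_sd: float = 0.4,
    piscivore_fraction: float = 0.5,
    seed: int = 0,
    realm: str = "marine",
) -> pd.DataFrame:
    """Draw a regional species pool with lognormal body sizes.

    Body sizes (maximum length, cm) are normal on the log10 scale. A latent
    "true" trophic level increases with size — larger fish sit higher in the
    web — which gives the trophic-group machinery realistic structure to work
    with.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    if size_log10_sd < 0:
        raise ValueError("size_log10_sd must be >= 0")
    if not 0.0 <= piscivore_fraction <= 1.0:
        raise ValueError("piscivore_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    log10_size = rng.normal(size_log10_mean, size_log10_sd, n_species)
    piscivorous = rng.random(n_species) < piscivore_fraction
    # TL rises with log size; clip into the range diet-based TLs occupy
    true_tl = np.clip(
        2.6 + 0.9 * (log10_size - size_log10_mean) + rng.normal(0.0, 0.25, n_species),
        1.0,
        5.5,
    )
    return pd.DataFrame(
        {
            "species_id": [f"sp{i:05d}" for i in range(n_species)],
            "max_length_cm": 10.0 ** log10_size,
            "log10_size": log10_size,
            "piscivorous": piscivorous,
            "true_TL": true_tl,
            "realm": realm,
        }
    )


def generate_interaction_records(
    pool: pd.DataFrame,
    true_kernel: FeedingKernel,
    n_records: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate predator-prey interaction records from a known feeding kernel.

    Predators are drawn uniformly from the piscivores in ``pool``; each prey
    log10 size is drawn from the predator's Gaussian kernel (prey size ~
    Normal(m_pred - mu, sigma)) truncated to the pool's size range, and the
    record is labelled with the pool species closest in size. Returns columns
    ``predator, prey, pred_log10_size, prey_log10_size, realm``.
    """
    if len(pool) < 2:
        raise ValueError("pool must contain at least 2 species")
    true_kernel.validate()
    if n_records < 0:
        raise ValueError("n_records must be >= 0")
    cols = ["predator", "prey", "pred_log10_size", "prey_log10_size", "realm"]
    piscivores = pool[pool["piscivorous"].astype(bool)]
    if n_records == 0 or piscivores.empty:
        # no piscivores: nothing can feed, emit an empty, well-formed table
        return pd.DataFrame(columns=cols)
    rng = np.random.default_rng(seed)
    lo, hi = float(pool["log10_size"].min()), float(pool["log10_size"].max())
    pred_idx = rng.integers(0, len(piscivores), n_records)
    pred = piscivores.iloc[pred_idx]
    m_pred = pred["log10_size"].to_numpy()
    m_prey = rng.normal(m_pred - true_kernel.mu, true_kernel.sigma)
    m_prey = np.clip(m_prey, lo, hi)
    # label each record with the pool species nearest in size
    order = np.argsort(pool["log10_size"].to_numpy())
    sorted_sizes = pool["log10_size"].to_numpy()[order]
    pos = np.searchsorted(sorted_sizes, m_prey)
    pos = np.clip(pos, 1, len(sorted_sizes) - 1)
    left_closer = (m_prey - sorted_sizes[pos - 1]) <= (sorted_sizes[pos] - m_prey)
    nearest = np.where(left_closer, pos - 1, pos)
    prey_ids = pool["species_id"].to_numpy()[order][nearest]
    return pd.DataFrame(
        {
            "predator": pred["species_id"].to_numpy(),
            "prey": prey_ids,
            "pred_log10_size": m_pred,
            "prey_log10_size": m_prey,
            "realm": pred["realm"].to_numpy(),
        }
    )


def generate_diet_records(pool: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Build adult-stage diet records whose fractional TL equals ``true_TL``.

    For each species, two diet items whose TLs bracket ``true_TL - 1`` are
    chosen from :data:`ITEM_TL_LOOKUP` and given the unique pair of weights
    for which 1 + weighted mean item TL reproduces the species' latent TL.
    Species with true_TL below 2 get a single item (TL truncated up to 2).
    """
    rng = np.random.default_rng(seed)
    items = sorted(ITEM_TL_LOOKUP.items(), key=lambda kv: kv[1])
    names = [k for k, _ in items]
    tls = np.array([v for _, v in items])
    rows = []
    for sp, tl in zip(pool["species_id"], pool["true_TL"]):
        target = max(float(tl), 2.0) - 1.0  # mean item TL needed
        target = min(target, float(tls[-1]))
        j = int(np.searchsorted(tls, target))
        if j == 0 or np.isclose(tls[min(j, len(tls) - 1)], target):
            j = min(j, len(tls) - 1)
            rows.append((sp, names[j], tls[j], 1.0, "adult"))
            continue
        lo_tl, hi_tl = tls[j - 1], tls[j]
        w_hi = (target - lo_tl) / (hi_tl - lo_tl)
        rows.append((sp, names[j - 1], lo_tl, 1.0 - w_hi, "adult"))
        rows.append((sp, names[j], hi_tl, w_hi, "adult"))
        # a little larval-stage noise that the adult-stage filter must drop
        if rng.random() < 0.1:
            k = rng.integers(0, len(names))
            rows.append((sp, names[k], tls[k], 1.0, "other"))
    return pd.DataFrame(
        rows, columns=["consumer", "item", "item_TL", "weight", "life_stage"]
    )


def _unit_coordinates(rng: np.random.Generator, n_units: int) -> np.ndarray:
    """Spread units on a coarse lattice (~1 degree apart) across hemispheres."""
    lat0 = rng.uniform(-60.0, 60.0)
    lon0 = rng.uniform(-150.0, 150.0)
    coords = []
    for u in range(n_units):
        coords.append((lat0 + 1.0 * (u // 12), lon0 + 1.0 * (u % 12)))
    return np.array(coords)


def generate_assemblage_timeseries(
    pool: pd.DataFrame, cfg: TurnoverConfig
) -> pd.DataFrame:
    """Simulate survey tables with controllable size-selective turnover.

    Each study x unit starts from a uniform random assemblage of
    ``cfg.richness`` species. Every year each resident is, independently with
    probability ``turnover_rate``, replaced by a colonist drawn from the
    remaining pool with probability proportional to
    ``exp(-size_selectivity * log10_size)``. Per-sample abundances are
    lognormal-Poisson: counts are Poisson with a species-level lognormal mean
    jittered per sample, which makes the coverage filter non-trivial.
    Zero counts are omitted (a species not detected in a sample has no row).
    """
    if pool.empty:
        raise ValueError("species pool is empty")
    richness = min(cfg.richness, len(pool))
    rng = np.random.default_rng(cfg.seed)
    sizes = pool["log10_size"].to_numpy()
    ids = pool["species_id"].to_numpy()
    realm = pool["realm"].iloc[0]
    colon_w = np.exp(-cfg.size_selectivity * sizes)

    rows = []
    for s in range(cfg.n_studies):
        study = f"study{s:03d}"
        coords = _unit_coordinates(rng, cfg.units_per_study)
        for u in range(cfg.units_per_study):
            unit = f"{study}_u{u:02d}"
            lat, lon = coords[u]
            resident = rng.choice(len(pool), size=richness, replace=False)
            # species-level mean abundance, fixed within the unit
            base = rng.lognormal(np.log(cfg.mean_abundance), 0.7, len(pool))
            for t in range(cfg.n_years):
                year = 2000 + t
                if t > 0:
                    leave = rng.random(richness) < cfg.turnover_rate
                    for k in np.flatnonzero(leave):
                        candidates = np.setdiff1d(
                            np.arange(len(pool)), resident, assume_unique=False
                        )
                        if candidates.size == 0:
                            continue  # whole pool resident: nobody to colonize
                        w = colon_w[candidates]
                        resident[k] = rng.choice(candidates, p=w / w.sum())
                for smp in range(cfg.samples_per_year):
                    month = int(rng.integers(1, 13))
                    warm = 4 <= month <= 9
                    if lat < 0:
                        warm = not warm
                    season = "warm" if warm else "cold"
                    sample_id = f"{unit}_y{year}_s{smp}"
                    lam = base[resident] * rng.lognormal(
                        -cfg.abundance_dispersion**2 / 2.0,
                        cfg.abundance_dispersion,
                        richness,
                    )
                    counts = rng.poisson(lam)
                    for sp_i, c in zip(resident, counts):
                        if c > 0:
                            rows.append(
                                (
                                    study,
                                    unit,
                                    year,
                                    season,
                                    sample_id,
                                    ids[sp_i],
                                    int(c),
                                    lat,
                                    lon,
                                    realm,
                                )
                            )
    return pd.DataFrame(rows, columns=SURVEY_COLUMNS)


def generate_trend_panel(cfg: TrendPanelConfig) -> pd.DataFrame:
    """Generate a metric panel from the random-slope hierarchical model.

    Returns one row per study x unit x year with columns ``study_id``,
    ``unit_id``, ``year``, ``year_c`` (centered), ``value`` and, for the
    binomial family, ``successes`` and ``trials`` (``value`` is then the
    observed proportion).
    """
    rng = np.random.default_rng(cfg.seed)
    years = np.arange(cfg.n_years, dtype=float)
    year_c = years - years.mean()
    rows = []
    for s in range(cfg.n_studies):
        b_s = rng.normal(0.0, cfg.random_intercept_sd)
        g_s = rng.normal(0.0, cfg.random_slope_sd)
        for u in range(cfg.units_per_study):
            b_su = rng.normal(0.0, cfg.random_intercept_sd)
            g_su = rng.normal(0.0, cfg.random_slope_sd)
            eta = cfg.intercept + b_s + b_su + (cfg.fixed_slope + g_s + g_su) * year_c
            if cfg.family == "gaussian":
                value = eta + rng.normal(0.0, cfg.residual_sd, cfg.n_years)
                extra = {}
            elif cfg.family == "poisson":
                value = rng.poisson(np.exp(eta)).astype(float)
                extra = {}
            else:  # binomial
                p = 1.0 / (1.0 + np.exp(-eta))
                succ = rng.binomial(cfg.trials, p)
                value = succ / cfg.trials
                extra = {"successes": succ, "trials": cfg.trials}
            df = pd.DataFrame(
                {
                    "study_id": f"study{s:03d}",
                    "unit_id": f"study{s:03d}_u{u:02d}",
                    "year": 2000 + years.astype(int),
                    "year_c": year_c,
                    "value": value,
                    **extra,
                }
            )
            rows.append(df)
    return pd.concat(rows, ignore_index=True)
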