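"""Fractional trophic levels and trophic-group classification.

A consumer's fractional trophic level is 1 plus the weighted mean TL of its
diet items (adult-stage records only; qualitative records get equal
weights). Species are then binned into four groups: primary consumers
(TL 2-2.19), omnivores (2.2-2.79), mesopredators (2.8-4) and top predators
(TL > 4). The two-decimal bounds are treated as truncations, so the bins
tile [2, inf) as [2, 2.2), [2.2, 2.8), [2.8, 4.0], (4.0, inf).
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TROPHIC_GROUPS",
    "fractional_trophic_level",
    "classify_trophic_group",
    "build_species_table",
]

TROPHIC_GROUPS = ["top_predator", "mesopredator", "omnivore", "primary_consumer"]


def fractional_trophic_level(records: pd.DataFrame) -> float:
    """Fractional TL of one consumer from its diet records.

    Expects columns ``item_TL``, optional ``weight`` and ``life_stage``;
    only adult-stage records contribute. Missing weights are treated as
    equal (qualitative data); weights are renormalized over usable records.
    Returns NaN (with a log entry) when no usable record remains, so the
    species can be excluded from group proportions downstream.
    """
    rec = records
    if "life_stage" in rec.columns:
        rec = rec[rec["life_stage"] == "adult"]
    rec = rec[np.isfinite(pd.to_numeric(rec["item_TL"], errors="coerce"))]
    if rec.empty:
        logger.info("no usable adult-stage diet records; TL missing")
        return float("nan")
    tl = rec["item_TL"].to_numpy(float)
    if "weight" in rec.columns:
        w = pd.to_numeric(rec["weight"], errors="coerce").to_numpy(float)
        if not (np.isfinite(w).all() and (w > 0).all()):
            # qualitative diet data: fall back to equal weights
            w = np.ones_like(tl)
    else:
        w = np.ones_like(tl)
    return float(1.0 + np.average(tl, weights=w))


def classify_trophic_group(tl: float) -> str | None:
    """Bin a fractional TL into one of the four trophic groups.

    Returns ``None`` for TL < 2 (out of the classifiable range; flagged) and
    raises for non-finite input.
    """
    if tl is None or not math.isfinite(tl):
        raise ValueError("trophic level must be finite")
    if tl < 2.0:
        logger.info("TL %.3f below 2: out of classifiable range", tl)
        return None
    if tl > 4.0:
        return "top_predator"
    if tl >= 2.8:
        return "mesopredator"
    if tl >= 2.2:
        return "omnivore"
    return "primary_consumer"


def build_species_table(
    pool: pd.DataFrame, diet_records: pd.DataFrame
) -> pd.DataFrame:
    """Attach fractional TL and trophic group to a species pool.

    Species without usable diet records get NaN TL and a ``None`` group;
    they stay in the table (they still have sizes and can appear in webs)
    but are excluded from trophic-group proportions.
    """
    tls = {}
    for sp, grp in diet_records.groupby("consumer"):
        tls[sp] = fractional_trophic_level(grp)
    out = pool.copy()
    out["TL"] = out["species_id"].map(tls)
    out["trophic_group"] = [
        classify_trophic_group(float(t)) if pd.notna(t) else None for t in out["TL"]
    ]
    n_missing = int(out["TL"].isna().sum())
    if n_missing:
        logger.info("%d species lack a usable TL", n_missing)
    return out
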