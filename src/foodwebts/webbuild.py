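"""Metaweb construction and per-assemblage food-web realization.

The metaweb holds every potential predator-prey link among the species in
the database: predator i eats prey j whenever j's log10 size falls inside
i's predation window (binary link rule). Out-links of non-piscivorous
species are removed — a size-only model would otherwise let large
herbivores "eat" smaller fish. Local webs are induced subgraphs of the
metaweb on the species co-occurring in one series-year.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd

from .nichemodel import WindowModel

logger = logging.getLogger(__name__)

__all__ = ["build_metaweb", "apply_piscivory_filter", "realize_web"]


def build_metaweb(
    species: pd.DataFrame,
    window: WindowModel,
    allow_cannibalism: bool = False,
) -> set[tuple[str, str]]:
    """All potential predator->prey edges under the predation window.

    Edge (i, j) is present iff lower(m_i) <= m_j <= upper(m_i) and i != j
    (self-links excluded unless ``allow_cannibalism``). Species missing a
    body size are excluded with a logged reason.
    """
    sp = species
    missing = sp["log10_size"].isna()
    if missing.any():
        logger.warning("excluding %d species without body size", int(missing.sum()))
        sp = sp[~missing]
    ids = sp["species_id"].to_numpy()
    m = sp["log10_size"].to_numpy(float)
    lo = window.lower(m)
    hi = window.upper(m)
    inside = (m[None, :] >= lo[:, None]) & (m[None, :] <= hi[:, None])
    if not allow_cannibalism:
        np.fill_diagonal(inside, False)
    pred_idx, prey_idx = np.nonzero(inside)
    return {(ids[a], ids[b]) for a, b in zip(pred_idx, prey_idx)}


def apply_piscivory_filter(
    metaweb: set[tuple[str, str]], species: pd.DataFrame
) -> set[tuple[str, str]]:
    """Remove all out-edges of non-piscivorous species; in-edges untouched.

    Species without a piscivory flag are conservatively treated as
    non-piscivorous (logged).
    """
    flags = {}
    n_missing = 0
    for sp, flag in zip(species["species_id"], species["piscivorous"]):
        if pd.isna(flag):
            n_missing += 1
            flags[sp] = False
        else:
            flags[sp] = bool(flag)
    if n_missing:
        logger.warning(
            "%d species lack a piscivory flag; treated as non-piscivorous",
            n_missing,
        )
    return {(p, q) for (p, q) in metaweb if flags.get(p, False)}


def realize_web(
    metaweb: set[tuple[str, str]],
    assemblage: set[str],
    species: pd.DataFrame,
    series_id: str | None = None,
    year: int | None = None,
) -> nx.DiGraph:
    """Induce the local food web on one series-year's species set.

    Nodes are the assemblage species found in the species table (unknown
    species are dropped with a log entry), annotated with ``log10_size``,
    ``TL`` and ``trophic_group``; edges are the metaweb edges among them.
    A pure function of (metaweb, assemblage): order-independent.
    """
    info = species.set_index("species_id")
    present = sorted(assemblage)
    unknown = [s for s in present if s not in info.index]
    if unknown:
        logger.warning("dropping %d species absent from the species table", len(unknown))
        present = [s for s in present if s not in set(unknown)]
    web = nx.DiGraph(series_id=series_id, year=year)
    for s in present:
        row = info.loc[s]
        web.add_node(
            s,
            log10_size=float(row["log10_size"]),
            TL=float(row["TL"]) if "TL" in row and pd.notna(row["TL"]) else float("nan"),
            trophic_group=row.get("trophic_group"),
        )
    node_set = set(present)
    for p, q in metaweb:
        if p in node_set and q in node_set:
            web.add_edge(p, q)
    return web
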