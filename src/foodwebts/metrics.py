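"""Assemblage- and web-level metrics per series-year.

Undefined metrics (modularity of an edgeless web, generality with no
consumers, ...) propagate as NaN rather than 0 — zeros would bias the trend
slopes fitted downstream.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd

from .trophic import TROPHIC_GROUPS, classify_trophic_group
from .webbuild import realize_web

logger = logging.getLogger(__name__)

__all__ = [
    "jaccard_dissimilarity",
    "connectance",
    "generality",
    "vulnerability",
    "mean_trophic_similarity",
    "modularity",
    "trophic_group_proportions",
    "metric_timeseries",
]

METRIC_COLUMNS = [
    "richness",
    "mean_log10_size",
    "jaccard_dissimilarity",
    "connectance",
    "modularity",
    "generality",
    "vulnerability",
    "trophic_similarity",
]


def jaccard_dissimilarity(first_year_species: set, year_species: set) -> float:
    """1 - |A n B| / |A u B| between the baseline year and a later year."""
    a, b = set(first_year_species), set(year_species)
    if not a:
        raise ValueError("baseline species set is empty")
    union = a | b
    if not union:
        return float("nan")
    return 1.0 - len(a & b) / len(union)


def connectance(web: nx.DiGraph) -> float:
    """Directed connectance L / S^2."""
    s = web.number_of_nodes()
    if s < 1:
        raise ValueError("web has no nodes")
    return web.number_of_edges() / s**2


def generality(web: nx.DiGraph) -> float:
    """Mean number of prey per consumer (nodes with out-degree >= 1)."""
    outs = [d for _, d in web.out_degree() if d >= 1]
    if not outs:
        logger.info("no consumers in web; generality undefined")
        return float("nan")
    return float(np.mean(outs))


def vulnerability(web: nx.DiGraph) -> float:
    """Mean number of predators per prey (nodes with in-degree >= 1)."""
    ins = [d for _, d in web.in_degree() if d >= 1]
    if not ins:
        logger.info("no prey in web; vulnerability undefined")
        return float("nan")
    return float(np.mean(ins))


def trophic_similarity(web: nx.DiGraph, i, j) -> float:
    """Similarity of two species' trophic roles.

    (shared prey + shared predators) divided by the pair's combined distinct
    prey and predators; 0 when the pair has neighbors but none shared, NaN
    when both species are completely isolated.
    """
    prey_i, prey_j = set(web.successors(i)), set(web.successors(j))
    pred_i, pred_j = set(web.predecessors(i)), set(web.predecessors(j))
    denom = len(prey_i | prey_j) + len(pred_i | pred_j)
    if denom == 0:
        return float("nan")
    return (len(prey_i & prey_j) + len(pred_i & pred_j)) / denom


def mean_trophic_similarity(
    web: nx.DiGraph, include_empty_pairs: bool = False
) -> float:
    """Mean trophic similarity over all unordered species pairs.

    Pairs in which both species are isolated have no defined similarity and
    are excluded by default; ``include_empty_pairs`` counts them as 0.
    """
    nodes = sorted(web.nodes())
    if len(nodes) < 2:
        logger.info("fewer than 2 species; trophic similarity undefined")
        return float("nan")
    vals = []
    for a in range(len(nodes)):
        for b in range(a + 1, len(nodes)):
            s = trophic_similarity(web, nodes[a], nodes[b])
            if np.isnan(s):
                if include_empty_pairs:
                    vals.append(0.0)
            else:
                vals.append(s)
    if not vals:
        return float("nan")
    return float(np.mean(vals))


def _set_partitions(items: list):
    """All set partitions of ``items``, in a canonical deterministic order."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def _partition_q(adj: np.ndarray, deg: np.ndarray, m2: float, part) -> float:
    """Q = sum_c (L_c/m - (d_c/2m)^2) on an undirected adjacency matrix."""
    q = 0.0
    for comm in part:
        idx = np.asarray(comm)
        q += adj[np.ix_(idx, idx)].sum() / m2 - (deg[idx].sum() / m2) ** 2
    return q


def modularity(web: nx.DiGraph, seed: int = 0, exact_max_nodes: int = 8) -> float:
    """Newman-Girvan modularity Q of the best partition found.

    The directed web is projected to an undirected simple graph. Webs with
    at most ``exact_max_nodes`` species are partitioned exhaustively (the
    global optimum over all set partitions); larger webs use greedy
    agglomerative modularity maximization (CNM). Both paths are
    deterministic given the canonical (sorted) node ordering; ``seed`` is
    accepted for interface uniformity.
    """
    if web.number_of_edges() == 0:
        logger.info("edgeless web; modularity undefined")
        return float("nan")
    und = nx.Graph()
    und.add_nodes_from(sorted(web.nodes()))
    und.add_edges_from((min(u, v), max(u, v)) for u, v in web.edges() if u != v)
    if und.number_of_edges() == 0:
        logger.info("only self-links; modularity undefined")
        return float("nan")
    if und.number_of_nodes() <= exact_max_nodes:
        nodes = sorted(und.nodes())
        adj = nx.to_numpy_array(und, nodelist=nodes)
        deg = adj.sum(axis=1)
        m2 = float(deg.sum())  # 2m
        best = -1.0
        for part in _set_partitions(list(range(len(nodes)))):
            q = _partition_q(adj, deg, m2, part)
            if q > best + 1e-12:
                best = q
        return float(best)
    communities = nx.algorithms.community.greedy_modularity_communities(und)
    return float(nx.algorithms.community.modularity(und, communities))


def trophic_group_proportions(tls) -> tuple[dict[str, int], dict[str, float], int]:
    """Counts and proportions of species by trophic group.

    ``tls`` is an iterable of fractional TLs (NaN = unknown, excluded).
    Returns (counts, proportions, total classified); proportions sum to 1
    over classified species. Counts feed the binomial trend models.
    """
    counts = {g: 0 for g in TROPHIC_GROUPS}
    total = 0
    for tl in tls:
        if tl is None or not np.isfinite(tl):
            continue
        g = classify_trophic_group(float(tl))
        if g is None:
            continue
        counts[g] += 1
        total += 1
    if total == 0:
        logger.info("no classifiable TLs; group proportions undefined")
        props = {g: float("nan") for g in TROPHIC_GROUPS}
    else:
        props = {g: counts[g] / total for g in TROPHIC_GROUPS}
    return counts, props, total


def metric_timeseries(
    iteration_table: pd.DataFrame,
    metaweb: set[tuple[str, str]],
    species: pd.DataFrame,
    iteration_index: int = 1,
    modularity_seed: int = 0,
) -> pd.DataFrame:
    """Compute the full metric panel for one rarefied iteration.

    One row per (study, unit, year): richness, mean log10 body size, Jaccard
    dissimilarity to the series' first year, the web topology metrics on the
    realized food web, and trophic-group counts for the binomial models.
    Series-years with no species are omitted (logged upstream).
    """
    info = species.set_index("species_id")
    rows = []
    for (study, unit), ser in iteration_table.groupby(["study_id", "unit_id"]):
        years = sorted(ser["year"].unique())
        first_species: set | None = None
        for yr in years:
            present = set(ser.loc[ser["year"] == yr, "species_id"])
            if not present:
                continue
            if first_species is None:
                first_species = present
            web = realize_web(metaweb, present, species,
                              series_id=f"{study}|{unit}", year=int(yr))
            known = [s for s in present if s in info.index]
            sizes = info.loc[known, "log10_size"].to_numpy(float)
            tls = (
                info.loc[known, "TL"].to_numpy(float)
                if "TL" in info.columns
                else np.full(len(known), np.nan)
            )
            counts, _props, total = trophic_group_proportions(tls)
            single = web.number_of_nodes() < 2
            rows.append(
                {
                    "iteration": iteration_index,
                    "study_id": study,
                    "unit_id": unit,
                    "year": int(yr),
                    "richness": len(present),
                    "mean_log10_size": float(np.mean(sizes)) if len(sizes) else float("nan"),
                    "jaccard_dissimilarity": jaccard_dissimilarity(first_species, present),
                    "connectance": connectance(web) if web.number_of_nodes() else float("nan"),
                    "modularity": float("nan") if single else modularity(web, seed=modularity_seed),
                    "generality": float("nan") if single else generality(web),
                    "vulnerability": float("nan") if single else vulnerability(web),
                    "trophic_similarity": float("nan") if single else mean_trophic_similarity(web),
                    **{f"n_{g}": counts[g] for g in TROPHIC_GROUPS},
                    "n_classified": total,
                }
            )
    return pd.DataFrame(rows)
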