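"""Web metrics against closed-form cases and brute-force oracles."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from foodwebts.metrics import (
    connectance,
    generality,
    jaccard_dissimilarity,
    mean_trophic_similarity,
    metric_timeseries,
    modularity,
    trophic_group_proportions,
    trophic_similarity,
    vulnerability,
)
from foodwebts.synth import generate_species_pool
from foodwebts.webbuild import build_metaweb
from foodwebts.nichemodel import WindowModel


def web_from_edges(edges, nodes=None):
    g = nx.DiGraph()
    if nodes:
        g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return g


def random_web(rng, n=8, p=0.35):
    g = nx.DiGraph()
    nodes = [f"s{i}" for i in range(n)]
    g.add_nodes_from(nodes)
    for a, b in itertools.permutations(nodes, 2):
        if rng.random() < p:
            g.add_edge(a, b)
    return g


class TestJaccard:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ({"a", "b"}, {"a", "b"}, 0.0),
            ({"a"}, {"b"}, 1.0),
            ({"a", "b", "c"}, {"b", "c", "d"}, 0.5),
        ],
    )
    def test_cases(self, a, b, expected):
        assert jaccard_dissimilarity(a, b) == pytest.approx(expected)

    def test_empty_baseline_rejected(self):
        with pytest.raises(ValueError):
            jaccard_dissimilarity(set(), {"a"})


class TestConnectance:
    def test_five_links_five_species(self):
        g = web_from_edges(
            [("a", "b"), ("b", "c"), ("c", "d"), ("d", "e"), ("e", "a")]
        )
        assert connectance(g) == pytest.approx(0.2)

    def test_edgeless(self):
        assert connectance(web_from_edges([], nodes=["a", "b"])) == 0.0

    def test_complete_without_self_links(self):
        nodes = list("abcd")
        g = web_from_edges(itertools.permutations(nodes, 2))
        assert connectance(g) == pytest.approx(3.0 / 4.0)

    def test_empty_web_rejected(self):
        with pytest.raises(ValueError):
            connectance(nx.DiGraph())


class TestGeneralityVulnerability:
    def test_chain(self):
        g = web_from_edges([("a", "b"), ("b", "c")])
        assert generality(g) == pytest.approx(1.0)
        assert vulnerability(g) == pytest.approx(1.0)

    def test_star_predator(self):
        g = web_from_edges([("p", x) for x in "abcd"])
        assert generality(g) == pytest.approx(4.0)
        assert vulnerability(g) == pytest.approx(1.0)

    def test_shared_prey(self):
        g = web_from_edges([(p, "prey") for p in "abcd"])
        assert vulnerability(g) == pytest.approx(4.0)

    def test_algebraic_identities_on_random_webs(self):
        rng = np.random.default_rng(41)
        for _ in range(15):
            g = random_web(rng)
            L = g.number_of_edges()
            consumers = sum(1 for _, d in g.out_degree() if d >= 1)
            prey = sum(1 for _, d in g.in_degree() if d >= 1)
            if consumers:
                assert generality(g) == pytest.approx(L / consumers)
            if prey:
                assert vulnerability(g) == pytest.approx(L / prey)

    def test_no_consumers_flagged(self):
        assert np.isnan(generality(web_from_edges([], nodes=["a"])))


class TestTrophicSimilarity:
    def test_identical_roles(self):
        g = web_from_edges([("p1", "x"), ("p1", "y"), ("p2", "x"), ("p2", "y")])
        assert trophic_similarity(g, "p1", "p2") == pytest.approx(1.0)

    def test_disjoint_neighborhoods(self):
        g = web_from_edges([("p1", "x"), ("p2", "y")])
        assert trophic_similarity(g, "p1", "p2") == pytest.approx(0.0)

    def test_isolated_pair_undefined_and_excluded(self):
        g = web_from_edges([("p1", "x")], nodes=["i1", "i2"])
        assert np.isnan(trophic_similarity(g, "i1", "i2"))
        # isolated-isolated pairs drop out of the mean by default
        with_excluded = mean_trophic_similarity(g)
        with_zeros = mean_trophic_similarity(g, include_empty_pairs=True)
        assert with_zeros <= with_excluded

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            g = random_web(rng, n=7)
            vals = []
            for i, j in itertools.combinations(sorted(g.nodes()), 2):
                prey_i, prey_j = set(g.successors(i)), set(g.successors(j))
                pred_i, pred_j = set(g.predecessors(i)), set(g.predecessors(j))
                denom = len(prey_i | prey_j) + len(pred_i | pred_j)
                if denom:
                    vals.append((len(prey_i & prey_j) + len(pred_i & pred_j)) / denom)
            expected = np.mean(vals) if vals else float("nan")
            assert mean_trophic_similarity(g) == pytest.approx(expected)


def independent_partitions(nodes):
    """All set partitions, generated independently of the implementation."""
    if not nodes:
        yield []
        return
    for part in independent_partitions(nodes[1:]):
        yield [[nodes[0]]] + part
        for k in range(len(part)):
            yield part[:k] + [[nodes[0]] + part[k]] + part[k + 1 :]


class TestModularity:
    def test_two_disjoint_dyads(self):
        g = web_from_edges([("a", "b"), ("c", "d")])
        assert modularity(g) == pytest.approx(0.5)

    def test_complete_graph_no_structure(self):
        g = web_from_edges(itertools.permutations("abcd", 2))
        assert modularity(g) == pytest.approx(0.0, abs=1e-12)

    def test_matches_exhaustive_best_partition(self):
        rng = np.random.default_rng(43)
        for _ in range(12):
            n = int(rng.integers(4, 9))
            g = random_web(rng, n=n, p=float(rng.uniform(0.2, 0.5)))
            und = nx.Graph()
            und.add_nodes_from(g.nodes())
            und.add_edges_from((u, v) for u, v in g.edges() if u != v)
            if und.number_of_edges() == 0:
                continue
            best = max(
                nx.algorithms.community.modularity(und, [set(c) for c in p])
                for p in independent_partitions(sorted(und.nodes()))
            )
            assert modularity(g) == pytest.approx(best, abs=1e-9)

    def test_edgeless_flagged(self):
        assert np.isnan(modularity(web_from_edges([], nodes=["a", "b"])))

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(44)
        g = random_web(rng, n=7)
        mapping = {f"s{i}": f"taxon_{9 - i}" for i in range(7)}
        assert modularity(nx.relabel_nodes(g, mapping)) == pytest.approx(modularity(g))


class TestGroupProportions:
    def test_all_top_predators(self):
        counts, props, total = trophic_group_proportions([4.5, 4.6, 5.0])
        assert props["top_predator"] == pytest.approx(1.0)
        assert total == 3

    def test_one_species_per_group(self):
        counts, props, total = trophic_group_proportions([4.5, 3.0, 2.5, 2.1])
        assert all(v == pytest.approx(0.25) for v in props.values())

    def test_proportions_sum_to_one(self):
        rng = np.random.default_rng(45)
        _, props, total = trophic_group_proportions(rng.uniform(2, 5, 50))
        assert sum(props.values()) == pytest.approx(1.0)

    def test_unknown_tls_excluded(self):
        counts, props, total = trophic_group_proportions([np.nan, 3.0, 1.5])
        assert total == 1


class TestMetricTimeseries:
    @pytest.fixture()
    def setup(self):
        pool = generate_species_pool(25, size_log10_sd=0.6, seed=51)
        pool["TL"] = np.clip(pool["true_TL"], 2.0, None)
        window = WindowModel(0.05, 0.95, -1.5, 1.0, -0.3, 1.0)
        metaweb = build_metaweb(pool, window)
        rng = np.random.default_rng(52)
        rows = []
        for unit in ("u1", "u2"):
            for year in (2000, 2001, 2002):
                for sp in rng.choice(pool["species_id"], 8, replace=False):
                    rows.append(
                        {"study_id": "s1", "unit_id": unit, "year": year,
                         "season": "warm", "sample_id": f"{unit}_{year}",
                         "species_id": sp, "abundance": 5}
                    )
        return pool, metaweb, pd.DataFrame(rows)

    def test_row_count_and_spot_checks(self, setup):
        pool, metaweb, table = setup
        panel = metric_timeseries(table, metaweb, pool)
        assert len(panel) == 6  # 2 units x 3 years
        row = panel.iloc[0]
        present = set(
            table[(table["unit_id"] == row["unit_id"]) & (table["year"] == row["year"])][
                "species_id"
            ]
        )
        assert row["richness"] == len(present)
        sizes = pool.set_index("species_id").loc[sorted(present), "log10_size"]
        assert row["mean_log10_size"] == pytest.approx(sizes.mean())
        assert row["jaccard_dissimilarity"] == 0.0  # first year baseline
        # connectance spot check against the induced edge count
        L = sum(1 for (p, q) in metaweb if p in present and q in present)
        assert row["connectance"] == pytest.approx(L / len(present) ** 2)

    def test_single_species_year_flags_web_metrics(self, setup):
        pool, metaweb, _ = setup
        table = pd.DataFrame(
            [{"study_id": "s1", "unit_id": "u1", "year": 2000, "season": "warm",
              "sample_id": "a", "species_id": pool["species_id"].iloc[0],
              "abundance": 3}]
        )
        panel = metric_timeseries(table, metaweb, pool)
        assert panel["richness"].iloc[0] == 1
        assert np.isnan(panel["generality"].iloc[0])
        assert np.isnan(panel["trophic_similarity"].iloc[0])


class TestMechanismSigns:
    def test_downsizing_raises_connectance_and_lowers_size(self):
        """Size-selective turnover must, in the strong-downsizing regime,
        produce a negative mean body-size slope and a positive mean
        connectance slope in >= 90% of seeded replicates."""
        from scipy import stats as sps
        from foodwebts.synth import TurnoverConfig, generate_assemblage_timeseries
        from foodwebts.webbuild import apply_piscivory_filter

        z = sps.norm.ppf(0.95)
        mu, sigma = 0.5, 0.5
        window = WindowModel(0.05, 0.95, -mu - z * sigma, 1.0, -mu + z * sigma, 1.0)
        conn_pos = size_neg = 0
        n_rep = 10
        for seed in range(n_rep):
            pool = generate_species_pool(100, seed=300 + seed)
            cfg = TurnoverConfig(
                n_studies=2, units_per_study=6, n_years=20, samples_per_year=3,
                turnover_rate=0.3, size_selectivity=6.0, seed=seed,
            )
            table = generate_assemblage_timeseries(pool, cfg)
            metaweb = apply_piscivory_filter(build_metaweb(pool, window), pool)
            sizes = pool.set_index("species_id")["log10_size"]
            cs_slopes, ms_slopes = [], []
            for _, unit in table.groupby("unit_id"):
                years, conn, msize = [], [], []
                for yr, grp in unit.groupby("year"):
                    present = set(grp["species_id"])
                    L = sum(1 for (p, q) in metaweb if p in present and q in present)
                    years.append(yr)
                    conn.append(L / len(present) ** 2)
                    msize.append(sizes.loc[list(present)].mean())
                cs_slopes.append(np.polyfit(years, conn, 1)[0])
                ms_slopes.append(np.polyfit(years, msize, 1)[0])
            conn_pos += np.mean(cs_slopes) > 0
            size_neg += np.mean(ms_slopes) < 0
        assert size_neg >= 0.9 * n_rep
        assert conn_pos >= 0.9 * n_rep
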