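"""Directed structure search and permutation key-driver analysis."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from plaquenet.keydrivers import (
    KeyDriverAnalysis,
    StructureSearchParams,
    gaussian_bic_local_score,
    infer_directed_network,
    key_driver_analysis,
    rank_key_drivers,
)
from plaquenet.synthetic import generate_dag_data


def all_dags(nodes):
    """Every labeled DAG on the given nodes (25 for three nodes)."""
    possible = list(itertools.permutations(nodes, 2))
    for mask in range(1 << len(possible)):
        edges = [possible[i] for i in range(len(possible)) if mask >> i & 1]
        g = nx.DiGraph()
        g.add_nodes_from(nodes)
        g.add_edges_from(edges)
        if nx.is_directed_acyclic_graph(g):
            yield g


def exhaustive_best_score(expr):
    """Independent exhaustive scorer: max BIC score over all DAGs."""
    nodes = list(expr.index)
    X = expr.to_numpy().T
    idx = {n: i for i, n in enumerate(nodes)}

    def total(g):
        return sum(
            gaussian_bic_local_score(
                X, idx[v], tuple(sorted(idx[p] for p in g.predecessors(v)))
            )
            for v in nodes
        )

    return max(total(g) for g in all_dags(nodes))


def graph_score(expr, graph):
    nodes = list(expr.index)
    X = expr.to_numpy().T
    idx = {n: i for i, n in enumerate(nodes)}
    return sum(
        gaussian_bic_local_score(
            X, idx[v], tuple(sorted(idx[p] for p in graph.predecessors(v)))
        )
        for v in nodes
    )


class TestStructureSearch:
    def test_independent_noise_yields_no_edges(self):
        expr, _ = generate_dag_data([], n=1000, seed=0, nodes=["a", "b", "c"])
        graph = infer_directed_network(expr)
        assert graph.number_of_edges() == 0

    def test_chain_recovers_skeleton_without_shortcut(self):
        hits = 0
        for seed in range(10):
            expr, _ = generate_dag_data(
                [("x", "y", 0.9), ("y", "z", 0.9)], n=1000, seed=seed
            )
            graph = infer_directed_network(expr)
            skeleton = {frozenset(e) for e in graph.to_undirected().edges}
            hits += skeleton == {frozenset({"x", "y"}), frozenset({"y", "z"})}
        assert hits >= 9

    @pytest.mark.parametrize("n_nodes", [2, 3])
    def test_matches_exhaustive_scoring_on_small_graphs(self, n_nodes, rng):
        for trial in range(10):
            nodes = list("xyz"[:n_nodes])
            edges = [("x", "y", 0.8)] if trial % 2 else []
            expr, _ = generate_dag_data(
                edges, n=400, seed=int(rng.integers(0, 2**31)), nodes=nodes
            )
            if n_nodes == 2:  # structure search needs >= 3 genes; pad a noise gene
                expr = pd.concat(
                    [expr, pd.DataFrame(
                        np.random.default_rng(trial).standard_normal((1, 400)),
                        index=["pad"], columns=expr.columns)]
                )
            graph = infer_directed_network(expr)
            assert graph_score(expr, graph) == pytest.approx(
                exhaustive_best_score(expr), abs=1e-9
            )

    def test_output_is_acyclic_and_respects_max_degree(self, rng):
        expr = pd.DataFrame(
            rng.standard_normal((8, 120)), index=[f"g{i}" for i in range(8)]
        )
        graph = infer_directed_network(expr, StructureSearchParams(max_degree=2))
        assert nx.is_directed_acyclic_graph(graph)
        und = graph.to_undirected()
        assert max((und.degree(n) for n in und.nodes), default=0) <= 2


class TestKeyDriverAnalysis:
    @staticmethod
    def _star(n_leaves=30, n_isolated=100):
        g = nx.DiGraph()
        leaves = [f"m{i:02d}" for i in range(n_leaves)]
        g.add_edges_from(("hub", leaf) for leaf in leaves)
        isolated = [f"x{i:03d}" for i in range(n_isolated)]
        g.add_nodes_from(isolated)
        return g, leaves, ["hub"] + leaves + isolated

    def test_star_hub_ranked_first_with_floor_p(self):
        g, leaves, universe = self._star()
        result = key_driver_analysis(g, set(leaves), universe, seed=7)
        top = result.sort_values(
            ["fdr", "statistic", "gene"], ascending=[True, False, True]
        ).iloc[0]
        assert top["gene"] == "hub"
        assert top["p"] == pytest.approx(1 / 21)
        assert top["module_in_neighborhood"] == 30

    def test_edgeless_graph_gives_empty_table(self):
        g = nx.DiGraph()
        g.add_nodes_from(["a", "b"])
        result = key_driver_analysis(g, {"a"}, ["a", "b"], seed=0)
        assert result.empty

    def test_module_equal_universe_has_no_enrichment(self):
        g, leaves, universe = self._star()
        result = key_driver_analysis(g, set(universe), universe, seed=0)
        assert (result["statistic"] == 0.0).all()
        assert not result["significant"].any()

    def test_pvalues_reproducible_and_floor_respected(self):
        g, leaves, universe = self._star()
        a = key_driver_analysis(g, set(leaves), universe, seed=11)
        b = key_driver_analysis(g, set(leaves), universe, seed=11)
        pd.testing.assert_frame_equal(a, b)
        assert (a["p"] >= 1 / 21 - 1e-12).all()

    def test_more_permutations_keep_maximal_statistic_gene(self):
        g, leaves, universe = self._star()
        few = key_driver_analysis(g, set(leaves), universe, n_permutations=20, seed=3)
        many = key_driver_analysis(g, set(leaves), universe, n_permutations=200, seed=3)
        assert few.loc[few["statistic"].idxmax(), "gene"] == "hub"
        assert many.loc[many["statistic"].idxmax(), "gene"] == "hub"

    def test_graph_node_outside_universe_rejected(self):
        g = nx.DiGraph()
        g.add_edge("a", "b")
        with pytest.raises(ValueError, match="outside"):
            key_driver_analysis(g, {"a"}, ["a"], seed=0)


class TestRanking:
    def test_merge_orders_by_fdr_statistic_then_gene(self):
        t1 = pd.DataFrame(
            {"gene": ["b", "a"], "neighborhood_size": [3, 3],
             "module_in_neighborhood": [2, 2], "statistic": [2.0, 2.0],
             "p": [0.1, 0.1], "fdr": [0.2, 0.2], "significant": [False, False]}
        )
        t2 = pd.DataFrame(
            {"gene": ["c"], "neighborhood_size": [5],
             "module_in_neighborhood": [5], "statistic": [5.0],
             "p": [0.05], "fdr": [0.1], "significant": [False]}
        )
        merged = rank_key_drivers({"m1": t1, "m2": t2})
        assert list(merged["gene"]) == ["c", "a", "b"]
        assert list(merged["module"]) == ["m2", "m1", "m1"]

    def test_empty_results_merge_to_empty_table(self):
        merged = rank_key_drivers({"m": pd.DataFrame(columns=["gene"])})
        assert merged.empty


def test_facade_recovers_planted_hub_end_to_end(rng):
    # hub drives 20 children; KD analysis on the inferred DAG finds it.
    # The universe holds extra unstructured genes so enrichment is informative.
    edges = [("hub", f"c{i:02d}", 0.7) for i in range(20)]
    expr, truth = generate_dag_data(edges, n=400, seed=5)
    noise = pd.DataFrame(
        rng.standard_normal((60, 400)),
        index=[f"bg{i:02d}" for i in range(60)],
        columns=expr.columns,
    )
    full = pd.concat([expr, noise])
    modules = {"star": list(expr.index)}
    kda = KeyDriverAnalysis(full, modules, universe=list(full.index), seed=5)
    ranked = kda.fit()
    assert ranked.iloc[0]["gene"] == "hub"
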