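import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from placnet.datamodel import AnalysisConfig
from placnet.coexpression import ModuleAssignment, NetworkParams, SweepResult
from placnet.topology import (
    ModuleGraph,
    build_module_graph,
    find_hub,
    hub_distances,
    kde_mode,
    summarize_topology,
)

from conftest import exact_cor_vectors


def manual_graph(edges):
    """Graph from (u, v, centrality, distance) tuples."""
    g = nx.Graph()
    for u, v, c, d in edges:
        g.add_edge(u, v, centrality=c, distance=d)
    return g


class TestBuildModuleGraph:
    def test_edge_weights_from_correlation(self):
        x, y = exact_cor_vectors(0.9, n=30, seed=1)
        expr = pd.DataFrame([x, y], index=["a", "b"])
        mg = build_module_graph(expr, power=3)
        data = mg.graph.get_edge_data("a", "b")
        assert data["centrality"] == pytest.approx(0.95**3)
        assert data["distance"] == pytest.approx(1 / 0.9)

    def test_weak_edges_pruned_by_adjacency_floor(self):
        # signed adjacency 0.05 corresponds to cor just above -1 at power 3
        r = 2 * 0.05 ** (1 / 3) - 1
        x, y = exact_cor_vectors(r, n=40, seed=2)
        expr = pd.DataFrame([x, y], index=["a", "b"])
        mg = build_module_graph(expr, power=3, adjacency_floor=0.10)
        assert mg.graph.number_of_edges() == 0

    def test_disconnected_module_warns(self):
        rng = np.random.default_rng(3)
        raw = rng.standard_normal((3, 200))
        q, _ = np.linalg.qr(raw.T)
        expr = pd.DataFrame(q.T[:3], index=["a", "b", "c"])  # orthogonal rows
        with pytest.warns(UserWarning, match="no edges"):
            mg = build_module_graph(expr, power=12, adjacency_floor=0.2)
        assert mg.hub_id is None


class TestFindHub:
    def test_star_center_wins(self):
        g = manual_graph([("c", leaf, 0.8, 1.2) for leaf in "abdef"])
        assert find_hub(g) == "c"

    def test_symmetric_tie_resolves_to_smaller_id(self):
        g = manual_graph([("a", "b", 0.7, 1.0)])
        assert find_hub(g) == "a"

    def test_matches_dense_eigendecomposition(self):
        rng = np.random.default_rng(4)
        for trial in range(15):
            n = int(rng.integers(3, 8))
            nodes = [f"n{i}" for i in range(n)]
            edges = []
            for i, j in itertools.combinations(range(n), 2):
                if rng.random() < 0.7:
                    edges.append((nodes[i], nodes[j],
                                  float(rng.uniform(0.1, 1.0)), 1.0))
            if not edges:
                continue
            g = manual_graph(edges)
            component = max(nx.connected_components(g), key=len)
            comp_nodes = sorted(component)
            W = np.zeros((len(comp_nodes), len(comp_nodes)))
            idx = {v: i for i, v in enumerate(comp_nodes)}
            for u, v, data in g.subgraph(component).edges(data=True):
                W[idx[u], idx[v]] = W[idx[v], idx[u]] = data["centrality"]
            eigvals, eigvecs = np.linalg.eigh(W)
            lead = np.abs(eigvecs[:, -1])
            expected = comp_nodes[int(np.argmax(lead))]
            assert find_hub(g) == expected

    def test_edgeless_graph_is_error(self):
        g = nx.Graph()
        g.add_nodes_from("ab")
        with pytest.raises(ValueError):
            find_hub(g)


class TestHubDistances:
    def test_path_lengths_add(self):
        g = manual_graph([("A", "B", 0.5, 2.0), ("B", "C", 0.5, 4.0)])
        mg = ModuleGraph(g, "A")
        out = hub_distances(mg, ["B", "C"])
        assert out == {"B": pytest.approx(2.0), "C": pytest.approx(6.0)}

    def test_unreachable_mediator_excluded_and_counted(self):
        g = manual_graph([("A", "B", 0.5, 1.0), ("X", "Y", 0.5, 1.0)])
        mg = ModuleGraph(g, "A")
        out = hub_distances(mg, ["B", "X"])
        assert set(out) == {"B"}
        assert mg.excluded == 1

    def test_matches_exhaustive_path_enumeration(self):
        rng = np.random.default_rng(5)
        for trial in range(15):
            n = int(rng.integers(4, 8))
            nodes = [f"n{i}" for i in range(n)]
            edges = []
            for i, j in itertools.combinations(range(n), 2):
                if rng.random() < 0.6:
                    edges.append((nodes[i], nodes[j], 0.5,
                                  float(rng.uniform(1.0, 5.0))))
            if not edges:
                continue
            g = manual_graph(edges)
            hub = sorted(g.nodes)[0]
            mg = ModuleGraph(g, hub)
            targets = [v for v in g.nodes if v != hub]
            out = hub_distances(mg, targets)
            for target in targets:
                best = np.inf
                for path in nx.all_simple_paths(g, hub, target):
                    length = sum(g[u][v]["distance"]
                                 for u, v in zip(path, path[1:]))
                    best = min(best, length)
                if np.isinf(best):
                    assert target not in out
                else:
                    assert out[target] == pytest.approx(best)

    def test_removing_an_edge_never_shortens_paths(self):
        rng = np.random.default_rng(6)
        g = manual_graph([
            (f"n{i}", f"n{j}", 0.5, float(rng.uniform(1, 4)))
            for i, j in itertools.combinations(range(7), 2)
            if rng.random() < 0.8
        ])
        hub = "n0"
        before = hub_distances(ModuleGraph(g, hub), list(g.nodes))
        u, v = next(iter(g.edges))
        g2 = g.copy()
        g2.remove_edge(u, v)
        after = hub_distances(ModuleGraph(g2, hub), list(g.nodes))
        for node, dist in after.items():
            assert dist >= before[node] - 1e-12

    def test_triangle_inequality(self):
        rng = np.random.default_rng(7)
        g = manual_graph([
            (f"n{i}", f"n{j}", 0.5, float(rng.uniform(1, 4)))
            for i, j in itertools.combinations(range(6), 2)
        ])
        dist = dict(nx.all_pairs_dijkstra_path_length(g, weight="distance"))
        for a in g.nodes:
            for b in g.nodes:
                for c in g.nodes:
                    assert dist[a][b] <= dist[a][c] + dist[c][b] + 1e-12


class TestKdeMode:
    def test_degenerate_values(self):
        assert kde_mode([2.5, 2.5, 2.5]) == 2.5
        assert kde_mode([4.2]) == 4.2
        assert np.isnan(kde_mode([]))

    def test_dominant_cluster_located(self):
        rng = np.random.default_rng(8)
        values = np.concatenate([
            1.0 + rng.normal(0, 0.05, 90), 5.0 + rng.normal(0, 0.05, 10)
        ])
        assert abs(kde_mode(values) - 1.0) < 0.2

    def test_standard_normal_mode_near_zero(self):
        values = np.random.default_rng(9).standard_normal(5000)
        assert abs(kde_mode(values)) < 0.15

    def test_translation_equivariance(self):
        rng = np.random.default_rng(10)
        values = rng.gamma(3.0, 1.0, 400)
        base = kde_mode(values)
        shifted = kde_mode(values + 7.3)
        grid_step = (values.max() - values.min() + 6) / 512
        assert abs(shifted - (base + 7.3)) < 2 * grid_step


class TestSummarizeTopology:
    @staticmethod
    def _setup(seed=0, n=60, size=30):
        """One planted module with known mediators for both sources."""
        rng = np.random.default_rng(seed)
        factor = rng.standard_normal(n)
        loads = np.concatenate([[0.95], rng.uniform(0.6, 0.9, size - 1)])
        rows = [l * factor + np.sqrt(1 - l * l) * rng.standard_normal(n)
                for l in loads]
        ids = [f"F{i:02d}" for i in range(size)]
        samples = [f"S{i}" for i in range(n)]
        expr = pd.DataFrame(rows, index=ids, columns=samples)
        labels = pd.Series(1, index=ids)
        eig = factor / np.linalg.norm(factor)
        eigengenes = pd.DataFrame([eig], index=[1], columns=samples)
        kme = pd.DataFrame(
            {1: [float(np.corrcoef(row, factor)[0, 1]) for row in rows]},
            index=ids,
        )
        assignment = ModuleAssignment(labels, eigengenes, kme, NetworkParams(5))
        return expr, SweepResult([assignment], [])

    def test_identical_mediator_sets_have_zero_separation(self):
        expr, sweep = self._setup()
        ids = set(expr.index[5:12])
        mediators = {("X", "fetal", "birth_weight"): ids,
                     ("X", "maternal", "birth_weight"): ids}
        units, summary = summarize_topology(
            sweep, mediators, {"birth_weight": expr},
            AnalysisConfig(), outcomes=("birth_weight",),
        )
        comp = summary[summary["statistic"] == "compartmentalization"]
        assert comp["mean"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_single_unit_has_missing_se(self):
        expr, sweep = self._setup()
        mediators = {("X", "fetal", "birth_weight"): set(expr.index[4:10])}
        units, summary = summarize_topology(
            sweep, mediators, {"birth_weight": expr},
            AnalysisConfig(), outcomes=("birth_weight",),
        )
        peak = summary[summary["statistic"] == "peak_distance"]
        assert len(peak) == 1 and np.isnan(peak["se"].iloc[0])

    def test_sparse_units_skipped_with_warning(self):
        expr, sweep = self._setup()
        mediators = {("X", "fetal", "birth_weight"): {expr.index[5]}}
        with pytest.warns(UserWarning, match="no contributing"):
            units, summary = summarize_topology(
                sweep, mediators, {"birth_weight": expr},
                AnalysisConfig(), outcomes=("birth_weight",),
            )
        assert len(summary) == 0

    def test_peak_kme_within_unit_interval(self):
        expr, sweep = self._setup(seed=2)
        mediators = {("X", "fetal", "birth_weight"): set(expr.index[3:15]),
                     ("X", "maternal", "birth_weight"): set(expr.index[15:25])}
        units, summary = summarize_topology(
            sweep, mediators, {"birth_weight": expr},
            AnalysisConfig(), outcomes=("birth_weight",),
        )
        kme_rows = summary[summary["statistic"] == "peak_kme"]
        assert ((kme_rows["mean"] >= 0) & (kme_rows["mean"] <= 1)).all()
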