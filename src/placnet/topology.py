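"""Module-graph topology: hubs, edge-weighted distances, and peak statistics.

Each module of each sweep iteration becomes a weighted graph over its
member features: edges are kept where the signed adjacency is at least the
floor (default 0.10) and carry two weights, the adjacency itself (used for
eigenvector centrality) and the inverse correlation strength ``1/|r|``
(used as a path length, so strongly co-expressed neighbours are close).
The module hub is the member with maximum eigenvector centrality; shortest
paths from the hub to significant mediators give per-module distance
distributions whose kernel-density modes are the peak distances ``D_f``
(fetal-exposure mediators) and ``D_m`` (maternal), and the maternal-fetal
compartmentalization of a module is ``|D_f - D_m|``.  Statistics are
aggregated to compound x source (x outcome) means with standard errors
across module x iteration units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import AnalysisConfig
from .coexpression import ModuleAssignment, SweepResult


@dataclass
class ModuleGraph:
    graph: nx.Graph
    hub_id: str | None
    excluded: int = 0  # mediators unreachable from the hub in the last query


def build_module_graph(
    expr_members: pd.DataFrame,
    power: int,
    adjacency_floor: float = 0.10,
) -> ModuleGraph:
    """Thresholded signed-adjacency graph over one module's members.

    Edge attributes: ``centrality`` = signed adjacency, ``distance`` =
    ``1/|cor|``.  The absolute value guards the handful of weakly negative
    correlations that can survive the adjacency floor at low powers.
    """
    features = list(expr_members.index)
    if len(features) < 2:
        raise ValueError("a module graph needs at least 2 members")
    cor = np.clip(np.corrcoef(np.asarray(expr_members, dtype=float)), -1.0, 1.0)
    adj = ((1.0 + cor) / 2.0) ** power
    G = nx.Graph()
    G.add_nodes_from(features)
    n = len(features)
    iu, ju = np.triu_indices(n, k=1)
    keep = adj[iu, ju] >= adjacency_floor
    for i, j in zip(iu[keep], ju[keep]):
        r = abs(cor[i, j])
        if r == 0:
            continue
        G.add_edge(features[i], features[j],
                   centrality=float(adj[i, j]), distance=float(1.0 / r))
    if G.number_of_edges() == 0:
        warnings.warn("module graph has no edges above the adjacency floor",
                      stacklevel=2)
        return ModuleGraph(G, None)
    return ModuleGraph(G, find_hub(G))


def find_hub(graph: nx.Graph, tol: float = 1e-10, max_iter: int = 10000) -> str:
    """Node with maximum eigenvector centrality on the ``centrality`` weights.

    Power iteration on the largest connected component; exact ties resolve
    to the lexicographically smallest node ID.
    """
    if graph.number_of_edges() == 0:
        raise ValueError("cannot locate a hub in an edgeless graph")
    component = max(nx.connected_components(graph), key=lambda c: (len(c), sorted(c)))
    nodes = sorted(component)
    index = {v: i for i, v in enumerate(nodes)}
    W = np.zeros((len(nodes), len(nodes)))
    for u, v, data in graph.subgraph(component).edges(data=True):
        W[index[u], index[v]] = W[index[v], index[u]] = data["centrality"]
    x = np.full(len(nodes), 1.0 / np.sqrt(len(nodes)))
    for _ in range(max_iter):
        # identity shift keeps the leading eigenvalue strictly dominant
        # (plain iteration oscillates on bipartite graphs)
        nxt = W @ x + x
        norm = np.linalg.norm(nxt)
        if norm == 0:
            break
        nxt /= norm
        if np.abs(nxt - x).max() < tol:
            x = nxt
            break
        x = nxt
    best = x.max()
    tied = [nodes[i] for i in np.flatnonzero(x >= best - 1e-9)]
    return min(tied)


def hub_distances(module_graph: ModuleGraph, mediator_ids) -> dict:
    """Dijkstra shortest-path lengths (``distance`` weights) hub -> mediators.

    Unreachable or absent mediators are excluded; the exclusion count is
    stored on the graph object.
    """
    if module_graph.hub_id is None:
        module_graph.excluded = len(list(mediator_ids))
        return {}
    lengths = nx.single_source_dijkstra_path_length(
        module_graph.graph, module_graph.hub_id, weight="distance"
    )
    out, excluded = {}, 0
    for mid in mediator_ids:
        if mid in lengths:
            out[mid] = float(lengths[mid])
        else:
            excluded += 1
    module_graph.excluded = excluded
    return out


def kde_mode(values, grid_points: int = 512) -> float:
    """Mode of the Gaussian-KDE (Silverman bandwidth) of ``values``.

    Evaluated on a regular grid spanning [min - 3h, max + 3h]; a single
    value (or zero spread) returns that value; an empty input is missing.
    Ties resolve to the smallest grid value.
    """
    x = np.asarray([v for v in np.ravel(values) if np.isfinite(v)], dtype=float)
    if len(x) == 0:
        return float("nan")
    if len(x) == 1 or np.ptp(x) == 0:
        return float(x[0])
    kde = stats.gaussian_kde(x, bw_method="silverman")
    h = float(np.sqrt(kde.covariance[0, 0]))
    grid = np.linspace(x.min() - 3 * h, x.max() + 3 * h, grid_points)
    density = kde(grid)
    return float(grid[np.argmax(density)])


def _peak(values: list[float]) -> tuple[float, bool]:
    """KDE mode, falling back to the median for degenerate (<3) inputs."""
    finite = [v for v in values if np.isfinite(v)]
    if not finite:
        return float("nan"), True
    if len(finite) < 3:
        return float(np.median(finite)), True
    return kde_mode(finite), False


def _mean_se(values: np.ndarray) -> tuple[float, float]:
    values = values[np.isfinite(values)]
    if len(values) == 0:
        return float("nan"), float("nan")
    mean = float(values.mean())
    se = float(values.std(ddof=1) / np.sqrt(len(values))) if len(values) > 1 else float("nan")
    return mean, se


def summarize_topology(
    sweep: SweepResult,
    mediators: dict,
    expr_by_outcome: dict,
    config: AnalysisConfig | None = None,
    outcomes=("birth_weight", "gestational_age"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Peak distances, peak |kME| and compartmentalization per compound.

    Parameters
    ----------
    sweep
        Module assignments across the parameter grid.
    mediators
        ``(compound, source, outcome) -> set of significant mediator IDs``.
    expr_by_outcome
        ``outcome -> expression matrix`` (features x samples) on the sample
        set of that outcome (all samples for birth weight, spontaneous-
        labor births for gestational age); the per-iteration adjacency is
        rebuilt on this matrix with that iteration's power.

    Returns
    -------
    (units, summary)
        ``units``: long format, one row per compound x source x outcome x
        module x iteration x statistic.  ``summary``: mean +/- SE across
        module x iteration units per compound x source x outcome, including
        the compartmentalization rows (source = "both").
    """
    config = config or AnalysisConfig()
    min_mediators = getattr(config, "min_mediators_per_unit", 3)
    compounds = sorted({key[0] for key in mediators})
    records = []

    for it, assignment in enumerate(sweep.assignments):
        power = assignment.params.power
        for outcome in outcomes:
            expr = expr_by_outcome[outcome]
            for module in assignment.modules:
                members = [f for f in assignment.members(module) if f in expr.index]
                if len(members) < 2:
                    continue
                mg = build_module_graph(expr.loc[members], power,
                                        config.adjacency_floor)
                if mg.hub_id is None:
                    continue
                all_lengths = nx.single_source_dijkstra_path_length(
                    mg.graph, mg.hub_id, weight="distance"
                )
                kme_col = assignment.kme[module]
                for compound in compounds:
                    peaks = {}
                    for source in ("fetal", "maternal"):
                        ids = mediators.get((compound, source, outcome), set())
                        ids = [m for m in ids if m in members]
                        dists = [all_lengths[m] for m in ids if m in all_lengths]
                        # a unit must carry enough mediators for its KDE mode
                        # to be informative; stray singletons are skipped
                        if len(dists) < min_mediators:
                            continue
                        peak_d, degenerate = _peak(dists)
                        kmes = [abs(float(kme_col.get(m, np.nan))) for m in ids]
                        peak_k, _ = _peak(kmes)
                        peaks[source] = peak_d
                        records.append({
                            "compound": compound, "source": source,
                            "outcome": outcome, "module": module,
                            "iteration": it, "statistic": "peak_distance",
                            "value": peak_d, "degenerate": degenerate,
                            "n_mediators": len(dists),
                        })
                        records.append({
                            "compound": compound, "source": source,
                            "outcome": outcome, "module": module,
                            "iteration": it, "statistic": "peak_kme",
                            "value": peak_k, "degenerate": degenerate,
                            "n_mediators": len(kmes),
                        })
                    if "fetal" in peaks and "maternal" in peaks:
                        records.append({
                            "compound": compound, "source": "both",
                            "outcome": outcome, "module": module,
                            "iteration": it, "statistic": "compartmentalization",
                            "value": abs(peaks["fetal"] - peaks["maternal"]),
                            "degenerate": False, "n_mediators": np.nan,
                        })

    units = pd.DataFrame(records)
    summary_rows = []
    if len(units):
        grouped = units.groupby(["compound", "source", "outcome", "statistic"])
        for (compound, source, outcome, statistic), part in grouped:
            mean, se = _mean_se(part["value"].values)
            summary_rows.append({
                "compound": compound, "source": source, "outcome": outcome,
                "statistic": statistic, "mean": mean, "se": se,
                "n_units": len(part),
            })
    expected = {(c, s, o) for c in compounds for s in ("fetal", "maternal")
                for o in outcomes if (c, s, o) in mediators}
    seen = {(r["compound"], r["source"], r["outcome"]) for r in summary_rows}
    for key in sorted(expected - seen):
        warnings.warn(f"no contributing module/iteration units for {key}",
                      stacklevel=2)
    return units, pd.DataFrame(summary_rows)
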