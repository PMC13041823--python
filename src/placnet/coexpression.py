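"""Signed weighted co-expression networks with a parameter-swept module search.

The construction follows the standard signed-network recipe: Pearson
correlations are rescaled to ``a_ij = ((1 + cor_ij)/2)^beta`` with the
soft-thresholding power ``beta`` chosen as the first integers whose
connectivity distribution achieves a scale-free topology fit R^2 >= 0.85;
topological overlap converts shared-neighbour structure into a similarity;
modules come from average-linkage clustering of TOM dissimilarity with a
recursive gap-based tree cut (a deliberately simple stand-in for hybrid
dynamic tree cutting: deeper split levels cut lower and split on smaller
internal height gaps, so deeper levels refine shallower ones); modules are
merged when their eigengenes correlate above ``1 - merge_cut_height``.

The module eigengene is the first principal component of standardized
member expression (unit-norm across samples, sign-aligned so that the mean
member kME is non-negative), and kME is the Pearson correlation between a
feature and an eigengene.  A sweep over the parameter grid (powers x
minimum module sizes x split depths x merge heights; the full study grid
has 144 combinations) yields per-iteration assignments and a consensus hub
set: the union over module x iteration of the top-10 |kME| member
features.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .datamodel import AnalysisConfig, ExpressionStudy, vst_transform

#: deep-split level -> (static-cut depth as a fraction of the dendrogram
#: height range below the top merge, relative internal height gap that
#: forces a further split); deeper levels cut lower and split on smaller
#: gaps, so their partitions refine the shallower ones
_DEEP_SPLIT_CUT = {2: 0.10, 3: 0.14, 4: 0.25}
_DEEP_SPLIT_GAP = {2: 0.50, 3: 0.25, 4: 0.10}

HUBS_PER_MODULE = 10


@dataclass
class NetworkParams:
    power: int
    min_module_size: int = 30
    deep_split: int = 2
    merge_cut_height: float = 0.15

    def __post_init__(self) -> None:
        if self.power < 1 or int(self.power) != self.power:
            raise ValueError("power must be a positive integer")
        if self.deep_split not in _DEEP_SPLIT_CUT:
            raise ValueError(f"deep_split must be in {sorted(_DEEP_SPLIT_CUT)}")


@dataclass
class ModuleAssignment:
    """Feature -> module labels with eigengenes and kME for one grid point."""

    labels: pd.Series              # feature -> int, 0 = unassigned
    eigengenes: pd.DataFrame       # module x sample, unit norm
    kme: pd.DataFrame              # feature x module
    params: NetworkParams

    @property
    def modules(self) -> list[int]:
        return [int(m) for m in self.eigengenes.index]

    def members(self, module: int) -> list[str]:
        return list(self.labels.index[self.labels == module])


@dataclass
class SweepResult:
    assignments: list
    consensus_hubs: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.assignments)


# ---------------------------------------------------------------------------
# Pre-processing
# ---------------------------------------------------------------------------


def prefilter_and_normalize(study: ExpressionStudy, min_features: int = 50) -> pd.DataFrame:
    """Detection and variance filter followed by the VST-like transform.

    Features must be nonzero (detected) in at least 20% of samples and have
    VST variance above the 10th percentile of feature variances.
    """
    counts = study.counts
    detected = (counts > 0).sum(axis=1) >= 0.2 * counts.shape[1]
    vst = vst_transform(counts)
    variances = vst.var(axis=1, ddof=1)
    floor = variances[detected].quantile(0.10) if detected.any() else np.inf
    keep = detected & (variances > floor)
    if keep.sum() < min_features:
        raise ValueError(
            f"only {int(keep.sum())} features survive the network prefilter"
        )
    return vst.loc[keep]


def estimate_latent_factors(
    expr: pd.DataFrame,
    exposures: pd.DataFrame | np.ndarray,
    n_factors: int = 1,
) -> np.ndarray:
    """Leading principal components of exposure-residualized expression.

    Expression is residualized on the exposure design, and the top
    right-singular vectors of the centered residual matrix are returned as
    per-sample latent factors (n_samples x n_factors).  Estimating factors
    on residuals keeps them (near) orthogonal to the exposures, so the
    factors can be regressed out - or used as covariates - without
    absorbing exposure-associated signal.
    """
    X = np.asarray(exposures, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    X = np.column_stack([np.ones(X.shape[0]), X])
    E = np.asarray(expr, dtype=float)
    coef, *_ = np.linalg.lstsq(X, E.T, rcond=None)
    resid = E - (X @ coef).T

    factors = []
    for _ in range(n_factors):
        centered = resid - resid.mean(axis=1, keepdims=True)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        factor = vt[0]
        factors.append(factor)
        D = np.column_stack([np.ones(len(factor)), factor])
        coef_r, *_ = np.linalg.lstsq(D, resid.T, rcond=None)
        resid = resid - np.outer(coef_r[1], factor)
    return np.column_stack(factors)


def remove_latent_factor(
    expr: pd.DataFrame,
    exposures: pd.DataFrame | np.ndarray,
    n_factors: int = 1,
) -> pd.DataFrame:
    """Regress out latent technical factors while protecting exposure signal.

    Factors come from :func:`estimate_latent_factors`; each is regressed
    out of every feature in turn.
    """
    factors = estimate_latent_factors(expr, exposures, n_factors)
    out = np.asarray(expr, dtype=float).copy()
    for j in range(factors.shape[1]):
        factor = factors[:, j]
        D = np.column_stack([np.ones(len(factor)), factor])
        coef_f, *_ = np.linalg.lstsq(D, out.T, rcond=None)
        out = out - np.outer(coef_f[1], factor)
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)


# ---------------------------------------------------------------------------
# Network construction
# ---------------------------------------------------------------------------


def signed_adjacency(expr: pd.DataFrame | np.ndarray, power: int) -> np.ndarray:
    """Signed adjacency ``((1 + cor)/2)^power`` with unit diagonal."""
    cor = np.corrcoef(np.asarray(expr, dtype=float))
    cor = np.clip(cor, -1.0, 1.0)
    adj = ((1.0 + cor) / 2.0) ** power
    np.fill_diagonal(adj, 1.0)
    return adj


def scale_free_fit(adjacency: np.ndarray, n_bins: int = 10) -> float:
    """Signed scale-free topology fit: -sign(slope) * R^2 of log p(k) vs log k."""
    k = adjacency.sum(axis=0) - np.diag(adjacency)
    k = k[k > 0]
    if len(k) < n_bins:
        return float("nan")
    logk = np.log10(k)
    edges = np.linspace(logk.min(), logk.max() + 1e-12, n_bins + 1)
    which = np.clip(np.digitize(logk, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if not mask.any():
            continue
        xs.append(np.log10(np.mean(k[mask])))
        ys.append(np.log10(mask.mean()))
    if len(xs) < 3:
        return float("nan")
    xs, ys = np.asarray(xs), np.asarray(ys)
    slope, intercept = np.polyfit(xs, ys, 1)
    pred = slope * xs + intercept
    ss_res = np.sum((ys - pred) ** 2)
    ss_tot = np.sum((ys - ys.mean()) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return float(-np.sign(slope) * r2)


def pick_soft_powers(
    expr: pd.DataFrame,
    candidates: list[int] | None = None,
    target: float = 0.85,
    n_keep: int = 3,
) -> list[int]:
    """First ``n_keep`` candidate powers achieving scale-free fit >= target."""
    if candidates is None:
        candidates = list(range(1, 21))
    cor = np.corrcoef(np.asarray(expr, dtype=float))
    cor = np.clip(cor, -1.0, 1.0)
    base = (1.0 + cor) / 2.0
    np.fill_diagonal(base, 1.0)
    chosen, fits = [], {}
    for beta in candidates:
        adj = base**beta
        np.fill_diagonal(adj, 1.0)
        fit = scale_free_fit(adj)
        fits[beta] = fit
        if np.isfinite(fit) and fit >= target:
            chosen.append(int(beta))
            if len(chosen) == n_keep:
                return chosen
    if not chosen:
        raise ValueError(f"no candidate power reaches fit >= {target}: {fits}")
    warnings.warn(
        f"only {len(chosen)} power(s) reach fit >= {target}: {chosen}", stacklevel=2
    )
    return chosen


def tom_similarity(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap: (shared-neighbour weight + a_ij) / (min(k) + 1 - a_ij)."""
    A = np.asarray(adjacency, dtype=float)
    k = A.sum(axis=0) - np.diag(A)
    numerator = A @ A - 2.0 * A + A  # sum_{u != i,j} a_iu a_uj + a_ij
    min_k = np.minimum.outer(k, k)
    tom = numerator / (min_k + 1.0 - A)
    np.fill_diagonal(tom, 1.0)
    return tom


# ---------------------------------------------------------------------------
# Module detection
# ---------------------------------------------------------------------------


def _recursive_cut(Z: np.ndarray, n: int, deep_split: int,
                   min_module_size: int) -> np.ndarray:
    """Gap-based recursive cut of an average-linkage dendrogram.

    A node is split when its merge height exceeds the static cut (a
    deep-split-dependent quantile of all merge heights) or when the
    relative gap between its height and its tallest child exceeds the
    deep-split-dependent tolerance.  Resulting clusters smaller than
    ``min_module_size`` are labeled 0 (unassigned).
    """
    heights = Z[:, 2]
    h_cut = float(heights.max()
                  - _DEEP_SPLIT_CUT[deep_split] * (heights.max() - heights.min()))
    gap_tol = _DEEP_SPLIT_GAP[deep_split]

    def node_height(node: int) -> float:
        return 0.0 if node < n else heights[node - n]

    def leaves(node: int) -> list[int]:
        out, stack = [], [node]
        while stack:
            v = stack.pop()
            if v < n:
                out.append(v)
            else:
                stack.extend((int(Z[v - n, 0]), int(Z[v - n, 1])))
        return out

    labels = np.zeros(n, dtype=int)
    next_label = 1
    stack = [n + len(Z) - 1]
    while stack:
        node = stack.pop()
        if node < n:
            continue  # singleton leaf stays unassigned
        h = node_height(node)
        left, right = int(Z[node - n, 0]), int(Z[node - n, 1])
        child_h = max(node_height(left), node_height(right))
        relgap = (h - child_h) / h if h > 0 else 0.0
        if h > h_cut or relgap > gap_tol:
            stack.extend((left, right))
        else:
            member_idx = leaves(node)
            if len(member_idx) >= min_module_size:
                labels[member_idx] = next_label
                next_label += 1
    return labels


def _module_eigengene(expr_members: np.ndarray) -> tuple[np.ndarray, float]:
    """Unit-norm first principal component of standardized member expression.

    Returns (eigengene over samples, variance fraction explained).
    """
    E = np.asarray(expr_members, dtype=float)
    sd = E.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    standardized = (E - E.mean(axis=1, keepdims=True)) / sd
    _, s, vt = np.linalg.svd(standardized, full_matrices=False)
    eig = vt[0]
    explained = float(s[0] ** 2 / np.sum(s**2))
    return eig / np.linalg.norm(eig), explained


def _compute_kme(expr: np.ndarray, eigengenes: np.ndarray) -> np.ndarray:
    """Pearson correlation of every feature with every eigengene."""
    E = np.asarray(expr, dtype=float)
    Ec = E - E.mean(axis=1, keepdims=True)
    En = Ec / np.maximum(np.linalg.norm(Ec, axis=1, keepdims=True), 1e-300)
    G = np.asarray(eigengenes, dtype=float)
    Gc = G - G.mean(axis=1, keepdims=True)
    Gn = Gc / np.maximum(np.linalg.norm(Gc, axis=1, keepdims=True), 1e-300)
    return np.clip(En @ Gn.T, -1.0, 1.0)


def _eigengenes_for_labels(expr: np.ndarray, labels: np.ndarray) -> dict:
    out = {}
    for module in sorted(set(labels) - {0}):
        members = np.flatnonzero(labels == module)
        eig, _ = _module_eigengene(expr[members])
        kme_members = _compute_kme(expr[members], eig[None, :])[:, 0]
        if kme_members.mean() < 0:
            eig = -eig
        out[int(module)] = eig
    return out


def _merge_modules(expr: np.ndarray, labels: np.ndarray,
                   merge_cut_height: float, max_rounds: int = 10) -> np.ndarray:
    """Merge modules whose (sign-aligned) eigengenes correlate >= 1 - cut."""
    labels = labels.copy()
    for _ in range(max_rounds):
        eigs = _eigengenes_for_labels(expr, labels)
        modules = sorted(eigs)
        if len(modules) < 2:
            break
        G = np.vstack([eigs[m] for m in modules])
        cor = np.clip(np.corrcoef(G), -1.0, 1.0)
        diss = 1.0 - cor
        np.fill_diagonal(diss, 0.0)
        diss = (diss + diss.T) / 2
        link = hierarchy.linkage(squareform(diss, checks=False), method="average")
        groups = hierarchy.fcluster(link, t=merge_cut_height, criterion="distance")
        if len(set(groups)) == len(modules):
            break
        remap = {}
        for module, group in zip(modules, groups):
            remap.setdefault(group, module)
        new = {module: remap[group] for module, group in zip(modules, groups)}
        labels = np.array([new.get(l, 0) if l != 0 else 0 for l in labels])
    # relabel densely 1..M
    final = sorted(set(labels) - {0})
    lut = {old: i + 1 for i, old in enumerate(final)}
    return np.array([lut.get(l, 0) for l in labels])


def cluster_modules(
    diss_tom: np.ndarray,
    params: NetworkParams,
    expr: pd.DataFrame,
    linkage: np.ndarray | None = None,
) -> ModuleAssignment:
    """Average-linkage clustering + recursive cut + eigengene merging."""
    features = list(expr.index)
    E = np.asarray(expr, dtype=float)
    if linkage is None:
        D = np.asarray(diss_tom, dtype=float)
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0.0)
        linkage = hierarchy.linkage(squareform(D, checks=False), method="average")
    labels = _recursive_cut(linkage, len(features), params.deep_split,
                            params.min_module_size)
    if labels.max() == 0:
        warnings.warn("no module satisfies the minimum size; all unassigned",
                      stacklevel=2)
        empty = pd.DataFrame(np.empty((0, E.shape[1])), columns=expr.columns)
        kme = pd.DataFrame(index=features)
        return ModuleAssignment(pd.Series(labels, index=features), empty, kme, params)
    labels = _merge_modules(E, labels, params.merge_cut_height)

    eigs = _eigengenes_for_labels(E, labels)
    modules = sorted(eigs)
    eigengenes = pd.DataFrame(
        np.vstack([eigs[m] for m in modules]), index=modules, columns=expr.columns
    )
    kme = pd.DataFrame(
        _compute_kme(E, eigengenes.values), index=features, columns=modules
    )
    return ModuleAssignment(pd.Series(labels, index=features), eigengenes, kme, params)


# ---------------------------------------------------------------------------
# Parameter sweep
# ---------------------------------------------------------------------------


def make_grid(config: AnalysisConfig, level: str = "transcript") -> list[NetworkParams]:
    powers = config.powers_transcript if level == "transcript" else config.powers_gene
    return [
        NetworkParams(int(p), int(s), int(d), float(m))
        for p, s, d, m in itertools.product(
            powers, config.min_module_sizes, config.deep_splits,
            config.merge_cut_heights
        )
    ]


def module_hubs(assignment: ModuleAssignment, top_n: int = HUBS_PER_MODULE) -> dict:
    """Top-``top_n`` member features per module by |kME| (ties by feature ID)."""
    out = {}
    for module in assignment.modules:
        members = assignment.members(module)
        if not members:
            continue
        scores = assignment.kme.loc[members, module].abs()
        ranked = sorted(members, key=lambda f: (-scores[f], f))
        out[module] = ranked[:top_n]
    return out


def run_sweep(
    expr: pd.DataFrame,
    grid: list[NetworkParams],
    hubs_per_module: int = HUBS_PER_MODULE,
) -> SweepResult:
    """One module assignment per grid point plus the consensus hub union.

    TOM and the dendrogram depend only on the power, so they are computed
    once per distinct power and shared across the rest of the grid.
    """
    if not grid:
        raise ValueError("empty parameter grid")
    assignments: list[ModuleAssignment] = []
    hubs: set[str] = set()
    by_power: dict[int, np.ndarray] = {}
    for params in grid:
        if params.power not in by_power:
            adj = signed_adjacency(expr, params.power)
            diss = 1.0 - tom_similarity(adj)
            diss = (diss + diss.T) / 2
            np.fill_diagonal(diss, 0.0)
            by_power[params.power] = hierarchy.linkage(
                squareform(diss, checks=False), method="average"
            )
        try:
            assignment = cluster_modules(
                None, params, expr, linkage=by_power[params.power]
            )
        except Exception as exc:  # pragma: no cover - defensive per-iteration guard
            warnings.warn(f"sweep iteration {params} failed: {exc}", stacklevel=2)
            continue
        assignments.append(assignment)
        for module_hub_list in module_hubs(assignment, hubs_per_module).values():
            hubs.update(module_hub_list)
    return SweepResult(assignments, sorted(hubs))
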