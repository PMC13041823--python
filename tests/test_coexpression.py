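import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from placnet.datamodel import AnalysisConfig
from placnet.coexpression import (
    NetworkParams,
    cluster_modules,
    make_grid,
    module_hubs,
    pick_soft_powers,
    prefilter_and_normalize,
    remove_latent_factor,
    run_sweep,
    scale_free_fit,
    signed_adjacency,
    tom_similarity,
    _module_eigengene,
)

from conftest import make_study


def block_expression(block_sizes, within_cor, n=120, seed=0, between_cor=None):
    """Factor-model expression with planted correlation blocks.

    ``between_cor`` optionally correlates consecutive block factors.
    """
    rng = np.random.default_rng(seed)
    k = len(block_sizes)
    factors = rng.standard_normal((k, n))
    if between_cor:
        for j in range(1, k):
            factors[j] = (between_cor * factors[0]
                          + np.sqrt(1 - between_cor**2) * factors[j])
    rows, labels = [], []
    loading = np.sqrt(within_cor)
    for j, size in enumerate(block_sizes):
        for _ in range(size):
            rows.append(loading * factors[j]
                        + np.sqrt(1 - loading**2) * rng.standard_normal(n))
            labels.append(j)
    ids = [f"F{i:04d}" for i in range(len(rows))]
    return pd.DataFrame(rows, index=ids), np.array(labels)


def brute_force_tom(adj):
    n = len(adj)
    k = adj.sum(axis=0) - np.diag(adj)
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(adj[i, u] * adj[u, j] for u in range(n)
                         if u != i and u != j)
            tom[i, j] = (shared + adj[i, j]) / (min(k[i], k[j]) + 1 - adj[i, j])
    return tom


class TestPrefilter:
    def test_detection_and_variance_rules(self):
        study = make_study(n_features=100, n_samples=20, seed=1, isoforms=1)
        # feature 0: detected in only 10% of samples
        study.counts.iloc[0, :] = 0
        study.counts.iloc[0, :2] = 50
        # feature 1: constant (variance at the minimum)
        study.counts.iloc[1, :] = 7
        expr = prefilter_and_normalize(study, min_features=10)
        assert study.feature_ids[0] not in expr.index
        assert study.feature_ids[1] not in expr.index

    def test_matches_bruteforce_filter(self):
        from placnet.datamodel import vst_transform
        study = make_study(n_features=100, n_samples=25, seed=2, isoforms=1)
        expr = prefilter_and_normalize(study, min_features=5)
        vst = vst_transform(study.counts)
        detected = (study.counts > 0).sum(axis=1) >= 0.2 * 25
        variances = vst.var(axis=1, ddof=1)
        floor = variances[detected].quantile(0.10)
        expected = set(study.counts.index[detected & (variances > floor)])
        assert set(expr.index) == expected

    def test_too_few_survivors_is_error(self):
        study = make_study(n_features=20, n_samples=10, seed=3, isoforms=1)
        with pytest.raises(ValueError, match="prefilter"):
            prefilter_and_normalize(study, min_features=50)


class TestLatentFactorRemoval:
    def _data(self, n=80, p=150, batch_scale=1.0, seed=0):
        rng = np.random.default_rng(seed)
        exposure = rng.standard_normal(n)
        batch = rng.standard_normal(n)
        load_x = rng.normal(0, 0.3, p)
        load_b = rng.choice([-1, 1], p) * rng.uniform(0.5, 1.5, p) * batch_scale
        E = (load_x[:, None] * exposure[None, :]
             + load_b[:, None] * batch[None, :]
             + rng.normal(0, 1, (p, n)))
        ids = [f"F{i}" for i in range(p)]
        return pd.DataFrame(E, index=ids), exposure, batch

    @staticmethod
    def _r2(expr, factor):
        out = []
        f = (factor - factor.mean()) / factor.std()
        for row in np.asarray(expr):
            out.append(np.corrcoef(row, f)[0, 1] ** 2)
        return np.median(out)

    def test_planted_batch_removed(self):
        expr, exposure, batch = self._data()
        cleaned = remove_latent_factor(expr, exposure)
        assert self._r2(cleaned, batch) < 0.05

    def test_near_noop_without_batch(self):
        expr, exposure, _ = self._data(batch_scale=0.0)
        cleaned = remove_latent_factor(expr, exposure)
        delta = np.asarray(expr) - np.asarray(cleaned)
        r2_change = np.var(delta, axis=1) / np.var(np.asarray(expr), axis=1)
        assert np.median(r2_change) < 0.02

    def test_exposure_signal_protected(self):
        expr, exposure, _ = self._data(seed=4)
        cleaned = remove_latent_factor(expr, exposure)
        before = [np.corrcoef(row, exposure)[0, 1] for row in np.asarray(expr)]
        after = [np.corrcoef(row, exposure)[0, 1] for row in np.asarray(cleaned)]
        assert np.median(np.abs(np.array(before) - np.array(after))) < 0.05


class TestSoftPowerSelection:
    def test_fixture_self_consistency(self):
        # hub-like connectivity: a heavily skewed loading spectrum over a few
        # factors gives an approximately scale-free degree distribution
        rng = np.random.default_rng(3)
        n, p = 300, 500
        loads = 0.97 * rng.uniform(0, 1, p) ** 5
        factors = rng.standard_normal((4, n))
        rows = [l * factors[i % 4] + np.sqrt(1 - l * l) * rng.standard_normal(n)
                for i, l in enumerate(loads)]
        data = pd.DataFrame(rows, index=[f"F{i}" for i in range(p)])
        first = pick_soft_powers(data, candidates=list(range(3, 13)))
        again = pick_soft_powers(data, candidates=list(range(3, 13)))
        assert first == again and len(first) == 3
        assert scale_free_fit(signed_adjacency(data, first[0])) >= 0.85

    def test_pure_noise_raises(self):
        noise = pd.DataFrame(
            np.random.default_rng(1).normal(0, 1, (150, 60)),
            index=[f"N{i}" for i in range(150)],
        )
        with pytest.raises(ValueError, match="no candidate"):
            pick_soft_powers(noise, candidates=[1, 2, 3], target=0.99)


class TestAdjacencyAndTom:
    def test_signed_adjacency_anchor_points(self):
        # correlations +1, -1 and 0 map to 1, 0 and (1/2)^beta
        rng = np.random.default_rng(2)
        x = rng.standard_normal(30)
        orth = rng.standard_normal(30)
        x = (x - x.mean())
        orth = orth - orth.mean()
        orth -= (orth @ x) / (x @ x) * x
        expr = pd.DataFrame([x, -x, orth], index=["a", "b", "c"])
        adj = signed_adjacency(expr, 3)
        assert adj[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert adj[0, 2] == pytest.approx(0.125, abs=1e-12)
        assert np.diag(adj) == pytest.approx(1.0)

    def test_three_node_clique_by_hand(self):
        adj = np.full((3, 3), 0.5)
        np.fill_diagonal(adj, 1.0)
        tom = tom_similarity(adj)
        assert tom[0, 1] == pytest.approx((0.25 + 0.5) / (1 + 1 - 0.5))

    def test_isolated_perfect_pair(self):
        adj = np.eye(4)
        adj[0, 1] = adj[1, 0] = 1.0
        tom = tom_similarity(adj)
        assert tom[0, 1] == pytest.approx(1.0)

    @pytest.mark.parametrize("n_nodes", [6, 15, 50])
    def test_matches_triple_loop_oracle(self, n_nodes):
        rng = np.random.default_rng(n_nodes)
        expr = pd.DataFrame(rng.normal(0, 1, (n_nodes, 25)))
        adj = signed_adjacency(expr, 4)
        np.testing.assert_allclose(tom_similarity(adj), brute_force_tom(adj),
                                   atol=1e-12)

    def test_symmetry_and_bounds(self):
        expr, _ = block_expression([20, 20], 0.6, n=50, seed=6)
        adj = signed_adjacency(expr, 5)
        tom = tom_similarity(adj)
        for mat in (adj, tom):
            assert np.allclose(mat, mat.T)
            assert mat.min() >= 0 and mat.max() <= 1 + 1e-12


class TestClusterModules:
    def _cluster(self, expr, **params):
        adj = signed_adjacency(expr, 5)
        diss = 1.0 - tom_similarity(adj)
        return cluster_modules(diss, NetworkParams(5, **params), expr)

    def test_two_planted_blocks_recovered(self):
        expr, labels = block_expression([60, 60], 0.8, n=120, seed=7)
        assignment = self._cluster(expr, min_module_size=30)
        ari = adjusted_rand_score(labels, assignment.labels.values)
        assert ari > 0.95

    def test_correlated_modules_merge_at_loose_cut(self):
        expr, _ = block_expression([50, 50], 0.8, n=150, seed=8,
                                   between_cor=0.75)
        loose = self._cluster(expr, min_module_size=30, merge_cut_height=0.30)
        strict = self._cluster(expr, min_module_size=30, merge_cut_height=0.05)
        assert len(loose.modules) < len(strict.modules)
        assert len(loose.modules) == 1

    def test_deeper_split_never_coarser(self):
        # nested blocks: two superblocks each containing two subblocks
        expr, _ = block_expression([35, 35, 35, 35], 0.75, n=140, seed=9,
                                   between_cor=0.5)
        counts = {}
        for deep_split in (2, 4):
            a = self._cluster(expr, min_module_size=30, deep_split=deep_split,
                              merge_cut_height=0.05)
            counts[deep_split] = len(a.modules)
        assert counts[4] >= counts[2]

    def test_eigengene_properties(self):
        expr, _ = block_expression([40], 0.7, n=60, seed=10)
        eig, explained = _module_eigengene(expr.values)
        assert np.linalg.norm(eig) == pytest.approx(1.0)
        # first PC explains the top eigenvalue share of the standardized data
        E = expr.values
        E = (E - E.mean(1, keepdims=True)) / E.std(1, ddof=1, keepdims=True)
        eigvals = np.linalg.eigvalsh(E.T @ E)[::-1]
        assert explained == pytest.approx(eigvals[0] / eigvals.sum(), rel=1e-6)

    def test_kme_bounded_and_signed(self):
        expr, labels = block_expression([50, 50], 0.8, n=100, seed=11)
        assignment = self._cluster(expr, min_module_size=30)
        assert (assignment.kme.abs() <= 1 + 1e-12).all().all()
        for module in assignment.modules:
            members = assignment.members(module)
            assert assignment.kme.loc[members, module].mean() > 0


class TestSweep:
    def test_full_grid_has_144_points(self):
        assert len(make_grid(AnalysisConfig(), "transcript")) == 144
        assert len(make_grid(AnalysisConfig(), "gene")) == 144

    def test_single_point_grid(self):
        expr, _ = block_expression([40, 40], 0.8, n=80, seed=12)
        sweep = run_sweep(expr, [NetworkParams(5)])
        assert len(sweep) == 1

    def test_small_module_yields_all_members_as_hubs(self):
        expr, _ = block_expression([8, 40], 0.85, n=90, seed=13)
        adj = signed_adjacency(expr, 5)
        diss = 1.0 - tom_similarity(adj)
        assignment = cluster_modules(
            diss, NetworkParams(5, min_module_size=5), expr
        )
        small = [m for m in assignment.modules
                 if len(assignment.members(m)) < 10]
        for module in small:
            hubs = module_hubs(assignment)[module]
            assert set(hubs) == set(assignment.members(module))

    def test_consensus_hubs_subset_of_features(self):
        expr, _ = block_expression([40, 40], 0.8, n=80, seed=14)
        grid = [NetworkParams(4), NetworkParams(5, deep_split=3)]
        sweep = run_sweep(expr, grid)
        assert set(sweep.consensus_hubs) <= set(expr.index)
        assert len(sweep) == 2
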