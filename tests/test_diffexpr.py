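import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from placnet.datamodel import ExpressionStudy, aggregate_to_gene
from placnet.diffexpr import (
    benjamini_hochberg,
    concordance_enrichment,
    fit_nb_de,
    lfc_cross_correlation,
)

from conftest import make_sample_table


def nb_study(log2_means, dispersion=0.15, n=80, seed=0, size_factors=None,
             lfc=None, x=None):
    """NB counts with optional per-feature log2 fold change along ``x``."""
    rng = np.random.default_rng(seed)
    F = len(log2_means)
    if x is None:
        x = rng.standard_normal(n)
    x = (x - x.mean()) / x.std(ddof=1)
    if size_factors is None:
        size_factors = np.exp(rng.uniform(np.log(0.8), np.log(1.25), n))
    log2 = np.tile(np.asarray(log2_means, dtype=float)[:, None], (1, n))
    if lfc is not None:
        log2 = log2 + np.asarray(lfc)[:, None] * x[None, :]
    mu = size_factors[None, :] * 2.0**log2
    shape = 1.0 / dispersion
    counts = rng.poisson(rng.gamma(shape, mu / shape))
    samples = make_sample_table(n=n, seed=seed)
    frame = pd.DataFrame(counts, index=[f"F{i:04d}" for i in range(F)],
                         columns=samples.sample_ids)
    tx2gene = pd.DataFrame({"transcript_id": frame.index,
                            "gene_id": frame.index})
    return ExpressionStudy(frame, tx2gene, samples), x


class TestBenjaminiHochberg:
    def test_hand_stepup(self):
        assert benjamini_hochberg([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert benjamini_hochberg([0.3]) == pytest.approx([0.3])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_bruteforce_stepup(self, pvals):
        p = np.asarray(pvals)
        adj = benjamini_hochberg(p)
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        for rank_idx, i in enumerate(order):
            expected = min(
                min(m * p[j] / (list(order).index(j) + 1) for j in order[rank_idx:]),
                1.0,
            )
            assert adj[i] == pytest.approx(expected)

    def test_order_invariance(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=30)
        perm = rng.permutation(30)
        assert benjamini_hochberg(p)[perm] == pytest.approx(
            benjamini_hochberg(p[perm])
        )

    def test_missing_values_pass_through(self):
        adj = benjamini_hochberg([0.01, np.nan, 0.5])
        assert np.isnan(adj[1])
        assert np.isfinite(adj[0]) and np.isfinite(adj[2])


class TestFitNbDe:
    def test_matches_statsmodels_glm(self):
        sm = pytest.importorskip("statsmodels.api")
        study, x = nb_study([6.0] * 20, n=70, seed=1, lfc=[0.5] * 20)
        table = fit_nb_de(study, x)
        from placnet.datamodel import median_of_ratios_size_factors
        from placnet.diffexpr import estimate_dispersions
        counts = study.counts.values.astype(float)
        sf = median_of_ratios_size_factors(study.counts)
        disp = estimate_dispersions(counts, sf)
        design = np.column_stack([np.ones(70), x])
        for i in range(0, 20, 4):
            fam = sm.families.NegativeBinomial(alpha=float(disp[i]))
            fit = sm.GLM(counts[i], design, family=fam,
                         offset=np.log(sf)).fit()
            assert table.loc[i, "log2fc"] == pytest.approx(
                fit.params[1] / np.log(2), abs=1e-4
            )
            assert table.loc[i, "se"] == pytest.approx(
                fit.bse[1] / np.log(2), rel=1e-3
            )

    def test_null_pvalues_uniform(self):
        study, x = nb_study([5.5] * 2000, n=60, seed=2)
        perm = np.random.default_rng(0).permutation(len(x))
        table = fit_nb_de(study, x[perm])
        p = table["p"].dropna().values
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_planted_lfc_recovered(self):
        # 50 responsive features amid 450 nulls, so normalization is anchored
        lfc = np.concatenate([np.full(50, 1.5), np.zeros(450)])
        study, x = nb_study([6.0] * 500, n=124, seed=3, lfc=lfc,
                            dispersion=0.2)
        table = fit_nb_de(study, x)
        assert abs(np.median(table["log2fc"][:50]) - 1.5) < 0.25

    def test_type_one_error_not_inflated(self):
        study, x = nb_study([6.0] * 1000, n=60, seed=4)
        table = fit_nb_de(study, x)
        # global null: BH at 10% plus the fold-change gate keeps calls near zero
        assert table["significant"].mean() <= 0.01

    def test_singular_design_is_error(self):
        study, x = nb_study([6.0] * 5, n=30, seed=5)
        with pytest.raises(ValueError, match="singular"):
            fit_nb_de(study, x, covariates=np.column_stack([x, x]))

    def test_too_few_samples_is_error(self):
        study, x = nb_study([6.0] * 5, n=30, seed=6)
        x = x.copy()
        x[5:] = np.nan
        with pytest.raises(ValueError, match="10 samples"):
            fit_nb_de(study, x)


class TestConcordance:
    @staticmethod
    def _table(feature_ids, p, lfc):
        return pd.DataFrame({"feature_id": feature_ids, "p": p, "log2fc": lfc})

    def test_hand_two_by_two(self):
        # construct tables realizing the 2x2 [[10,10],[10,70]]
        n = 100
        ids = [f"F{i}" for i in range(n)]
        conc = np.zeros(n, bool); conc[:20] = True          # 20 concordant
        hit = np.zeros(n, bool); hit[:10] = True; hit[20:30] = True
        a = self._table(ids, np.where(hit | conc, 0.01, 0.5),
                        np.where(hit, 2.0, 0.1))
        b = self._table(ids, np.where(conc, 0.01, 0.5),
                        np.where(hit, 2.0, 0.1))
        out = concordance_enrichment(a, b)
        assert out["table"] == [[10, 10], [10, 70]]
        assert out["log_odds"] == pytest.approx(np.log(7.0), abs=1e-12)
        expected_p = stats.fisher_exact([[10, 10], [10, 70]])[1]
        assert out["fisher_p"] == pytest.approx(expected_p)

    def test_identical_tables_fully_concordant(self):
        rng = np.random.default_rng(0)
        ids = [f"F{i}" for i in range(50)]
        t = self._table(ids, rng.uniform(size=50), rng.normal(0, 2, 50))
        out = concordance_enrichment(t, t.copy())
        sig = ((t["p"] < 0.05) & (t["log2fc"].abs() > 1)).sum()
        assert out["table"][0][0] == sig  # every study-A hit is concordant

    def test_independent_labels_near_null(self):
        # hit-set membership (driven by |lfc_a|) is independent of
        # concordance (driven by table-b significance) by construction
        rng = np.random.default_rng(1)
        ids = [f"F{i}" for i in range(2000)]
        a = self._table(ids, np.full(2000, 0.01), rng.normal(0, 1.2, 2000))
        b = self._table(ids, rng.uniform(size=2000),
                        np.sign(a["log2fc"]) * rng.uniform(0.1, 2, 2000))
        out = concordance_enrichment(a, b)
        assert abs(out["log_odds"]) < 0.5

    def test_gene_collapse(self):
        ids = ["G1.t1", "G1.t2", "G2.t1"]
        tx2gene = pd.DataFrame({"transcript_id": ids,
                                "gene_id": ["G1", "G1", "G2"]})
        a = self._table(ids, [0.01, 0.9, 0.9], [2.0, 0.0, 0.0])
        b = self._table(ids, [0.01, 0.9, 0.9], [1.5, 0.0, 0.0])
        out = concordance_enrichment(a, b, tx2gene=tx2gene)
        assert out["n_concordant"] == 1  # G1 via its first isoform

    def test_empty_universe_is_error(self):
        a = self._table(["A"], [0.5], [0.0])
        b = self._table(["B"], [0.5], [0.0])
        with pytest.raises(ValueError):
            concordance_enrichment(a, b)


class TestLfcCrossCorrelation:
    def test_identity_and_negation(self):
        ids = [f"F{i}" for i in range(10)]
        lfc = np.linspace(-2, 2, 10)
        a = pd.DataFrame({"feature_id": ids, "log2fc": lfc})
        b = pd.DataFrame({"feature_id": ids, "log2fc": lfc})
        assert lfc_cross_correlation(a, b) == pytest.approx(1.0)
        b["log2fc"] = -lfc
        assert lfc_cross_correlation(a, b) == pytest.approx(-1.0)

    def test_matches_direct_pearson(self):
        rng = np.random.default_rng(2)
        ids = [f"F{i}" for i in range(40)]
        a = pd.DataFrame({"feature_id": ids, "log2fc": rng.normal(size=40)})
        b = pd.DataFrame({"feature_id": ids, "log2fc": rng.normal(size=40)})
        expected = np.corrcoef(a["log2fc"], b["log2fc"])[0, 1]
        assert lfc_cross_correlation(a, b) == pytest.approx(expected)

    def test_too_few_pairs_warns_nan(self):
        a = pd.DataFrame({"feature_id": ["A", "B"], "log2fc": [1.0, 2.0]})
        with pytest.warns(UserWarning):
            assert np.isnan(lfc_cross_correlation(a, a))


class TestGeneLevelDilution:
    def test_antagonistic_isoforms_attenuate_gene_lfc(self):
        # two isoforms of one gene respond in opposite directions
        study, x = nb_study([7.0, 7.0], n=124, seed=7, lfc=[1.5, -1.5])
        study = ExpressionStudy(
            study.counts, pd.DataFrame({
                "transcript_id": study.feature_ids, "gene_id": ["G1", "G1"],
            }), study.samples,
        )
        tx = fit_nb_de(study, x)
        gene = fit_nb_de(aggregate_to_gene(study), x)
        assert abs(gene["log2fc"].iloc[0]) < tx["log2fc"].abs().max()
        assert abs(gene["log2fc"].iloc[0]) < 0.5
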