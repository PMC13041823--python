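"""Negative-binomial differential expression against exposure z-scores.

Per feature, a negative-binomial GLM with log link is fitted by iteratively
reweighted least squares with median-of-ratios size factors as offsets.
Dispersions come from a per-feature method-of-moments estimate with a small
floor, lightly smoothed toward a mean-dispersion trend for stability at
cohort scale (n ~ 124).  The exposure coefficient is reported in log2 units
with a Wald test; this is a deliberately simple engine (no shrinkage, no
outlier replacement) whose guarantees are calibration and recovery, not
equality with any particular reference implementation.

Significance calling follows the study convention: Benjamini-Hochberg
adjusted p < 0.10 and |log2FC| > 1.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import ExpressionStudy, median_of_ratios_size_factors

LN2 = np.log(2.0)
DISPERSION_FLOOR = 1e-4
_TREND_WEIGHT = 0.2  # weight of the mean-dispersion trend in log space


def estimate_dispersions(counts: np.ndarray, size_factors: np.ndarray) -> np.ndarray:
    """Method-of-moments NB dispersions with floor and light trend smoothing."""
    q = counts / size_factors[None, :]
    mean = q.mean(axis=1)
    var = q.var(axis=1, ddof=1)
    inv_sf = float(np.mean(1.0 / size_factors))
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (var - mean * inv_sf) / mean**2
    raw = np.where(np.isfinite(raw), raw, DISPERSION_FLOOR)
    raw = np.maximum(raw, DISPERSION_FLOOR)

    # trend alpha(m) = a1/m + a0 fitted by least squares on well-expressed features
    ok = mean > 1
    if ok.sum() >= 10:
        A = np.column_stack([np.ones(ok.sum()), 1.0 / mean[ok]])
        coef, *_ = np.linalg.lstsq(A, raw[ok], rcond=None)
        trend = np.maximum(coef[0] + coef[1] / np.maximum(mean, 1e-8), DISPERSION_FLOOR)
        smoothed = np.exp((1 - _TREND_WEIGHT) * np.log(raw)
                          + _TREND_WEIGHT * np.log(trend))
    else:
        smoothed = raw
    return np.maximum(smoothed, DISPERSION_FLOOR)


def _batched_nb_irls(
    counts: np.ndarray,
    design: np.ndarray,
    offset: np.ndarray,
    dispersions: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-8,
):
    """Fit one NB log-link GLM per row of ``counts`` against a shared design.

    Returns (beta [F x k], cov [F x k x k], converged [F]).
    """
    F, n = counts.shape
    k = design.shape[1]
    # start from OLS on the log scale
    y0 = np.log((counts + 0.5)) - offset[None, :]
    beta, *_ = np.linalg.lstsq(design, y0.T, rcond=None)
    beta = beta.T  # F x k
    converged = np.zeros(F, dtype=bool)
    alpha = dispersions[:, None]

    active = np.ones(F, dtype=bool)
    for _ in range(max_iter):
        if not active.any():
            break
        b = beta[active]
        eta = np.clip(b @ design.T + offset[None, :], -30.0, 30.0)
        mu = np.exp(eta)
        w = mu / (1.0 + alpha[active] * mu)
        z = eta - offset[None, :] + (counts[active] - mu) / mu
        xtwx = np.einsum("ni,fn,nj->fij", design, w, design, optimize=True)
        xtwz = np.einsum("ni,fn,fn->fi", design, w, z, optimize=True)
        try:
            new_b = np.linalg.solve(xtwx, xtwz[..., None])[..., 0]
        except np.linalg.LinAlgError:
            xtwx = xtwx + 1e-8 * np.eye(k)[None]
            new_b = np.linalg.solve(xtwx, xtwz[..., None])[..., 0]
        delta = np.abs(new_b - b).max(axis=1)
        beta[active] = new_b
        done = delta < tol
        idx = np.flatnonzero(active)
        converged[idx[done]] = True
        active[idx[done]] = False

    eta = np.clip(beta @ design.T + offset[None, :], -30.0, 30.0)
    mu = np.exp(eta)
    w = mu / (1.0 + alpha * mu)
    xtwx = np.einsum("ni,fn,nj->fij", design, w, design, optimize=True)
    try:
        cov = np.linalg.inv(xtwx)
    except np.linalg.LinAlgError:
        cov = np.linalg.inv(xtwx + 1e-8 * np.eye(k)[None])
    return beta, cov, converged


def fit_nb_de(
    study: ExpressionStudy,
    exposure_z: pd.Series | np.ndarray,
    covariates: pd.DataFrame | None = None,
    fdr: float = 0.10,
    lfc_threshold: float = 1.0,
) -> pd.DataFrame:
    """Per-feature NB Wald differential expression for one exposure.

    ``exposure_z`` is the z-scored exposure over the study samples; samples
    with missing exposure are dropped.  Covariates (with no intercept
    column; one is added) must leave the design full-rank.  Non-converged
    features keep their estimates but get missing p-values and are excluded
    from the BH family.
    """
    x = np.asarray(exposure_z, dtype=float)
    keep = np.isfinite(x)
    if keep.sum() < 10:
        raise ValueError("need >= 10 samples with exposure")
    counts = np.asarray(study.counts, dtype=float)[:, keep]
    x = x[keep]

    cols = [np.ones(keep.sum()), x]
    names = ["intercept", "exposure"]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)[keep]
        if cov.ndim == 1:
            cov = cov[:, None]
        for j in range(cov.shape[1]):
            cols.append(cov[:, j])
            names.append(f"cov{j}")
    design = np.column_stack(cols)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("singular design matrix")

    sf = median_of_ratios_size_factors(
        pd.DataFrame(counts, index=study.counts.index)
    )
    offset = np.log(sf)
    dispersions = estimate_dispersions(counts, sf)
    beta, cov_b, converged = _batched_nb_irls(counts, design, offset, dispersions)

    j = 1  # exposure column
    log2fc = beta[:, j] / LN2
    se_ln = np.sqrt(np.maximum(cov_b[:, j, j], 0.0))
    se = se_ln / LN2
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = beta[:, j] / se_ln
    p = 2.0 * stats.norm.sf(np.abs(wald))
    p[~converged] = np.nan
    padj = benjamini_hochberg(p)
    out = pd.DataFrame(
        {
            "feature_id": study.feature_ids,
            "log2fc": log2fc,
            "se": se,
            "wald_stat": wald,
            "p": p,
            "padj": padj,
            "converged": converged,
        }
    )
    out["significant"] = (out["padj"] < fdr) & (out["log2fc"].abs() > lfc_threshold)
    out["significant"] = out["significant"].fillna(False)
    return out


def benjamini_hochberg(p: np.ndarray | pd.Series) -> np.ndarray:
    """BH step-up adjusted p-values; missing entries stay missing.

    The family size is the number of non-missing p-values.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    m = int(ok.sum())
    if m == 0:
        return out
    pv = p[ok]
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    result = np.empty(m)
    result[order] = adj
    out[ok] = result
    return out


def _collapse_to_genes(table: pd.DataFrame, tx2gene: pd.DataFrame,
                       mask: pd.Series) -> tuple[set, set]:
    """Gene universe and the genes with >= 1 transcript satisfying ``mask``."""
    mapping = tx2gene.set_index("transcript_id")["gene_id"]
    genes = table["feature_id"].map(mapping)
    universe = set(genes.dropna())
    hits = set(genes[mask.values].dropna())
    return universe, hits


def concordance_enrichment(
    de_a: pd.DataFrame,
    de_b: pd.DataFrame,
    tx2gene: pd.DataFrame | None = None,
    lfc_threshold: float = 1.0,
    alpha: float = 0.05,
) -> dict:
    """Enrichment of cross-study concordant features in the study-A hit set.

    Features are concordant when nominally significant (p < ``alpha``) with
    the same effect direction in both tables; the reference set is features
    with |log2FC| > ``lfc_threshold`` and p < ``alpha`` in ``de_a`` (the
    experimental arm).  With ``tx2gene`` both criteria are collapsed to
    genes (a gene qualifies if any of its transcripts does).  Returns the
    log odds ratio (Haldane-Anscombe +0.5 on zero cells), the two-sided
    Fisher exact p, and the concordant count.
    """
    a = de_a.set_index("feature_id")
    b = de_b.set_index("feature_id")
    shared = a.index.intersection(b.index)
    if not len(shared):
        raise ValueError("no shared features between tables")
    a, b = a.loc[shared], b.loc[shared]

    concordant = (
        (a["p"] < alpha)
        & (b["p"] < alpha)
        & (np.sign(a["log2fc"]) == np.sign(b["log2fc"]))
    ).fillna(False)
    a_hit = ((a["p"] < alpha) & (a["log2fc"].abs() > lfc_threshold)).fillna(False)

    if tx2gene is not None:
        table = pd.DataFrame({"feature_id": shared})
        universe, conc_genes = _collapse_to_genes(table, tx2gene,
                                                  concordant.reset_index(drop=True))
        _, hit_genes = _collapse_to_genes(table, tx2gene, a_hit.reset_index(drop=True))
        units = sorted(universe)
        concordant = pd.Series([u in conc_genes for u in units], index=units)
        a_hit = pd.Series([u in hit_genes for u in units], index=units)

    n11 = int((concordant & a_hit).sum())
    n10 = int((concordant & ~a_hit).sum())
    n01 = int((~concordant & a_hit).sum())
    n00 = int((~concordant & ~a_hit).sum())
    table22 = np.array([[n11, n10], [n01, n00]], dtype=float)
    _, fisher_p = stats.fisher_exact(table22, alternative="two-sided")
    if (table22 == 0).any():
        table22 = table22 + 0.5
    log_odds = float(np.log(table22[0, 0] * table22[1, 1]
                            / (table22[0, 1] * table22[1, 0])))
    return {
        "log_odds": log_odds,
        "fisher_p": float(fisher_p),
        "n_concordant": int(concordant.sum()),
        "table": [[n11, n10], [n01, n00]],
    }


def lfc_cross_correlation(de_maternal: pd.DataFrame, de_fetal: pd.DataFrame) -> float:
    """Pearson r of log2 fold changes between matched features."""
    a = de_maternal.set_index("feature_id")["log2fc"]
    b = de_fetal.set_index("feature_id")["log2fc"]
    shared = a.index.intersection(b.index)
    a, b = a.loc[shared], b.loc[shared]
    ok = np.isfinite(a.values) & np.isfinite(b.values)
    if ok.sum() < 3:
        warnings.warn("fewer than 3 matched features; correlation undefined",
                      stacklevel=2)
        return float("nan")
    return float(np.corrcoef(a.values[ok], b.values[ok])[0, 1])
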