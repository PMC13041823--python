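"""Transcriptome-scale causal mediation of exposure -> transcript -> outcome.

For each feature the mediator model ``m ~ x + C`` and outcome model
``y ~ x + m + C`` are fitted by OLS, and uncertainty is propagated by
quasi-Bayesian Monte Carlo: coefficient vectors are drawn from their
asymptotic normal sampling distributions, and per draw the average causal
mediation effect is ``ACME = a * b`` (exposure->mediator times
mediator->outcome), the average direct effect is the exposure coefficient
of the outcome model, and the total effect is their sum (linear model, no
exposure-mediator interaction).  Point estimates are draw means; confidence
intervals are percentile intervals; the two-sided p-value is
``2 * min(Pr(ACME <= 0), Pr(ACME >= 0))``.  By default the sign
probabilities are evaluated in closed form (a coefficient-product draw is
negative exactly when the two independent normal draws disagree in sign),
the n_sims -> infinity limit of the draw-based test; ``p_method=
"montecarlo"`` uses the empirical draw frequencies floored at
``1/(n_sims + 1)`` instead.

Mediators are variance-stabilized (log2 median-of-ratios normalized)
transcript abundances; exposure and outcome enter as z-scores.  The
covariate set is fetal sex plus gestational age for birth-weight analyses
and fetal sex alone for gestational-age analyses, with gestational-age
analyses restricted to births following spontaneous onset of labor.

The exposure contrast for ACME/ADE is one z-score unit, matching the
z-scored estimand.  Both regression stages share the same covariate set.

All computation is vectorized across features; a table of thousands of
mediators fits in one call.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import (
    AnalysisConfig,
    ExpressionStudy,
    impute_censored,
    vst_transform,
    zscore,
)
from .diffexpr import benjamini_hochberg

_CHUNK = 256  # features per Monte Carlo block (bounds draw memory)


def _batched_mediation(
    m_matrix: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None,
    n_sims: int,
    rng: np.random.Generator,
    p_method: str = "analytic",
) -> pd.DataFrame:
    """Quasi-Bayesian mediation for every row of ``m_matrix`` at once."""
    n = len(x)
    Z_cols = [np.ones(n), x]
    if covariates is not None and covariates.size:
        cov = covariates if covariates.ndim == 2 else covariates[:, None]
        Z_cols.extend(cov[:, j] for j in range(cov.shape[1]))
    Z = np.column_stack(Z_cols)
    k = Z.shape[1]
    if np.linalg.matrix_rank(Z) < k:
        raise ValueError("rank-deficient design matrix")

    A = np.linalg.inv(Z.T @ Z)
    F = m_matrix.shape[0]
    M = m_matrix

    # mediator model: m ~ Z  (exposure coefficient = a)
    coef_m = M @ Z @ A.T                      # F x k
    resid_m = M - coef_m @ Z.T
    dof_m = n - k
    sigma2_m = (resid_m**2).sum(axis=1) / dof_m
    a_hat = coef_m[:, 1]
    var_a = sigma2_m * A[1, 1]

    # outcome model: y ~ Z + m, via partitioned regression
    g = Z.T @ y                               # k
    u = M @ Z                                 # F x k  (= Z' m per feature)
    v = u @ A.T                               # F x k  (= A u)
    s = (M**2).sum(axis=1) - np.einsum("fk,fk->f", u, v)
    s = np.maximum(s, 1e-300)
    mty = M @ y
    b_hat = (mty - v @ g) / s
    Ag = A @ g
    cprime_hat = Ag[1] - v[:, 1] * b_hat
    yty = float(y @ y)
    rss = yty - g @ Ag - b_hat**2 * s
    dof_y = n - k - 1
    sigma2_y = np.maximum(rss, 0.0) / dof_y

    V_xx = A[1, 1] + v[:, 1] ** 2 / s
    V_xm = -v[:, 1] / s
    V_mm = 1.0 / s

    zero_var = M.var(axis=1) == 0

    acme = np.full(F, np.nan)
    ade = np.full(F, np.nan)
    total = np.full(F, np.nan)
    ci_low = np.full(F, np.nan)
    ci_high = np.full(F, np.nan)
    ade_var = np.full(F, np.nan)
    pval = np.full(F, np.nan)

    for start in range(0, F, _CHUNK):
        idx = np.arange(start, min(start + _CHUNK, F))
        nb = len(idx)
        z_a = rng.standard_normal((nb, n_sims))
        z1 = rng.standard_normal((nb, n_sims))
        z2 = rng.standard_normal((nb, n_sims))
        a_s = a_hat[idx, None] + np.sqrt(var_a[idx])[:, None] * z_a
        # joint draw of (c', b) via the 2x2 Cholesky of their covariance
        sig = np.sqrt(sigma2_y[idx])[:, None]
        l11 = np.sqrt(np.maximum(V_xx[idx], 0.0))[:, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            l21 = np.where(l11 > 0, V_xm[idx][:, None] / l11, 0.0)
        l22 = np.sqrt(np.maximum(V_mm[idx][:, None] - l21**2, 0.0))
        c_s = cprime_hat[idx, None] + sig * l11 * z1
        b_s = b_hat[idx, None] + sig * (l21 * z1 + l22 * z2)
        acme_s = a_s * b_s
        total_s = acme_s + c_s
        acme[idx] = acme_s.mean(axis=1)
        ade[idx] = c_s.mean(axis=1)
        total[idx] = total_s.mean(axis=1)
        ci_low[idx] = np.percentile(acme_s, 2.5, axis=1)
        ci_high[idx] = np.percentile(acme_s, 97.5, axis=1)
        ade_var[idx] = c_s.var(axis=1, ddof=1)
        if p_method == "montecarlo":
            p_le = (acme_s <= 0).mean(axis=1)
            p_ge = (acme_s >= 0).mean(axis=1)
            pval[idx] = np.maximum(2.0 * np.minimum(p_le, p_ge),
                                   1.0 / (n_sims + 1))

    if p_method == "analytic":
        # exact limit of the draw-based sign test: a draw of ACME = a_s * b_s
        # is positive iff a_s and b_s share a sign, and the two coefficient
        # draws are independent across the mediator and outcome models
        with np.errstate(divide="ignore", invalid="ignore"):
            ta = a_hat / np.sqrt(var_a)
            tb = b_hat / (np.sqrt(sigma2_y) * np.sqrt(np.maximum(V_mm, 0.0)))
        pa = stats.norm.cdf(ta)
        pb = stats.norm.cdf(tb)
        q_pos = pa * pb + (1.0 - pa) * (1.0 - pb)
        pval = np.maximum(2.0 * np.minimum(q_pos, 1.0 - q_pos),
                          np.finfo(float).tiny)
    pval = np.minimum(pval, 1.0)

    out = pd.DataFrame(
        {
            "acme": acme,
            "ade": ade,
            "total_effect": total,
            "ci_low": ci_low,
            "ci_high": ci_high,
            "ade_var": ade_var,
            "p": pval,
            "a": a_hat,
            "b": b_hat,
        }
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        out["prop_mediated"] = out["acme"] / out["total_effect"]
    if zero_var.any():
        warnings.warn(f"skipped {int(zero_var.sum())} zero-variance mediator(s)",
                      stacklevel=2)
        out.loc[zero_var, ["acme", "ade", "total_effect", "ci_low", "ci_high",
                           "ade_var", "p", "prop_mediated"]] = np.nan
    return out


def fit_mediation(
    x_z: np.ndarray,
    m: np.ndarray,
    y_z: np.ndarray,
    covariates: np.ndarray | None = None,
    n_sims: int = 1000,
    seed: int = 0,
    p_method: str = "analytic",
) -> dict:
    """Single-mediator quasi-Bayesian mediation; see module docstring."""
    rng = np.random.default_rng(seed)
    table = _batched_mediation(
        np.asarray(m, dtype=float)[None, :],
        np.asarray(x_z, dtype=float),
        np.asarray(y_z, dtype=float),
        None if covariates is None else np.asarray(covariates, dtype=float),
        n_sims,
        rng,
        p_method=p_method,
    )
    return table.iloc[0].to_dict()


def mediate_features(
    mediators: pd.DataFrame,
    x_z: np.ndarray,
    y_z: np.ndarray,
    covariates: np.ndarray | None = None,
    n_sims: int = 1000,
    seed: int = 0,
    fdr: float = 0.05,
    nominal: bool = False,
    p_method: str = "analytic",
) -> pd.DataFrame:
    """Mediation over every feature (rows of ``mediators``) with BH control.

    The BH family is all features in the call (one compound x source x
    outcome analysis).  With ``nominal=True`` significance uses the raw
    p-value instead of the BH-adjusted one.  Monte Carlo draws are assigned
    in feature-ID order, so results do not depend on row ordering.
    """
    rng = np.random.default_rng(seed)
    ids = list(mediators.index)
    order = np.argsort(np.asarray(ids, dtype=object))
    m_sorted = np.asarray(mediators, dtype=float)[order]
    table = _batched_mediation(
        m_sorted,
        np.asarray(x_z, dtype=float),
        np.asarray(y_z, dtype=float),
        None if covariates is None else np.asarray(covariates, dtype=float),
        n_sims,
        rng,
        p_method=p_method,
    )
    inverse = np.empty_like(order)
    inverse[order] = np.arange(len(order))
    table = table.iloc[inverse].reset_index(drop=True)
    table.insert(0, "feature_id", ids)
    table["padj"] = benjamini_hochberg(table["p"].values)
    crit = table["p"] if nominal else table["padj"]
    excludes_zero = (table["ci_low"] > 0) | (table["ci_high"] < 0)
    table["significant"] = ((crit < fdr) & excludes_zero).fillna(False)
    return table


def prepare_mediation_inputs(
    study: ExpressionStudy,
    compound: str,
    source: str,
    outcome: str,
    vst: pd.DataFrame | None = None,
):
    """Assemble (mediator matrix, x_z, y_z, covariates) for one analysis.

    Exposures are log-transformed after censoring imputation and z-scored.
    Gestational-age analyses are restricted to spontaneous-labor births and
    adjust for fetal sex only; birth-weight analyses use all samples with
    the exposure and adjust for fetal sex and gestational-age z-score.
    """
    samples = impute_censored(study.samples)
    if outcome == "gestational_age":
        keep_ids = samples.data.index[samples.data["spontaneous_labor"].astype(bool)]
    else:
        keep_ids = samples.data.index
    conc = samples.concentration(compound, source).loc[keep_ids]
    keep_ids = conc.index[conc.notna() & (conc > 0)]
    conc = conc.loc[keep_ids]
    data = samples.data.loc[keep_ids]

    x_z = zscore(np.log(conc.values))
    y_z = zscore(data[outcome].values.astype(float))
    sex = data["fetal_sex"].values.astype(float)
    if outcome == "birth_weight":
        ga_z = zscore(data["gestational_age"].values.astype(float))
        covariates = np.column_stack([sex, ga_z])
    else:
        covariates = sex[:, None]

    if vst is None:
        vst = vst_transform(study.counts)
    m = vst[list(keep_ids)]
    return m, x_z, y_z, covariates


def mediate_study(
    study: ExpressionStudy,
    compound: str,
    source: str,
    outcome: str,
    config: AnalysisConfig | None = None,
    vst: pd.DataFrame | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Transcriptome-wide mediation for one compound x source x outcome."""
    config = config or AnalysisConfig()
    m, x_z, y_z, covariates = prepare_mediation_inputs(
        study, compound, source, outcome, vst=vst
    )
    return mediate_features(
        m, x_z, y_z, covariates,
        n_sims=config.n_sims,
        seed=config.seed if seed is None else seed,
        fdr=config.mediation_fdr,
    )


def weighted_mean_ade(results: pd.DataFrame) -> dict:
    """Inverse-variance weighted mean ADE over significant mediators.

    Weights are reciprocals of the per-feature ADE draw variances; the CI
    is the normal-approximation 95% interval of the weighted mean.
    """
    table = results
    if "significant" in table:
        table = table[table["significant"].astype(bool)]
    table = table.dropna(subset=["ade", "ade_var"])
    if not len(table):
        warnings.warn("no significant mediators; weighted mean ADE undefined",
                      stacklevel=2)
        return {"estimate": float("nan"), "ci": (float("nan"), float("nan"))}
    w = 1.0 / table["ade_var"].values
    est = float(np.sum(w * table["ade"].values) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    z = stats.norm.ppf(0.975)
    return {"estimate": est, "ci": (est - z * se, est + z * se), "se": se}
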