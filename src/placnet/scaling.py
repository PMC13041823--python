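"""TPTE-scaling regressions and the hub-versus-DE mediation comparison.

Across the compound panel, compound-level summaries of the mediation
architecture (significant mediator counts, peak |kME|, peak hub distance,
maternal-fetal compartmentalization, and the maternal-fetal log2FC
correlation) are regressed on transplacental transfer efficiency with
Pearson correlation and ordinary least squares; the reported R^2 is
exactly r^2.  For the architecture summary, network centrality is the
negated peak distance so that larger values mean closer to the hub.

The mediation-strength comparison assigns features to three disjoint
categories - significant differentially expressed features, consensus-hub
mediators, and consensus-hub non-mediators (hub status takes precedence
over DE for overlapping features) - and compares |ACME| distributions by
one-way ANOVA with Tukey HSD p-values, bootstrapped (resampling ``n_per``
per category, averaging p-values across bootstrap draws).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

PROPERTIES = (
    "mediator_count",
    "peak_kme",
    "peak_distance",
    "compartmentalization",
    "lfc_cross_correlation",
)

CATEGORIES = ("DE_significant", "hub_mediator", "hub_nonmediator")


def pearson_with_p(x, y) -> dict:
    """Pearson r with two-sided t-test p, plus the OLS slope and its 95% CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 paired finite values")
    if x.std() == 0 or y.std() == 0:
        warnings.warn("zero variance; correlation undefined", stacklevel=2)
        nan = float("nan")
        return {"r": nan, "r_squared": nan, "p": nan, "slope": nan,
                "slope_ci": (nan, nan), "n": n}
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    df = n - 2
    if abs(r) == 1.0:
        p = float(np.finfo(float).tiny)
    else:
        t = r * np.sqrt(df / (1.0 - r**2))
        p = float(max(2.0 * stats.t.sf(abs(t), df), np.finfo(float).tiny))
    fit = stats.linregress(x, y)
    tcrit = stats.t.ppf(0.975, df)
    ci = (float(fit.slope - tcrit * fit.stderr), float(fit.slope + tcrit * fit.stderr))
    return {"r": r, "r_squared": r**2, "p": p, "slope": float(fit.slope),
            "slope_ci": ci, "n": n}


def compile_compound_properties(
    topology_summary: pd.DataFrame,
    mediation_tables: dict,
    lfc_correlations: dict | None = None,
) -> pd.DataFrame:
    """Tidy per-compound property table for the scaling regressions.

    ``mediation_tables`` maps ``(compound, source, outcome)`` to a
    mediation result table; the mediator count is the number of unique
    significant features in that analysis.  Peak statistics come from the
    topology summary means; ``lfc_correlations`` maps compound -> Pearson r
    of maternal vs fetal log2 fold changes (source = "both", no outcome).
    """
    rows = []
    for (compound, source, outcome), table in mediation_tables.items():
        count = int(table.loc[table["significant"], "feature_id"].nunique())
        rows.append({"compound": compound, "source": source, "outcome": outcome,
                     "property": "mediator_count", "value": float(count)})
    if topology_summary is not None and len(topology_summary):
        for _, row in topology_summary.iterrows():
            prop = {"peak_distance": "peak_distance", "peak_kme": "peak_kme",
                    "compartmentalization": "compartmentalization"}.get(row["statistic"])
            if prop is None:
                continue
            rows.append({"compound": row["compound"], "source": row["source"],
                         "outcome": row["outcome"], "property": prop,
                         "value": float(row["mean"])})
    if lfc_correlations:
        for compound, r in lfc_correlations.items():
            rows.append({"compound": compound, "source": "both", "outcome": "",
                         "property": "lfc_cross_correlation", "value": float(r)})
    return pd.DataFrame(rows)


def tpte_scaling(
    properties: pd.DataFrame,
    compound_table,
    min_compounds: int = 3,
) -> pd.DataFrame:
    """Regress each property x source x outcome on TPTE across compounds."""
    tpte = {c: compound_table.tpte(c) for c in compound_table.compounds}
    results = []
    for (prop, source, outcome), part in properties.groupby(
        ["property", "source", "outcome"]
    ):
        part = part[part["compound"].isin(tpte)]
        x = np.array([tpte[c] for c in part["compound"]])
        y = part["value"].values.astype(float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < min_compounds:
            warnings.warn(
                f"{prop}/{source}/{outcome}: only {int(ok.sum())} compounds; skipped",
                stacklevel=2,
            )
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error")
                fit = pearson_with_p(x[ok], y[ok])
        except (Warning, ValueError):
            warnings.warn(f"{prop}/{source}/{outcome}: degenerate values; skipped",
                          stacklevel=2)
            continue
        results.append({
            "property": prop, "source": source, "outcome": outcome,
            "r": fit["r"], "r_squared": fit["r_squared"], "p": fit["p"],
            "slope": fit["slope"], "slope_ci_low": fit["slope_ci"][0],
            "slope_ci_high": fit["slope_ci"][1], "n_compounds": fit["n"],
        })
    return pd.DataFrame(results)


def summarize_architecture(scaling: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Slope/CI/significance per property x source x outcome.

    Network centrality is reported as the negated peak distance, so a
    positive centrality slope means mediators move toward the hub as TPTE
    increases.
    """
    out = {}
    for _, row in scaling.iterrows():
        prop = row["property"]
        slope, lo, hi, r = row["slope"], row["slope_ci_low"], row["slope_ci_high"], row["r"]
        if prop == "peak_distance":
            prop = "centrality"
            slope, lo, hi, r = -slope, -hi, -lo, -r
        key = f"{prop}|{row['source']}|{row['outcome']}"
        out[key] = {
            "slope": float(slope), "ci": [float(lo), float(hi)],
            "r": float(r), "p": float(row["p"]),
            "significant": bool(row["p"] < alpha),
        }
    return out


# ---------------------------------------------------------------------------
# Hub vs DE mediation-strength comparison
# ---------------------------------------------------------------------------


def categorize_features(
    de_table: pd.DataFrame,
    mediation_table: pd.DataFrame,
    consensus_hubs,
) -> pd.DataFrame:
    """Assign features to DE_significant / hub_mediator / hub_nonmediator.

    Hub status takes precedence: a feature that is both DE-significant and
    a consensus hub lands in the hub category.  Features in none of the
    categories are excluded.  |ACME| is attached from the mediation table.
    """
    de = de_table.set_index("feature_id")
    med = mediation_table.set_index("feature_id")
    if set(de.index) != set(med.index):
        raise ValueError("DE and mediation tables cover different feature universes")
    hubs = set(consensus_hubs)
    unknown = hubs - set(de.index)
    if unknown:
        raise ValueError(f"consensus hubs outside the feature universe: "
                         f"{sorted(unknown)[:5]}")
    rows = []
    for feature in de.index:
        is_hub = feature in hubs
        is_de = bool(de.loc[feature, "significant"])
        is_mediator = bool(med.loc[feature, "significant"])
        if is_hub:
            category = "hub_mediator" if is_mediator else "hub_nonmediator"
        elif is_de:
            category = "DE_significant"
        else:
            continue
        rows.append({"feature_id": feature, "category": category,
                     "abs_acme": float(abs(med.loc[feature, "acme"]))})
    return pd.DataFrame(rows)


def _tukey_p(means: np.ndarray, mse: float, ns: np.ndarray, df_within: int):
    """Tukey(-Kramer) pairwise p-values via the studentized range."""
    k = len(means)
    out = {}
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(mse / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            if se == 0:
                p = 1.0 if means[i] == means[j] else 0.0
            else:
                q = abs(means[i] - means[j]) / se
                p = float(stats.studentized_range.sf(q, k, df_within))
            out[(i, j)] = min(max(p, 0.0), 1.0)
    return out


def bootstrap_tukey(
    groups: dict,
    B: int = 1000,
    n_per: int = 100,
    seed: int = 0,
    test_mode: bool = False,
) -> dict:
    """Bootstrapped ANOVA + Tukey HSD across ``groups`` (name -> samples).

    Per bootstrap draw, ``n_per`` observations are resampled with
    replacement from each group, a one-way ANOVA F is computed, and Tukey
    HSD pairwise p-values come from the studentized-range distribution;
    reported p-values are means across draws.  ``test_mode`` disables
    resampling (single pass on the original groups, Tukey-Kramer for
    unequal sizes) and then matches a direct Tukey HSD.
    """
    names = list(groups)
    data = [np.asarray(groups[name], dtype=float) for name in names]
    if len(names) < 2 or any(len(d) < 2 for d in data):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    rng = np.random.default_rng(seed)
    k = len(names)

    if test_mode:
        draws = [data]
    else:
        draws = [
            [d[rng.integers(0, len(d), size=n_per)] for d in data]
            for _ in range(B)
        ]

    pair_ps = {(i, j): [] for i in range(k) for j in range(i + 1, k)}
    fs = []
    degenerate = False
    for sample in draws:
        ns = np.array([len(s) for s in sample])
        means = np.array([s.mean() for s in sample])
        n_total = int(ns.sum())
        grand = float(np.concatenate(sample).mean())
        ss_within = float(sum(((s - m) ** 2).sum() for s, m in zip(sample, means)))
        ss_between = float(np.sum(ns * (means - grand) ** 2))
        df_within = n_total - k
        mse = ss_within / df_within if df_within > 0 else 0.0
        if mse == 0:
            degenerate = True
            fs.append(np.inf if ss_between > 0 else np.nan)
        else:
            fs.append((ss_between / (k - 1)) / mse)
        for pair, p in _tukey_p(means, mse, ns, max(df_within, 1)).items():
            pair_ps[pair].append(p)

    pairwise = {
        (names[i], names[j]): float(np.mean(ps)) for (i, j), ps in pair_ps.items()
    }
    fs_arr = np.asarray(fs, dtype=float)
    finite_fs = fs_arr[np.isfinite(fs_arr)]
    return {
        "pairwise_p": pairwise,
        "anova_f": float(np.mean(finite_fs)) if len(finite_fs) else float("nan"),
        "degenerate": degenerate,
        "n_bootstrap": len(draws),
    }
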