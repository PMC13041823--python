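"""Synthetic exposure-study generator with planted network/mediation structure.

The generator emulates the statistical structure the downstream analyses
assume, at desk scale:

* **Exposures.**  Eight PFAS compounds with transplacental transfer
  efficiencies (TPTE) spanning ~0.4-2.4.  Maternal log-concentrations are
  Gaussian; fetal (cord blood) log-concentrations equal ``log(T)`` plus a
  maternal component whose weight rho(T) decays from 0.85 below T = 1 to
  0.05 above T = 2, so maternal and fetal levels are correlated for
  low-transfer compounds and near-independent for high-transfer ones.
  The lowest measurements are left-censored at configurable LOD/LOQ
  fractions.

* **Expression.**  A modular factor model: each module has a latent
  per-sample factor; transcript log2-means combine a baseline, the module
  factor scaled by a per-feature loading (hubs ~0.9-0.98, members spanning
  a |kME| spectrum), exposure effects on designated responder transcripts,
  and a fetal-sex term.  Counts are negative-binomial with sample-specific
  size factors.  Transcripts nest inside genes; a configurable fraction of
  multi-isoform exposure-responsive genes receives opposite-sign effects
  across isoforms, so gene-level aggregation cancels transcript-level fold
  changes.

* **Outcomes.**  Birth weight and gestational age z-scores are linear in
  direct exposure effects, a fetal-sex term, Gaussian noise, and - the
  mediated path - the per-module sums of standardized planted-mediator
  expression for a small number of large *outcome-wired* modules (birth
  weight and gestational age each wire to their own modules; birth weight
  additionally loads on gestational age).  Concentrating the outcome
  signal in co-expression modules is what makes transcriptome-wide
  mediation detectable at n ~ 124: a mediator's outcome-side coefficient
  is proportional to its module loading, so strongly co-expressed (high
  |kME|) transcripts carry the largest mediation effects - the
  hub-mediation architecture the analysis is designed to detect.

  Per compound, the planted fetal mediator count, exposure effect and
  co-expression stratum grow with TPTE, and the maternal stratum for birth
  weight is offset downward by a TPTE-dependent amount so the
  fetal/maternal hub-distance separation is monotone in TPTE.
  Gestational-age mediators sit in one fixed stratum for both sources, so
  no centrality or compartmentalization trend is planted for that outcome.

Ground truth (module labels, loadings, hub flags, planted mediators with
realized true ACME contributions, differential-expression features) is
recorded and serialized next to the study files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    CompoundTable,
    ExpressionStudy,
    SampleTable,
    conc_column,
    flag_column,
    FLAG_BELOW_LOD,
    FLAG_BELOW_LOQ,
    FLAG_QUANTIFIED,
    write_compounds,
    write_counts,
    write_samples,
    write_tx2gene,
)

LN2 = np.log(2.0)

#: default compound panel: TPTE spans <0.5 (long-chain) to >2.0 (short-chain)
DEFAULT_COMPOUNDS = {
    "PFOS": (0.40, 8),
    "PFDA": (0.55, 10),
    "PFUnDA": (0.75, 11),
    "PFNA": (0.95, 9),
    "PFHxS": (1.20, 6),
    "PFOA": (1.50, 8),
    "PFBA": (2.00, 4),
    "PFBS": (2.40, 4),
}


def rho_of_tpte(tpte: float, rho_high: float = 0.85, rho_low: float = 0.05) -> float:
    """Maternal-fetal log-concentration correlation as a function of TPTE.

    Piecewise linear: ``rho_high`` for TPTE <= 1, decreasing to ``rho_low``
    at TPTE >= 2.
    """
    if tpte <= 1.0:
        return rho_high
    if tpte >= 2.0:
        return rho_low
    return rho_high + (rho_low - rho_high) * (tpte - 1.0)


@dataclass
class SimulationDesign:
    """Parameters of the synthetic study.

    ``*_count``, ``*_loading`` and ``*_a`` pairs are (intercept, slope)
    coefficients of linear functions of TPTE; counts are rounded.
    """

    n_samples: int = 124
    compounds: dict = field(default_factory=lambda: dict(DEFAULT_COMPOUNDS))
    seed: int = 0

    # exposures
    sigma_log_conc: float = 0.6
    rho_high: float = 0.85
    rho_low: float = 0.05
    lod_fraction: float = 0.04
    loq_fraction: float = 0.04

    # expression architecture: outcome-wired modules come first, then
    # background modules of equal size, then an unstructured pool (no module,
    # loading 0) filling up to n_transcripts.  The unstructured majority
    # mirrors real transcriptomes - most transcripts sit in no strong module
    # - and anchors the median-of-ratios size factors so that module-factor
    # swings do not masquerade as library-size changes.
    n_transcripts: int = 3000
    n_bw_wired: int = 1
    bw_wired_size: int = 700
    n_ga_wired: int = 1
    ga_wired_size: int = 500
    n_background: int = 6
    n_unstructured: int = 1080
    n_hubs_per_module: int = 5
    hub_loading: tuple = (0.95, 0.99)
    member_loading: tuple = (0.30, 0.85)
    isoform_probs: tuple = (0.60, 0.25, 0.10, 0.05)
    antagonism_fraction: float = 0.30
    baseline_log2: tuple = (5.0, 9.5)
    expr_scale: float = 1.6
    dispersion: float = 0.15
    size_factor_range: tuple = (0.7, 1.4)
    sex_expr_fraction: float = 0.05
    sex_expr_effect: float = 0.3
    # technical batch factor: one latent per-sample variable loading on a
    # block of otherwise-unstructured transcripts with strong signed
    # loadings (a subset-confined composition effect, like rRNA-depletion
    # or GC-content batch variability, that library-size normalization
    # cannot absorb); scale in log2 units
    batch_scale: float = 1.3
    n_technical: int = 500

    # planted mediators (per compound x source x outcome)
    bw_fetal_count: tuple = (14.0, 20.0)
    bw_maternal_count: tuple = (7.0, 8.0)
    ga_count: tuple = (10.0, 10.0)
    bw_fetal_loading: tuple = (0.46, 0.19)
    # maternal loading offset per unit TPTE above 1 (the offset opens up
    # as fetal exposure decouples from maternal, so cross-detected
    # maternal mediators never sit in a displaced stratum while the two
    # exposures are still correlated)
    bw_maternal_offset: float = 0.21
    ga_loading: float = 0.82
    mediator_a: tuple = (0.75, 0.08)
    ga_mediator_a: tuple = (1.90, 0.0)
    n_hub_mediators: int = 1
    hub_mediator_a: float = 0.40
    max_combos_per_hub: int = 2

    # outcome wiring: weight of each wired module's summed mediator signal
    bw_module_weight: float = 1.90
    ga_module_weight: float = 3.00

    # differential-expression-only features (background modules)
    n_de_per_combo: int = 15
    de_log2fc: float = 1.5
    de_loading_max: float = 0.55

    # outcomes
    gamma_fetal: float = -0.08
    gamma_maternal: float = -0.08
    outcome_noise_sd: float = 0.5
    sex_bw_effect: float = 0.25
    sex_ga_effect: float = -0.10
    bw_ga_coef: float = 0.35
    ga_mean_weeks: float = 39.0
    ga_sd_weeks: float = 1.1
    bw_mean_g: float = 3050.0
    bw_sd_g: float = 400.0
    p_male: float = 60 / 124
    p_spontaneous: float = 72 / 124

    @property
    def module_sizes(self) -> list[int]:
        """Sizes of the real modules (wired then background); excludes the
        unstructured pool."""
        wired = ([self.bw_wired_size] * self.n_bw_wired
                 + [self.ga_wired_size] * self.n_ga_wired)
        remaining = self.n_transcripts - sum(wired) - self.n_unstructured
        if remaining < 0 or (self.n_background > 0 and remaining < self.n_background):
            raise ValueError("wired modules exceed the transcript budget")
        if self.n_background == 0:
            if remaining:
                raise ValueError("transcripts left over with no background modules")
            return wired
        base = remaining // self.n_background
        sizes = [base] * self.n_background
        sizes[-1] += remaining - base * self.n_background
        return wired + sizes

    @property
    def n_modules(self) -> int:
        return len(self.module_sizes)

    def bw_modules(self) -> list[int]:
        return list(range(self.n_bw_wired))

    def ga_modules(self) -> list[int]:
        return list(range(self.n_bw_wired, self.n_bw_wired + self.n_ga_wired))

    def wired_modules(self, outcome: str) -> list[int]:
        return self.bw_modules() if outcome == "birth_weight" else self.ga_modules()

    def validate(self) -> None:
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        for p in (self.lod_fraction, self.loq_fraction, self.antagonism_fraction,
                  self.p_male, self.p_spontaneous, self.sex_expr_fraction):
            if not 0 <= p <= 1:
                raise ValueError(f"probability {p} outside [0, 1]")
        if min(self.module_sizes) < self.n_hubs_per_module:
            raise ValueError("module sizes must accommodate designated hubs")
        for t in self.compounds.values():
            rho = rho_of_tpte(t[0], self.rho_high, self.rho_low)
            if not 0 <= rho <= 1:
                raise ValueError("rho(T) outside [0, 1]")

    def tpte(self, compound: str) -> float:
        return float(self.compounds[compound][0])

    @classmethod
    def reduced(cls, seed: int = 0, **overrides) -> "SimulationDesign":
        """Smaller design for replicate simulations (same structure)."""
        base = dict(
            seed=seed,
            n_transcripts=2000,
            n_bw_wired=1, bw_wired_size=340,
            n_ga_wired=1, ga_wired_size=260,
            n_background=2,
            n_unstructured=1300,
            n_technical=300,
            bw_fetal_count=(10.0, 13.0),
            bw_maternal_count=(5.0, 5.0),
            ga_count=(7.0, 5.0),
            n_hub_mediators=1,
            n_de_per_combo=6,
        )
        base.update(overrides)
        return cls(**base)


def _linear(coefs: tuple, tpte: float) -> float:
    return coefs[0] + coefs[1] * tpte


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """Planted structure recorded alongside a generated study."""

    modules: dict            # feature -> module index
    loadings: dict           # feature -> factor loading
    hubs: list               # designated hub feature IDs
    mediators: list          # dicts: feature, compound, source, outcome, a,
                             # loading, module, is_hub, b (realized outcome-
                             # side coefficient on the z-scored outcome) and
                             # acme = a * b
    de_features: list        # dicts: feature, compound, source, log2fc
    rho: dict                # compound -> maternal-fetal correlation used
    maternal_offset: dict    # compound -> planted maternal loading offset (birth weight)
    batch_factor: dict = field(default_factory=dict)    # sample -> latent batch value
    batch_loadings: dict = field(default_factory=dict)  # feature -> batch loading

    def validate(self, feature_ids: set) -> None:
        planted = {m["feature"] for m in self.mediators}
        if not planted <= feature_ids:
            raise ValueError("planted mediator IDs are not a subset of feature IDs")

    def mediator_ids(self, compound=None, source=None, outcome=None) -> list:
        out = []
        for m in self.mediators:
            if compound is not None and m["compound"] != compound:
                continue
            if source is not None and m["source"] != source:
                continue
            if outcome is not None and m["outcome"] != outcome:
                continue
            out.append(m["feature"])
        return out

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            raw = json.load(fh)
        raw["modules"] = {k: int(v) for k, v in raw["modules"].items()}
        return cls(**raw)


# ---------------------------------------------------------------------------
# Exposures
# ---------------------------------------------------------------------------


@dataclass
class ExposureDraw:
    """Generated exposure columns plus uncensored z-scored log-concentrations."""

    data: pd.DataFrame       # conc_*/flag_* columns per compound x source
    limits: pd.DataFrame     # compound, source, lod, loq
    x_z: pd.DataFrame        # columns "<compound>_<source>": true z-scores


def simulate_exposures(design: SimulationDesign, rng: np.random.Generator) -> ExposureDraw:
    """Draw maternal/fetal concentrations with TPTE and censoring structure."""
    design.validate()
    n = design.n_samples
    sigma = design.sigma_log_conc
    cols, xz_cols, limit_rows = {}, {}, []
    for compound, (tpte, _chain) in design.compounds.items():
        rho = rho_of_tpte(tpte, design.rho_high, design.rho_low)
        log_m = rng.normal(0.0, sigma, size=n)
        eps = rng.normal(0.0, 1.0, size=n)
        log_f = np.log(tpte) + rho * log_m + np.sqrt(1.0 - rho**2) * sigma * eps
        for source, log_c in (("maternal", log_m), ("fetal", log_f)):
            conc = np.exp(log_c)
            lod = float(np.quantile(conc, design.lod_fraction)) if design.lod_fraction > 0 else 0.0
            loq = float(np.quantile(conc, design.lod_fraction + design.loq_fraction))
            flags = np.full(n, FLAG_QUANTIFIED, dtype=object)
            values = conc.copy()
            below_lod = conc < lod
            below_loq = (~below_lod) & (conc < loq)
            flags[below_lod] = FLAG_BELOW_LOD
            flags[below_loq] = FLAG_BELOW_LOQ
            values[below_lod] = lod
            values[below_loq] = loq
            cols[conc_column(compound, source)] = values
            cols[flag_column(compound, source)] = flags
            limit_rows.append({"compound": compound, "source": source,
                               "lod": lod, "loq": loq})
            z = (log_c - log_c.mean()) / log_c.std(ddof=1)
            xz_cols[f"{compound}_{source}"] = z
    index = pd.Index([f"S{i + 1:03d}" for i in range(n)], name="sample_id")
    return ExposureDraw(
        data=pd.DataFrame(cols, index=index),
        limits=pd.DataFrame(limit_rows),
        x_z=pd.DataFrame(xz_cols, index=index),
    )


# ---------------------------------------------------------------------------
# Feature architecture and planted effects
# ---------------------------------------------------------------------------


@dataclass
class _Plan:
    feature_ids: list
    tx2gene: pd.DataFrame
    modules: np.ndarray          # per-feature module index
    loadings: np.ndarray
    hub_mask: np.ndarray
    baselines: np.ndarray
    sex_effects: np.ndarray
    batch_loadings: np.ndarray
    effects: list                # dicts: feature_idx, xz column, effect (log2/z-unit)
    mediators: list              # dicts as in GroundTruth plus feature_idx
    de_features: list
    batch_factor: np.ndarray | None = None  # realized per-sample batch values


def _plan_architecture(design: SimulationDesign, rng: np.random.Generator) -> _Plan:
    p = design.n_transcripts
    sizes = design.module_sizes
    # module -1 is the unstructured pool (no factor, loading 0)
    modules = np.concatenate([
        np.repeat(np.arange(len(sizes)), sizes),
        np.full(design.n_unstructured, -1),
    ])

    loadings = rng.uniform(*design.member_loading, size=p)
    loadings[modules == -1] = 0.0
    hub_mask = np.zeros(p, dtype=bool)
    for k in range(len(sizes)):
        members = np.flatnonzero(modules == k)
        hubs = members[: design.n_hubs_per_module]
        loadings[hubs] = rng.uniform(*design.hub_loading, size=len(hubs))
        hub_mask[hubs] = True

    # transcripts nest inside genes; isoforms of a gene share a module
    feature_ids, gene_ids = [], []
    gene_no, i = 0, 0
    iso_sizes = np.arange(1, len(design.isoform_probs) + 1)
    module_end = np.cumsum(list(sizes) + [design.n_unstructured])
    while i < p:
        k = int(rng.choice(iso_sizes, p=np.asarray(design.isoform_probs)))
        boundary = module_end[np.searchsorted(module_end, i, side="right")]
        k = min(k, p - i, boundary - i)
        gene_no += 1
        gene = f"G{gene_no:05d}"
        for j in range(k):
            feature_ids.append(f"{gene}.t{j + 1}")
            gene_ids.append(gene)
            i += 1
    tx2gene = pd.DataFrame({"transcript_id": feature_ids, "gene_id": gene_ids})

    baselines = rng.uniform(*design.baseline_log2, size=p)
    sex_effects = np.zeros(p)
    sex_idx = rng.choice(p, size=int(round(design.sex_expr_fraction * p)), replace=False)
    sex_effects[sex_idx] = rng.choice([-1.0, 1.0], size=len(sex_idx)) * design.sex_expr_effect
    # technical block: first slice of the unstructured pool
    batch_loadings = np.zeros(p)
    unstructured = np.flatnonzero(modules == -1)
    technical = unstructured[: design.n_technical]
    batch_loadings[technical] = (rng.choice([-1.0, 1.0], size=len(technical))
                                 * rng.uniform(0.6, 1.4, size=len(technical))
                                 * design.batch_scale)

    available = ~hub_mask
    effects: list = []
    mediators: list = []
    de_features: list = []

    def take_with_loading(module: int, target_loading: float,
                          jitter: float = 0.02) -> int | None:
        """Reserve a module member and pin its loading to the target stratum."""
        members = np.flatnonzero((modules == module) & available)
        if not len(members):
            return None
        idx = int(rng.choice(members))
        available[idx] = False
        loadings[idx] = float(np.clip(
            target_loading + rng.normal(0.0, jitter), 0.05, 0.88
        ))
        return idx

    compound_names = list(design.compounds)
    tpte_min = min(design.tpte(c) for c in compound_names)
    hub_usage: dict[int, int] = {}

    for compound in compound_names:
        tpte = design.tpte(compound)
        specs = [
            ("birth_weight", ("fetal",),
             max(1, int(round(_linear(design.bw_fetal_count, tpte)))),
             _linear(design.bw_fetal_loading, tpte),
             _linear(design.mediator_a, tpte)),
            ("birth_weight", ("maternal",),
             max(1, int(round(_linear(design.bw_maternal_count, tpte)))),
             _linear(design.bw_fetal_loading, tpte)
             - design.bw_maternal_offset * max(tpte - 1.0, 0.0),
             _linear(design.mediator_a, tpte)),
            # gestational-age mediators respond to both exposure sources from
            # one fixed stratum: no maternal-fetal separation is planted for
            # this outcome at any TPTE.  The effect is scaled by
            # 1/sqrt(2(1+rho(T))) so the total exposure variance a feature
            # carries - and hence its co-expression attenuation and hub
            # distance - is the same for every compound; detection is
            # outcome-side-limited, so recovery stays even across compounds
            ("gestational_age", ("fetal", "maternal"),
             max(1, int(round(_linear(design.ga_count, tpte)))),
             design.ga_loading,
             _linear(design.ga_mediator_a, tpte)
             / np.sqrt(2.0 * (1.0 + rho_of_tpte(tpte, design.rho_high,
                                                design.rho_low)))),
        ]
        for outcome, sources, count, target_loading, a in specs:
            wired = design.wired_modules(outcome)
            for j in range(count):
                idx = take_with_loading(wired[j % len(wired)], target_loading)
                if idx is None:
                    continue
                for source in sources:
                    effects.append({"feature_idx": idx,
                                    "xz": f"{compound}_{source}", "effect": a})
                    mediators.append({
                        "feature_idx": idx, "compound": compound,
                        "source": source, "outcome": outcome, "a": a,
                        "loading": float(loadings[idx]),
                        "module": int(modules[idx]), "is_hub": False,
                    })
            # designated hub mediators: rotate through the wired-module hubs
            # so no single hub accumulates exposure effects from many combos
            hub_pool = np.flatnonzero(hub_mask & np.isin(modules, wired))
            for source in sources:
                order = sorted(hub_pool, key=lambda i: (hub_usage.get(int(i), 0),
                                                        -loadings[i]))
                taken = 0
                for idx in order:
                    if taken >= design.n_hub_mediators:
                        break
                    if hub_usage.get(int(idx), 0) >= design.max_combos_per_hub:
                        continue
                    hub_usage[int(idx)] = hub_usage.get(int(idx), 0) + 1
                    effects.append({"feature_idx": int(idx),
                                    "xz": f"{compound}_{source}",
                                    "effect": design.hub_mediator_a})
                    mediators.append({
                        "feature_idx": int(idx), "compound": compound,
                        "source": source, "outcome": outcome,
                        "a": design.hub_mediator_a,
                        "loading": float(loadings[idx]),
                        "module": int(modules[idx]), "is_hub": True,
                    })
                    taken += 1

        # differential-expression-only features live in the unstructured
        # pool: they are peripheral by construction, and their large
        # exposure effects would otherwise dilute the coherence of the
        # background modules they landed in
        for source in ("fetal", "maternal"):
            pool = np.flatnonzero(available & (loadings <= design.de_loading_max)
                                  & (modules == -1))
            if not len(pool):
                break
            chosen = rng.choice(pool, size=min(design.n_de_per_combo, len(pool)),
                                replace=False)
            available[chosen] = False
            by_gene: dict = {int(idx): [int(idx)] for idx in chosen}
            # antagonistic isoforms: for a fraction of responsive genes with
            # more than one isoform, a sibling isoform responds with the
            # opposite sign, so gene-level aggregation cancels the change
            for idx in list(by_gene):
                if rng.random() >= design.antagonism_fraction:
                    continue
                gene = gene_ids[idx]
                siblings = [j for j in range(max(0, idx - 3), min(p, idx + 4))
                            if j != idx and gene_ids[j] == gene and available[j]]
                if siblings:
                    sibling = siblings[0]
                    available[sibling] = False
                    by_gene[idx].append(sibling)
            for idxs in by_gene.values():
                signs = [1.0] + [-1.0] * (len(idxs) - 1)
                for idx, sign in zip(idxs, signs):
                    lfc = sign * design.de_log2fc
                    effects.append({"feature_idx": idx,
                                    "xz": f"{compound}_{source}", "effect": lfc})
                    de_features.append({"feature": feature_ids[idx],
                                        "compound": compound, "source": source,
                                        "log2fc": lfc})

    return _Plan(feature_ids, tx2gene, modules, loadings, hub_mask,
                 baselines, sex_effects, batch_loadings, effects, mediators,
                 de_features)


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


def simulate_expression(
    design: SimulationDesign,
    exposures: ExposureDraw,
    sex: np.ndarray,
    rng: np.random.Generator,
    plan: _Plan | None = None,
) -> tuple[pd.DataFrame, _Plan]:
    """NB counts from the modular factor model with planted exposure effects."""
    if plan is None:
        plan = _plan_architecture(design, rng)
    p, n = design.n_transcripts, design.n_samples
    if design.member_loading[1] > 0:
        factors = rng.normal(0.0, 1.0, size=(design.n_modules, n))
    else:
        factors = np.zeros((design.n_modules, n))

    load = plan.loadings[:, None]
    noise = rng.normal(0.0, 1.0, size=(p, n))
    latent = load * factors[plan.modules] + np.sqrt(1.0 - load**2) * noise
    log2_mean = plan.baselines[:, None] + design.expr_scale * latent
    sex_c = sex - sex.mean()
    log2_mean += plan.sex_effects[:, None] * sex_c[None, :]
    batch = rng.normal(0.0, 1.0, size=n)
    log2_mean += plan.batch_loadings[:, None] * batch[None, :]
    plan.batch_factor = batch
    for eff in plan.effects:
        log2_mean[eff["feature_idx"]] += eff["effect"] * exposures.x_z[eff["xz"]].values

    sf = np.exp(rng.uniform(np.log(design.size_factor_range[0]),
                            np.log(design.size_factor_range[1]), size=n))
    mu = sf[None, :] * np.exp(LN2 * log2_mean)
    # NB via Poisson-gamma mixture, variance = mu + dispersion * mu^2
    shape = 1.0 / design.dispersion
    lam = rng.gamma(shape, mu / shape)
    counts = rng.poisson(lam).astype(np.int64)
    counts_df = pd.DataFrame(counts, index=pd.Index(plan.feature_ids, name="feature_id"),
                             columns=exposures.data.index)
    return counts_df, plan


# ---------------------------------------------------------------------------
# Outcomes
# ---------------------------------------------------------------------------


def simulate_outcomes(
    design: SimulationDesign,
    exposures: ExposureDraw,
    mediator_values: pd.DataFrame,
    plan: _Plan,
    sex: np.ndarray,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, list]:
    """Linear structural outcomes from planted mediators and direct effects.

    ``mediator_values`` holds VST expression (features x samples).  For each
    outcome and each of its wired modules, the standardized per-sample sum
    of standardized planted-mediator expression enters the outcome with the
    module weight; each mediator's realized outcome-side coefficient ``b``
    (per z-scored outcome unit) and true ACME ``a * b`` are recorded.
    """
    n = design.n_samples
    missing = [plan.feature_ids[m["feature_idx"]] for m in plan.mediators
               if plan.feature_ids[m["feature_idx"]] not in mediator_values.index]
    if missing:
        raise ValueError(f"mediator set references dropped features: {missing[:5]}")
    sex_c = sex - sex.mean()

    direct = {"birth_weight": np.zeros(n), "gestational_age": np.zeros(n)}
    for compound in design.compounds:
        for source, gamma in (("fetal", design.gamma_fetal),
                              ("maternal", design.gamma_maternal)):
            x = exposures.x_z[f"{compound}_{source}"].values
            direct["birth_weight"] += gamma * x
            direct["gestational_age"] += gamma * x

    # standardized mediator expression, cached per feature
    standardized: dict[str, np.ndarray] = {}
    for m in plan.mediators:
        fid = plan.feature_ids[m["feature_idx"]]
        if fid in standardized:
            continue
        values = mediator_values.loc[fid].values.astype(float)
        sd = values.std(ddof=1)
        standardized[fid] = ((values - values.mean()) / sd if sd > 0
                             else np.zeros(n))

    # per outcome x wired module: standardized sum of mediator signals
    weights = {"birth_weight": design.bw_module_weight,
               "gestational_age": design.ga_module_weight}
    mediated = {"birth_weight": np.zeros(n), "gestational_age": np.zeros(n)}
    signals: dict[tuple, np.ndarray] = {}
    for outcome in ("birth_weight", "gestational_age"):
        for module in design.wired_modules(outcome):
            # hubs are excluded from the sum: their outcome association flows
            # through the shared module factor, not their own (exposure-
            # perturbed) expression
            fids = {plan.feature_ids[m["feature_idx"]] for m in plan.mediators
                    if m["outcome"] == outcome and m["module"] == module
                    and not m["is_hub"]}
            if not fids:
                continue
            total = np.sum([standardized[f] for f in sorted(fids)], axis=0)
            sd = total.std(ddof=1)
            if sd == 0:
                continue
            signal = (total - total.mean()) / sd
            signals[(outcome, module)] = signal
            mediated[outcome] += weights[outcome] * signal

    ga_z = (direct["gestational_age"] + mediated["gestational_age"]
            + design.sex_ga_effect * sex_c
            + rng.normal(0.0, design.outcome_noise_sd, size=n))
    bw_z = (direct["birth_weight"] + mediated["birth_weight"]
            + design.bw_ga_coef * ga_z + design.sex_bw_effect * sex_c
            + rng.normal(0.0, design.outcome_noise_sd, size=n))
    outcome_z = {"birth_weight": bw_z, "gestational_age": ga_z}

    # realized outcome-side coefficients on the z-scored outcome scale
    mediator_records = []
    for m in plan.mediators:
        fid = plan.feature_ids[m["feature_idx"]]
        rec = {k: v for k, v in m.items() if k != "feature_idx"}
        rec["feature"] = fid
        signal = signals.get((m["outcome"], m["module"]))
        y_sd = outcome_z[m["outcome"]].std(ddof=1)
        if signal is None or y_sd == 0:
            rec["b"] = 0.0
        else:
            r = float(np.corrcoef(standardized[fid], signal)[0, 1])
            rec["b"] = weights[m["outcome"]] * r / y_sd
        rec["acme"] = m["a"] * rec["b"]
        mediator_records.append(rec)

    ga_weeks = np.maximum(design.ga_mean_weeks + design.ga_sd_weeks * ga_z, 30.0)
    bw_grams = np.maximum(design.bw_mean_g + design.bw_sd_g * bw_z, 800.0)
    out = pd.DataFrame(
        {"gestational_age": ga_weeks, "birth_weight": bw_grams},
        index=exposures.data.index,
    )
    return out, mediator_records


# ---------------------------------------------------------------------------
# Full study
# ---------------------------------------------------------------------------


@dataclass
class GenerationResult:
    study: ExpressionStudy
    compounds: CompoundTable
    truth: GroundTruth


def generate_study(design: SimulationDesign, outdir: str | Path | None = None) -> GenerationResult:
    """Generate a complete reproducible study; optionally write all files."""
    from .datamodel import median_of_ratios_size_factors, vst_transform

    design.validate()
    rng = np.random.default_rng(design.seed)
    exposures = simulate_exposures(design, rng)
    sex = (rng.random(design.n_samples) < design.p_male).astype(int)
    spontaneous = rng.random(design.n_samples) < design.p_spontaneous
    counts, plan = simulate_expression(design, exposures, sex, rng)
    vst = vst_transform(counts, median_of_ratios_size_factors(counts))
    outcomes, mediator_records = simulate_outcomes(
        design, exposures, vst, plan, sex, rng
    )

    sample_data = pd.DataFrame(
        {
            "fetal_sex": sex,
            "gestational_age": outcomes["gestational_age"].round(6),
            "birth_weight": outcomes["birth_weight"].round(6),
            "spontaneous_labor": spontaneous,
        },
        index=exposures.data.index,
    )
    sample_data = pd.concat([sample_data, exposures.data], axis=1)
    samples = SampleTable(sample_data, exposures.limits)
    study = ExpressionStudy(counts, plan.tx2gene, samples, level="transcript")

    compounds = CompoundTable(pd.DataFrame({
        "compound": list(design.compounds),
        "tpte": [design.tpte(c) for c in design.compounds],
        "chain_length": [design.compounds[c][1] for c in design.compounds],
    }))

    tpte_min = min(design.tpte(c) for c in design.compounds)
    truth = GroundTruth(
        modules={f: int(m) for f, m in zip(plan.feature_ids, plan.modules)},
        loadings={f: float(l) for f, l in zip(plan.feature_ids, plan.loadings)},
        hubs=[plan.feature_ids[i] for i in np.flatnonzero(plan.hub_mask)],
        mediators=mediator_records,
        de_features=plan.de_features,
        rho={c: rho_of_tpte(design.tpte(c), design.rho_high, design.rho_low)
             for c in design.compounds},
        maternal_offset={c: design.bw_maternal_offset
                         * max(design.tpte(c) - 1.0, 0.0)
                         for c in design.compounds},
        batch_factor={s: float(v) for s, v in
                      zip(exposures.data.index, plan.batch_factor)},
        batch_loadings={f: float(v) for f, v in
                        zip(plan.feature_ids, plan.batch_loadings)},
    )
    truth.validate(set(plan.feature_ids))

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_counts(study, outdir / "counts.tsv")
        write_tx2gene(study.tx2gene, outdir / "tx2gene.tsv")
        write_samples(samples, outdir / "samples.csv", outdir / "limits.csv")
        write_compounds(compounds, outdir / "compounds.csv")
        truth.to_json(outdir / "truth.json")

    return GenerationResult(study, compounds, truth)
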