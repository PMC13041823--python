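"""End-to-end orchestration: simulate -> DE -> mediation -> network -> topology -> scaling.

A run directory is driven by one YAML config and a master seed.  The master
seed deterministically spawns per-stage seeds, every stage writes its
outputs (floats at 12 significant digits) plus an entry in ``manifest.json``
recording config hash, stage seeds, completion status and output
checksums; re-running an up-to-date directory is a no-op, and a stage whose
outputs fail their checksum is re-executed.

Config YAML keys (all optional):

``seed``        master seed (int)
``design``      overrides for :class:`placnet.simulate.SimulationDesign`
``analysis``    overrides for :class:`placnet.datamodel.AnalysisConfig`
``full_grid``   run the full parameter grid (default: a reduced
                2 powers x 2 sizes x 1 split x 3 merges = 12-point grid)
``level``       "transcript" (default) or "gene"
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coexpression, diffexpr, mediation, scaling, topology
from .datamodel import (
    AnalysisConfig,
    CompoundTable,
    ExpressionStudy,
    aggregate_to_gene,
    filter_low_counts,
    impute_censored,
    read_compounds,
    read_counts,
    read_samples,
    read_tx2gene,
    vst_transform,
    zscore,
)
from .simulate import SimulationDesign, generate_study

log = logging.getLogger("placnet")

STAGES = ("simulate", "filter", "de", "mediate", "network", "topology",
          "scale", "compare")
_FLOAT_FMT = "%.12g"


# ---------------------------------------------------------------------------
# Config & manifest plumbing
# ---------------------------------------------------------------------------


def load_run_config(path: str | Path) -> dict:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    raw.setdefault("design", {})
    raw.setdefault("analysis", {})
    raw.setdefault("full_grid", False)
    raw.setdefault("level", "transcript")
    return raw


def validate_config(path: str | Path) -> dict:
    """Schema/threshold validation report for a run config."""
    errors: list[str] = []
    try:
        raw = load_run_config(path)
    except Exception as exc:
        return {"valid": False, "errors": [f"unreadable config: {exc}"]}
    known = {"seed", "design", "analysis", "full_grid", "level"}
    errors += [f"unknown key: {k}" for k in set(raw) - known]
    if "seed" not in raw:
        errors.append("missing seed")
    elif not isinstance(raw["seed"], int):
        errors.append("seed must be an integer")
    if raw.get("level") not in ("transcript", "gene"):
        errors.append(f"invalid level: {raw.get('level')}")

    design_fields = {f.name for f in dataclasses.fields(SimulationDesign)}
    errors += [f"unknown design key: {k}"
               for k in set(raw["design"]) - design_fields]
    analysis_fields = {f.name for f in dataclasses.fields(AnalysisConfig)}
    errors += [f"unknown analysis key: {k}"
               for k in set(raw["analysis"]) - analysis_fields]
    grid_product = None
    if not errors:
        try:
            analysis = _analysis_config(raw)
            errors += analysis.validate()
            grid_product = analysis.grid_size(raw["level"])
        except Exception as exc:
            errors.append(str(exc))
    return {"valid": not errors, "errors": errors, "grid_product": grid_product}


def _analysis_config(raw: dict) -> AnalysisConfig:
    payload = dict(raw.get("analysis", {}))
    for key in ("powers_transcript", "powers_gene", "min_module_sizes",
                "deep_splits", "merge_cut_heights"):
        if key in payload:
            payload[key] = tuple(payload[key])
    payload.setdefault("seed", raw.get("seed", 0))
    return AnalysisConfig(**payload)


def _config_hash(raw: dict) -> str:
    return hashlib.md5(
        json.dumps(raw, sort_keys=True, default=str).encode()
    ).hexdigest()


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    digest = hashlib.md5(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def _checksum(path: Path) -> str:
    return hashlib.md5(path.read_bytes()).hexdigest()


class _Manifest:
    def __init__(self, outdir: Path, config_hash: str, master_seed: int):
        self.path = outdir / "manifest.json"
        if self.path.exists():
            self.data = json.loads(self.path.read_text())
            if self.data.get("config_hash") != config_hash:
                log.info("config changed; invalidating previous run")
                self.data = {}
        else:
            self.data = {}
        self.data.setdefault("config_hash", config_hash)
        self.data.setdefault("master_seed", master_seed)
        self.data.setdefault("stages", {})

    def up_to_date(self, stage: str, outdir: Path) -> bool:
        entry = self.data["stages"].get(stage)
        if not entry or entry.get("status") != "complete":
            return False
        for rel, digest in entry.get("outputs", {}).items():
            path = outdir / rel
            if not path.exists() or _checksum(path) != digest:
                log.info("stage %s: checksum mismatch for %s; re-running",
                         stage, rel)
                return False
        return True

    def record(self, stage: str, outdir: Path, outputs: list, seed: int) -> None:
        self.data["stages"][stage] = {
            "status": "complete",
            "seed": seed,
            "outputs": {
                str(Path(p).relative_to(outdir)): _checksum(Path(p))
                for p in outputs
            },
        }
        self.save()

    def save(self) -> None:
        self.path.write_text(json.dumps(self.data, indent=2, sort_keys=True))


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> Path:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)
    return path


# ---------------------------------------------------------------------------
# Shared state loaded lazily between stages
# ---------------------------------------------------------------------------


class _RunState:
    """Stage inputs re-read from disk so stages are independently resumable."""

    def __init__(self, outdir: Path, raw: dict):
        self.outdir = outdir
        self.raw = raw
        self._cache: dict = {}

    def study(self) -> ExpressionStudy:
        if "study" not in self._cache:
            sim = self.outdir / "simulate"
            self._cache["study"] = ExpressionStudy(
                read_counts(sim / "counts.tsv"),
                read_tx2gene(sim / "tx2gene.tsv"),
                read_samples(sim / "samples.csv", sim / "limits.csv"),
            )
        return self._cache["study"]

    def filtered(self) -> ExpressionStudy:
        if "filtered" not in self._cache:
            counts = read_counts(self.outdir / "filter" / "filtered_counts.tsv")
            base = self.study()
            study = ExpressionStudy(counts, base.tx2gene, base.samples,
                                    level=self.raw["level"])
            self._cache["filtered"] = study
        return self._cache["filtered"]

    def compounds(self) -> CompoundTable:
        if "compounds" not in self._cache:
            self._cache["compounds"] = read_compounds(
                self.outdir / "simulate" / "compounds.csv"
            )
        return self._cache["compounds"]

    def exposure_design(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """(x_z per compound_source, covariate frame) on the study samples."""
        if "xz" not in self._cache:
            study = self.filtered()
            samples = impute_censored(study.samples)
            cols = {}
            for compound in self.compounds().compounds:
                for source in ("maternal", "fetal"):
                    conc = samples.concentration(compound, source)
                    x = np.full(len(conc), np.nan)
                    ok = conc.notna() & (conc > 0)
                    if ok.sum() >= 3:
                        x[ok.values] = zscore(np.log(conc[ok].values))
                    cols[f"{compound}_{source}"] = x
            xz = pd.DataFrame(cols, index=samples.data.index)
            cov = pd.DataFrame({
                "fetal_sex": samples.data["fetal_sex"].astype(float),
                "ga_z": zscore(samples.data["gestational_age"].values),
            }, index=samples.data.index)
            self._cache["xz"] = (xz, cov)
        return self._cache["xz"]

    def mediation_tables(self) -> dict:
        if "mediation" not in self._cache:
            tables = {}
            for path in sorted((self.outdir / "mediate").glob("mediation_*.tsv")):
                # file name: mediation_<compound>_<source>_<outcome>.tsv
                # outcomes contain one underscore (birth_weight, gestational_age)
                parts = path.stem.split("_")
                outcome = "_".join(parts[-2:])
                source = parts[-3]
                compound = "_".join(parts[1:-3])
                tables[(compound, source, outcome)] = pd.read_csv(path, sep="\t")
            self._cache["mediation"] = tables
        return self._cache["mediation"]

    def de_tables(self) -> dict:
        if "de" not in self._cache:
            tables = {}
            for path in sorted((self.outdir / "de").glob("de_*.tsv")):
                parts = path.stem.split("_")
                source = parts[-1]
                compound = "_".join(parts[1:-1])
                tables[(compound, source)] = pd.read_csv(path, sep="\t")
            self._cache["de"] = tables
        return self._cache["de"]


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def _stage_simulate(state: _RunState, seed: int) -> list:
    raw = state.raw
    design = SimulationDesign(**{**raw["design"], "seed": seed})
    outdir = state.outdir / "simulate"
    generate_study(design, outdir=outdir)
    return sorted(outdir.glob("*"))


def _stage_filter(state: _RunState, seed: int) -> list:
    study = state.study()
    filtered = filter_low_counts(study)
    if state.raw["level"] == "gene":
        filtered = aggregate_to_gene(filtered)
    outdir = state.outdir / "filter"
    outdir.mkdir(exist_ok=True)
    out = filtered.counts.copy()
    out.index.name = "feature_id"
    return [_write_tsv(out, outdir / "filtered_counts.tsv", index=True)]


def _stage_de(state: _RunState, seed: int) -> list:
    study = state.filtered()
    analysis = _analysis_config(state.raw)
    xz, cov = state.exposure_design()
    vst = vst_transform(study.counts)
    outdir = state.outdir / "de"
    outdir.mkdir(exist_ok=True)
    outputs = []
    for compound in state.compounds().compounds:
        for source in ("maternal", "fetal"):
            x = xz[f"{compound}_{source}"]
            ok = np.isfinite(x.values)
            latent = coexpression.estimate_latent_factors(
                vst.iloc[:, ok], x.values[ok], analysis.n_latent_factors
            )
            covariates = np.column_stack([
                cov["fetal_sex"].values[ok], cov["ga_z"].values[ok], latent
            ])
            sub = ExpressionStudy(study.counts.iloc[:, ok], study.tx2gene,
                                  study.samples.subset(study.counts.columns[ok]),
                                  study.level)
            table = diffexpr.fit_nb_de(sub, x.values[ok], covariates,
                                       fdr=analysis.de_fdr,
                                       lfc_threshold=analysis.de_lfc)
            outputs.append(_write_tsv(table, outdir / f"de_{compound}_{source}.tsv"))
    return outputs


def _stage_mediate(state: _RunState, seed: int) -> list:
    study = state.filtered()
    analysis = _analysis_config(state.raw)
    vst = vst_transform(study.counts)
    outdir = state.outdir / "mediate"
    outdir.mkdir(exist_ok=True)
    outputs, skip_log = [], []
    for i, compound in enumerate(state.compounds().compounds):
        for j, source in enumerate(("maternal", "fetal")):
            for outcome in ("birth_weight", "gestational_age"):
                sub_seed = stage_seed(seed, f"{compound}:{source}:{outcome}")
                try:
                    table = mediation.mediate_study(
                        study, compound, source, outcome,
                        config=analysis, vst=vst, seed=sub_seed,
                    )
                except Exception as exc:
                    skip_log.append({"compound": compound, "source": source,
                                     "outcome": outcome, "error": str(exc)})
                    continue
                path = outdir / f"mediation_{compound}_{source}_{outcome}.tsv"
                outputs.append(_write_tsv(table, path))
    log_path = outdir / "skipped.jsonl"
    log_path.write_text("\n".join(json.dumps(r) for r in skip_log))
    outputs.append(log_path)
    return outputs


def _network_grid(analysis: AnalysisConfig, level: str, full_grid: bool):
    grid = coexpression.make_grid(analysis, level)
    if full_grid:
        return grid
    powers = (analysis.powers_transcript if level == "transcript"
              else analysis.powers_gene)[:2]
    reduced = AnalysisConfig(
        powers_transcript=tuple(powers), powers_gene=tuple(powers),
        min_module_sizes=tuple(analysis.min_module_sizes[:2]),
        deep_splits=(analysis.deep_splits[0],),
        merge_cut_heights=tuple(analysis.merge_cut_heights[:3]),
    )
    return coexpression.make_grid(reduced, level)


def _network_expression(state: _RunState) -> pd.DataFrame:
    study = state.filtered()
    analysis = _analysis_config(state.raw)
    expr = coexpression.prefilter_and_normalize(study)
    xz, _ = state.exposure_design()
    design = np.nan_to_num(np.asarray(xz, dtype=float))
    return coexpression.remove_latent_factor(expr, design,
                                             analysis.n_latent_factors)


def _stage_network(state: _RunState, seed: int) -> list:
    analysis = _analysis_config(state.raw)
    expr = _network_expression(state)
    grid = _network_grid(analysis, state.raw["level"], state.raw["full_grid"])
    sweep = coexpression.run_sweep(expr, grid)
    outdir = state.outdir / "network"
    outdir.mkdir(exist_ok=True)
    outputs = []
    module_rows = []
    for it, assignment in enumerate(sweep.assignments):
        for feature in assignment.labels.index:
            module = int(assignment.labels[feature])
            kme = (float(assignment.kme.loc[feature, module])
                   if module in assignment.kme.columns else np.nan)
            module_rows.append({"iteration": it, "feature_id": feature,
                                "module": module, "kme": kme})
    outputs.append(_write_tsv(pd.DataFrame(module_rows),
                              outdir / "module_assignments.tsv"))
    outputs.append(_write_tsv(pd.DataFrame({"feature_id": sweep.consensus_hubs}),
                              outdir / "consensus_hubs.tsv"))
    manifest = {
        "n_iterations": len(sweep),
        "grid": [dataclasses.asdict(a.params) for a in sweep.assignments],
        "n_features": int(expr.shape[0]),
    }
    path = outdir / "sweep_manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    outputs.append(path)
    return outputs


def _rebuild_sweep(state: _RunState, expr: pd.DataFrame):
    """Reconstruct ModuleAssignments from the network stage outputs."""
    outdir = state.outdir / "network"
    table = pd.read_csv(outdir / "module_assignments.tsv", sep="\t")
    manifest = json.loads((outdir / "sweep_manifest.json").read_text())
    assignments = []
    E = np.asarray(expr, dtype=float)
    for it, params in enumerate(manifest["grid"]):
        part = table[table["iteration"] == it].set_index("feature_id")
        labels = part["module"].reindex(expr.index).fillna(0).astype(int)
        eigs = coexpression._eigengenes_for_labels(E, labels.values)
        modules = sorted(eigs)
        eigengenes = pd.DataFrame(
            np.vstack([eigs[m] for m in modules]) if modules else
            np.empty((0, E.shape[1])),
            index=modules, columns=expr.columns,
        )
        kme = pd.DataFrame(
            coexpression._compute_kme(E, eigengenes.values)
            if modules else np.empty((len(expr), 0)),
            index=expr.index, columns=modules,
        )
        assignments.append(coexpression.ModuleAssignment(
            pd.Series(labels.values, index=expr.index), eigengenes, kme,
            coexpression.NetworkParams(**params),
        ))
    hubs = pd.read_csv(outdir / "consensus_hubs.tsv", sep="\t")["feature_id"].tolist()
    return coexpression.SweepResult(assignments, hubs)


def _stage_topology(state: _RunState, seed: int) -> list:
    analysis = _analysis_config(state.raw)
    expr = _network_expression(state)
    sweep = _rebuild_sweep(state, expr)
    study = state.filtered()
    spont = study.samples.data.index[
        study.samples.data["spontaneous_labor"].astype(bool)
    ]
    expr_by_outcome = {
        "birth_weight": expr,
        "gestational_age": expr[[c for c in expr.columns if c in set(spont)]],
    }
    mediators = {
        key: set(tbl.loc[tbl["significant"], "feature_id"])
        for key, tbl in state.mediation_tables().items()
    }
    units, summary = topology.summarize_topology(
        sweep, mediators, expr_by_outcome, analysis
    )
    outdir = state.outdir / "topology"
    outdir.mkdir(exist_ok=True)
    return [
        _write_tsv(units, outdir / "topology_units.tsv"),
        _write_tsv(summary, outdir / "topology_summary.tsv"),
    ]


def _stage_scale(state: _RunState, seed: int) -> list:
    summary = pd.read_csv(state.outdir / "topology" / "topology_summary.tsv",
                          sep="\t")
    de_tables = state.de_tables()
    lfc_r = {}
    for compound in state.compounds().compounds:
        key_m, key_f = (compound, "maternal"), (compound, "fetal")
        if key_m in de_tables and key_f in de_tables:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                lfc_r[compound] = diffexpr.lfc_cross_correlation(
                    de_tables[key_m], de_tables[key_f]
                )
    properties = scaling.compile_compound_properties(
        summary, state.mediation_tables(), lfc_r
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scaled = scaling.tpte_scaling(properties, state.compounds())
    summary_json = scaling.summarize_architecture(scaled)
    outdir = state.outdir / "scale"
    outdir.mkdir(exist_ok=True)
    outputs = [
        _write_tsv(properties, outdir / "compound_properties.tsv"),
        _write_tsv(scaled, outdir / "tpte_scaling.tsv"),
    ]
    path = outdir / "architecture_summary.json"
    path.write_text(json.dumps(summary_json, indent=2, sort_keys=True))
    outputs.append(path)
    return outputs


def _stage_compare(state: _RunState, seed: int) -> list:
    analysis = _analysis_config(state.raw)
    hubs = pd.read_csv(state.outdir / "network" / "consensus_hubs.tsv",
                       sep="\t")["feature_id"].tolist()
    de_tables = state.de_tables()
    med_tables = state.mediation_tables()
    frames = []
    for (compound, source, outcome), med in med_tables.items():
        if outcome != "birth_weight" or (compound, source) not in de_tables:
            continue
        universe = set(med["feature_id"])
        usable_hubs = [h for h in hubs if h in universe]
        cats = scaling.categorize_features(
            de_tables[(compound, source)], med, usable_hubs
        )
        cats["compound"], cats["source"] = compound, source
        frames.append(cats)
    pooled = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["feature_id", "category", "abs_acme"])
    outdir = state.outdir / "compare"
    outdir.mkdir(exist_ok=True)
    outputs = [_write_tsv(pooled, outdir / "categories.tsv")]
    groups = {
        name: part["abs_acme"].dropna().values
        for name, part in pooled.groupby("category")
    }
    groups = {k: v for k, v in groups.items() if len(v) >= 2}
    result: dict = {"pairwise_p": {}, "anova_f": float("nan")}
    if len(groups) >= 2:
        raw = scaling.bootstrap_tukey(groups, B=analysis.bootstrap_b,
                                      n_per=analysis.bootstrap_n, seed=seed)
        result = {
            "pairwise_p": {f"{a}|{b}": p for (a, b), p in raw["pairwise_p"].items()},
            "anova_f": raw["anova_f"],
            "degenerate": raw["degenerate"],
        }
    path = outdir / "category_comparison.json"
    path.write_text(json.dumps(result, indent=2, sort_keys=True))
    outputs.append(path)
    return outputs


def analyze_study(
    study,
    compound_table,
    config: AnalysisConfig | None = None,
    grid=None,
    seed: int = 0,
    run_de: bool = False,
) -> dict:
    """In-memory end-to-end analysis of one study (no file IO).

    Runs censoring imputation, mediation for every compound x source x
    outcome, the network sweep on latent-factor-removed expression (the
    reduced grid by default), topology summaries, and the TPTE-scaling
    regressions; optionally the differential-expression tables.  Returns a
    dict with keys ``mediation``, ``de``, ``sweep``, ``expr``,
    ``topology_units``, ``topology_summary``, ``properties``, ``scaling``.
    """
    config = config or AnalysisConfig()
    samples = impute_censored(study.samples)
    vst = vst_transform(study.counts)
    sex = samples.data["fetal_sex"].values.astype(float)
    ga_z = zscore(samples.data["gestational_age"].values)

    xz = {}
    for compound in compound_table.compounds:
        for source in ("maternal", "fetal"):
            conc = samples.concentration(compound, source)
            xz[f"{compound}_{source}"] = zscore(np.log(conc.values))

    mediation_tables, de_tables = {}, {}
    for compound in compound_table.compounds:
        for source in ("maternal", "fetal"):
            if run_de:
                de_tables[(compound, source)] = diffexpr.fit_nb_de(
                    study, xz[f"{compound}_{source}"],
                    np.column_stack([sex, ga_z]),
                    fdr=config.de_fdr, lfc_threshold=config.de_lfc,
                )
            for outcome in ("birth_weight", "gestational_age"):
                sub_seed = stage_seed(seed, f"{compound}:{source}:{outcome}")
                mediation_tables[(compound, source, outcome)] = mediation.mediate_study(
                    study, compound, source, outcome,
                    config=config, vst=vst, seed=sub_seed,
                )

    expr = coexpression.prefilter_and_normalize(study)
    design = np.column_stack([xz[key] for key in sorted(xz)])
    expr = coexpression.remove_latent_factor(expr, np.nan_to_num(design),
                                             config.n_latent_factors)
    if grid is None:
        grid = _network_grid(config, study.level, full_grid=False)
    sweep = coexpression.run_sweep(expr, grid)

    spont = samples.data.index[samples.data["spontaneous_labor"].astype(bool)]
    expr_by_outcome = {
        "birth_weight": expr,
        "gestational_age": expr[[c for c in expr.columns if c in set(spont)]],
    }
    mediators = {
        key: set(tbl.loc[tbl["significant"], "feature_id"])
        for key, tbl in mediation_tables.items()
    }
    units, summary = topology.summarize_topology(
        sweep, mediators, expr_by_outcome, config
    )
    properties = scaling.compile_compound_properties(summary, mediation_tables)
    scaled = scaling.tpte_scaling(properties, compound_table)
    return {
        "mediation": mediation_tables,
        "de": de_tables,
        "sweep": sweep,
        "expr": expr,
        "topology_units": units,
        "topology_summary": summary,
        "properties": properties,
        "scaling": scaled,
    }


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "filter": _stage_filter,
    "de": _stage_de,
    "mediate": _stage_mediate,
    "network": _stage_network,
    "topology": _stage_topology,
    "scale": _stage_scale,
    "compare": _stage_compare,
}


def run_all(config_path: str | Path, outdir: str | Path,
            stages=STAGES, force: bool = False) -> Path:
    """Execute the pipeline stages in order inside ``outdir``.

    Completed stages with intact checksums are skipped; a stage failure
    halts the run with the failing stage named, preserving prior outputs.
    """
    report = validate_config(config_path)
    if not report["valid"]:
        raise ValueError(f"invalid config: {report['errors']}")
    raw = load_run_config(config_path)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(outdir, _config_hash(raw), raw["seed"])
    state = _RunState(outdir, raw)
    for stage in STAGES:
        if stage not in stages:
            continue
        if not force and manifest.up_to_date(stage, outdir):
            log.info("stage %s: up to date", stage)
            continue
        seed = stage_seed(raw["seed"], stage)
        log.info("stage %s: running (seed %d)", stage, seed)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                outputs = _STAGE_FUNCS[stage](state, seed)
        except Exception as exc:
            raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc
        manifest.record(stage, outdir, outputs, seed)
    return outdir
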