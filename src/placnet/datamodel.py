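"""Core data types, file IO, and exposure/feature preprocessing.

The study container couples a feature-by-sample count matrix with a
transcript-to-gene map and a sample table carrying perinatal covariates
and per-compound maternal/cord-blood PFAS concentrations.  Concentration
measurements may be left-censored: values below the limit of quantification
(LOQ) or the limit of detection (LOD) are flagged and later imputed at half
the respective limit, the standard convention for exposure biomonitoring
data.  Transplacental transfer efficiency (TPTE) for a compound is the mean
cord:maternal concentration ratio over samples with paired measurements.

File formats
------------
counts      TSV, first column ``feature_id``, remaining columns = sample IDs.
tx2gene     two-column TSV ``transcript_id`` / ``gene_id``.
samples     CSV with one row per sample: ``sample_id``, ``fetal_sex`` (0/1),
            ``gestational_age`` (weeks), ``birth_weight`` (grams),
            ``spontaneous_labor`` (0/1), then per compound and source a
            concentration column ``conc_<compound>_<source>`` and a flag
            column ``flag_<compound>_<source>`` (``quantified``,
            ``below_LOQ``, ``below_LOD``).  Missing measurements are empty
            fields, never zero.
limits      CSV with columns ``compound``, ``source``, ``lod``, ``loq``.
compounds   CSV with columns ``compound``, ``tpte`` and optional
            ``chain_length``.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

SOURCES = ("maternal", "fetal")
OUTCOMES = ("birth_weight", "gestational_age")
LEVELS = ("transcript", "gene")

FLAG_QUANTIFIED = "quantified"
FLAG_BELOW_LOQ = "below_LOQ"
FLAG_BELOW_LOD = "below_LOD"
CENSOR_FLAGS = (FLAG_QUANTIFIED, FLAG_BELOW_LOQ, FLAG_BELOW_LOD)

COVARIATE_COLUMNS = (
    "fetal_sex",
    "gestational_age",
    "birth_weight",
    "spontaneous_labor",
)


class DataModelError(ValueError):
    """Raised when a container violates its invariants."""


def conc_column(compound: str, source: str) -> str:
    return f"conc_{compound}_{source}"


def flag_column(compound: str, source: str) -> str:
    return f"flag_{compound}_{source}"


# ---------------------------------------------------------------------------
# Sample table
# ---------------------------------------------------------------------------


@dataclass
class SampleTable:
    """Per-sample covariates, exposures and censoring metadata.

    ``data`` is indexed by sample ID and holds covariate columns plus the
    wide ``conc_*``/``flag_*`` exposure columns.  ``limits`` is indexed by
    ``(compound, source)`` with columns ``lod`` and ``loq``.
    """

    data: pd.DataFrame
    limits: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = self.data.copy()
        self.data.index = self.data.index.astype(str)
        if self.data.index.has_duplicates:
            raise DataModelError("duplicate sample IDs")
        limits = self.limits.copy()
        if not isinstance(limits.index, pd.MultiIndex):
            limits = limits.set_index(["compound", "source"])
        self.limits = limits
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        ga = self.data["gestational_age"]
        bw = self.data["birth_weight"]
        if (ga <= 0).any():
            raise DataModelError("gestational_age must be positive")
        if (bw <= 0).any():
            raise DataModelError("birth_weight must be positive")
        for compound, source in self.measured_pairs():
            flags = self.data[flag_column(compound, source)]
            bad = flags.dropna()[~flags.dropna().isin(CENSOR_FLAGS)]
            if len(bad):
                raise DataModelError(
                    f"invalid censor flags for {compound}/{source}: "
                    f"{sorted(bad.unique())}"
                )
            conc = self.data[conc_column(compound, source)]
            if (conc.dropna() < 0).any():
                raise DataModelError(f"negative concentration for {compound}/{source}")

    # -- accessors ----------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def compounds(self) -> list[str]:
        seen: list[str] = []
        for col in self.data.columns:
            if col.startswith("conc_"):
                compound = col[len("conc_"):].rsplit("_", 1)[0]
                if compound not in seen:
                    seen.append(compound)
        return seen

    def measured_pairs(self) -> list[tuple[str, str]]:
        pairs = []
        for col in self.data.columns:
            if col.startswith("conc_"):
                stem = col[len("conc_"):]
                compound, source = stem.rsplit("_", 1)
                pairs.append((compound, source))
        return pairs

    def concentration(self, compound: str, source: str) -> pd.Series:
        return self.data[conc_column(compound, source)]

    def flags(self, compound: str, source: str) -> pd.Series:
        return self.data[flag_column(compound, source)]

    def limit(self, compound: str, source: str, kind: str) -> float:
        return float(self.limits.loc[(compound, source), kind])

    def subset(self, sample_ids: Sequence[str]) -> "SampleTable":
        return SampleTable(self.data.loc[list(sample_ids)], self.limits)

    def copy(self) -> "SampleTable":
        return SampleTable(self.data.copy(), self.limits.copy())


# ---------------------------------------------------------------------------
# Expression study
# ---------------------------------------------------------------------------


@dataclass
class ExpressionStudy:
    """Feature-by-sample count matrix with feature map and sample metadata."""

    counts: pd.DataFrame
    tx2gene: pd.DataFrame
    samples: SampleTable
    level: str = "transcript"

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise DataModelError(f"level must be one of {LEVELS}")
        self.counts = self.counts.copy()
        self.counts.index = self.counts.index.astype(str)
        self.counts.columns = self.counts.columns.astype(str)
        tx2gene = self.tx2gene.copy()
        tx2gene.columns = ["transcript_id", "gene_id"]
        self.tx2gene = tx2gene.astype(str)
        self.validate()

    def validate(self) -> None:
        if self.counts.index.has_duplicates:
            raise DataModelError("duplicate feature IDs")
        if (np.asarray(self.counts) < 0).any():
            raise DataModelError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.samples.sample_ids)
        if missing:
            raise DataModelError(f"count columns without sample records: {sorted(missing)}")
        if self.level == "gene":
            known = set(self.tx2gene["gene_id"])
            orphans = set(self.counts.index) - known
            if orphans:
                raise DataModelError(
                    f"gene-level features missing from tx2gene: {sorted(orphans)[:5]}"
                )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionStudy":
        ids = [s for s in sample_ids if s in self.counts.columns]
        return ExpressionStudy(
            self.counts[ids], self.tx2gene, self.samples.subset(ids), self.level
        )


@dataclass
class CompoundTable:
    """Compound metadata: TPTE (cord:maternal ratio) and chain length."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        data = self.data.copy()
        if data.index.name != "compound":
            data = data.set_index("compound")
        data.index = data.index.astype(str)
        if data.index.has_duplicates:
            raise DataModelError("compound names must be unique")
        if (data["tpte"] <= 0).any():
            raise DataModelError("tpte must be positive")
        self.data = data

    @property
    def compounds(self) -> list[str]:
        return list(self.data.index)

    def tpte(self, compound: str) -> float:
        return float(self.data.loc[compound, "tpte"])


# ---------------------------------------------------------------------------
# Analysis configuration
# ---------------------------------------------------------------------------


@dataclass
class AnalysisConfig:
    """Thresholds, grids and simulation settings for the full pipeline.

    Defaults follow the analysis conventions used throughout the package:
    differential expression calls at BH FDR < 0.10 with |log2FC| > 1,
    mediation calls at BH FDR < 0.05 with 95% CI excluding zero, network
    edges thresholded at signed adjacency 0.10, and soft powers accepted at
    scale-free fit R^2 >= 0.85.
    """

    seed: int = 0
    de_fdr: float = 0.10
    de_lfc: float = 1.0
    mediation_fdr: float = 0.05
    adjacency_floor: float = 0.10
    scale_free_target: float = 0.85
    n_sims: int = 1000
    bootstrap_b: int = 1000
    bootstrap_n: int = 100
    kde_grid_points: int = 512
    min_mediators_per_unit: int = 3
    powers_transcript: tuple = (3, 4, 5)
    powers_gene: tuple = (14, 15, 16)
    min_module_sizes: tuple = (30, 50, 75, 100)
    deep_splits: tuple = (2, 3, 4)
    merge_cut_heights: tuple = (0.15, 0.20, 0.25, 0.30)
    n_latent_factors: int = 1

    def validate(self) -> list[str]:
        errors = []
        for name, lo, hi in [
            ("de_fdr", 0, 1),
            ("mediation_fdr", 0, 1),
            ("adjacency_floor", 0, 1),
            ("scale_free_target", 0, 1),
        ]:
            v = getattr(self, name)
            if not (lo < v < hi):
                errors.append(f"{name}={v} outside ({lo}, {hi})")
        if self.de_lfc < 0:
            errors.append("de_lfc must be non-negative")
        for name in ("n_sims", "bootstrap_b", "bootstrap_n", "kde_grid_points"):
            if getattr(self, name) < 1:
                errors.append(f"{name} must be >= 1")
        for name in (
            "powers_transcript",
            "powers_gene",
            "min_module_sizes",
            "deep_splits",
            "merge_cut_heights",
        ):
            if not len(getattr(self, name)):
                errors.append(f"{name} grid is empty")
        return errors

    def grid_size(self, level: str = "transcript") -> int:
        powers = self.powers_transcript if level == "transcript" else self.powers_gene
        return (
            len(powers)
            * len(self.min_module_sizes)
            * len(self.deep_splits)
            * len(self.merge_cut_heights)
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise DataModelError(f"unknown config keys: {sorted(unknown)}")
        for key in ("powers_transcript", "powers_gene", "min_module_sizes",
                    "deep_splits", "merge_cut_heights"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        for key, value in payload.items():
            if isinstance(value, tuple):
                payload[key] = list(value)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Exposure preprocessing
# ---------------------------------------------------------------------------


def impute_censored(samples: SampleTable) -> SampleTable:
    """Replace left-censored concentrations by half their detection limit.

    Values flagged ``below_LOQ`` become LOQ/2 and values flagged
    ``below_LOD`` become LOD/2; quantified values and censor flags are
    left untouched.  A censored entry whose limit is missing or non-finite
    is a hard error naming the offending sample and compound.
    """
    out = samples.copy()
    for compound, source in out.measured_pairs():
        flags = out.flags(compound, source)
        col = conc_column(compound, source)
        for flag_value, kind in ((FLAG_BELOW_LOQ, "loq"), (FLAG_BELOW_LOD, "lod")):
            mask = flags == flag_value
            if not mask.any():
                continue
            try:
                limit = out.limit(compound, source, kind)
            except KeyError:
                limit = np.nan
            if not np.isfinite(limit):
                offender = out.data.index[mask][0]
                raise DataModelError(
                    f"censored entry without finite {kind.upper()} "
                    f"(sample {offender}, compound {compound}, source {source})"
                )
            out.data.loc[mask, col] = limit / 2.0
    return out


def compute_tpte(samples: SampleTable, compound: str) -> float:
    """Mean cord:maternal concentration ratio over paired samples.

    Samples lacking either measurement are excluded; samples with zero
    maternal concentration are excluded with a warning (the ratio is
    undefined).  Raises if no valid pair remains.
    """
    maternal = samples.concentration(compound, "maternal")
    fetal = samples.concentration(compound, "fetal")
    paired = maternal.notna() & fetal.notna()
    zero_m = paired & (maternal == 0)
    if zero_m.any():
        warnings.warn(
            f"{compound}: excluding {int(zero_m.sum())} sample(s) with zero "
            "maternal concentration from the TPTE ratio",
            stacklevel=2,
        )
        paired &= maternal != 0
    if not paired.any():
        raise DataModelError(f"{compound}: no valid maternal/fetal pairs for TPTE")
    ratios = fetal[paired] / maternal[paired]
    return float(ratios.mean())


def zscore(values: Iterable[float]) -> np.ndarray:
    """Standardize to mean 0 and sample SD 1 (n-1 denominator)."""
    x = np.asarray(list(values) if not isinstance(values, np.ndarray) else values,
                   dtype=float)
    finite = np.isfinite(x)
    if finite.sum() < 2:
        raise DataModelError("zscore requires at least 2 finite values")
    mean = x[finite].mean()
    sd = x[finite].std(ddof=1)
    if sd == 0:
        raise DataModelError("zscore undefined for zero-variance input")
    out = np.full_like(x, np.nan, dtype=float)
    out[finite] = (x[finite] - mean) / sd
    return out


# ---------------------------------------------------------------------------
# Feature-level transforms
# ---------------------------------------------------------------------------


def aggregate_to_gene(study: ExpressionStudy) -> ExpressionStudy:
    """Sum member transcript counts per gene, preserving sample order."""
    if study.level != "transcript":
        raise DataModelError("aggregate_to_gene requires a transcript-level study")
    mapping = study.tx2gene.set_index("transcript_id")["gene_id"]
    missing = [f for f in study.feature_ids if f not in mapping.index]
    if missing:
        raise DataModelError(
            f"transcripts absent from tx2gene: {missing[:10]}"
            + ("..." if len(missing) > 10 else "")
        )
    genes = mapping.loc[study.counts.index]
    gene_counts = study.counts.groupby(genes.values, sort=False).sum()
    gene_counts.index.name = "feature_id"
    return ExpressionStudy(gene_counts, study.tx2gene, study.samples, level="gene")


def filter_low_counts(
    study: ExpressionStudy, min_count: int = 5, min_samples: int = 3
) -> ExpressionStudy:
    """Keep features with >= ``min_count`` reads in >= ``min_samples`` samples."""
    keep = (study.counts >= min_count).sum(axis=1) >= min_samples
    if not keep.any():
        raise DataModelError("count filter removed every feature")
    return ExpressionStudy(
        study.counts.loc[keep], study.tx2gene, study.samples, study.level
    )


def median_of_ratios_size_factors(counts: pd.DataFrame) -> np.ndarray:
    """Median-of-ratios library size factors.

    Per sample, the median across features of count / geometric-mean count,
    taken over features with nonzero counts in every sample.
    """
    mat = np.asarray(counts, dtype=float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise DataModelError("no feature has nonzero counts in all samples")
    log_ref = np.log(mat[positive]).mean(axis=1, keepdims=True)
    sf = np.exp(np.median(np.log(mat[positive]) - log_ref, axis=0))
    return sf


def vst_transform(counts: pd.DataFrame, size_factors: np.ndarray | None = None) -> pd.DataFrame:
    """Variance-stabilizing stand-in: log2(normalized count + 1)."""
    if size_factors is None:
        size_factors = median_of_ratios_size_factors(counts)
    normalized = np.asarray(counts, dtype=float) / np.asarray(size_factors)[None, :]
    return pd.DataFrame(np.log2(normalized + 1.0), index=counts.index,
                        columns=counts.columns)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def write_counts(study: ExpressionStudy, path: str | Path) -> None:
    out = study.counts.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t")


def read_counts(path: str | Path) -> pd.DataFrame:
    counts = pd.read_csv(path, sep="\t", index_col=0)
    counts.index = counts.index.astype(str)
    return counts


def write_tx2gene(tx2gene: pd.DataFrame, path: str | Path) -> None:
    tx2gene.to_csv(path, sep="\t", index=False)


def read_tx2gene(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = ["transcript_id", "gene_id"]
    return df


def write_samples(samples: SampleTable, path: str | Path,
                  limits_path: str | Path) -> None:
    out = samples.data.copy()
    out.index.name = "sample_id"
    out.to_csv(path, float_format="%.12g")
    limits = samples.limits.reset_index()
    limits.to_csv(limits_path, index=False, float_format="%.12g")


def read_samples(path: str | Path, limits_path: str | Path) -> SampleTable:
    data = pd.read_csv(path, index_col="sample_id")
    data.index = data.index.astype(str)
    if "spontaneous_labor" in data:
        data["spontaneous_labor"] = data["spontaneous_labor"].astype(bool)
    limits = pd.read_csv(limits_path)
    return SampleTable(data, limits)


def write_compounds(compounds: CompoundTable, path: str | Path) -> None:
    compounds.data.to_csv(path, float_format="%.12g")


def read_compounds(path: str | Path) -> CompoundTable:
    return CompoundTable(pd.read_csv(path))


def write_manifest(path: str | Path, payload: Mapping) -> None:
    with open(path, "w") as fh:
        json.dump(dict(payload), fh, indent=2, sort_keys=True)


def read_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
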