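"""Tabular data model, CSV/JSON round-trips and pipeline orchestration.

The canonical exchange format is a long (tidy) CSV with header
``genotype,concentration,replicate,trait,value`` — UTF-8, "." decimal
separator, concentrations in mM/L NaCl, one row per replicate measurement.
Germination may instead enter as count pairs
(``genotype,concentration,replicate,germinated_7das,total_sown``), which are
converted to GR percentage rows on read; counts are authoritative when both
forms are supplied.  A wide per-trait-column importer is provided as a
convenience.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import dose_finder, indices, regression_model, tolerance_eval, trait_selector
from .errors import IntegrityError, SchemaError, ValidationError
from .traits import ALL_TRAITS, MODEL_TRAITS, normalize_traits

logger = logging.getLogger(__name__)

MEASUREMENT_COLUMNS = ("genotype", "concentration", "replicate", "trait", "value")
GERMINATION_COLUMNS = ("genotype", "concentration", "replicate",
                       "germinated_7das", "total_sown")
KEY_COLUMNS = ("genotype", "concentration", "replicate", "trait")


@dataclass
class PipelineConfig:
    """User-tunable knobs for a full screening run."""

    tested_concentrations: tuple[float, ...] = (0.0, 75.0, 150.0, 225.0, 300.0)
    traits_for_mean_mfv: tuple[str, ...] = ALL_TRAITS
    traits_for_model: tuple[str, ...] = MODEL_TRAITS
    cluster_count: int = 5
    replicate_aggregator: str = "mean"
    random_seed: int = 0
    target_sii: float = 0.5
    sti_mode: str = "mean_ratio"
    undefined_policy: str = "drop"
    degenerate_trait: str = "fail"
    include_control_point: bool = True
    dose_fit_mode: str = "pooled_mean"
    ci_level: float = 0.99

    def __post_init__(self) -> None:
        self.tested_concentrations = tuple(float(c) for c in self.tested_concentrations)
        self.traits_for_mean_mfv = normalize_traits(self.traits_for_mean_mfv)
        self.traits_for_model = normalize_traits(self.traits_for_model)
        if self.cluster_count < 2:
            raise ValidationError("cluster_count must be >= 2")
        if not (0 < self.target_sii < 1):
            raise ValidationError("target_sii must lie in (0, 1)")
        if self.replicate_aggregator not in ("mean", "median"):
            raise ValidationError("replicate_aggregator must be 'mean' or 'median'")

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True,
                           default_flow_style=None)


def validate_trait_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the long-table invariants; returns the table unchanged.

    Raises :class:`SchemaError` for missing columns, :class:`IntegrityError`
    for duplicate (genotype, concentration, replicate, trait) keys and
    :class:`ValidationError` for negative/non-finite values, unknown traits
    or stressed keys without controls.
    """
    missing = [c for c in MEASUREMENT_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")

    bad_traits = set(table["trait"].unique()) - set(ALL_TRAITS)
    if bad_traits:
        raise ValidationError(f"unknown trait codes: {sorted(bad_traits)}")

    values = pd.to_numeric(table["value"], errors="coerce")
    bad = table[values.isna() | (values < 0)]
    if not bad.empty:
        raise ValidationError(
            f"{len(bad)} rows with negative or non-numeric values, first: "
            f"{bad.iloc[0][list(MEASUREMENT_COLUMNS)].to_dict()}")
    if (pd.to_numeric(table["concentration"], errors="coerce") < 0).any():
        raise ValidationError("negative concentrations present")

    dupes = table[table.duplicated(list(KEY_COLUMNS), keep=False)]
    if not dupes.empty:
        keys = dupes[list(KEY_COLUMNS)].drop_duplicates().apply(tuple, axis=1)
        raise IntegrityError(f"duplicate measurement keys: {list(keys)[:5]}"
                             f"{'...' if len(keys) > 5 else ''}")

    stressed = table[table["concentration"] > 0][["genotype", "trait"]].drop_duplicates()
    controls = set(map(tuple, table[table["concentration"] == 0]
                       [["genotype", "trait"]].drop_duplicates().to_numpy()))
    orphans = [tuple(r) for r in stressed.to_numpy() if tuple(r) not in controls]
    if orphans:
        raise ValidationError(
            f"stressed (genotype, trait) keys without 0 mM/L controls: "
            f"{sorted(orphans)[:5]}{'...' if len(orphans) > 5 else ''}")
    return table


def read_trait_table(path, schema_mode: str = "measurements") -> pd.DataFrame:
    """Read and validate a long-format CSV.

    ``schema_mode="germination_counts"`` expects the count schema and
    converts each row to a GR percentage measurement.
    """
    if schema_mode not in ("measurements", "germination_counts"):
        raise ValueError(f"unknown schema_mode {schema_mode!r}")
    df = pd.read_csv(path)
    if schema_mode == "germination_counts":
        missing = [c for c in GERMINATION_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required columns: {missing}")
        df = df.copy()
        df["value"] = [
            indices.germination_rate(int(gt), int(t))
            for gt, t in zip(df["germinated_7das"], df["total_sown"])]
        df["trait"] = "GR"
        df = df[list(MEASUREMENT_COLUMNS)]
    df = validate_trait_table(df)
    logger.info("read %d rows from %s (%d genotypes)", len(df), path,
                df["genotype"].nunique())
    return df


def read_wide_table(path, trait_columns=None) -> pd.DataFrame:
    """Convenience importer for wide CSVs with one column per trait.

    Expects ``genotype,concentration,replicate`` plus trait-named columns;
    melts to the canonical long layout.
    """
    df = pd.read_csv(path)
    id_cols = ["genotype", "concentration", "replicate"]
    missing = [c for c in id_cols if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    traits = list(trait_columns) if trait_columns else \
        [c for c in df.columns if c in ALL_TRAITS]
    if not traits:
        raise SchemaError("no trait columns found in wide table")
    long = df.melt(id_vars=id_cols, value_vars=traits,
                   var_name="trait", value_name="value")
    return validate_trait_table(long)


def write_table(table: pd.DataFrame, path) -> None:
    """Write any tabular product as CSV (lossless round-trip)."""
    path = Path(path)
    if not path.parent.is_dir():
        raise IOError(f"directory does not exist: {path.parent}")
    table.to_csv(path, index=False)


def write_report(report, path) -> None:
    """Write a pipeline product: DataFrames as CSV, models/configs as JSON/YAML."""
    path = Path(path)
    if not path.parent.is_dir():
        raise IOError(f"directory does not exist: {path.parent}")
    if isinstance(report, pd.DataFrame):
        report.to_csv(path, index=False)
    elif isinstance(report, regression_model.SaltToleranceModel):
        path.write_text(report.to_json(), encoding="utf-8")
    elif isinstance(report, tolerance_eval.ToleranceReport):
        report.table.to_csv(path, index=False)
    elif isinstance(report, PipelineConfig):
        report.to_yaml(path)
    elif isinstance(report, dose_finder.OptimumDose):
        path.write_text(json.dumps(dataclasses.asdict(report), indent=2),
                        encoding="utf-8")
    elif isinstance(report, dict):
        path.write_text(json.dumps(report, indent=2, default=str), encoding="utf-8")
    else:
        raise TypeError(f"cannot serialise object of type {type(report).__name__}")


def read_model(path) -> regression_model.SaltToleranceModel:
    return regression_model.SaltToleranceModel.from_json(
        Path(path).read_text(encoding="utf-8"))


@dataclass
class PipelineResult:
    """All products of a full screening run."""

    config: PipelineConfig
    index_table: pd.DataFrame
    screening_concentration: float
    dose_fits: list = field(default_factory=list)
    optimum: dose_finder.OptimumDose | None = None
    mfv_table: tolerance_eval.MFVTable | None = None
    mean_mfv: pd.Series | None = None
    tolerance_report: tolerance_eval.ToleranceReport | None = None
    model: regression_model.SaltToleranceModel | None = None
    verification: regression_model.VerificationResult | None = None
    reliability: trait_selector.TraitReliabilityReport | None = None


def run_pipeline(trait_table: pd.DataFrame, config: PipelineConfig | None = None) -> PipelineResult:
    """Run every stage: indices, (optional) dose-finding, grading, model, selection.

    If the table holds more than one stress concentration the optimum
    screening dose is determined first and downstream stages use the index
    rows at that dose; with a single stress concentration it is used
    directly.  Deterministic given (table, config), and stage outputs equal
    calling the stage functions individually.
    """
    config = config or PipelineConfig()
    stage = "validation"
    try:
        validate_trait_table(trait_table)

        stage = "indices"
        index_table = indices.build_index_table(
            trait_table, config.replicate_aggregator, config.sti_mode)

        stress_concs = sorted(index_table["concentration"].unique())
        dose_fits: list = []
        optimum = None
        if len(stress_concs) > 1:
            stage = "dose_finder"
            dose_fits, avg_fit, optimum = dose_finder.find_optimum_dose(
                index_table, config.tested_concentrations, config.target_sii,
                config.include_control_point, config.dose_fit_mode,
                config.undefined_policy)
            dose_fits = dose_fits + [avg_fit]
            screening_c = optimum.chosen_concentration
            if screening_c not in stress_concs:
                # snapped dose not measured: fall back to nearest measured dose
                screening_c = min(stress_concs,
                                  key=lambda c: (abs(c - screening_c), -c))
        else:
            screening_c = stress_concs[0]

        stage = "tolerance_eval"
        at_dose = index_table[index_table["concentration"] == screening_c]
        mfv_table, scores, report = tolerance_eval.evaluate_tolerance(
            at_dose, config.traits_for_mean_mfv, config.cluster_count,
            config.undefined_policy, config.degenerate_trait)

        stage = "regression_model"
        sti_wide = trait_selector.sti_pivot(
            indices.apply_undefined_policy(at_dose, config.undefined_policy))
        model = regression_model.fit_model(
            sti_wide, scores, config.traits_for_model, config.ci_level)
        verification = regression_model.verify_model(model, sti_wide, scores)

        stage = "trait_selector"
        reliability = trait_selector.build_reliability_report(
            sti_wide, scores, model)
    except Exception as exc:
        try:
            wrapped = type(exc)(f"[stage: {stage}] {exc}")
        except Exception:  # exception type with a non-str constructor
            raise exc
        raise wrapped from exc

    logger.info("pipeline complete at %.4g mM/L (config %s)", screening_c,
                config.digest())
    return PipelineResult(
        config=config, index_table=index_table, screening_concentration=screening_c,
        dose_fits=dose_fits, optimum=optimum, mfv_table=mfv_table,
        mean_mfv=scores, tolerance_report=report, model=model,
        verification=verification, reliability=reliability)
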