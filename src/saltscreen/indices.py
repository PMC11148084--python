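"""Stress indices: germination rate, salt tolerance index and salt injury index.

For every genotype g and trait t measured at a stress concentration c and at
the 0 mM/L control, the salt tolerance index is the ratio

    STI(g, t, c) = mean value under stress / mean value under control

and the salt injury index is its complement, SII = 1 - STI.  STI = 1 means the
trait is unaffected by salt; STI > 1 (stimulation at mild stress) is legal and
is never clamped, so SII may be negative.

Replicates are aggregated to a per-(genotype, concentration, trait) mean
first and the ratio of means is taken ("mean_ratio").  A per-replicate-ratio
mode ("ratio_mean", the mean over replicate pairs of stress/control) exists
for sensitivity analysis; the two agree for balanced, noise-free designs.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import MissingControlError, UndefinedIndexError, ValidationError

logger = logging.getLogger(__name__)

#: columns of an index table
INDEX_COLUMNS = ("genotype", "concentration", "trait", "sti", "sii",
                 "control_mean", "stress_mean", "undefined")


def germination_rate(germinated_7das: int, total_sown: int) -> float:
    """Germination rate G = Gt / T x 100, in percent.

    Parameters
    ----------
    germinated_7das
        Number of seeds germinated 7 days after sowing (radicle >= 2 mm).
    total_sown
        Total seeds sown in the dish.
    """
    if total_sown <= 0:
        raise ValidationError(f"total_sown must be positive, got {total_sown}")
    if germinated_7das < 0 or germinated_7das > total_sown:
        raise ValidationError(
            f"germinated count {germinated_7das} outside [0, {total_sown}]")
    return germinated_7das / total_sown * 100.0


def aggregate_replicates(table: pd.DataFrame, aggregator: str = "mean") -> pd.DataFrame:
    """Collapse replicates to one value per (genotype, concentration, trait).

    ``aggregator`` is ``"mean"`` (default) or ``"median"``.
    """
    if aggregator not in ("mean", "median"):
        raise ValueError(f"aggregator must be 'mean' or 'median', got {aggregator!r}")
    if table.empty:
        raise ValidationError("cannot aggregate an empty trait table")
    grouped = (table.groupby(["genotype", "concentration", "trait"], sort=True)["value"]
               .agg(aggregator)
               .reset_index())
    return grouped


def compute_sti(stress_mean: float, control_mean: float) -> float:
    """Salt tolerance index: trait value under stress over value under control.

    A zero control mean makes the ratio undefined; callers must handle that
    case explicitly (see :func:`build_index_table`), so here it raises.
    """
    if control_mean <= 0:
        raise ValidationError(
            f"control mean must be positive for STI, got {control_mean}")
    if stress_mean < 0:
        raise ValidationError(f"stress mean must be >= 0, got {stress_mean}")
    return stress_mean / control_mean


def compute_sii(sti: float) -> float:
    """Salt injury index, the complement 1 - STI.

    Negative when STI > 1 (trait stimulated by stress); retained untouched.
    """
    if not np.isfinite(sti):
        raise ValidationError(f"STI must be finite, got {sti}")
    return 1.0 - sti


def build_index_table(table: pd.DataFrame, aggregator: str = "mean",
                      sti_mode: str = "mean_ratio") -> pd.DataFrame:
    """Compute STI/SII for every (genotype, stress concentration, trait).

    Parameters
    ----------
    table
        Long-format trait table with columns
        (genotype, concentration, replicate, trait, value); must contain
        control (0 mM/L) rows for every stressed (genotype, trait).
    aggregator
        Replicate aggregation, ``"mean"`` or ``"median"``.
    sti_mode
        ``"mean_ratio"`` (aggregate replicates, then ratio; default) or
        ``"ratio_mean"`` (mean over replicate-wise stress/control ratios,
        matching replicates by index).

    Returns
    -------
    DataFrame with :data:`INDEX_COLUMNS`.  Control rows are consumed, not
    emitted.  Rows whose control mean is zero carry ``undefined=True`` and
    NaN indices; downstream stages drop or fail on them according to their
    ``undefined_policy``.
    """
    if sti_mode not in ("mean_ratio", "ratio_mean"):
        raise ValueError(f"unknown sti_mode {sti_mode!r}")

    agg = aggregate_replicates(table, aggregator)
    control = agg[agg["concentration"] == 0].set_index(["genotype", "trait"])["value"]
    stress = agg[agg["concentration"] > 0]
    if stress.empty:
        raise ValidationError("no stress (concentration > 0) rows in table")

    missing = [
        (g, t) for g, t in stress.set_index(["genotype", "trait"]).index.unique()
        if (g, t) not in control.index
    ]
    if missing:
        raise MissingControlError(
            f"no control rows for {len(missing)} (genotype, trait) keys: "
            f"{sorted(missing)[:5]}{'...' if len(missing) > 5 else ''}")

    rows = []
    for (g, c, t), stress_mean in stress.set_index(
            ["genotype", "concentration", "trait"])["value"].items():
        control_mean = control.loc[(g, t)]
        if control_mean <= 0:
            rows.append((g, c, t, np.nan, np.nan, control_mean, stress_mean, True))
            continue
        if sti_mode == "mean_ratio":
            sti = stress_mean / control_mean
        else:
            sti = _ratio_mean_sti(table, g, c, t, aggregator)
        rows.append((g, c, t, sti, 1.0 - sti, control_mean, stress_mean, False))

    out = pd.DataFrame(rows, columns=list(INDEX_COLUMNS))
    n_undef = int(out["undefined"].sum())
    if n_undef:
        logger.warning("index table: %d rows undefined (zero control mean)", n_undef)
    logger.info("index table: %d rows (%d genotypes, %d concentrations, %d traits)",
                len(out), out["genotype"].nunique(),
                out["concentration"].nunique(), out["trait"].nunique())
    return out


def _ratio_mean_sti(table: pd.DataFrame, genotype: str, concentration: float,
                    trait: str, aggregator: str) -> float:
    sub = table[(table["genotype"] == genotype) & (table["trait"] == trait)]
    ctrl = sub[sub["concentration"] == 0].set_index("replicate")["value"]
    strs = sub[sub["concentration"] == concentration].set_index("replicate")["value"]
    common = ctrl.index.intersection(strs.index)
    if common.empty:
        raise ValidationError(
            f"ratio_mean mode needs matching replicate ids for {genotype}/{trait}")
    ratios = strs.loc[common] / ctrl.loc[common]
    return float(ratios.median() if aggregator == "median" else ratios.mean())


def apply_undefined_policy(index_table: pd.DataFrame, policy: str = "drop") -> pd.DataFrame:
    """Resolve undefined (zero-control) rows: ``"drop"`` them or ``"fail"``."""
    if policy not in ("drop", "fail"):
        raise ValueError(f"undefined_policy must be 'drop' or 'fail', got {policy!r}")
    undef = index_table["undefined"]
    if undef.any():
        keys = index_table.loc[undef, ["genotype", "trait"]].apply(tuple, axis=1).tolist()
        if policy == "fail":
            raise UndefinedIndexError(f"undefined STI rows for keys: {keys}")
        logger.warning("dropping %d undefined index rows: %s", len(keys), keys)
        return index_table[~undef].reset_index(drop=True)
    return index_table
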