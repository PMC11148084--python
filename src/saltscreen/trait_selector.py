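"""Identify the single most reliable screening trait.

Two views of trait association at the screening concentration:

* a Pearson correlation matrix among the trait STIs across genotypes
  (with two-sided p < 0.01 significance flags), and
* a simple linear regression of the composite tolerance score (mean MFV)
  on each trait's STI.

Traits are ranked by the R-squared of that per-trait fit; the top trait is
selected as the screening trait, ties broken by the larger standardized
coefficient in the multiple-regression model, then alphabetically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .regression_model import SaltToleranceModel
from .traits import normalize_traits

logger = logging.getLogger(__name__)


def sti_pivot(index_table: pd.DataFrame, traits=None) -> pd.DataFrame:
    """Genotype x trait STI matrix from an index table at one concentration."""
    concs = index_table["concentration"].unique()
    if len(concs) != 1:
        raise ValidationError(
            f"expected a single screening concentration, got {sorted(concs)}")
    wide = index_table.pivot(index="genotype", columns="trait", values="sti")
    if traits is not None:
        traits = normalize_traits(traits)
        missing = set(traits) - set(wide.columns)
        if missing:
            raise ValidationError(f"traits absent: {sorted(missing)}")
        wide = wide[list(traits)]
    return wide


def sti_correlation_matrix(sti_by_trait: pd.DataFrame,
                           traits=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlations among trait STIs across genotypes.

    Returns ``(r, significant)``: the correlation matrix and a boolean
    matrix flagging two-sided p < 0.01 (the report's ** convention).
    """
    if traits is not None:
        sti_by_trait = sti_by_trait[list(normalize_traits(traits))]
    if len(sti_by_trait) < 3:
        raise ValidationError("need at least 3 genotypes for correlations")
    constant = [c for c in sti_by_trait.columns
                if sti_by_trait[c].std(ddof=1) == 0]
    if constant:
        raise ValidationError(f"zero-variance traits: {constant}")

    cols = list(sti_by_trait.columns)
    r = sti_by_trait.corr(method="pearson")
    sig = pd.DataFrame(False, index=cols, columns=cols)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            p = stats.pearsonr(sti_by_trait[a], sti_by_trait[b]).pvalue
            sig.loc[a, b] = sig.loc[b, a] = bool(p < 0.01)
    return r, sig


def fit_trait_vs_mean_mfv(sti: pd.Series, mean_mfv: pd.Series) -> tuple[float, float, float]:
    """Simple OLS of mean MFV on one trait's STI: (slope, intercept, R^2)."""
    x = np.asarray(sti, float)
    y = np.asarray(mean_mfv, float)
    if len(x) < 3:
        raise ValidationError("need at least 3 genotypes")
    if np.ptp(x) == 0:
        raise ValidationError("degenerate predictor: constant STI")
    if np.ptp(y) == 0:
        # constant response: flat line explains everything and nothing
        return 0.0, float(y[0]), 0.0
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2)


@dataclass
class TraitReliabilityReport:
    """Association summary and the selected screening trait."""

    correlation_matrix: pd.DataFrame
    correlation_significant: pd.DataFrame
    per_trait_fit: pd.DataFrame      # trait, slope, intercept, r_squared
    ranked_traits: tuple[str, ...]
    selected_trait: str
    rationale: dict                  # r_squared, rank, standardized beta of pick


def select_reliable_trait(per_trait_fit: pd.DataFrame,
                          model: SaltToleranceModel | None = None) -> tuple[str, dict]:
    """Pick the trait with maximum R^2 against mean MFV.

    Ties go to the larger standardized beta from ``model`` (when available),
    then to alphabetical order.
    """
    if per_trait_fit.empty:
        raise ValidationError("no per-trait fits to select from")

    def std_beta(trait: str) -> float:
        if model is not None and trait in model.coefficients:
            b = model.coefficients[trait].beta_standardized
            return b if np.isfinite(b) else -np.inf
        return -np.inf

    ranked = sorted(
        per_trait_fit.itertuples(index=False),
        key=lambda row: (-row.r_squared, -std_beta(row.trait), row.trait))
    best = ranked[0]
    rationale = {
        "selected_trait": best.trait,
        "r_squared": float(best.r_squared),
        "rank": 1,
        "standardized_beta": (float(std_beta(best.trait))
                              if np.isfinite(std_beta(best.trait)) else None),
    }
    return best.trait, rationale


def build_reliability_report(sti_by_trait: pd.DataFrame, mean_mfv: pd.Series,
                             model: SaltToleranceModel | None = None,
                             traits=None) -> TraitReliabilityReport:
    """Correlations, per-trait fits, ranking and selection in one call."""
    if traits is not None:
        sti_by_trait = sti_by_trait[list(normalize_traits(traits))]
    r, sig = sti_correlation_matrix(sti_by_trait)
    fits = []
    for t in sti_by_trait.columns:
        slope, intercept, r2 = fit_trait_vs_mean_mfv(
            sti_by_trait.loc[mean_mfv.index, t], mean_mfv)
        fits.append((t, slope, intercept, r2))
    fit_df = pd.DataFrame(fits, columns=["trait", "slope", "intercept", "r_squared"])
    selected, rationale = select_reliable_trait(fit_df, model)

    def std_beta(trait: str) -> float:
        if model is not None and trait in model.coefficients:
            b = model.coefficients[trait].beta_standardized
            return b if np.isfinite(b) else -np.inf
        return -np.inf

    ranked = tuple(row.trait for row in sorted(
        fit_df.itertuples(index=False),
        key=lambda row: (-row.r_squared, -std_beta(row.trait), row.trait)))
    logger.info("trait ranking by R^2: %s; selected %s (R^2=%.3f)",
                ranked, selected, rationale["r_squared"])
    return TraitReliabilityReport(
        correlation_matrix=r, correlation_significant=sig, per_trait_fit=fit_df,
        ranked_traits=ranked, selected_trait=selected, rationale=rationale)
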