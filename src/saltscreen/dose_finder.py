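"""Optimum screening-dose determination from the injury dose-response.

The injury index SII rises roughly linearly with NaCl concentration over the
screening range.  For each trait, the mean SII per concentration (averaged
across the pilot genotypes) is regressed on concentration by ordinary least
squares; the concentration at which the fitted line reaches the target injury
level (SII = 0.5, i.e. 50% of control) is the trait's c50.  The same is done
for the across-trait average curve, and the final screening dose is the
tested concentration nearest that average crossing, ties resolved upward to
the more stringent screen.

The control point (0 mM/L, SII = 0 by construction) is included as a
regression point by default; set ``include_control=False`` to drop it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FitError, NoCrossingError
from .indices import apply_undefined_policy

logger = logging.getLogger(__name__)


@dataclass
class DoseResponseFit:
    """An OLS line SII = intercept + slope * concentration for one trait."""

    trait: str                      # trait code, or "average"
    slope: float                    # SII per mM/L
    intercept: float                # SII at 0 mM/L
    r_squared: float
    c_at_target: float              # mM/L at which fitted SII = target
    n_points: int
    target_sii: float = 0.5
    degenerate: str | None = None   # None | "flat_at_target"


@dataclass
class OptimumDose:
    """The chosen screening concentration and the crossings that led to it."""

    per_trait_c50: dict[str, float]
    average_c50: float
    chosen_concentration: float
    tested: tuple[float, ...] = field(default_factory=tuple)


def fit_sii_vs_concentration(points, target_sii: float = 0.5) -> DoseResponseFit:
    """OLS fit of SII against concentration and the target crossing.

    ``points`` is an iterable of (concentration mM/L, sii) pairs.  Degenerate
    cases: all concentrations equal raises :class:`FitError`; a zero-slope
    line that never reaches the target raises :class:`NoCrossingError`; a
    zero-slope line already at the target is flagged ``flat_at_target`` and
    resolves to the smallest positive concentration among the points.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise FitError("need at least two (concentration, sii) points")
    conc, sii = pts[:, 0], pts[:, 1]
    if not np.all(np.isfinite(sii)):
        raise FitError("non-finite SII values in regression input")
    if np.ptp(conc) == 0:
        raise FitError("all concentrations identical; line is undetermined")

    res = stats.linregress(conc, sii)
    slope, intercept = float(res.slope), float(res.intercept)
    r2 = float(res.rvalue ** 2) if np.isfinite(res.rvalue) else 1.0

    degenerate = None
    if slope == 0.0:
        if np.isclose(intercept, target_sii):
            degenerate = "flat_at_target"
            positive = conc[conc > 0]
            c_at_target = float(positive.min() if positive.size else conc.min())
            logger.warning("flat dose-response already at target %.3g; "
                           "resolving to %.3g mM/L", target_sii, c_at_target)
        else:
            raise NoCrossingError(
                f"flat line at SII={intercept:.4g} never crosses target {target_sii}")
    else:
        c_at_target = (target_sii - intercept) / slope

    return DoseResponseFit(trait="", slope=slope, intercept=intercept,
                           r_squared=r2, c_at_target=c_at_target,
                           n_points=len(pts), target_sii=target_sii,
                           degenerate=degenerate)


def average_sii_curve(index_table: pd.DataFrame, include_control: bool = True,
                      undefined_policy: str = "drop") -> pd.DataFrame:
    """Mean SII per concentration across all genotype x trait rows.

    Returns a DataFrame (concentration, sii), one row per stress
    concentration, plus the (0, 0) control point when ``include_control``.
    """
    table = apply_undefined_policy(index_table, undefined_policy)
    if table.empty:
        raise FitError("no defined index rows to average")
    curve = (table.groupby("concentration")["sii"].mean()
             .reset_index().sort_values("concentration", ignore_index=True))
    if include_control and not (curve["concentration"] == 0).any():
        curve = pd.concat([pd.DataFrame({"concentration": [0.0], "sii": [0.0]}),
                           curve], ignore_index=True)
    return curve


def per_trait_sii_curves(index_table: pd.DataFrame, include_control: bool = True,
                         undefined_policy: str = "drop") -> dict[str, pd.DataFrame]:
    """Mean-SII-per-concentration curve for each trait separately."""
    table = apply_undefined_policy(index_table, undefined_policy)
    return {
        trait: average_sii_curve(sub, include_control=include_control,
                                 undefined_policy="drop")
        for trait, sub in table.groupby("trait")
    }


def fit_all_traits(index_table: pd.DataFrame, target_sii: float = 0.5,
                   include_control: bool = True, mode: str = "pooled_mean",
                   undefined_policy: str = "drop") -> tuple[list[DoseResponseFit], DoseResponseFit]:
    """Per-trait dose-response fits plus the average-curve fit.

    ``mode`` ``"pooled_mean"`` regresses the mean SII per concentration
    (one point per dose, the default); ``"pooled_raw"`` regresses every
    genotype's SII as its own point — the identical line for balanced
    designs but a different R².
    """
    if mode not in ("pooled_mean", "pooled_raw"):
        raise ValueError(f"unknown dose-fit mode {mode!r}")
    table = apply_undefined_policy(index_table, undefined_policy)

    fits = []
    for trait, sub in table.groupby("trait"):
        if mode == "pooled_mean":
            curve = average_sii_curve(sub, include_control, "drop")
            pts = curve[["concentration", "sii"]].to_numpy()
        else:
            pts = sub[["concentration", "sii"]].to_numpy()
            if include_control:
                zeros = np.column_stack([np.zeros(sub["genotype"].nunique()),
                                         np.zeros(sub["genotype"].nunique())])
                pts = np.vstack([zeros, pts])
        fit = fit_sii_vs_concentration(pts, target_sii)
        fit.trait = str(trait)
        fits.append(fit)

    if mode == "pooled_mean":
        avg_pts = average_sii_curve(table, include_control, "drop")[
            ["concentration", "sii"]].to_numpy()
    else:
        avg_pts = np.vstack([np.column_stack([np.full(1, 0.0), np.full(1, 0.0)]),
                             table[["concentration", "sii"]].to_numpy()]) \
            if include_control else table[["concentration", "sii"]].to_numpy()
    avg_fit = fit_sii_vs_concentration(avg_pts, target_sii)
    avg_fit.trait = "average"
    return fits, avg_fit


def choose_optimum(per_trait: list[DoseResponseFit], average_fit: DoseResponseFit,
                   tested) -> OptimumDose:
    """Snap the average crossing to the nearest tested stress dose, ties upward."""
    tested = tuple(sorted(float(c) for c in tested))
    candidates = [c for c in tested if c > 0]
    if not candidates:
        raise FitError("no positive tested concentrations to choose from")
    if not np.isfinite(average_fit.c_at_target):
        raise NoCrossingError("average fit has no defined target crossing")
    target = average_fit.c_at_target
    # ties upward: among equal distances prefer the larger (more stringent) dose
    chosen = max(candidates, key=lambda c: (-abs(c - target), c))
    logger.info("average c50 = %.4g mM/L -> chosen screening dose %.4g mM/L",
                target, chosen)
    return OptimumDose(
        per_trait_c50={f.trait: f.c_at_target for f in per_trait},
        average_c50=target, chosen_concentration=chosen, tested=tested)


def find_optimum_dose(index_table: pd.DataFrame, tested, target_sii: float = 0.5,
                      include_control: bool = True, mode: str = "pooled_mean",
                      undefined_policy: str = "drop") -> tuple[list[DoseResponseFit], DoseResponseFit, OptimumDose]:
    """One-call pipeline stage: fits per trait, average fit, snapped optimum."""
    fits, avg = fit_all_traits(index_table, target_sii, include_control, mode,
                               undefined_policy)
    return fits, avg, choose_optimum(fits, avg, tested)


def fits_to_frame(fits: list[DoseResponseFit]) -> pd.DataFrame:
    """Tabular view of dose-response fits (one row per trait)."""
    return pd.DataFrame(
        [(f.trait, f.slope, f.intercept, f.r_squared, f.c_at_target, f.n_points)
         for f in fits],
        columns=["trait", "slope", "intercept", "r_squared", "c_at_target", "n_points"])
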