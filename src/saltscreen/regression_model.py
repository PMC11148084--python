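"""Multiple-regression tolerance model Y = mu + sum_t beta_t * STI_t.

The composite tolerance score (mean MFV) is regressed on the trait salt
tolerance indices by ordinary least squares, giving a predictive score Y for
any genotype from its STIs alone.  By default the five growth traits RL,
SHL, SL, SFW, SDW are the predictors (germination rate is screened and
correlated but kept out of the model).  Inference (t statistics, two-sided
p values, confidence intervals at the 99% level) uses the standard linear
model with n - p - 1 residual degrees of freedom.

mu is an ordinary fitted intercept: with all STIs zero (total growth
inhibition) the predicted score is mu.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import FitError, ValidationError
from .traits import MODEL_TRAITS, normalize_traits

logger = logging.getLogger(__name__)


@dataclass
class CoefficientStats:
    beta: float                  # unstandardized coefficient
    beta_standardized: float     # beta * sd(x)/sd(y)
    std_error: float
    t_value: float
    p_value: float
    ci_lower: float
    ci_upper: float


@dataclass
class SaltToleranceModel:
    """Fitted tolerance model: intercept, per-trait coefficients, inference."""

    mu: float
    traits: tuple[str, ...]
    coefficients: dict[str, CoefficientStats]
    mu_stats: CoefficientStats
    n_obs: int
    ci_level: float = 0.99
    r_squared: float = float("nan")

    def to_json(self) -> str:
        payload = {
            "mu": self.mu,
            "traits": list(self.traits),
            "coefficients": {t: asdict(c) for t, c in self.coefficients.items()},
            "mu_stats": asdict(self.mu_stats),
            "n_obs": self.n_obs,
            "ci_level": self.ci_level,
            "r_squared": self.r_squared,
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SaltToleranceModel":
        d = json.loads(text)
        return cls(mu=d["mu"], traits=tuple(d["traits"]),
                   coefficients={t: CoefficientStats(**c)
                                 for t, c in d["coefficients"].items()},
                   mu_stats=CoefficientStats(**d["mu_stats"]),
                   n_obs=d["n_obs"], ci_level=d["ci_level"],
                   r_squared=d["r_squared"])

    def coefficient_table(self) -> pd.DataFrame:
        """Report-style coefficient table (constant first)."""
        rows = [("(Constant)", self.mu_stats)] + [
            (t, self.coefficients[t]) for t in self.traits]
        return pd.DataFrame(
            [(name, s.beta, s.std_error, s.beta_standardized, s.t_value,
              s.p_value, s.ci_lower, s.ci_upper) for name, s in rows],
            columns=["term", "beta", "std_error", "beta_standardized",
                     "t_value", "p_value", "ci_lower", "ci_upper"])


def fit_model(sti_by_trait: pd.DataFrame, mean_mfv: pd.Series,
              traits=MODEL_TRAITS, ci_level: float = 0.99) -> SaltToleranceModel:
    """OLS fit of mean MFV on trait STIs.

    Parameters
    ----------
    sti_by_trait
        Genotype x trait DataFrame of STIs (columns must cover ``traits``).
    mean_mfv
        Per-genotype response, aligned on the same genotype index.
    """
    traits = normalize_traits(traits)
    missing = set(traits) - set(sti_by_trait.columns)
    if missing:
        raise ValidationError(f"STI matrix lacks traits {sorted(missing)}")
    x = sti_by_trait.loc[mean_mfv.index, list(traits)].astype(float)
    y = mean_mfv.astype(float)
    n, p = x.shape
    if n <= p + 1:
        raise FitError(f"{n} observations cannot identify {p} slopes + intercept")

    design = sm.add_constant(x, has_constant="add")
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < p + 1:
        corr = x.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        worst = corr.stack().idxmax()
        raise FitError(f"collinear predictors (rank {rank} < {p + 1}); "
                       f"most correlated pair: {worst}")

    res = sm.OLS(y, design).fit()
    ci = res.conf_int(alpha=1 - ci_level)
    sd_y = y.std(ddof=1)
    coefs = {}
    for t in traits:
        coefs[t] = CoefficientStats(
            beta=float(res.params[t]),
            beta_standardized=float(res.params[t] * x[t].std(ddof=1) / sd_y)
            if sd_y > 0 else float("nan"),
            std_error=float(res.bse[t]), t_value=float(res.tvalues[t]),
            p_value=float(res.pvalues[t]),
            ci_lower=float(ci.loc[t, 0]), ci_upper=float(ci.loc[t, 1]))
    mu_stats = CoefficientStats(
        beta=float(res.params["const"]), beta_standardized=float("nan"),
        std_error=float(res.bse["const"]), t_value=float(res.tvalues["const"]),
        p_value=float(res.pvalues["const"]),
        ci_lower=float(ci.loc["const", 0]), ci_upper=float(ci.loc["const", 1]))
    model = SaltToleranceModel(
        mu=float(res.params["const"]), traits=traits, coefficients=coefs,
        mu_stats=mu_stats, n_obs=n, ci_level=ci_level,
        r_squared=float(res.rsquared))
    logger.info("fitted tolerance model on %d genotypes, R^2 = %.3f", n,
                model.r_squared)
    return model


def make_model(mu: float, betas: dict[str, float], n_obs: int = 0) -> SaltToleranceModel:
    """Construct a model from published constants (no inference stats)."""
    nan = float("nan")
    stats = {t: CoefficientStats(b, nan, nan, nan, nan, nan, nan)
             for t, b in betas.items()}
    return SaltToleranceModel(
        mu=mu, traits=normalize_traits(betas.keys()), coefficients=stats,
        mu_stats=CoefficientStats(mu, nan, nan, nan, nan, nan, nan), n_obs=n_obs)


def predict_y(model: SaltToleranceModel, sti_vector) -> float:
    """Predicted tolerance score Y = mu + sum beta_t * STI_t for one genotype.

    ``sti_vector`` is a mapping (or Series) trait -> STI covering
    ``model.traits``.  Full precision is returned; round to 3 decimals for
    report display.
    """
    y = model.mu
    for t in model.traits:
        try:
            value = sti_vector[t]
        except (KeyError, IndexError) as exc:
            raise ValidationError(f"STI vector missing trait {t}") from exc
        y += model.coefficients[t].beta * float(value)
    return float(y)


def predict_frame(model: SaltToleranceModel, sti_by_trait: pd.DataFrame) -> pd.Series:
    """Vectorised :func:`predict_y` over a genotype x trait STI matrix."""
    missing = set(model.traits) - set(sti_by_trait.columns)
    if missing:
        raise ValidationError(f"STI matrix missing traits {sorted(missing)}")
    betas = np.array([model.coefficients[t].beta for t in model.traits])
    vals = sti_by_trait[list(model.traits)].to_numpy(float) @ betas + model.mu
    return pd.Series(vals, index=sti_by_trait.index, name="y_predicted")


@dataclass
class VerificationResult:
    """Predicted Y against observed mean MFV, per genotype and summarised."""

    table: pd.DataFrame          # genotype, y_predicted, mean_mfv_observed, abs_difference
    max_abs_difference: float
    mean_abs_difference: float
    median_abs_difference: float
    mean_signed_difference: float


def verify_model(model: SaltToleranceModel, sti_by_trait: pd.DataFrame,
                 mean_mfv: pd.Series) -> VerificationResult:
    """Compare model predictions with the observed composite score."""
    y = predict_frame(model, sti_by_trait.loc[mean_mfv.index])
    diff = y - mean_mfv.astype(float)
    table = pd.DataFrame({
        "genotype": mean_mfv.index,
        "y_predicted": y.to_numpy(),
        "mean_mfv_observed": mean_mfv.to_numpy(float),
        "abs_difference": diff.abs().to_numpy(),
    }).reset_index(drop=True)
    return VerificationResult(
        table=table,
        max_abs_difference=float(diff.abs().max()),
        mean_abs_difference=float(diff.abs().mean()),
        median_abs_difference=float(diff.abs().median()),
        mean_signed_difference=float(diff.mean()),
    )
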