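"""Synthetic replicated germination-assay data with known ground truth.

The generator emulates a seedling salt-screen: each genotype g carries a
latent tolerance tau_g in [0, 1], and every trait t declines linearly with
NaCl concentration c at a genotype- and trait-specific rate

    k_gt = k0 * sensitivity_t * (1 - tau_g)        [per mM/L]

so a replicate measurement is

    value = baseline_gt * max(0, 1 - k_gt * c) * (1 + eps),
    eps ~ Normal(0, noise_cv^2), truncated at 0.

With this construction the expected injury index is SII = min(k_gt * c, 1)
— exactly linear in dose until total inhibition — so dose-response fits
have closed-form truth: the genotype-mean SII curve of trait t crosses a
target s at c = s / mean_g(k_gt) whenever no genotype is fully inhibited in
the tested range.

Germination is a dish-level binomial: Gt ~ Binomial(seeds_per_dish,
p0 * max(0, 1 - k_gGR * c)), reported as a percentage.  At noise_cv = 0 the
generator is fully deterministic and emits the exact expected germination
percentage instead of a binomial draw, so zero-noise closed-form checks
hold for all six traits.

Default dose-response sensitivities place the per-trait 50%-injury
concentrations in the 160-270 mM/L band typical of Indian-mustard seedling
screens, with growth traits (root/shoot/seedling length) more salt-sensitive
than biomass and germination.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .traits import ALL_TRAITS

#: default per-trait (baseline mean, between-genotype CV); lengths cm, weights mg
DEFAULT_BASELINES: dict[str, tuple[float, float]] = {
    "RL": (5.0, 0.15),
    "SHL": (4.0, 0.15),
    "SL": (9.0, 0.15),
    "SFW": (30.0, 0.20),
    "SDW": (2.5, 0.20),
}

#: default relative dose sensitivity per trait (dimensionless multiplier)
DEFAULT_SENSITIVITY: dict[str, float] = {
    "GR": 0.77, "RL": 1.20, "SHL": 1.19, "SL": 1.22, "SFW": 1.04, "SDW": 0.75,
}


@dataclass
class SyntheticConfig:
    """Study-design and noise parameters for the generator."""

    n_genotypes: int = 59
    replicates: int = 4
    concentrations: tuple[float, ...] = (0.0, 75.0, 150.0, 225.0, 300.0)
    tolerance_range: tuple[float, float] = (0.1, 0.9)
    trait_baselines: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BASELINES))
    decline_rate_k0: float = 0.005          # per mM/L at tau = 0
    trait_sensitivity: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SENSITIVITY))
    noise_cv: float = 0.05
    seeds_per_dish: int = 10
    germination_p0: float = 0.95
    random_seed: int = 0

    def validate(self) -> None:
        if self.n_genotypes < 1 or self.replicates < 1:
            raise ValidationError("n_genotypes and replicates must be positive")
        if 0.0 not in self.concentrations:
            raise ValidationError("concentrations must include the 0 mM/L control")
        if any(c < 0 for c in self.concentrations):
            raise ValidationError("concentrations must be non-negative")
        lo, hi = self.tolerance_range
        if not (0 <= lo <= hi <= 1):
            raise ValidationError(f"tolerance_range {self.tolerance_range} not in [0,1]")
        if self.decline_rate_k0 <= 0:
            raise ValidationError("decline_rate_k0 must be positive")
        if not (0 <= self.germination_p0 <= 1):
            raise ValidationError("germination_p0 must be a probability")
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be >= 0")
        if self.seeds_per_dish < 1:
            raise ValidationError("seeds_per_dish must be positive")
        unknown = set(self.trait_sensitivity) - set(ALL_TRAITS)
        if unknown:
            raise ValidationError(f"unknown traits in sensitivity map: {unknown}")


@dataclass
class GroundTruth:
    """Latent parameters behind a generated table."""

    tau: pd.Series                    # genotype -> latent tolerance
    decline_rates: pd.DataFrame       # genotype x trait k_gt (per mM/L)
    trait_c50: pd.Series              # trait -> crossing of the mean SII curve
    genotype_c50: pd.DataFrame        # genotype x trait 0.5 / k_gt

    def expected_sii(self, genotype: str, trait: str, concentration: float) -> float:
        return float(min(self.decline_rates.loc[genotype, trait] * concentration, 1.0))


def _genotype_ids(n: int) -> list[str]:
    width = max(2, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def generate(config: SyntheticConfig | None = None) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw a replicated long-format trait table plus its ground truth.

    Returns ``(table, truth)`` where ``table`` has columns
    (genotype, concentration, replicate, trait, value) — GR rows in percent —
    and is byte-identical for identical config (including random_seed).
    """
    config = config or SyntheticConfig()
    config.validate()
    rng = np.random.default_rng(config.random_seed)

    genotypes = _genotype_ids(config.n_genotypes)
    lo, hi = config.tolerance_range
    tau = pd.Series(rng.uniform(lo, hi, config.n_genotypes), index=genotypes,
                    name="tau")

    traits = [t for t in ALL_TRAITS
              if t == "GR" or t in config.trait_baselines]
    rates = pd.DataFrame(
        {t: config.decline_rate_k0 * config.trait_sensitivity.get(t, 1.0)
            * (1.0 - tau) for t in traits},
        index=genotypes)

    continuous = [t for t in traits if t != "GR"]
    baselines = pd.DataFrame(
        {t: np.maximum(rng.normal(m, cv * m, config.n_genotypes), 0.05 * m)
         for t, (m, cv) in config.trait_baselines.items()},
        index=genotypes)

    concs = sorted(config.concentrations)
    rows: list[tuple] = []
    for g in genotypes:
        for c in concs:
            for rep in range(1, config.replicates + 1):
                for t in continuous:
                    mean = baselines.loc[g, t] * max(0.0, 1.0 - rates.loc[g, t] * c)
                    if config.noise_cv > 0:
                        value = max(0.0, mean * (1.0 + rng.normal(0.0, config.noise_cv)))
                    else:
                        value = mean
                    rows.append((g, float(c), rep, t, value))
                if "GR" in traits:
                    p = config.germination_p0 * max(0.0, 1.0 - rates.loc[g, "GR"] * c)
                    if config.noise_cv > 0:
                        gt = rng.binomial(config.seeds_per_dish, p)
                        value = gt / config.seeds_per_dish * 100.0
                    else:
                        value = p * 100.0
                    rows.append((g, float(c), rep, "GR", value))

    table = pd.DataFrame(rows, columns=["genotype", "concentration", "replicate",
                                        "trait", "value"])
    trait_c50 = pd.Series({t: 0.5 / rates[t].mean() for t in traits},
                          name="trait_c50")
    genotype_c50 = 0.5 / rates
    truth = GroundTruth(tau=tau, decline_rates=rates, trait_c50=trait_c50,
                        genotype_c50=genotype_c50)
    return table, truth


def pilot_config(random_seed: int = 0, **overrides) -> SyntheticConfig:
    """Dose-finding pilot design: 15 genotypes, 2 replicates, 5 doses, 20 seeds."""
    defaults = dict(n_genotypes=15, replicates=2, seeds_per_dish=20,
                    random_seed=random_seed)
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


def screening_config(random_seed: int = 0, screening_concentration: float = 225.0,
                     **overrides) -> SyntheticConfig:
    """Main screen design: 59 genotypes, 4 replicates, control + one stress dose."""
    defaults = dict(n_genotypes=59, replicates=4, seeds_per_dish=10,
                    concentrations=(0.0, screening_concentration),
                    random_seed=random_seed)
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


# ---------------------------------------------------------------------------
# In-report worked-example fixtures: the published verification table (fifteen
# genotypes with their five trait STIs, observed mean MFV and predicted Y) and
# the published model constants with full inference statistics.
# ---------------------------------------------------------------------------

#: columns: genotype, STI RL, STI SHL, STI SL, STI SFW, STI SDW, mean MFV, Y
_VERIFICATION_ROWS = [
    ("33", 0.018, 0.021, 0.020, 0.049, 0.115, 0.062, 0.076),
    ("36", 0.025, 0.031, 0.029, 0.041, 0.178, 0.068, 0.090),
    ("16", 0.024, 0.038, 0.029, 0.064, 0.228, 0.082, 0.107),
    ("48", 0.074, 0.118, 0.101, 0.104, 0.575, 0.229, 0.229),
    ("55", 0.103, 0.161, 0.136, 0.222, 1.027, 0.359, 0.361),
    ("13", 0.182, 0.294, 0.227, 0.195, 0.436, 0.361, 0.370),
    ("43", 0.078, 0.354, 0.180, 0.332, 1.020, 0.463, 0.478),
    ("59", 0.238, 0.266, 0.252, 0.304, 0.846, 0.480, 0.470),
    ("20", 0.156, 0.322, 0.230, 0.459, 0.998, 0.536, 0.539),
    ("1", 0.288, 0.440, 0.368, 0.665, 0.561, 0.599, 0.669),
    ("52", 0.264, 0.345, 0.302, 0.502, 1.032, 0.607, 0.613),
    ("11", 0.233, 0.386, 0.308, 0.650, 0.907, 0.654, 0.658),
    ("18", 0.633, 0.402, 0.526, 0.465, 0.545, 0.712, 0.707),
    ("58", 0.392, 0.484, 0.425, 0.590, 0.909, 0.746, 0.745),
    ("24", 0.423, 0.606, 0.528, 0.540, 0.602, 0.778, 0.772),
]

#: published model: intercept and per-trait
#: (beta, std_error, beta_standardized, t, p, ci99_lower, ci99_upper)
PUBLISHED_MU = 0.027
PUBLISHED_MU_STATS = (0.027, 0.008, float("nan"), 3.593, 0.001, 0.007, 0.047)
PUBLISHED_COEFFICIENTS = {
    "RL": (0.207, 0.187, 0.132, 1.107, 0.273, -0.292, 0.706),
    "SHL": (0.362, 0.161, 0.263, 2.250, 0.029, -0.068, 0.792),
    "SL": (0.328, 0.332, 0.214, 0.989, 0.327, -0.558, 1.214),
    "SFW": (0.345, 0.042, 0.287, 8.294, 0.000, 0.234, 0.456),
    "SDW": (0.130, 0.013, 0.230, 9.973, 0.000, 0.095, 0.164),
}


def make_fixture_tables():
    """Published worked-example fixtures as typed objects.

    Returns ``(verification_df, model)``: a DataFrame with columns
    (genotype, RL, SHL, SL, SFW, SDW, mean_mfv, y_published) and the
    published tolerance model (point estimates only; see
    :data:`PUBLISHED_COEFFICIENTS` for the full inference table).
    """
    from .regression_model import make_model

    df = pd.DataFrame(
        _VERIFICATION_ROWS,
        columns=["genotype", "RL", "SHL", "SL", "SFW", "SDW",
                 "mean_mfv", "y_published"])
    model = make_model(PUBLISHED_MU,
                       {t: v[0] for t, v in PUBLISHED_COEFFICIENTS.items()},
                       n_obs=59)
    return df, model
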