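"""Seeded Monte Carlo propagation of input distributions through the risk equations.

Stochastic symbols are named with a small string convention:

    conc:<category>:<metal>   concentration draw, mg/kg (mg/L for water)
    di:<category>             daily intake draw, g/day
    ef:<category>             exposure frequency draw, day/year
    bw                        body weight draw, kg

Under ``shared_person`` coupling each iteration represents one simulated
resident: a single body-weight draw is reused across every category. Under
``independent`` coupling a fresh body weight is drawn per category.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import risk_core
from .distribution_fitting import DistributionSpec, lognormal_from_moments, zero_inflated_lognormal
from .exceptions import ValidationError
from .risk_core import METALS, ExposureFactors, ToxicityReference, medium_for

COUPLINGS = ("shared_person", "independent")


@dataclass(frozen=True)
class SimulationConfig:
    iterations: int = 10_000
    seed: int = 0
    coupling: str = "shared_person"
    hi_threshold: float = 1.0
    r_threshold: float = 1e-4
    quantiles: tuple[float, ...] = (0.1, 0.5, 0.9)

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValidationError("iterations must be >= 1")
        if self.coupling not in COUPLINGS:
            raise ValidationError(f"coupling must be one of {COUPLINGS}")
        if self.hi_threshold <= 0 or self.r_threshold <= 0:
            raise ValidationError("thresholds must be > 0")
        if any(not (0.0 <= q <= 1.0) for q in self.quantiles):
            raise ValidationError("quantiles must be in [0, 1]")


@dataclass(frozen=True)
class QuantitySummary:
    """Summary of one simulated output quantity."""

    percentiles: dict[float, float]
    exceedance: float
    threshold: float
    fitted: DistributionSpec

    def __post_init__(self) -> None:
        qs = sorted(self.percentiles)
        vals = [self.percentiles[q] for q in qs]
        if any(b < a for a, b in zip(vals, vals[1:])):
            raise ValidationError("percentiles must be non-decreasing in q")
        if not (0.0 <= self.exceedance <= 1.0):
            raise ValidationError("exceedance must be in [0, 1]")


@dataclass
class SimulationSummary:
    """Summaries of every per-category and total HI / R output."""

    config: SimulationConfig
    quantities: dict[str, QuantitySummary]
    outputs: dict[str, np.ndarray] = field(repr=False, default_factory=dict)
    inputs: dict[str, np.ndarray] = field(repr=False, default_factory=dict)


def empirical_percentiles(values, q) -> np.ndarray:
    """Order statistics with linear interpolation between closest ranks."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValidationError("empirical_percentiles requires non-empty values")
    q = np.atleast_1d(np.asarray(q, dtype=float))
    if np.any((q < 0) | (q > 1)):
        raise ValidationError("quantile levels must be in [0, 1]")
    return np.quantile(values, q, method="linear")


def exceedance_probability(values, threshold: float) -> float:
    """Fraction of values strictly greater than the threshold."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValidationError("exceedance_probability requires non-empty values")
    return float(np.mean(values > threshold))


def fit_output_distribution(values) -> DistributionSpec:
    """Descriptive location-0 lognormal matching the sample mean and SD."""
    values = np.asarray(values, dtype=float)
    if values.size == 0 or np.any(values < 0):
        raise ValidationError("values must be non-negative and non-empty")
    if not np.any(values > 0):
        raise ValidationError("all-zero input cannot be described by a lognormal")
    return lognormal_from_moments(float(values.mean()), float(values.std()))


def summarize_output(values, config: SimulationConfig, threshold: float) -> QuantitySummary:
    values = np.asarray(values, dtype=float)
    pct = empirical_percentiles(values, config.quantiles)
    if np.any(values > 0):
        fitted = fit_output_distribution(values)
    else:
        # undetectable everywhere (e.g. As absent): no lognormal can be fitted
        fitted = DistributionSpec("lognormal", (0.0, 0.0), zero_mass=1.0)
    return QuantitySummary(
        percentiles={q: float(p) for q, p in zip(config.quantiles, pct)},
        exceedance=exceedance_probability(values, threshold),
        threshold=threshold,
        fitted=fitted,
    )


def _required_symbols(categories: Sequence[str], coupling: str) -> list[str]:
    symbols = ["bw"]
    for cat in categories:
        symbols.append(f"di:{cat}")
        symbols.append(f"ef:{cat}")
        for metal in METALS:
            symbols.append(f"conc:{cat}:{metal}")
    return symbols


def sample_inputs(
    specs: Mapping[str, DistributionSpec],
    config: SimulationConfig,
    categories: Sequence[str] | None = None,
) -> dict[str, np.ndarray]:
    """Draw every stochastic symbol; reproducible given (seed, iterations).

    When ``categories`` is given, completeness is enforced and an error
    names any missing symbol. Under ``independent`` coupling the shared
    ``bw`` symbol is expanded into one ``bw:<category>`` draw per category.
    """
    rng = np.random.default_rng(config.seed)
    if categories is not None:
        missing = [s for s in _required_symbols(categories, config.coupling) if s not in specs]
        if missing:
            raise ValidationError("missing distribution specs for: " + ", ".join(missing))
    draws: dict[str, np.ndarray] = {}
    for name in sorted(specs):  # canonical order => seed determinism
        if name == "bw" and config.coupling == "independent" and categories is not None:
            for cat in categories:
                draws[f"bw:{cat}"] = specs[name].sample(rng, config.iterations)
        else:
            draws[name] = specs[name].sample(rng, config.iterations)
    return draws


def run_simulation(
    specs: Mapping[str, DistributionSpec],
    factors: Mapping[str, ExposureFactors],
    tox: Mapping[tuple[str, str], ToxicityReference],
    config: SimulationConfig,
) -> SimulationSummary:
    """Propagate input draws through the deterministic risk equations.

    ``factors`` supplies the non-sampled symbols (exposure duration and
    lifetime). Exposure-frequency draws are capped at 365 day/year.
    Returns per-category and total HI and R summaries plus raw draws for
    downstream sensitivity analysis.
    """
    categories = sorted(factors, key=risk_core.CATEGORIES.index)
    draws = sample_inputs(specs, config, categories=categories)
    n = config.iterations

    outputs: dict[str, np.ndarray] = {}
    total_hi = np.zeros(n)
    total_r = np.zeros(n)
    for cat in categories:
        f = factors[cat]
        med = medium_for(cat)
        bw = draws.get(f"bw:{cat}", draws.get("bw"))
        di = draws[f"di:{cat}"]
        ef = np.minimum(draws[f"ef:{cat}"], risk_core.DAYS_PER_YEAR)
        hi = np.zeros(n)
        for metal in METALS:
            c = draws[f"conc:{cat}:{metal}"]
            expo = risk_core.daily_dose(c, di, ef, f.ed, bw, f.lt)
            hi = hi + risk_core.hazard_quotient(expo, tox[(metal, med)].rfd)
            if metal == "As":
                sf = tox[("As", med)].sf or risk_core.ARSENIC_SLOPE_FACTOR
                r = risk_core.carcinogenic_risk(expo, sf)
        outputs[f"hi:{cat}"] = hi
        outputs[f"r:{cat}"] = r
        total_hi += hi
        total_r += r
    outputs["hi:total"] = total_hi
    outputs["r:total"] = total_r

    quantities = {}
    for name, values in outputs.items():
        threshold = config.hi_threshold if name.startswith("hi:") else config.r_threshold
        quantities[name] = summarize_output(values, config, threshold)
    return SimulationSummary(config=config, quantities=quantities, outputs=outputs, inputs=draws)


def specs_from_tables(
    stats: Mapping[tuple[str, str], risk_core.ConcentrationStats],
    factors: Mapping[str, ExposureFactors],
    *,
    cv_intake: float = 0.3,
    cv_bw: float = 0.15,
    zero_mass_default: float = 0.1,
) -> dict[str, DistributionSpec]:
    """Build input distribution specs from summary tables.

    Concentrations become zero-inflated lognormals moment-matched to the
    reported mean/SD; the zero atom defaults to ``zero_mass_default`` for
    cells whose reported minimum is 0 (non-detects present) and collapses
    to a pure zero atom when the mean itself is 0. Intake and frequency
    get lognormals at a configurable coefficient of variation; a frequency
    already at the 365-day ceiling stays fixed. Body weight is a single
    lognormal shared by all categories.
    """
    specs: dict[str, DistributionSpec] = {}
    bw_values = {f.bw for f in factors.values()}
    if len(bw_values) != 1:
        raise ValidationError("expected a single shared body weight across categories")
    bw = bw_values.pop()
    specs["bw"] = lognormal_from_moments(bw, cv_bw * bw)
    for cat, f in factors.items():
        specs[f"di:{cat}"] = lognormal_from_moments(f.di, cv_intake * f.di)
        if f.ef >= risk_core.DAYS_PER_YEAR:
            specs[f"ef:{cat}"] = lognormal_from_moments(f.ef, 0.0)
        else:
            specs[f"ef:{cat}"] = lognormal_from_moments(f.ef, cv_intake * f.ef)
    for (cat, metal), s in stats.items():
        name = f"conc:{cat}:{metal}"
        if s.mean == 0.0:
            specs[name] = DistributionSpec("lognormal", (0.0, 0.0), zero_mass=1.0)
            continue
        zm = zero_mass_default if s.min == 0.0 else 0.0
        if zm > 0.0 and s.sd**2 * (1.0 - zm) <= zm * s.mean**2:
            zm = 0.0  # zero atom would absorb more variance than reported
        if zm > 0.0:
            specs[name] = zero_inflated_lognormal(s.mean, s.sd, zm)
        else:
            specs[name] = lognormal_from_moments(s.mean, s.sd)
    return specs


def sum_exceedance_probability(
    component_moments: Mapping[str, tuple[float, float]],
    threshold: float = 1.0,
    iterations: int = 10_000,
    seed: int = 0,
) -> float:
    """P(sum of independent moment-matched lognormal components > threshold), in %.

    Each component is drawn from a location-0 lognormal whose arithmetic
    mean/SD equal the supplied moments; components are sampled in key
    order for reproducibility.
    """
    rng = np.random.default_rng(seed)
    total = np.zeros(iterations)
    for name in component_moments:
        mean, sd = component_moments[name]
        total += lognormal_from_moments(mean, sd).sample(rng, iterations)
    return 100.0 * exceedance_probability(total, threshold)
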