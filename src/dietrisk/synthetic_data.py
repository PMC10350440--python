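"""Synthetic sample-level datasets with the statistical structure the analysis assumes.

Concentration samples are drawn from a zero-inflated lognormal whose
positive part is truncated at the reported maximum; the lognormal
parameters are solved numerically so that the overall sample mean and SD
still converge to the reported summary targets. Questionnaire records
carry per-category daily intake and exposure frequency (lognormal around
the reported means) and a discrete body weight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar
from scipy.stats import norm

from .cli_io import ningxia_tables
from .exceptions import FitError, ValidationError
from .risk_core import CATEGORIES, DAYS_PER_YEAR, ConcentrationStats, ExposureFactors


@dataclass
class GeneratorSpec:
    """Targets for the synthetic generators.

    ``zero_fraction`` overrides the per-cell exact-zero share; cells whose
    reported minimum is 0 default to ``default_zero_fraction`` (non-detects
    are present but their count is not reported), others to 0.
    """

    concentrations: dict[tuple[str, str], ConcentrationStats]
    factors: dict[str, ExposureFactors]
    resident_count: int = 97
    bw_mean: float = 54.93
    cv_intake: float = 0.3
    default_zero_fraction: float = 0.1
    zero_fraction: dict[tuple[str, str], float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.resident_count < 1:
            raise ValidationError("resident_count must be >= 1")
        if self.bw_mean <= 0:
            raise ValidationError("bw_mean must be > 0")
        if not (0.0 <= self.default_zero_fraction < 1.0):
            raise ValidationError("default_zero_fraction must be in [0, 1)")

    def cell_zero_fraction(self, category: str, metal: str) -> float:
        key = (category, metal)
        if key in self.zero_fraction:
            return self.zero_fraction[key]
        stats = self.concentrations[key]
        return self.default_zero_fraction if stats.min == 0.0 else 0.0


def ningxia_profile(seed: int = 0, **overrides) -> GeneratorSpec:
    """GeneratorSpec parameterized by the packaged survey-region tables."""
    stats, factors, _ = ningxia_tables()
    return GeneratorSpec(concentrations=stats, factors=factors, seed=seed, **overrides)


def _truncated_lognormal_moments(mu: float, sigma: float, upper: float) -> tuple[float, float]:
    """Arithmetic mean/SD of a lognormal conditioned on X <= upper (log-space safe)."""
    a = (math.log(upper) - mu) / sigma
    logz0 = norm.logcdf(a)
    m1 = math.exp(mu + sigma**2 / 2 + norm.logcdf(a - sigma) - logz0)
    m2 = math.exp(2 * mu + 2 * sigma**2 + norm.logcdf(a - 2 * sigma) - logz0)
    var = max(m2 - m1**2, 0.0)
    return m1, math.sqrt(var)


def _solve_truncated_lognormal(mean: float, sd: float, upper: float) -> tuple[float, float]:
    """Find (mu, sigma) whose upper-truncated lognormal matches mean/SD.

    The mean is matched exactly (mu solved by root-finding at each sigma);
    sigma then minimizes the SD gap. Near the variance bound implied by
    the truncation the SD target may be unattainable, in which case the
    closest achievable SD is used while the mean stays faithful.
    """
    if upper <= 0 or mean >= upper:
        raise FitError(f"upper bound {upper} incompatible with target mean {mean}")
    sigma2 = math.log1p((sd / mean) ** 2)
    mu0, sigma0 = math.log(mean) - sigma2 / 2, math.sqrt(sigma2)
    # negligible truncation: keep the closed-form parameters
    if (math.log(upper) - mu0) / sigma0 > 6.0:
        return mu0, sigma0

    def mu_for_mean(sigma: float) -> float:
        # truncated mean is strictly increasing in mu and approaches `upper`
        lo = mu0 - 20.0
        hi = math.log(upper) + sigma**2 + 10.0 * sigma
        while _truncated_lognormal_moments(lo, sigma, upper)[0] > mean:
            lo -= 10.0
        while _truncated_lognormal_moments(hi, sigma, upper)[0] < mean:
            hi += sigma**2 + 10.0
        return float(brentq(lambda m: _truncated_lognormal_moments(m, sigma, upper)[0] - mean, lo, hi))

    def sd_gap(log_sigma: float) -> float:
        sigma = math.exp(log_sigma)
        s = _truncated_lognormal_moments(mu_for_mean(sigma), sigma, upper)[1]
        return (s - sd) ** 2

    sol = minimize_scalar(sd_gap, bounds=(math.log(1e-6), math.log(10.0)), method="bounded")
    sigma = float(math.exp(sol.x))
    return mu_for_mean(sigma), sigma


def generate_concentration_samples(
    spec: GeneratorSpec,
    category: str,
    metal: str,
    n: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw ``n`` concentration values for one (category, metal) cell.

    Values are exactly zero with the cell's zero fraction; positive values
    follow the truncated moment-matched lognormal, so no draw exceeds the
    reported maximum. Defaults to the cell's reported sample count.
    """
    stats = spec.concentrations[(category, metal)]
    if n is None:
        n = stats.n
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if stats.mean == 0.0:
        return np.zeros(n)
    p0 = spec.cell_zero_fraction(category, metal)
    q = 1.0 - p0
    if stats.sd == 0.0:
        if p0 > 0.0:
            raise FitError(
                f"{category}/{metal}: sd target 0 with zero fraction {p0} and "
                f"nonzero mean {stats.mean} is infeasible"
            )
        return np.full(n, stats.mean)
    pos_mean = stats.mean / q
    pos_m2 = (stats.mean**2 + stats.sd**2) / q
    pos_var = pos_m2 - pos_mean**2
    if pos_var <= 0:
        raise FitError(f"{category}/{metal}: zero fraction {p0} leaves no positive variance")
    mu, sigma = _solve_truncated_lognormal(pos_mean, math.sqrt(pos_var), stats.max)
    zeros = rng.random(n) < p0
    # inverse-CDF sampling restricted to (0, F(max)] keeps draws below max
    cap = norm.cdf((math.log(stats.max) - mu) / sigma)
    u = rng.random(n) * cap
    values = np.exp(mu + sigma * norm.ppf(u))
    values = np.minimum(values, stats.max)  # guard float round-up at the cap
    values[zeros] = 0.0
    return values


def generate_concentration_table(
    spec: GeneratorSpec, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Long-format sample table for every (category, metal) cell."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    rows = []
    for cat, metal in sorted(spec.concentrations, key=lambda k: (CATEGORIES.index(k[0]), k[1])):
        values = generate_concentration_samples(spec, cat, metal, rng=rng)
        for i, v in enumerate(values):
            rows.append({"category": cat, "metal": metal, "sample": i, "concentration": v})
    return pd.DataFrame(rows)


def generate_questionnaire(
    spec: GeneratorSpec,
    n: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Resident records: body weight plus per-category intake and frequency.

    Body weight is Poisson with the target mean (a discrete family, as the
    survey data were modeled); DI and EF are lognormal around the reported
    means at ``cv_intake``, with EF capped at 365 day/year.
    """
    if n is None:
        n = spec.resident_count
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    records: dict[str, np.ndarray] = {
        "resident": np.arange(n),
        "bw_kg": rng.poisson(spec.bw_mean, n).astype(float),
    }
    for cat in sorted(spec.factors, key=CATEGORIES.index):
        f = spec.factors[cat]
        records[f"di_{cat}"] = _lognormal_mean_cv(rng, f.di, spec.cv_intake, n)
        ef = _lognormal_mean_cv(rng, f.ef, spec.cv_intake, n)
        records[f"ef_{cat}"] = np.minimum(ef, DAYS_PER_YEAR)
    return pd.DataFrame(records)


def _lognormal_mean_cv(rng: np.random.Generator, mean: float, cv: float, n: int) -> np.ndarray:
    if mean == 0.0 or cv == 0.0:
        return np.full(n, mean)
    sigma2 = math.log1p(cv**2)
    return rng.lognormal(math.log(mean) - sigma2 / 2, math.sqrt(sigma2), n)


def summarize_samples(samples: Mapping[tuple[str, str], np.ndarray]) -> pd.DataFrame:
    """Mean/SD/min/max/n/zero-share summary of generated cells (QC helper)."""
    rows = []
    for (cat, metal), v in samples.items():
        v = np.asarray(v, dtype=float)
        rows.append(
            {
                "category": cat,
                "metal": metal,
                "mean": v.mean(),
                "sd": v.std(),
                "min": v.min(),
                "max": v.max(),
                "n": v.size,
                "zero_fraction": float(np.mean(v == 0.0)),
            }
        )
    return pd.DataFrame(rows)
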