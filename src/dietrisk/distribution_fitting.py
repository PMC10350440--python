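"""Candidate-distribution fitting and goodness-of-fit selection.

Continuous families are scored with the Anderson-Darling statistic,
discrete families with a Pearson chi-square statistic; the candidate with
the smallest statistic wins. Zero inflation (exact-zero non-detects) is
handled as a separate point mass at zero: families are fitted to the
strictly positive part of the data only and ``zero_mass`` records the
observed zero fraction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .exceptions import FitError, ValidationError

CONTINUOUS_FAMILIES = ("lognormal", "normal", "gamma", "weibull")
DISCRETE_FAMILIES = ("poisson", "negative_binomial")
FAMILIES = CONTINUOUS_FAMILIES + DISCRETE_FAMILIES


@dataclass(frozen=True)
class DistributionSpec:
    """A (possibly zero-inflated, shifted) parametric distribution.

    params by family:
      lognormal           (mu, sigma)     log-scale location/scale
      normal              (mu, sigma)
      gamma               (shape, scale)
      weibull             (shape, scale)
      poisson             (lam,)
      negative_binomial   (n, p)

    ``zero_mass`` is the probability of an exact zero; the remaining mass
    follows the parametric family shifted by ``location``. A degenerate
    scale of 0 is allowed and represents a point mass, whose exact value
    may be pinned via ``point_value`` to avoid exp(log(x)) round-off.
    """

    family: str
    params: tuple[float, ...]
    location: float = 0.0
    zero_mass: float = 0.0
    point_value: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValidationError(f"unknown family {self.family!r}")
        if not (0.0 <= self.zero_mass <= 1.0):
            raise ValidationError("zero_mass must be in [0, 1]")
        if self.location < 0:
            raise ValidationError("location must be >= 0")
        if self.zero_mass < 1.0:
            self._validate_params()

    def _validate_params(self) -> None:
        p = self.params
        if self.family in ("lognormal", "normal"):
            if len(p) != 2 or p[1] < 0:
                raise ValidationError(f"{self.family} needs (mu, sigma >= 0)")
        elif self.family in ("gamma", "weibull"):
            if len(p) != 2 or p[0] <= 0 or p[1] < 0:
                raise ValidationError(f"{self.family} needs (shape > 0, scale >= 0)")
        elif self.family == "poisson":
            if len(p) != 1 or p[0] < 0:
                raise ValidationError("poisson needs (lam >= 0,)")
        elif self.family == "negative_binomial":
            if len(p) != 2 or p[0] <= 0 or not (0 < p[1] <= 1):
                raise ValidationError("negative_binomial needs (n > 0, 0 < p <= 1)")

    # -- structural queries -------------------------------------------------

    @property
    def is_discrete(self) -> bool:
        return self.family in DISCRETE_FAMILIES

    @property
    def is_degenerate(self) -> bool:
        """True when the positive part is a point mass (scale parameter 0)."""
        if self.zero_mass >= 1.0:
            return True
        if self.family in ("lognormal", "normal", "gamma", "weibull"):
            return self.params[1] == 0.0
        return False

    def _point(self) -> float:
        if self.zero_mass >= 1.0:
            return 0.0
        if self.point_value is not None:
            return self.location + self.point_value
        if self.family == "lognormal":
            return self.location + math.exp(self.params[0])
        if self.family == "normal":
            return self.location + self.params[0]
        raise FitError(f"degenerate {self.family} has no defined point")

    def frozen(self):
        """scipy frozen distribution of the positive (continuous/discrete) part."""
        if self.is_degenerate:
            raise FitError("degenerate spec has no scipy counterpart")
        f, p = self.family, self.params
        if f == "lognormal":
            return sps.lognorm(s=p[1], scale=math.exp(p[0]))
        if f == "normal":
            return sps.norm(loc=p[0], scale=p[1])
        if f == "gamma":
            return sps.gamma(a=p[0], scale=p[1])
        if f == "weibull":
            return sps.weibull_min(c=p[0], scale=p[1])
        if f == "poisson":
            return sps.poisson(mu=p[0])
        if f == "negative_binomial":
            return sps.nbinom(n=p[0], p=p[1])
        raise AssertionError(f)

    # -- moments (of the full mixture, including the zero atom) -------------

    def _positive_moments(self) -> tuple[float, float]:
        """(mean, variance) of the shifted positive part."""
        if self.is_degenerate:
            return self._point(), 0.0
        if self.family == "lognormal":
            mu, sigma = self.params
            m = math.exp(mu + sigma**2 / 2)
            v = math.expm1(sigma**2) * math.exp(2 * mu + sigma**2)
        else:
            fr = self.frozen()
            m, v = float(fr.mean()), float(fr.var())
        return self.location + m, v

    def mean(self) -> float:
        if self.zero_mass >= 1.0:
            return 0.0
        return (1.0 - self.zero_mass) * self._positive_moments()[0]

    def sd(self) -> float:
        if self.zero_mass >= 1.0:
            return 0.0
        pos_m, pos_v = self._positive_moments()
        q = 1.0 - self.zero_mass
        var = q * pos_v + q * (1.0 - q) * pos_m**2
        return math.sqrt(var)

    # -- sampling and cdf ---------------------------------------------------

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.zero_mass >= 1.0:
            return np.zeros(size)
        if self.is_degenerate:
            out = np.full(size, self._point())
        else:
            out = self.location + np.asarray(
                self.frozen().rvs(size=size, random_state=rng), dtype=float
            )
        if self.zero_mass > 0.0:
            out = np.where(rng.random(size) < self.zero_mass, 0.0, out)
        return out

    def cdf(self, x) -> np.ndarray:
        """Mixture CDF: zero atom plus the shifted positive part."""
        x = np.asarray(x, dtype=float)
        if self.zero_mass >= 1.0:
            return np.where(x >= 0, 1.0, 0.0)
        if self.is_degenerate:
            cont = np.where(x >= self._point(), 1.0, 0.0)
        else:
            cont = self.frozen().cdf(x - self.location)
        return self.zero_mass * (x >= 0) + (1.0 - self.zero_mass) * cont


@dataclass(frozen=True)
class FitResult:
    """A fitted spec together with its goodness-of-fit statistic."""

    spec: DistributionSpec
    statistic: float
    test: str  # "anderson_darling" | "chi_square"

    def __post_init__(self) -> None:
        if not math.isfinite(self.statistic) or self.statistic < 0:
            raise ValidationError("statistic must be finite and >= 0")


def lognormal_from_moments(mean: float, sd: float) -> DistributionSpec:
    """Lognormal spec whose *arithmetic* mean and SD equal the inputs.

    Inverts mu = ln(mean) - sigma^2/2, sigma^2 = ln(1 + (sd/mean)^2).
    ``sd == 0`` yields a degenerate point mass at ``mean``.
    """
    if mean <= 0:
        raise ValidationError("mean must be > 0")
    if sd < 0:
        raise ValidationError("sd must be >= 0")
    if sd == 0:
        return DistributionSpec("lognormal", (math.log(mean), 0.0), point_value=mean)
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return DistributionSpec("lognormal", (mu, math.sqrt(sigma2)))


def zero_inflated_lognormal(mean: float, sd: float, zero_mass: float) -> DistributionSpec:
    """Zero-inflated lognormal whose *overall* mean/SD match the targets.

    The positive part is moment-matched so that the mixture (zero atom of
    probability ``zero_mass`` plus lognormal) has the requested arithmetic
    mean and SD. Infeasible combinations (all variance absorbed by the
    zero atom) raise :class:`FitError`.
    """
    if not (0.0 <= zero_mass < 1.0):
        raise ValidationError("zero_mass must be in [0, 1)")
    if zero_mass == 0.0:
        return lognormal_from_moments(mean, sd)
    q = 1.0 - zero_mass
    pos_mean = mean / q
    pos_m2 = (mean**2 + sd**2) / q
    pos_var = pos_m2 - pos_mean**2
    if pos_var <= 0:
        raise FitError(
            f"infeasible targets: zero_mass={zero_mass} absorbs more variance "
            f"than sd={sd} provides at mean={mean}"
        )
    spec = lognormal_from_moments(pos_mean, math.sqrt(pos_var))
    return DistributionSpec(spec.family, spec.params, zero_mass=zero_mass)


def anderson_darling_statistic(samples, spec: DistributionSpec) -> float:
    """A^2 = -n - (1/n) sum (2i-1)[ln F(x_i) + ln(1 - F(x_{n+1-i}))].

    Samples are sorted ascending internally; the spec must be continuous
    and must place every sample strictly inside (0, 1) of its CDF.
    """
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    if n < 1:
        raise ValidationError("need at least one sample")
    if spec.is_discrete:
        raise ValidationError("anderson_darling_statistic requires a continuous spec")
    f = np.asarray(spec.cdf(x), dtype=float)
    if np.any(f <= 0.0) or np.any(f >= 1.0):
        raise FitError("degenerate fit: CDF hits 0 or 1 at a sample")
    i = np.arange(1, n + 1)
    a2 = -n - np.sum((2 * i - 1) * (np.log(f) + np.log1p(-f[::-1]))) / n
    return float(a2)


def _merge_small_bins(edges: np.ndarray, expected: np.ndarray, min_expected: float):
    """Merge bins with small expectations inward from both tails."""
    edges = list(edges)
    expected = list(expected)
    while len(expected) > 1 and expected[0] < min_expected:
        expected[1] += expected[0]
        del expected[0], edges[1]
    while len(expected) > 1 and expected[-1] < min_expected:
        expected[-2] += expected[-1]
        del expected[-1], edges[-2]
    return np.asarray(edges), np.asarray(expected)


def chi_square_statistic(
    samples, spec: DistributionSpec, bins=None, min_expected: float = 5.0
) -> float:
    """Pearson chi-square statistic of samples against a spec.

    ``bins`` may be an explicit array of edges; by default Sturges' rule is
    applied (integer-aligned for discrete families) and bins with expected
    counts below ``min_expected`` are merged inward from the tails. The
    outermost bins are extended to cover the full support.
    """
    x = np.asarray(samples, dtype=float)
    n = x.size
    if n < 1:
        raise ValidationError("need at least one sample")
    if bins is None:
        k = max(2, int(np.ceil(np.log2(n) + 1)))  # Sturges
        lo, hi = x.min(), x.max()
        if spec.is_discrete:
            edges = np.unique(np.round(np.linspace(lo - 0.5, hi + 0.5, k + 1)) - 0.5)
        else:
            edges = np.linspace(lo, hi, k + 1)
        edges = edges.astype(float)
    else:
        edges = np.array(bins, dtype=float, copy=True)
    if edges.size < 3:
        raise ValidationError("need at least two bins")
    # open the tails so the expected counts sum to n
    edges[0], edges[-1] = -np.inf, np.inf
    cdf_at = spec.cdf(edges[1:-1])
    cum = np.concatenate(([0.0], np.atleast_1d(cdf_at), [1.0]))
    expected = n * np.diff(cum)
    if bins is None:
        edges, expected = _merge_small_bins(edges, expected, min_expected)
    if np.any(expected <= 0):
        raise FitError("empty expected bin; cannot compute chi-square")
    observed = np.histogram(x, bins=np.nan_to_num(edges, neginf=-1e300, posinf=1e300))[0]
    return float(np.sum((observed - expected) ** 2 / expected))


def _fit_positive(family: str, pos: np.ndarray) -> DistributionSpec:
    """Maximum-likelihood (or moment) fit of one family to positive data."""
    if pos.size == 0:
        raise FitError(f"{family}: no positive observations to fit")
    if family == "lognormal":
        logs = np.log(pos)
        return DistributionSpec("lognormal", (float(logs.mean()), float(logs.std())))
    if family == "normal":
        return DistributionSpec("normal", (float(pos.mean()), float(pos.std())))
    if family == "gamma":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a, _, scale = sps.gamma.fit(pos, floc=0)
        return DistributionSpec("gamma", (float(a), float(scale)))
    if family == "weibull":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            c, _, scale = sps.weibull_min.fit(pos, floc=0)
        return DistributionSpec("weibull", (float(c), float(scale)))
    if family == "poisson":
        return DistributionSpec("poisson", (float(pos.mean()),))
    if family == "negative_binomial":
        m, v = pos.mean(), pos.var()
        if v <= m:
            raise FitError("negative_binomial requires overdispersion (var > mean)")
        p = m / v
        return DistributionSpec("negative_binomial", (float(m * p / (1 - p)), float(p)))
    raise ValidationError(f"unknown family {family!r}")


def fit_family(samples, family: str) -> FitResult:
    """Fit one family to data (zero atom split off) and score it."""
    x = np.asarray(samples, dtype=float)
    zero_mass = float(np.mean(x == 0.0))
    pos = x[x > 0.0]
    spec = _fit_positive(family, pos)
    spec = DistributionSpec(spec.family, spec.params, zero_mass=zero_mass)
    pure = DistributionSpec(spec.family, spec.params)  # score the positive part alone
    if spec.is_discrete:
        stat = chi_square_statistic(pos, pure)
        test = "chi_square"
    else:
        stat = anderson_darling_statistic(pos, pure)
        test = "anderson_darling"
    return FitResult(spec=spec, statistic=stat, test=test)


def select_best_fit(samples, candidates) -> FitResult:
    """Fit every candidate family and return the smallest-statistic fit.

    Ties break toward the earlier candidate. Candidates whose fit is
    degenerate are skipped; if all fail, :class:`FitError` is raised.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValidationError("candidates must be non-empty")
    x = np.asarray(samples, dtype=float)
    if x.size < 5:
        raise ValidationError("need at least 5 samples to select a fit")
    best: FitResult | None = None
    errors = []
    for family in candidates:
        try:
            result = fit_family(x, family)
        except (FitError, ValidationError) as exc:
            errors.append(f"{family}: {exc}")
            continue
        if best is None or result.statistic < best.statistic:
            best = result
    if best is None:
        raise FitError("all candidate fits are degenerate: " + "; ".join(errors))
    return best
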