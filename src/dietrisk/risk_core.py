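"""Deterministic stage of the dietary risk pipeline.

Computes chronic daily doses from concentration and intake data, converts
them to hazard quotients (HQ) against oral reference doses, aggregates
hazard indices (HI) per food category, and evaluates the incremental
lifetime cancer risk (R) for arsenic via its oral slope factor.

All dose arithmetic accepts scalars or numpy arrays so the Monte Carlo
stage can reuse the exact same expressions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError

#: Canonical metal codes, in reporting order.
METALS: tuple[str, ...] = ("Al", "As", "Cr", "Cd", "Cu", "Ni", "Pb", "Zn")

#: Canonical food-category identifiers, in reporting order.
CATEGORIES: tuple[str, ...] = (
    "drinking_water",
    "meat",
    "cereal",
    "beans",
    "potatoes",
    "solanaceous_fruit",
    "vegetables",
    "fruit",
)

#: Human-readable display names keyed by canonical identifier.
DISPLAY_NAMES: dict[str, str] = {
    "drinking_water": "Drinking water",
    "meat": "Meat",
    "cereal": "Cereal",
    "beans": "Beans",
    "potatoes": "Potatoes",
    "solanaceous_fruit": "Solanaceous fruit",
    "vegetables": "Vegetables",
    "fruit": "Fruit",
}

#: Oral slope factor for arsenic, (kg*day)/mg.
ARSENIC_SLOPE_FACTOR = 1.5

#: Cancer-risk acceptability anchors (dimensionless lifetime probability).
R_NEGLIGIBLE = 1e-6
R_WHO = 1e-5
R_MAX_ACCEPTABLE = 1e-4

DAYS_PER_YEAR = 365.0


def medium_for(category: str) -> str:
    """Exposure medium of a category: ``water`` for drinking water, else ``food``."""
    validate_category(category)
    return "water" if category == "drinking_water" else "food"


def validate_metal(code: str) -> str:
    if code not in METALS:
        raise ValidationError(f"unknown metal code {code!r}; expected one of {METALS}")
    return code


def validate_category(name: str) -> str:
    if name not in CATEGORIES:
        raise ValidationError(
            f"unknown food category {name!r}; expected one of {CATEGORIES}"
        )
    return name


@dataclass(frozen=True)
class FoodCategory:
    """A food category together with its exposure medium."""

    name: str
    medium: str = field(default="")

    def __post_init__(self) -> None:
        validate_category(self.name)
        expected = "water" if self.name == "drinking_water" else "food"
        medium = self.medium or expected
        if medium != expected:
            raise ValidationError(
                f"category {self.name!r} must have medium {expected!r}, got {medium!r}"
            )
        object.__setattr__(self, "medium", medium)


@dataclass(frozen=True)
class ConcentrationStats:
    """Summary statistics of a metal's concentration in one food category.

    Units are mg/kg for foods and mg/L for drinking water (density 1 g/mL
    makes the two interchangeable in the dose equation).
    """

    category: str
    metal: str
    mean: float
    sd: float
    min: float
    max: float
    n: int
    safe_limit: float

    def __post_init__(self) -> None:
        validate_category(self.category)
        validate_metal(self.metal)
        for name in ("mean", "sd", "min", "max", "safe_limit"):
            if getattr(self, name) < 0:
                raise ValidationError(
                    f"{self.category}/{self.metal}: {name} must be >= 0"
                )
        if not (self.min <= self.mean <= self.max):
            raise ValidationError(
                f"{self.category}/{self.metal}: need min <= mean <= max "
                f"({self.min} <= {self.mean} <= {self.max})"
            )
        if self.n < 1:
            raise ValidationError(f"{self.category}/{self.metal}: n must be >= 1")


@dataclass(frozen=True)
class ExposureFactors:
    """Per-category intake factors of an (average) resident.

    di: daily intake, g/day (mL/day for water at density 1 g/mL)
    ef: exposure frequency, day/year
    ed: exposure duration, years
    bw: body weight, kg
    lt: averaging lifetime, years
    """

    category: str
    di: float
    ef: float
    ed: float
    bw: float
    lt: float = 70.0

    def __post_init__(self) -> None:
        validate_category(self.category)
        if self.di < 0:
            raise ValidationError(f"{self.category}: di must be >= 0")
        if not (0 <= self.ef <= DAYS_PER_YEAR):
            raise ValidationError(f"{self.category}: ef must be in [0, 365]")
        if self.ed <= 0:
            raise ValidationError(f"{self.category}: ed must be > 0")
        if self.bw <= 0:
            raise ValidationError(f"{self.category}: bw must be > 0")
        if self.lt <= 0:
            raise ValidationError(f"{self.category}: lt must be > 0")
        if self.ed > self.lt:
            raise ValidationError(f"{self.category}: ed must not exceed lt")


@dataclass(frozen=True)
class ToxicityReference:
    """Oral reference dose (and optional slope factor) for a metal/medium pair."""

    metal: str
    medium: str
    rfd: float
    sf: float | None = None

    def __post_init__(self) -> None:
        validate_metal(self.metal)
        if self.medium not in ("water", "food"):
            raise ValidationError(f"medium must be 'water' or 'food', got {self.medium!r}")
        if self.rfd <= 0:
            raise ValidationError(f"{self.metal}/{self.medium}: rfd must be > 0")
        if self.sf is not None and self.metal != "As":
            raise ValidationError(f"slope factor only defined for As, not {self.metal}")


def daily_dose(c, di, ef, ed, bw, lt):
    """Chronic daily dose, mg/(kg*day).

    ``C * (DI/1000) * EF * ED / (BW * LT * 365)`` — concentration in mg/kg,
    intake in g/day (hence the /1000), frequency in day/year, duration and
    lifetime in years, body weight in kg. Accepts scalars or arrays.
    """
    c = np.asarray(c, dtype=float) if np.ndim(c) else c
    if np.any(np.asarray(c) < 0):
        raise ValidationError("concentration must be >= 0")
    if np.any(np.asarray(bw) <= 0) or np.any(np.asarray(lt) <= 0):
        raise ValidationError("bw and lt must be > 0")
    return c * (np.asarray(di, dtype=float) / 1000.0) * ef * ed / (
        np.asarray(bw, dtype=float) * lt * DAYS_PER_YEAR
    )


def compute_expo(c, factors: ExposureFactors):
    """Daily dose for concentration ``c`` under validated exposure factors."""
    return daily_dose(c, factors.di, factors.ef, factors.ed, factors.bw, factors.lt)


def hazard_quotient(expo, rfd: float):
    """HQ = dose / reference dose. HQ >= 1 flags a serious noncarcinogenic risk."""
    if rfd <= 0:
        raise ValidationError("rfd must be > 0")
    if np.any(np.asarray(expo) < 0):
        raise ValidationError("expo must be >= 0")
    return expo / rfd


def hazard_index(hqs: Iterable):
    """HI = sum of hazard quotients; HI <= 1 means no notable adverse effect."""
    hqs = list(hqs)
    if not hqs:
        raise ValidationError("hazard_index requires at least one HQ")
    if any(np.any(np.asarray(h) < 0) for h in hqs):
        raise ValidationError("all HQs must be >= 0")
    return sum(hqs)


def carcinogenic_risk(expo, sf: float | None):
    """R = slope factor * dose: incremental lifetime cancer probability."""
    if sf is None:
        raise ValidationError("metal has no slope factor; carcinogenic risk undefined")
    if sf <= 0:
        raise ValidationError("slope factor must be > 0")
    if np.any(np.asarray(expo) < 0):
        raise ValidationError("expo must be >= 0")
    return sf * expo


def over_limit_ratio(samples: Sequence[float], limit: float) -> float:
    """Percentage of samples strictly above a regulatory limit, 1-decimal rounded."""
    samples = list(samples)
    if not samples:
        raise ValidationError("over_limit_ratio requires a non-empty sample list")
    if limit <= 0:
        raise ValidationError("limit must be > 0")
    frac = sum(1 for s in samples if s > limit) / len(samples)
    return round(100.0 * frac, 1)


@dataclass
class RiskTable:
    """Deterministic risk surface: per-category HQ per metal, HI, and As risk."""

    hq: dict[str, dict[str, float]]
    hi: dict[str, float]
    r: dict[str, float]

    @property
    def tthq(self) -> float:
        """Grand total of the per-category hazard indices."""
        return float(sum(self.hi.values()))

    @property
    def tr(self) -> float:
        """Grand total of the per-category arsenic cancer risks."""
        return float(sum(self.r.values()))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cat in self.hq:
            row: dict[str, object] = {"category": cat}
            row.update({f"HQ_{m}": self.hq[cat][m] for m in METALS})
            row["HI"] = self.hi[cat]
            row["R_As"] = self.r[cat]
            rows.append(row)
        total: dict[str, object] = {"category": "TOTAL"}
        total.update({f"HQ_{m}": float("nan") for m in METALS})
        total["HI"] = self.tthq
        total["R_As"] = self.tr
        rows.append(total)
        return pd.DataFrame(rows)


def build_risk_table(
    stats: Mapping[tuple[str, str], ConcentrationStats],
    factors: Mapping[str, ExposureFactors],
    tox: Mapping[tuple[str, str], ToxicityReference],
) -> RiskTable:
    """Assemble the full deterministic risk table from input tables.

    ``stats`` maps (category, metal) to concentration summaries, ``factors``
    maps category to exposure factors, and ``tox`` maps (metal, medium) to
    reference values. RfDs are matched by the category's medium.
    """
    categories = sorted({cat for cat, _ in stats}, key=CATEGORIES.index)
    missing = []
    for cat in categories:
        med = medium_for(cat)
        for metal in METALS:
            if (metal, med) not in tox:
                missing.append(f"{metal}/{med}")
    if missing:
        raise ValidationError("missing RfD entries: " + ", ".join(sorted(set(missing))))

    hq: dict[str, dict[str, float]] = {}
    hi: dict[str, float] = {}
    r: dict[str, float] = {}
    for cat in categories:
        if cat not in factors:
            raise ValidationError(f"missing exposure factors for category {cat!r}")
        med = medium_for(cat)
        f = factors[cat]
        hq[cat] = {}
        for metal in METALS:
            key = (cat, metal)
            if key not in stats:
                raise ValidationError(f"missing concentration entry for {cat}/{metal}")
            expo = compute_expo(stats[key].mean, f)
            hq[cat][metal] = float(hazard_quotient(expo, tox[(metal, med)].rfd))
        hi[cat] = float(hazard_index(hq[cat].values()))
        sf = tox[("As", med)].sf
        expo_as = compute_expo(stats[(cat, "As")].mean, f)
        r[cat] = float(carcinogenic_risk(expo_as, sf if sf is not None else ARSENIC_SLOPE_FACTOR))
    return RiskTable(hq=hq, hi=hi, r=r)


def classify_cancer_risk(r: float) -> str:
    """Bucket a cancer risk against the 1e-6 / 1e-5 / 1e-4 anchors."""
    if r < 0:
        raise ValidationError("risk must be >= 0")
    if r <= R_NEGLIGIBLE:
        return "negligible (<=1e-6)"
    if r <= R_WHO:
        return "between negligible (1e-6) and WHO (1e-5) levels"
    if r <= R_MAX_ACCEPTABLE:
        return "between WHO (1e-5) and maximum acceptable (1e-4) levels"
    return "above maximum acceptable level (1e-4)"
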