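"""Contribution-to-variance sensitivity analysis over Monte Carlo draws.

Each input's contribution is the signed, normalized squared Spearman rank
correlation with the output: positive contributions mean the input pushes
the risk up, and absolute contributions sum to 100%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .exceptions import ValidationError


def rank_correlation(x, y) -> float:
    """Spearman correlation: Pearson correlation of midranks.

    Constant inputs cannot be ranked against anything; they yield 0.0 with
    a warning so downstream contributions treat them as inert.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-d arrays of equal length")
    if x.size < 3:
        raise ValidationError("need at least 3 paired draws")
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("constant input in rank_correlation; returning 0.0", stacklevel=2)
        return 0.0
    rx, ry = rankdata(x), rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(np.dot(rx, ry) / np.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))


@dataclass(frozen=True)
class SensitivityReport:
    """Signed contribution percentages, ordered by descending |contribution|."""

    contributions: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        total = sum(abs(c) for _, c in self.contributions)
        if abs(total - 100.0) > 1e-9:
            raise ValidationError("absolute contributions must sum to 100%")

    def ranking(self) -> list[str]:
        return [name for name, _ in self.contributions]

    def as_dict(self) -> dict[str, float]:
        return dict(self.contributions)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.contributions, columns=["variable", "contribution_pct"])


def contribution_to_variance(
    inputs: Mapping[str, np.ndarray], output
) -> SensitivityReport:
    """Apportion output variance among inputs by signed squared rank correlation.

    contribution_i = sign(rho_i) * 100 * rho_i^2 / sum_j rho_j^2
    """
    if not inputs:
        raise ValidationError("need at least one input variable")
    output = np.asarray(output, dtype=float)
    rhos = {name: rank_correlation(draws, output) for name, draws in inputs.items()}
    denom = sum(r * r for r in rhos.values())
    if denom == 0.0:
        raise ValidationError("all rank correlations are zero; no attributable variance")
    contribs = {
        name: float(np.sign(r)) * 100.0 * r * r / denom for name, r in rhos.items()
    }
    ordered = sorted(contribs.items(), key=lambda kv: abs(kv[1]), reverse=True)
    return SensitivityReport(contributions=tuple(ordered))
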