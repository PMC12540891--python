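"""Fit-quality statistics: AARD, R2, adjusted R2.

AARD (average absolute relative deviation, %) is the ranking statistic of
the supercritical-solubility correlation literature; it is computed on the
mole-fraction scale, not in log space. R2 is likewise computed on the
linear y scale for every model — including models fitted in log space — so
that cross-model comparisons are uniform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FitStatistics", "aard", "r_squared", "r2_adjusted", "fit_statistics"]


@dataclass(frozen=True)
class FitStatistics:
    aard_pct: float
    r2: float
    r2_adj: float
    n_points: int
    n_params: int

    def __post_init__(self) -> None:
        if self.aard_pct < 0:
            raise ValueError("aard_pct must be non-negative")
        if self.n_points <= self.n_params:
            raise ValueError("need n_points > n_params")


def _as_pair(y_exp, y_calc) -> tuple[np.ndarray, np.ndarray]:
    y_exp = np.asarray(y_exp, dtype=float)
    y_calc = np.asarray(y_calc, dtype=float)
    if y_exp.shape != y_calc.shape:
        raise ValueError(f"length mismatch: {y_exp.shape} vs {y_calc.shape}")
    if y_exp.size == 0:
        raise ValueError("empty input")
    return y_exp, y_calc


def aard(y_exp, y_calc) -> float:
    """(100/N) * sum |y_calc - y_exp| / y_exp, in percent."""
    y_exp, y_calc = _as_pair(y_exp, y_calc)
    if np.any(y_exp <= 0):
        raise ValueError("AARD requires strictly positive reference values")
    return 100.0 * float(np.mean(np.abs(y_calc - y_exp) / y_exp))


def r_squared(y_exp, y_calc) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot on the y scale."""
    y_exp, y_calc = _as_pair(y_exp, y_calc)
    ss_tot = float(np.sum((y_exp - y_exp.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("zero variance in y_exp")
    ss_res = float(np.sum((y_exp - y_calc) ** 2))
    return 1.0 - ss_res / ss_tot


def r2_adjusted(y_exp, y_calc, n_params: int) -> float:
    """Adjusted R2 = 1 - (1 - R2)(N - 1)/(N - n_params - 1)."""
    y_exp, y_calc = _as_pair(y_exp, y_calc)
    n = y_exp.size
    if n <= n_params + 1:
        raise ValueError("need N > n_params + 1")
    r2 = r_squared(y_exp, y_calc)
    return 1.0 - (1.0 - r2) * (n - 1) / (n - n_params - 1)


def fit_statistics(y_exp, y_calc, n_params: int) -> FitStatistics:
    y_exp, y_calc = _as_pair(y_exp, y_calc)
    return FitStatistics(
        aard_pct=aard(y_exp, y_calc),
        r2=r_squared(y_exp, y_calc),
        r2_adj=r2_adjusted(y_exp, y_calc, n_params),
        n_points=int(y_exp.size),
        n_params=int(n_params),
    )
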