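"""Density-based solubility correlations and derived thermodynamics.

Four three-parameter semi-empirical models relate the solute mole fraction
y to the solvent density rho (kg/m3) and temperature T (K):

  Chrastil            ln y = a0 + a1 ln(rho) + a2/T
  Kumar-Johnston (KJ) ln y = a0 + a1 rho + a2/T
  Bartle et al.       ln(y P / P_ref) = a0 + a1/T + a2 (rho - rho_ref)
  Mendez-Santiago-Teja (MST)   T ln(y P) = a0 + a1 rho + a2 T

The Chrastil picture is an equilibrium solvato-complex: a1 plays the role
of an association number and the 1/T coefficient carries the total heat of
dissolution (dH_total = -R a2). The Bartle 1/T coefficient carries the
solute's vaporization/sublimation enthalpy (dH_vap = -R a1) because its
density term removes the solvent contribution; the difference
dH_sol = dH_total - dH_vap estimates the (exothermic) solvation heat.

Pressure enters Bartle and MST through the product y*P expressed in bar
(P_ref = 1 bar, rho_ref = 700 kg/m3), the prevailing convention in this
literature.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize, stats

from .constants import R
from .data_core import SolubilityDataset
from .metrics import FitStatistics, aard, fit_statistics

__all__ = [
    "MODEL_IDS",
    "DensityModelParams",
    "DensityModelFit",
    "DerivedEnthalpies",
    "predict",
    "fit_model",
    "fit_all",
    "derive_enthalpies",
    "mst_consistency_points",
    "find_crossover",
]

MODEL_IDS = ("chrastil", "bartle", "mst", "kj")

_MPA_TO_BAR = 10.0


@dataclass(frozen=True)
class DensityModelParams:
    """Coefficients of one correlation. Units depend on the model: a2 is in
    K for chrastil/kj (the 1/T coefficient), a1 is in K for bartle. P_ref
    (bar) and rho_ref (kg/m3) are used by bartle only."""

    model_id: str
    a0: float
    a1: float
    a2: float
    P_ref: float = 1.0
    rho_ref: float = 700.0
    pressure_unit: str = "bar"  # unit of P inside the y*P products (bartle/mst)

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_IDS:
            raise ValueError(f"unknown model {self.model_id!r}; expected one of {MODEL_IDS}")
        if self.P_ref <= 0 or self.rho_ref <= 0:
            raise ValueError("P_ref and rho_ref must be positive")
        if self.pressure_unit not in ("bar", "mpa"):
            raise ValueError("pressure_unit must be 'bar' or 'mpa'")


@dataclass(frozen=True)
class DensityModelFit:
    params: DensityModelParams
    stats: FitStatistics
    residuals: np.ndarray  # per-point relative deviations (y_calc - y_exp)/y_exp

    def __post_init__(self) -> None:
        if self.stats.n_params != 3:
            raise ValueError("density models have exactly 3 parameters")


@dataclass(frozen=True)
class DerivedEnthalpies:
    """Apparent dissolution thermochemistry (kJ/mol), from the Chrastil and
    Bartle 1/T coefficients."""

    dH_total: float
    dH_vap: float
    dH_sol: float


def predict(params: DensityModelParams, T, P, rho):
    """Model mole fraction at (T [K], P [MPa], rho [kg/m3]). Vectorized."""
    T = np.asarray(T, dtype=float)
    P = np.asarray(P, dtype=float)
    rho = np.asarray(rho, dtype=float)
    if np.any(T <= 0) or np.any(P <= 0) or np.any(rho <= 0):
        raise ValueError("T, P, rho must all be positive")
    a0, a1, a2 = params.a0, params.a1, params.a2
    m = params.model_id
    if m == "chrastil":
        return np.exp(a0 + a1 * np.log(rho) + a2 / T)
    if m == "kj":
        return np.exp(a0 + a1 * rho + a2 / T)
    P_u = P * (_MPA_TO_BAR if params.pressure_unit == "bar" else 1.0)
    if m == "bartle":
        return (params.P_ref / P_u) * np.exp(a0 + a1 / T + a2 * (rho - params.rho_ref))
    # mst
    return np.exp((a0 + a1 * rho + a2 * T) / T) / P_u


def _design_matrix(model_id: str, T, P_bar, rho, y, P_ref, rho_ref):
    """Linearized form (X, z) of each model, used to seed the optimizer."""
    if model_id == "chrastil":
        X = np.column_stack([np.ones_like(T), np.log(rho), 1.0 / T])
        z = np.log(y)
    elif model_id == "kj":
        X = np.column_stack([np.ones_like(T), rho, 1.0 / T])
        z = np.log(y)
    elif model_id == "bartle":
        X = np.column_stack([np.ones_like(T), 1.0 / T, rho - rho_ref])
        z = np.log(y * P_bar / P_ref)
    else:  # mst
        X = np.column_stack([np.ones_like(T), rho, T])
        z = T * np.log(y * P_bar)
    return X, z


# Fixed multiplicative perturbations applied to the linearized least-squares
# solution to build a deterministic 8-point start grid for the simplex.
_START_SCALES = np.array(
    [
        [1.0, 1.0, 1.0],
        [1.02, 1.0, 1.0],
        [1.0, 1.05, 1.0],
        [1.0, 1.0, 1.05],
        [0.98, 0.95, 1.0],
        [1.0, 0.95, 0.95],
        [1.05, 1.0, 0.95],
        [0.95, 1.05, 1.05],
    ]
)


def fit_model(
    model_id: str,
    dataset: SolubilityDataset,
    objective: str = "aard",
    P_ref: float = 1.0,
    rho_ref: float = 700.0,
    pressure_unit: str = "bar",
) -> DensityModelFit:
    """Fit one correlation to a dataset.

    ``objective="aard"`` (default) minimizes the mean absolute relative
    deviation of y directly — the statistic the models are ranked by.
    ``objective="sse_log"`` minimizes the residual sum of squares in the
    model's linearized space (equivalent to the common log-space least
    squares fit, and available in closed form).

    The optimizer is a Nelder-Mead simplex restarted from a fixed 8-point
    grid around the linearized least-squares solution; it uses no random
    numbers, so repeated calls agree bitwise.
    """
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model {model_id!r}")
    if objective not in ("aard", "sse_log"):
        raise ValueError("objective must be 'aard' or 'sse_log'")
    T, P, rho, y = dataset.arrays()
    if np.unique(T).size < 2 or T.size < 4:
        raise ValueError("need at least 2 temperatures and 4 points")
    P_u = P * (_MPA_TO_BAR if pressure_unit == "bar" else 1.0)
    X, z = _design_matrix(model_id, T, P_u, rho, y, P_ref, rho_ref)
    theta_ls, *_ = np.linalg.lstsq(X, z, rcond=None)

    def mk_params(theta) -> DensityModelParams:
        return DensityModelParams(
            model_id, *map(float, theta), P_ref=P_ref, rho_ref=rho_ref, pressure_unit=pressure_unit
        )

    if objective == "sse_log":
        best = theta_ls
    else:

        def obj(theta):
            y_calc = predict(mk_params(theta), T, P, rho)
            return float(np.mean(np.abs(y_calc - y) / y))

        best, best_val = None, np.inf
        for scale in _START_SCALES:
            res = optimize.minimize(
                obj,
                theta_ls * scale,
                method="Nelder-Mead",
                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000, "maxfev": 4000},
            )
            if res.fun < best_val:
                best, best_val = res.x, res.fun
        if best is None:
            raise RuntimeError("all simplex starts failed")

    params = mk_params(best)
    y_calc = predict(params, T, P, rho)
    return DensityModelFit(
        params=params,
        stats=fit_statistics(y, y_calc, n_params=3),
        residuals=(y_calc - y) / y,
    )


def fit_all(
    dataset: SolubilityDataset, objective: str = "aard", pressure_unit: str = "bar"
) -> dict[str, DensityModelFit]:
    return {
        m: fit_model(m, dataset, objective=objective, pressure_unit=pressure_unit) for m in MODEL_IDS
    }


def derive_enthalpies(chrastil_fit: DensityModelFit, bartle_fit: DensityModelFit) -> DerivedEnthalpies:
    """Apparent enthalpies (kJ/mol) from the fitted 1/T coefficients:
    dH_total = -R * a2(chrastil); dH_vap = -R * a1(bartle);
    dH_sol = dH_total - dH_vap.
    """
    if chrastil_fit.params.model_id != "chrastil":
        raise ValueError("first argument must be a Chrastil fit")
    if bartle_fit.params.model_id != "bartle":
        raise ValueError("second argument must be a Bartle fit")
    dh_total = -R * chrastil_fit.params.a2 / 1000.0
    dh_vap = -R * bartle_fit.params.a1 / 1000.0
    return DerivedEnthalpies(dH_total=dh_total, dH_vap=dh_vap, dH_sol=dh_total - dh_vap)


def mst_consistency_points(dataset: SolubilityDataset, mst_fit: DensityModelFit) -> np.ndarray:
    """Self-consistency transform of the MST model.

    Returns an (n, 2) array of (rho_i, T_i ln(y_i P_i) - a2 T_i) with P in
    bar. Under the MST form this quantity is a0 + a1 rho, so thermodynamically
    consistent data collapse onto a single straight line in density across
    all isotherms.
    """
    if mst_fit.params.model_id != "mst":
        raise ValueError("mst_fit must be an MST fit")
    T, P, rho, y = dataset.arrays()
    if T.size < 2:
        raise ValueError("need at least 2 points to assess linearity")
    scale = _MPA_TO_BAR if mst_fit.params.pressure_unit == "bar" else 1.0
    val = T * np.log(y * P * scale) - mst_fit.params.a2 * T
    return np.column_stack([rho, val])


def find_crossover(dataset: SolubilityDataset) -> tuple[float, float] | None:
    """Locate the crossover pressure interval on the measurement grid.

    Below the crossover, solubility falls with temperature at fixed P (the
    density effect dominates); above it, solubility rises with temperature
    (the sublimation-pressure effect dominates). For each grid pressure the
    Spearman correlation of y with T is computed; the interval of adjacent
    pressures where its sign flips from negative to positive is returned as
    (P_low, P_high) in MPa, or None with no sign change. Reported as a grid
    interval rather than an interpolated point: the data live on a coarse
    pressure grid.
    """
    if dataset.temperatures.size < 2:
        raise ValueError("need at least 2 isotherms")
    pressures = dataset.pressures
    signs = []
    for p in pressures:
        recs = sorted((r for r in dataset.records if r.P == p), key=lambda r: r.T)
        if len(recs) < 2:
            raise ValueError(f"pressure {p} MPa not shared across isotherms")
        rho_s = stats.spearmanr([r.T for r in recs], [r.y for r in recs]).statistic
        signs.append(np.sign(rho_s))
    for i in range(len(signs) - 1):
        if signs[i] < 0 <= signs[i + 1]:
            return float(pressures[i]), float(pressures[i + 1])
    return None
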