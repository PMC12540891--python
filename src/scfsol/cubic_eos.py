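"""Peng-Robinson and Soave-Redlich-Kwong equations of state with two-
parameter van der Waals (vdW2) mixing rules, and solid-fluid equilibrium.

Both are two-parameter cubics

    P = RT/(v - b) - a(T) / ((v + d1*b)(v + d2*b))

with (d1, d2) = (1+sqrt(2), 1-sqrt(2)) for PR and (1, 0) for SRK. Mixture
parameters use quadratic composition mixing for both a and b:

    a_m = sum_ij y_i y_j sqrt(a_i a_j)(1 - k_ij)
    b_m = sum_ij y_i y_j (b_i + b_j)/2 (1 - l_ij)

which makes b composition-dependent; the partial-molar covolume
b_bar_i = 2 sum_j y_j b_ij - b_m therefore enters the fugacity expression.

The solid solubility y2 solves the solid-fluid isofugacity condition

    y2 = (P_sub/P) * (1/phi2(T, P, y)) * exp[v_s (P - P_sub)/(RT)]

with the solute's saturated-vapor fugacity coefficient taken as 1 (its
sublimation pressure is tiny). Per isotherm, (k_ij, l_ij) are regressed by
direct AARD minimization.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt

import numpy as np
from scipy import optimize

from .constants import R
from .data_core import SolubilityDataset
from .metrics import FitStatistics, fit_statistics
from .solute_props import SolutePropertySet, SolventPropertySet, sublimation_pressure

__all__ = [
    "CubicPureParams",
    "BinaryInteraction",
    "CubicEosIsothermFit",
    "pure_params",
    "mix_params",
    "solve_Z",
    "fugacity_coefficients",
    "solid_solubility",
    "fit_isotherm",
    "fit_all_isotherms",
]

_DELTAS = {"pr": (1.0 + sqrt(2.0), 1.0 - sqrt(2.0)), "srk": (1.0, 0.0)}
_OMEGA_A = {"pr": 0.45724, "srk": 0.42747}
_OMEGA_B = {"pr": 0.0778, "srk": 0.08664}


class EosError(RuntimeError):
    """Unphysical state or failed equilibrium solve."""


@dataclass(frozen=True)
class CubicPureParams:
    a: float  # Pa m6 / mol2, includes alpha(T)
    b: float  # m3 / mol
    eos: str

    def __post_init__(self) -> None:
        if self.eos not in _DELTAS:
            raise ValueError("eos must be 'pr' or 'srk'")
        if self.a < 0 or self.b <= 0:
            raise ValueError("need a >= 0 and b > 0")


@dataclass(frozen=True)
class BinaryInteraction:
    k_ij: float = 0.0
    l_ij: float = 0.0

    def __post_init__(self) -> None:
        if not (abs(self.k_ij) < 1 and abs(self.l_ij) < 1):
            raise ValueError("interaction parameters must lie in (-1, 1)")


@dataclass(frozen=True)
class CubicEosIsothermFit:
    T: float
    eos: str
    interaction: BinaryInteraction
    stats: FitStatistics
    y_calc: np.ndarray

    def __post_init__(self) -> None:
        if self.stats.n_params != 2:
            raise ValueError("cubic-EoS isotherm fits have 2 parameters")


def alpha_slope(eos: str, omega: float) -> float:
    """Acentric-factor polynomial of the alpha function (PR 'k', SRK 'm')."""
    if eos == "pr":
        return 0.37464 + 1.5422 * omega - 0.26992 * omega**2
    return 0.480 + 1.574 * omega - 0.176 * omega**2


def pure_params(eos: str, Tc: float, Pc: float, omega: float, T: float) -> CubicPureParams:
    """Temperature-dependent pure-component (a, b)."""
    if min(T, Tc, Pc) <= 0:
        raise ValueError("T, Tc, Pc must be positive")
    if eos not in _DELTAS:
        raise ValueError("eos must be 'pr' or 'srk'")
    tr = T / Tc
    s = alpha_slope(eos, omega)
    alpha = (1.0 + s * (1.0 - sqrt(tr))) ** 2
    a = _OMEGA_A[eos] * R**2 * Tc**2 / Pc * alpha
    b = _OMEGA_B[eos] * R * Tc / Pc
    return CubicPureParams(a=a, b=b, eos=eos)


def _pair_arrays(pures: list[CubicPureParams], interaction: BinaryInteraction):
    a = np.array([p.a for p in pures])
    b = np.array([p.b for p in pures])
    n = len(pures)
    K = np.zeros((n, n))
    L = np.zeros((n, n))
    if n == 2:
        K[0, 1] = K[1, 0] = interaction.k_ij
        L[0, 1] = L[1, 0] = interaction.l_ij
    elif n > 2:
        raise ValueError("only pure and binary systems are supported")
    a_ij = np.sqrt(np.outer(a, a)) * (1.0 - K)
    b_ij = 0.5 * (b[:, None] + b[None, :]) * (1.0 - L)
    return a_ij, b_ij


def mix_params(y, pures: list[CubicPureParams], interaction: BinaryInteraction) -> tuple[float, float]:
    """vdW2 quadratic mixing: (a_m, b_m)."""
    y = np.asarray(y, dtype=float)
    if abs(y.sum() - 1.0) > 1e-12:
        raise ValueError("composition must sum to 1")
    if len({p.eos for p in pures}) != 1:
        raise ValueError("all components must use the same EoS")
    a_ij, b_ij = _pair_arrays(pures, interaction)
    a_m = float(y @ a_ij @ y)
    b_m = float(y @ b_ij @ y)
    return a_m, b_m


def solve_Z(eos: str, A: float, B: float) -> np.ndarray:
    """Real compressibility-factor roots greater than B, ascending.

    The cubic in Z for a general two-parameter EoS with u = d1 + d2 and
    w = d1*d2 is Z^3 + (uB - B - 1) Z^2 + (wB^2 - uB^2 - uB + A) Z
    - (wB^3 + wB^2 + AB) = 0.
    """
    if eos not in _DELTAS:
        raise ValueError("eos must be 'pr' or 'srk'")
    if B < 0:
        raise ValueError("B must be non-negative")
    d1, d2 = _DELTAS[eos]
    u, w = d1 + d2, d1 * d2
    coeffs = [
        1.0,
        (u - 1.0) * B - 1.0,
        w * B**2 - u * B**2 - u * B + A,
        -(w * B**3 + w * B**2 + A * B),
    ]
    roots = np.roots(coeffs)
    real = np.sort(roots[np.abs(roots.imag) < 1e-9].real)
    real = real[real > B]
    if real.size == 0:
        raise EosError(f"no physical root (A={A}, B={B})")
    return real


def _ln_phi_at_Z(eos, T, P, y, pures, interaction, Z) -> np.ndarray:
    d1, d2 = _DELTAS[eos]
    y = np.asarray(y, dtype=float)
    a_ij, b_ij = _pair_arrays(pures, interaction)
    a_m = float(y @ a_ij @ y)
    b_m = float(y @ b_ij @ y)
    D_i = 2.0 * a_ij @ y  # partial d(n^2 a)/dn_i
    B_i = 2.0 * b_ij @ y - b_m  # partial molar covolume
    v = Z * R * T / P
    Lg = np.log((v + d1 * b_m) / (v + d2 * b_m))
    term_rep = np.log(v / (v - b_m)) + B_i / (v - b_m)
    term_att = (
        (D_i * b_m - a_m * B_i) / b_m**2 * Lg
        + (a_m / b_m) * B_i * (d1 / (v + d1 * b_m) - d2 / (v + d2 * b_m))
    ) / (R * T * (d1 - d2))
    return term_rep - term_att - np.log(Z)


def fugacity_coefficients(
    eos: str,
    T: float,
    P: float,
    y,
    pures: list[CubicPureParams],
    interaction: BinaryInteraction,
) -> np.ndarray:
    """Fugacity coefficients phi_i at (T [K], P [Pa], composition y).

    Closed-form for two-parameter cubics with composition-dependent a_m and
    b_m. When the cubic has several real roots the one minimizing the
    mixture residual Gibbs energy (sum_i y_i ln phi_i) is selected.
    """
    y = np.asarray(y, dtype=float)
    a_m, b_m = mix_params(y, pures, interaction)
    A = a_m * P / (R * T) ** 2
    B = b_m * P / (R * T)
    roots = solve_Z(eos, A, B)
    best, best_g = None, np.inf
    for Z in roots:
        ln_phi = _ln_phi_at_Z(eos, T, P, y, pures, interaction, Z)
        g = float(y @ ln_phi)
        if g < best_g:
            best, best_g = ln_phi, g
    return np.exp(best)


def solid_solubility(
    eos: str,
    T: float,
    P: float,
    solute: SolutePropertySet,
    solvent: SolventPropertySet,
    interaction: BinaryInteraction,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> float:
    """Equilibrium solute mole fraction y2 from the isofugacity condition.

    Solved by damped fixed-point iteration starting at y2 = 1e-8; a damping
    factor of 0.5 is applied when the update direction oscillates.
    T in K, P in Pa.
    """
    p_sub = sublimation_pressure(solute, T)
    pures = [
        pure_params(eos, solvent.Tc, solvent.Pc, solvent.omega, T),
        pure_params(eos, solute.Tc, solute.Pc, solute.omega, T),
    ]
    poynting = np.exp(solute.v_solid * (P - p_sub) / (R * T))
    y2 = 1e-8
    prev_step = 0.0
    lam = 1.0  # damping factor, halved on oscillation or step growth
    for _ in range(max_iter):
        phi2 = fugacity_coefficients(eos, T, P, [1.0 - y2, y2], pures, interaction)[1]
        y_star = (p_sub / P) / phi2 * poynting
        step = y_star - y2
        if abs(step) <= tol * max(y2, 1e-300):
            if y_star >= 1.0:
                raise EosError(f"unphysical solubility y2={y_star} at T={T}, P={P}")
            return float(y_star)
        if step * prev_step < 0 or abs(step) > 2.0 * abs(prev_step) > 0:
            lam = max(0.5 * lam, 1.0 / 64.0)
        prev_step = step
        y2 = min(max(y2 + lam * step, 1e-14), 0.9)
    raise EosError(f"fixed point did not converge at T={T}, P={P} (last y2={y2})")


def _isotherm_aard(eos, T, P_pa, y_exp, solute, solvent, kij, lij) -> tuple[float, np.ndarray]:
    inter = BinaryInteraction(k_ij=kij, l_ij=lij)
    y_calc = np.empty_like(y_exp)
    for i, p in enumerate(P_pa):
        y_calc[i] = solid_solubility(eos, T, p, solute, solvent, inter)
    return 100.0 * float(np.mean(np.abs(y_calc - y_exp) / y_exp)), y_calc


def fit_isotherm(
    eos: str,
    dataset: SolubilityDataset,
    solute: SolutePropertySet,
    solvent: SolventPropertySet,
    bounds: tuple[float, float] = (-1.0, 1.0),
) -> CubicEosIsothermFit:
    """Regress (k_ij, l_ij) on one isotherm by AARD minimization.

    Deterministic multi-start Nelder-Mead from a fixed 5x5 grid spanning
    the interior of the bounds; values stepping outside the bounds are
    penalized. The dataset must contain a single temperature.
    """
    T_arr, P_arr, _, y_exp = dataset.arrays()
    Ts = np.unique(T_arr)
    if Ts.size != 1:
        raise ValueError("fit_isotherm expects a single-temperature dataset")
    if y_exp.size < 3:
        raise ValueError("need at least 3 points on the isotherm")
    T = float(Ts[0])
    P_pa = P_arr * 1.0e6
    lo, hi = bounds

    def obj(x) -> float:
        kij, lij = x
        if not (lo < kij < hi and lo < lij < hi):
            return 1e6 + 1e6 * (abs(kij) + abs(lij))
        try:
            val, _ = _isotherm_aard(eos, T, P_pa, y_exp, solute, solvent, kij, lij)
        except EosError:
            return 1e6
        return val

    span = hi - lo
    grid = np.linspace(lo + 0.1 * span, hi - 0.1 * span, 5)
    best_x, best_val = None, np.inf
    for k0 in grid:
        for l0 in grid:
            res = optimize.minimize(
                obj,
                [k0, l0],
                method="Nelder-Mead",
                options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 400},
            )
            if res.fun < best_val:
                best_x, best_val = res.x, res.fun
    if best_x is None or best_val >= 1e6:
        raise EosError("all optimizer starts failed")
    _, y_calc = _isotherm_aard(eos, T, P_pa, y_exp, solute, solvent, *best_x)
    return CubicEosIsothermFit(
        T=T,
        eos=eos,
        interaction=BinaryInteraction(k_ij=float(best_x[0]), l_ij=float(best_x[1])),
        stats=fit_statistics(y_exp, y_calc, n_params=2),
        y_calc=y_calc,
    )


def fit_all_isotherms(
    eos: str,
    dataset: SolubilityDataset,
    solute: SolutePropertySet,
    solvent: SolventPropertySet,
) -> list[CubicEosIsothermFit]:
    return [fit_isotherm(eos, dataset.isotherm(float(t)), solute, solvent) for t in dataset.temperatures]
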