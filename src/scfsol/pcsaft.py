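"""Non-associating PC-SAFT equation of state and solid-solubility fitting.

The model writes the residual molar Helmholtz energy (reduced by NkT) as a
hard-chain reference plus a second-order dispersion perturbation,

    a_res = a_hc + a_disp,

for chains of m spherical segments of diameter sigma (Angstrom) and
dispersion energy eps/k (K). The temperature-dependent segment diameter is
d = sigma * (1 - 0.12 exp(-3 eps/kT)); the hard-chain term uses the
Boublik-Mansoori-Carnahan-Starling hard-sphere mixture free energy and the
site-site hard-sphere pair correlation at contact; the dispersion term uses
the standard power-series integrals I1(eta, m_bar), I2(eta, m_bar) with the
published universal constants and the C1 compressibility correction.
Cross parameters follow the conventional combining rules
sigma_ij = (sigma_i + sigma_j)/2 and eps_ij = sqrt(eps_i eps_j)(1 - k_ij).

Everything downstream (Z, pressure, fugacity coefficients) derives from
a_res. Derivatives with respect to packing fraction and composition are
computed by complex-step differentiation of the single a_res
implementation, which is exact to machine precision; the test suite checks
them against real central differences.

Association and polar contributions are out of scope: the systems modeled
here are treated as non-associating solute/CO2 binaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .constants import K_B, R
from .data_core import SolubilityDataset
from .metrics import FitStatistics, fit_statistics
from .solute_props import SolutePropertySet, sublimation_pressure

__all__ = [
    "PcSaftPure",
    "PcSaftState",
    "PcSaftIsothermFit",
    "CO2_PCSAFT",
    "estimate_pure_params",
    "a_res",
    "compressibility",
    "pressure",
    "density_from_pressure",
    "fugacity_coefficient",
    "solid_solubility",
    "fit_kij",
]

ETA_MAX = 0.7405  # close packing

# Universal dispersion-integral constants: rows i = 0..6, columns are the
# constant, (m-1)/m, and (m-1)(m-2)/m^2 coefficients.
_A_UNIV = np.array(
    [
        [0.9105631445, -0.3084016918, -0.0906148351],
        [0.6361281449, 0.1860531159, 0.4527842806],
        [2.6861347891, -2.5030047259, 0.5962700728],
        [-26.547362491, 21.419793629, -1.7241829131],
        [97.759208784, -65.255885330, -4.1302112531],
        [-159.59154087, 83.318680481, 13.776631870],
        [91.297774084, -33.746922930, -8.6728470368],
    ]
)
_B_UNIV = np.array(
    [
        [0.7240946941, -0.5755498075, 0.0976883116],
        [2.2382791861, 0.6995095521, -0.2557574982],
        [-4.0025849485, 3.8925673390, -9.1558561530],
        [-21.003576815, -17.215471648, 20.642075974],
        [26.855641363, 192.67226447, -38.804430052],
        [206.55133841, -161.82646165, 93.626774077],
        [-355.60235612, -165.20769346, -29.666905585],
    ]
)

_CS = 1e-20  # complex-step size; the step error is O(h^2) below machine eps


class PcSaftError(RuntimeError):
    pass


@dataclass(frozen=True)
class PcSaftPure:
    """Pure-component parameters: segment number m, segment diameter sigma
    (Angstrom), dispersion energy eps/k (K)."""

    m: float
    sigma: float
    eps_k: float

    def __post_init__(self) -> None:
        if self.m < 1 or self.sigma <= 0 or self.eps_k <= 0:
            raise ValueError("need m >= 1, sigma > 0, eps_k > 0")


# Literature non-associating CO2 parameters (a non-measured input of this
# analysis; override via config where better values are available).
CO2_PCSAFT = PcSaftPure(m=2.0729, sigma=2.7852, eps_k=169.21)


def estimate_pure_params(Mw: float, sigma: float = 3.9, eps_k: float = 280.0) -> PcSaftPure:
    """Crude initial estimate for a rigid organic solid of molar mass Mw:
    m = 0.0249*Mw (a typical segment-per-mass ratio for non-associating
    organics) with generic segment diameter and energy. A starting point
    for regression, not a substitute for fitted parameters."""
    return PcSaftPure(m=max(1.0, 0.0249 * Mw), sigma=sigma, eps_k=eps_k)


# Synthetic stand-in for sumatriptan's (unpublished) fitted pure
# parameters: no regressed set exists in the open literature, so these were
# calibrated once against the reported qualitative behaviour of the binary
# interaction parameter (k_ij negative and decreasing with temperature)
# while staying in the typical range for rigid drug-like organics. They
# reproduce that trend, not the reported per-isotherm deviations.
SUMATRIPTAN_PCSAFT_EST = PcSaftPure(m=5.5, sigma=3.8, eps_k=250.0)


@dataclass(frozen=True)
class PcSaftState:
    """A (T, eta, x) state point; eta is the segment packing fraction."""

    T: float
    eta: float
    composition: tuple[float, ...]

    def __post_init__(self) -> None:
        if not 0.0 < self.eta < ETA_MAX:
            raise ValueError(f"eta={self.eta} outside (0, {ETA_MAX})")
        if abs(sum(self.composition) - 1.0) > 1e-10:
            raise ValueError("composition must sum to 1")


@dataclass(frozen=True)
class PcSaftIsothermFit:
    T: float
    k_ij: float
    stats: FitStatistics
    y_calc: np.ndarray

    def __post_init__(self) -> None:
        if self.stats.n_params != 1:
            raise ValueError("PC-SAFT isotherm fits have 1 parameter")


def _unpack(pures: list[PcSaftPure]):
    m = np.array([p.m for p in pures])
    sig = np.array([p.sigma for p in pures])
    eps = np.array([p.eps_k for p in pures])
    return m, sig, eps


def _diameters(T: float, sig: np.ndarray, eps: np.ndarray) -> np.ndarray:
    return sig * (1.0 - 0.12 * np.exp(-3.0 * eps / T))


def _ares_rho(T: float, rho, x, pures: list[PcSaftPure], k_ij: float):
    """Reduced residual Helmholtz energy at number density rho (A^-3).

    rho and the composition array may be complex (complex-step
    differentiation); T is always real.
    """
    m, sig, eps = _unpack(pures)
    d = _diameters(T, sig, eps)
    x = np.asarray(x)
    mbar = np.sum(x * m)

    zeta = [(np.pi / 6.0) * rho * np.sum(x * m * d**n) for n in range(4)]
    z0, z1, z2, z3 = zeta
    om = 1.0 - z3

    a_hs = (1.0 / z0) * (
        3.0 * z1 * z2 / om + z2**3 / (z3 * om**2) + (z2**3 / z3**2 - z0) * np.log(om)
    )
    half_d = d / 2.0  # d_ii d_jj / (d_ii + d_jj) for i == j
    g_ii = 1.0 / om + half_d * 3.0 * z2 / om**2 + half_d**2 * 2.0 * z2**2 / om**3
    a_hc = mbar * a_hs - np.sum(x * (m - 1.0) * np.log(g_ii))

    eta = z3
    coef = np.array([1.0, (mbar - 1.0) / mbar, (mbar - 1.0) * (mbar - 2.0) / mbar**2])
    a_i = _A_UNIV @ coef
    b_i = _B_UNIV @ coef
    powers = eta ** np.arange(7)
    I1 = np.sum(a_i * powers)
    I2 = np.sum(b_i * powers)
    C1 = 1.0 / (
        1.0
        + mbar * (8.0 * eta - 2.0 * eta**2) / om**4
        + (1.0 - mbar) * (20.0 * eta - 27.0 * eta**2 + 12.0 * eta**3 - 2.0 * eta**4) / (om * (2.0 - eta)) ** 2
    )

    sig_ij = 0.5 * (sig[:, None] + sig[None, :])
    eps_ij = np.sqrt(np.outer(eps, eps))
    if len(pures) == 2:
        off = 1.0 - k_ij
        eps_ij = eps_ij * np.array([[1.0, off], [off, 1.0]])
    elif len(pures) > 2:
        raise ValueError("only pure and binary systems are supported")
    xm = x * m
    m2es3 = np.sum(np.outer(xm, xm) * (eps_ij / T) * sig_ij**3)
    m2e2s3 = np.sum(np.outer(xm, xm) * (eps_ij / T) ** 2 * sig_ij**3)
    a_disp = -2.0 * np.pi * rho * I1 * m2es3 - np.pi * rho * mbar * C1 * I2 * m2e2s3
    return a_hc + a_disp


def _eta_to_rho(T: float, eta, x, pures) -> float:
    m, sig, eps = _unpack(pures)
    d = _diameters(T, sig, eps)
    return eta / ((np.pi / 6.0) * np.sum(np.asarray(x) * m * d**3))


def a_res(state: PcSaftState, pures: list[PcSaftPure], k_ij: float = 0.0) -> float:
    """Reduced residual Helmholtz energy a_res = A_res/(NkT) at the state."""
    rho = _eta_to_rho(state.T, state.eta, state.composition, pures)
    return float(np.real(_ares_rho(state.T, rho, np.asarray(state.composition, float), pures, k_ij)))


def _Z_rho(T: float, rho: float, x, pures, k_ij: float) -> float:
    """Z = 1 + rho * d(a_res)/d(rho) (equals 1 + eta * d(a_res)/d(eta))."""
    da = np.imag(_ares_rho(T, rho + 1j * _CS * rho, x, pures, k_ij)) / (_CS * rho)
    return 1.0 + rho * da


def compressibility(state: PcSaftState, pures: list[PcSaftPure], k_ij: float = 0.0) -> float:
    """Compressibility factor at the state."""
    rho = _eta_to_rho(state.T, state.eta, state.composition, pures)
    return float(_Z_rho(state.T, rho, np.asarray(state.composition, float), pures, k_ij))


def pressure(state: PcSaftState, pures: list[PcSaftPure], k_ij: float = 0.0) -> float:
    """Pressure (Pa) at the state: P = Z rho k_B T with rho in m^-3."""
    rho = _eta_to_rho(state.T, state.eta, state.composition, pures)
    Z = _Z_rho(state.T, rho, np.asarray(state.composition, float), pures, k_ij)
    return float(Z * rho * 1.0e30 * K_B * state.T)


def _pressure_eta(T, eta, x, pures, k_ij) -> float:
    rho = _eta_to_rho(T, eta, x, pures)
    return _Z_rho(T, rho, x, pures, k_ij) * rho * 1.0e30 * K_B * T


def _density_roots(T, P, x, pures, k_ij) -> list[float]:
    """All eta roots of P_calc(eta) = P in (0, ETA_MAX), ascending."""
    x = np.asarray(x, dtype=float)

    def f(eta: float) -> float:
        return _pressure_eta(T, eta, x, pures, k_ij) - P

    grid = np.concatenate([np.geomspace(1e-11, 0.01, 25), np.linspace(0.012, 0.72, 72)])
    vals = np.array([f(e) for e in grid])
    roots = []
    for i in range(len(grid) - 1):
        if vals[i] == 0.0:
            roots.append(grid[i])
        elif vals[i] * vals[i + 1] < 0:
            roots.append(optimize.brentq(f, grid[i], grid[i + 1], xtol=1e-15, rtol=1e-14))
    return roots


def _solve_eta_warm(T, P, x, pures, k_ij, eta0: float) -> float | None:
    """Secant refinement of the density root from a nearby starting guess;
    returns None when it wanders, so the caller can fall back to the full
    bracketed scan."""
    x = np.asarray(x, dtype=float)

    def f(eta: float) -> float:
        return _pressure_eta(T, eta, x, pures, k_ij) - P

    e0, e1 = eta0, min(eta0 * 1.001 + 1e-8, ETA_MAX - 1e-9)
    f0, f1 = f(e0), f(e1)
    for _ in range(60):
        if f1 == f0:
            return None
        e2 = e1 - f1 * (e1 - e0) / (f1 - f0)
        if not (1e-12 < e2 < ETA_MAX - 1e-9) or abs(e2 - eta0) > 0.2:
            return None
        if abs(e2 - e1) < 1e-14 * max(1.0, abs(e1)):
            return e2 if abs(f(e2)) <= 1e-8 * P else None
        e0, f0, e1 = e1, f1, e2
        f1 = f(e1)
    return None


def density_from_pressure(
    T: float,
    P: float,
    composition,
    pures: list[PcSaftPure],
    k_ij: float = 0.0,
    phase_hint: str = "liquid-like",
) -> PcSaftState:
    """Solve P_calc(eta) = P for the packing fraction at fixed (T, x).

    ``phase_hint`` selects the low-eta ("vapor") or high-eta
    ("liquid-like") root when the isotherm admits several.
    """
    if P <= 0:
        raise ValueError("P must be positive")
    roots = _density_roots(T, P, composition, pures, k_ij)
    if not roots:
        raise PcSaftError(f"no density root at T={T}, P={P}")
    eta = roots[0] if phase_hint == "vapor" else roots[-1]
    return PcSaftState(T=T, eta=eta, composition=tuple(np.asarray(composition, float)))


def _ln_phi_at_eta(T, eta, x, pures, k_ij) -> np.ndarray:
    """ln phi_k at fixed (T, eta, x) from composition derivatives of a_res
    taken at constant total number density."""
    x = np.asarray(x, dtype=float)
    rho = _eta_to_rho(T, eta, x, pures)
    ares = float(np.real(_ares_rho(T, rho, x, pures, k_ij)))
    Z = _Z_rho(T, rho, x, pures, k_ij)
    dadx = np.empty(len(x))
    for k in range(len(x)):
        xc = x.astype(complex)
        xc[k] += 1j * _CS
        dadx[k] = np.imag(_ares_rho(T, rho, xc, pures, k_ij)) / _CS
    mu = ares + (Z - 1.0) + dadx - float(x @ dadx)
    return mu - np.log(Z)


def fugacity_coefficient(
    T: float,
    P: float,
    composition,
    pures: list[PcSaftPure],
    k_ij: float = 0.0,
) -> np.ndarray:
    """Fugacity coefficients phi_k at (T [K], P [Pa], x). Among multiple
    density roots the one minimizing the mixture residual Gibbs energy is
    selected."""
    if P <= 0:
        raise ValueError("P must be positive")
    x = np.asarray(composition, dtype=float)
    roots = _density_roots(T, P, x, pures, k_ij)
    if not roots:
        raise PcSaftError(f"no density root at T={T}, P={P}")
    best, best_g = None, np.inf
    for eta in roots:
        ln_phi = _ln_phi_at_eta(T, eta, x, pures, k_ij)
        g = float(x @ ln_phi)
        if g < best_g:
            best, best_g = ln_phi, g
    if best is None:
        raise PcSaftError(f"no stable root at T={T}, P={P}")
    return np.exp(best)


def solid_solubility(
    T: float,
    P: float,
    solute_pure: PcSaftPure,
    solvent_pure: PcSaftPure,
    solute_props: SolutePropertySet,
    k_ij: float = 0.0,
    tol: float = 1e-10,
    max_iter: int = 200,
    warm: dict | None = None,
) -> float:
    """Solid-fluid equilibrium mole fraction y2 with PC-SAFT fugacities,
    by damped fixed-point iteration (the damping factor is halved whenever
    the update direction oscillates or the step grows). The density solve
    is warm-started from the previous iteration's packing fraction; an
    optional ``warm`` dict carries the starting guess across calls at the
    same (T, P) — an accelerator only, it does not change the solution."""
    p_sub = sublimation_pressure(solute_props, T)
    pures = [solvent_pure, solute_pure]
    poynting = np.exp(solute_props.v_solid * (P - p_sub) / (R * T))
    y2 = 1e-8
    prev_step = 0.0
    lam = 1.0
    eta_prev: float | None = None if warm is None else warm.get((T, P))

    def phi2_of(y: float) -> float:
        nonlocal eta_prev
        x = np.array([1.0 - y, y])
        eta = None
        if eta_prev is not None:
            eta = _solve_eta_warm(T, P, x, pures, k_ij, eta_prev)
        if eta is None:
            roots = _density_roots(T, P, x, pures, k_ij)
            if not roots:
                raise PcSaftError(f"no density root at T={T}, P={P}, y2={y}")
            eta = roots[-1]
        eta_prev = eta
        return float(np.exp(_ln_phi_at_eta(T, eta, x, pures, k_ij)[1]))

    for _ in range(max_iter):
        y_star = (p_sub / P) / phi2_of(y2) * poynting
        step = y_star - y2
        if abs(step) <= tol * max(y2, 1e-300):
            if y_star >= 1.0:
                raise PcSaftError(f"unphysical solubility y2={y_star}")
            if warm is not None and eta_prev is not None:
                warm[(T, P)] = eta_prev
            return float(y_star)
        if step * prev_step < 0 or abs(step) > 2.0 * abs(prev_step) > 0:
            lam = max(0.5 * lam, 1.0 / 64.0)
        prev_step = step
        y2 = min(max(y2 + lam * step, 1e-14), 0.9)
    raise PcSaftError(f"fixed point did not converge at T={T}, P={P} (last y2={y2})")


def fit_kij(
    dataset: SolubilityDataset,
    solute_pure: PcSaftPure,
    solvent_pure: PcSaftPure,
    solute_props: SolutePropertySet,
    seed: int = 0,
    bounds: tuple[float, float] = (-0.5, 0.5),
) -> PcSaftIsothermFit:
    """Regress the binary k_ij on one isotherm by AARD minimization.

    A seeded differential-evolution global search over the bounds is
    followed by a Nelder-Mead polish, so the result is reproducible for a
    fixed seed and, in practice, seed-independent after the polish.
    """
    T_arr, P_arr, _, y_exp = dataset.arrays()
    Ts = np.unique(T_arr)
    if Ts.size != 1:
        raise ValueError("fit_kij expects a single-temperature dataset")
    if y_exp.size < 3:
        raise ValueError("need at least 3 points on the isotherm")
    T = float(Ts[0])
    P_pa = P_arr * 1.0e6
    warm: dict = {}  # density warm starts shared across objective evaluations

    def aard_of(kij: float) -> tuple[float, np.ndarray]:
        y_calc = np.empty_like(y_exp)
        for i, p in enumerate(P_pa):
            y_calc[i] = solid_solubility(T, p, solute_pure, solvent_pure, solute_props, kij, warm=warm)
        return 100.0 * float(np.mean(np.abs(y_calc - y_exp) / y_exp)), y_calc

    def obj(v) -> float:
        kij = float(np.atleast_1d(v)[0])
        try:
            val, _ = aard_of(kij)
        except PcSaftError:
            return 1e6
        return val

    de = optimize.differential_evolution(
        obj,
        bounds=[bounds],
        seed=seed,
        popsize=6,
        maxiter=15,
        tol=1e-6,
        polish=False,
    )
    res = optimize.minimize(
        obj,
        de.x,
        method="Nelder-Mead",
        options={"xatol": 1e-9, "fatol": 1e-10, "maxiter": 200},
    )
    kij = float(res.x[0])
    _, y_calc = aard_of(kij)
    return PcSaftIsothermFit(
        T=T,
        k_ij=kij,
        stats=fit_statistics(y_exp, y_calc, n_params=1),
        y_calc=y_calc,
    )
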