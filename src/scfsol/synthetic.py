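"""Synthetic solubility datasets for end-to-end recovery testing.

A generator produces the noiseless "truth" y(T, P, rho) on a stated grid
from one of the package's forward models (a density correlation, a cubic
EoS, or PC-SAFT); observations are then drawn with multiplicative
lognormal noise,

    y_obs = y_true * exp(eps),  eps ~ Normal(0, s),
    s = sqrt(ln(1 + rsd^2)),

so the relative standard deviation of y_obs equals ``noise_rsd`` and
positivity is preserved regardless of noise level. The default
noise_rsd = 0.03 mirrors the reproducibility of careful gravimetric
measurements (replicate RSD below 5%). Densities on the grid are inputs,
never computed — exactly as real data are treated downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol

import numpy as np

from . import cubic_eos, density_models, pcsaft
from .data_core import SolubilityDataset, SolubilityMeasurement, load_dataset
from .solute_props import SolutePropertySet, SolventPropertySet

__all__ = [
    "ForwardModel",
    "DensityModelGenerator",
    "CubicEosGenerator",
    "PcSaftGenerator",
    "SyntheticSpec",
    "generate",
    "default_grid",
]


class ForwardModel(Protocol):
    def predict(self, T: float, P: float, rho: float) -> float: ...


@dataclass(frozen=True)
class DensityModelGenerator:
    params: density_models.DensityModelParams

    def predict(self, T: float, P: float, rho: float) -> float:
        return float(density_models.predict(self.params, T, P, rho))


@dataclass(frozen=True)
class CubicEosGenerator:
    eos: str
    solute: SolutePropertySet
    solvent: SolventPropertySet
    interaction: cubic_eos.BinaryInteraction

    def predict(self, T: float, P: float, rho: float) -> float:
        return cubic_eos.solid_solubility(self.eos, T, P * 1.0e6, self.solute, self.solvent, self.interaction)


@dataclass(frozen=True)
class PcSaftGenerator:
    solute_pure: pcsaft.PcSaftPure
    solvent_pure: pcsaft.PcSaftPure
    solute_props: SolutePropertySet
    k_ij: float

    def predict(self, T: float, P: float, rho: float) -> float:
        return pcsaft.solid_solubility(T, P * 1.0e6, self.solute_pure, self.solvent_pure, self.solute_props, self.k_ij)


@dataclass(frozen=True)
class SyntheticSpec:
    generator: ForwardModel
    grid: tuple[tuple[float, float, float], ...]  # (T [K], P [MPa], rho [kg/m3])
    noise_rsd: float = 0.03
    seed: int = 0
    solute_name: str = "synthetic solute"
    Mw_solute: float = 295.40
    Mw_solvent: float = 44.01

    def __post_init__(self) -> None:
        if self.noise_rsd < 0:
            raise ValueError("noise_rsd must be non-negative")
        if not self.grid:
            raise ValueError("grid must be non-empty")


def generate(spec: SyntheticSpec) -> SolubilityDataset:
    """Evaluate the forward model on the grid and apply lognormal noise.

    Deterministic under a fixed seed; the sd_y column records the nominal
    absolute standard deviation noise_rsd * y_obs.
    """
    y_true = np.empty(len(spec.grid))
    for i, (T, P, rho) in enumerate(spec.grid):
        try:
            y_true[i] = spec.generator.predict(T, P, rho)
        except Exception as exc:
            raise RuntimeError(f"forward model failed at grid point (T={T}, P={P}, rho={rho}): {exc}") from exc
    if spec.noise_rsd > 0:
        rng = np.random.default_rng(spec.seed)
        s = np.sqrt(np.log1p(spec.noise_rsd**2))
        y_obs = y_true * np.exp(rng.normal(0.0, s, size=y_true.size))
    else:
        y_obs = y_true.copy()
    records = tuple(
        SolubilityMeasurement(T=T, P=P, rho=rho, y=float(y), sd_y=float(spec.noise_rsd * y))
        for (T, P, rho), y in zip(spec.grid, y_obs)
    )
    return SolubilityDataset(spec.solute_name, spec.Mw_solute, spec.Mw_solvent, records)


def default_grid() -> tuple[tuple[float, float, float], ...]:
    """The bundled 28-point (T, P, rho) measurement grid (4 isotherms x 7
    pressures), for grid-matched simulations."""
    ds = load_dataset("sumatriptan")
    return tuple((r.T, r.P, r.rho) for r in ds.records)
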