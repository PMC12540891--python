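"""Solubility dataset container, bundled sumatriptan data, and gravimetric
solubility arithmetic.

A solubility point is an equilibrium measurement (T, P, rho_CO2, y) from a
static gravimetric experiment: a weighed drug compact is equilibrated with
supercritical CO2, the vessel is depressurised, and the dissolved mass is
the difference between initial and recovered solid. The mole fraction
follows from the dissolved mass and the CO2 charge; the volumetric
solubility (g/L) additionally needs the CO2 density at (T, P).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = [
    "DatasetError",
    "SolubilityMeasurement",
    "SolubilityDataset",
    "GravimetricRun",
    "load_dataset",
    "write_csv",
    "dissolved_mass",
    "mole_fraction_from_masses",
    "gl_from_mole_fraction",
]

# CO2 critical point: measurements below these are not supercritical.
_T_CRIT_CO2 = 304.1  # K
_P_CRIT_CO2_MPA = 7.38  # MPa

CSV_COLUMNS = ("T_K", "P_MPa", "rho_kg_m3", "y", "sd_y", "sol_g_L")


class DatasetError(ValueError):
    """Malformed or physically invalid solubility data."""


@dataclass(frozen=True)
class SolubilityMeasurement:
    """One equilibrium point: T (K), P (MPa), CO2 density (kg/m3), solute
    mole fraction y, its standard deviation, and the informational g/L value."""

    T: float
    P: float
    rho: float
    y: float
    sd_y: float = 0.0
    sol_gL: float = float("nan")

    def __post_init__(self) -> None:
        if not self.T > _T_CRIT_CO2:
            raise DatasetError(f"T={self.T} K is not supercritical (need T > {_T_CRIT_CO2} K)")
        if not self.P >= _P_CRIT_CO2_MPA:
            raise DatasetError(f"P={self.P} MPa below the CO2 critical pressure {_P_CRIT_CO2_MPA} MPa")
        if not self.rho > 0:
            raise DatasetError(f"rho={self.rho} must be positive")
        if not 0.0 < self.y < 1.0:
            raise DatasetError(f"mole fraction y={self.y} outside (0, 1)")
        if self.sd_y < 0:
            raise DatasetError(f"sd_y={self.sd_y} must be non-negative")


@dataclass(frozen=True)
class SolubilityDataset:
    """An ordered collection of solubility points for one solute/solvent pair."""

    solute_name: str
    Mw_solute: float
    Mw_solvent: float
    records: tuple[SolubilityMeasurement, ...]

    def __post_init__(self) -> None:
        if self.Mw_solute <= 0 or self.Mw_solvent <= 0:
            raise DatasetError("molar masses must be positive")
        if not self.records:
            raise DatasetError("dataset has no records")
        seen = set()
        for r in self.records:
            key = (r.T, r.P)
            if key in seen:
                raise DatasetError(f"duplicate (T, P) pair {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SolubilityMeasurement]:
        return iter(self.records)

    @property
    def temperatures(self) -> np.ndarray:
        """Distinct temperatures, ascending (K)."""
        return np.unique([r.T for r in self.records])

    @property
    def pressures(self) -> np.ndarray:
        """Distinct pressures, ascending (MPa)."""
        return np.unique([r.P for r in self.records])

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(T, P, rho, y) as parallel arrays in record order."""
        T = np.array([r.T for r in self.records])
        P = np.array([r.P for r in self.records])
        rho = np.array([r.rho for r in self.records])
        y = np.array([r.y for r in self.records])
        return T, P, rho, y

    def isotherm(self, T: float, atol: float = 1e-9) -> "SolubilityDataset":
        recs = tuple(r for r in self.records if abs(r.T - T) <= atol)
        if not recs:
            raise DatasetError(f"no records at T={T}")
        return replace(self, records=recs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "T_K": [r.T for r in self.records],
                "P_MPa": [r.P for r in self.records],
                "rho_kg_m3": [r.rho for r in self.records],
                "y": [r.y for r in self.records],
                "sd_y": [r.sd_y for r in self.records],
                "sol_g_L": [r.sol_gL for r in self.records],
            }
        )


def _dataset_from_frame(df: pd.DataFrame, solute_name: str, Mw_solute: float, Mw_solvent: float) -> SolubilityDataset:
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetError(f"missing CSV columns: {missing}")
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                SolubilityMeasurement(
                    T=float(row["T_K"]),
                    P=float(row["P_MPa"]),
                    rho=float(row["rho_kg_m3"]),
                    y=float(row["y"]),
                    sd_y=float(row["sd_y"]),
                    sol_gL=float(row["sol_g_L"]),
                )
            )
        except DatasetError as exc:
            raise DatasetError(f"row {i}: {exc}") from exc
        except (TypeError, ValueError) as exc:
            raise DatasetError(f"row {i}: cannot parse ({exc})") from exc
    return SolubilityDataset(solute_name, Mw_solute, Mw_solvent, tuple(records))


def load_dataset(
    path_or_builtin: str | Path,
    solute_name: str = "solute",
    Mw_solute: float = float("nan"),
    Mw_solvent: float = 44.01,
) -> SolubilityDataset:
    """Load a solubility dataset from CSV, or the bundled fixture by name.

    ``load_dataset("sumatriptan")`` returns the bundled 28-point sumatriptan
    dataset (4 isotherms 308.2-338.2 K x 7 pressures 12-30 MPa) with mole
    fractions and standard deviations stored unscaled.
    """
    if str(path_or_builtin) == "sumatriptan":
        src = resources.files("scfsol.data").joinpath("sumatriptan_sc_co2.csv")
        with resources.as_file(src) as p:
            df = pd.read_csv(p)
        return _dataset_from_frame(df, "sumatriptan", 295.40, 44.01)
    path = Path(path_or_builtin)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise DatasetError(f"{path}: empty CSV") from exc
    if df.empty:
        raise DatasetError(f"{path}: no data rows")
    if np.isnan(Mw_solute):
        raise DatasetError("Mw_solute is required when loading from a file")
    return _dataset_from_frame(df, solute_name, Mw_solute, Mw_solvent)


def write_csv(dataset: SolubilityDataset, path: str | Path) -> None:
    """Write the dataset in the canonical CSV dialect. Floats are written
    in shortest round-trip form, so write/load reproduces every field."""
    df = dataset.to_frame()
    df.to_csv(path, index=False)


# --- gravimetric arithmetic -------------------------------------------------


@dataclass(frozen=True)
class GravimetricRun:
    """Raw masses from one gravimetric run: drug charge and recovered solid
    in mg, CO2 charge in g."""

    m_initial: float
    m_undissolved: float
    m_CO2: float

    def __post_init__(self) -> None:
        if not 0 <= self.m_undissolved <= self.m_initial:
            raise DatasetError("need 0 <= m_undissolved <= m_initial")
        if not self.m_CO2 > 0:
            raise DatasetError("m_CO2 must be positive")


def dissolved_mass(run: GravimetricRun) -> float:
    """Dissolved drug mass (mg): initial minus recovered solid."""
    return run.m_initial - run.m_undissolved


def mole_fraction_from_masses(m_dissolved: float, m_CO2: float, Mw_drug: float, Mw_CO2: float = 44.01) -> float:
    """Equilibrium mole fraction from dissolved drug mass (mg) and CO2 mass (g).

    y = n_drug / (n_drug + n_CO2), with the drug mass converted mg -> g.
    """
    if m_dissolved < 0:
        raise DatasetError("m_dissolved must be non-negative")
    if m_CO2 <= 0:
        raise DatasetError("m_CO2 must be positive")
    if Mw_drug <= 0 or Mw_CO2 <= 0:
        raise DatasetError("molar masses must be positive")
    n_drug = (m_dissolved / 1000.0) / Mw_drug
    n_co2 = m_CO2 / Mw_CO2
    return n_drug / (n_drug + n_co2)


def gl_from_mole_fraction(y: float, rho: float, Mw_drug: float, Mw_CO2: float = 44.01) -> float:
    """Volumetric solubility (g drug per L of CO2) from mole fraction and
    CO2 density (kg/m3 = g/L): rho * Mw_drug * y / (Mw_CO2 * (1 - y))."""
    if not 0 <= y < 1:
        raise DatasetError("need 0 <= y < 1")
    return rho * Mw_drug * y / (Mw_CO2 * (1.0 - y))
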