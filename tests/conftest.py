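"""Shared fixtures. The expensive regressions (cubic EoS and PC-SAFT
isotherm fits) are session-scoped so the unit and acceptance tests share
one computation."""

import numpy as np
import pytest

from scfsol import cubic_eos, density_models, load_dataset, pcsaft
from scfsol.solute_props import builtin_co2, builtin_sumatriptan


@pytest.fixture(scope="session")
def sumatriptan_ds():
    return load_dataset("sumatriptan")


@pytest.fixture(scope="session")
def solute():
    return builtin_sumatriptan()


@pytest.fixture(scope="session")
def solvent():
    return builtin_co2()


@pytest.fixture(scope="session")
def density_fits(sumatriptan_ds):
    return density_models.fit_all(sumatriptan_ds, objective="aard")


@pytest.fixture(scope="session")
def pr_fits(sumatriptan_ds, solute, solvent):
    return cubic_eos.fit_all_isotherms("pr", sumatriptan_ds, solute, solvent)


@pytest.fixture(scope="session")
def srk_fits(sumatriptan_ds, solute, solvent):
    return cubic_eos.fit_all_isotherms("srk", sumatriptan_ds, solute, solvent)


@pytest.fixture(scope="session")
def pcsaft_fits(sumatriptan_ds, solute):
    return [
        pcsaft.fit_kij(
            sumatriptan_ds.isotherm(float(T)),
            pcsaft.SUMATRIPTAN_PCSAFT_EST,
            pcsaft.CO2_PCSAFT,
            solute,
            seed=1,
        )
        for T in sumatriptan_ds.temperatures
    ]
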