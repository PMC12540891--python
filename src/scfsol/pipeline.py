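"""Full-analysis orchestration: density correlations, enthalpy chain,
cubic-EoS and PC-SAFT isotherm regressions, and crossover detection,
collected into one machine-readable report.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from typing import Any

import numpy as np

from . import __version__, cubic_eos, density_models, pcsaft
from .data_core import SolubilityDataset
from .solute_props import SolutePropertySet, SolventPropertySet

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "AnalysisReport", "run_analysis", "report_to_json", "render_text"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Pins every non-measured input of the analysis so a report is fully
    reproducible from (dataset, config, seed)."""

    density_objective: str = "aard"
    pressure_unit_bartle_mst: str = "bar"  # pressure convention inside y*P products
    run_density: bool = True
    run_cubic: bool = True
    run_pcsaft: bool = True
    cubic_eoss: tuple[str, ...] = ("pr", "srk")
    pcsaft_solute: pcsaft.PcSaftPure | None = None  # None -> shipped estimate
    pcsaft_solvent: pcsaft.PcSaftPure = pcsaft.CO2_PCSAFT
    seed: int = 0

    def digest(self) -> str:
        raw = json.dumps(
            {
                k: (asdict(v) if hasattr(v, "__dataclass_fields__") else v)
                for k, v in asdict(self).items()
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(raw.encode()).hexdigest()[:16]


@dataclass
class AnalysisReport:
    density_fits: dict[str, density_models.DensityModelFit]
    enthalpies: density_models.DerivedEnthalpies | None
    cubic_fits: dict[str, list[cubic_eos.CubicEosIsothermFit]]
    pcsaft_fits: list[pcsaft.PcSaftIsothermFit]
    crossover: tuple[float, float] | None
    failures: dict[str, str]
    provenance: dict[str, Any]

    def cubic_mean_aard(self, eos: str) -> float:
        fits = self.cubic_fits[eos]
        return float(np.mean([f.stats.aard_pct for f in fits]))

    def pcsaft_mean_aard(self) -> float:
        return float(np.mean([f.stats.aard_pct for f in self.pcsaft_fits]))


def run_analysis(
    dataset: SolubilityDataset,
    solute: SolutePropertySet,
    solvent: SolventPropertySet,
    config: AnalysisConfig = AnalysisConfig(),
) -> AnalysisReport:
    """Run every enabled stage; a stage failure is recorded and the
    remaining stages still run."""
    density_fits: dict[str, density_models.DensityModelFit] = {}
    enthalpies = None
    cubic_fits: dict[str, list[cubic_eos.CubicEosIsothermFit]] = {}
    pcsaft_fits: list[pcsaft.PcSaftIsothermFit] = []
    crossover = None
    failures: dict[str, str] = {}

    if config.run_density:
        t0 = time.perf_counter()
        try:
            density_fits = density_models.fit_all(
                dataset,
                objective=config.density_objective,
                pressure_unit=config.pressure_unit_bartle_mst,
            )
            enthalpies = density_models.derive_enthalpies(density_fits["chrastil"], density_fits["bartle"])
            crossover = density_models.find_crossover(dataset)
            logger.info("density stage done in %.2fs", time.perf_counter() - t0)
        except Exception as exc:  # recorded, not fatal
            failures["density"] = str(exc)
            logger.exception("density stage failed")

    if config.run_cubic:
        for eos in config.cubic_eoss:
            t0 = time.perf_counter()
            try:
                cubic_fits[eos] = cubic_eos.fit_all_isotherms(eos, dataset, solute, solvent)
                logger.info("cubic %s stage done in %.2fs", eos, time.perf_counter() - t0)
            except Exception as exc:
                failures[f"cubic:{eos}"] = str(exc)
                logger.exception("cubic %s stage failed", eos)

    if config.run_pcsaft:
        t0 = time.perf_counter()
        try:
            if config.pcsaft_solute is not None:
                solute_pure = config.pcsaft_solute
            elif solute.name == "sumatriptan":
                solute_pure = pcsaft.SUMATRIPTAN_PCSAFT_EST
            else:
                solute_pure = pcsaft.estimate_pure_params(solute.Mw)
            for T in dataset.temperatures:
                pcsaft_fits.append(
                    pcsaft.fit_kij(
                        dataset.isotherm(float(T)),
                        solute_pure,
                        config.pcsaft_solvent,
                        solute,
                        seed=config.seed,
                    )
                )
            logger.info("pcsaft stage done in %.2fs", time.perf_counter() - t0)
        except Exception as exc:
            failures["pcsaft"] = str(exc)
            logger.exception("pcsaft stage failed")

    return AnalysisReport(
        density_fits=density_fits,
        enthalpies=enthalpies,
        cubic_fits=cubic_fits,
        pcsaft_fits=pcsaft_fits,
        crossover=crossover,
        failures=failures,
        provenance={
            "package_version": __version__,
            "config_digest": config.digest(),
            "seed": config.seed,
            "n_points": len(dataset),
            "solute": solute.name,
        },
    )


def report_to_json(report: AnalysisReport) -> dict[str, Any]:
    """JSON-serializable view of a report; mean rows are recomputed from
    the per-isotherm rows."""
    out: dict[str, Any] = {"provenance": report.provenance, "failures": report.failures}
    out["density_models"] = {
        mid: {
            "a0": f.params.a0,
            "a1": f.params.a1,
            "a2": f.params.a2,
            "aard_pct": f.stats.aard_pct,
            "r2_adj": f.stats.r2_adj,
        }
        for mid, f in report.density_fits.items()
    }
    if report.enthalpies is not None:
        out["enthalpies_kJ_mol"] = asdict(report.enthalpies)
    out["crossover_MPa"] = list(report.crossover) if report.crossover else None
    out["cubic_eos"] = {}
    for eos, fits in report.cubic_fits.items():
        out["cubic_eos"][eos] = {
            "isotherms": [
                {
                    "T_K": f.T,
                    "k_ij": f.interaction.k_ij,
                    "l_ij": f.interaction.l_ij,
                    "aard_pct": f.stats.aard_pct,
                    "r2_adj": f.stats.r2_adj,
                }
                for f in fits
            ],
            "mean_aard_pct": report.cubic_mean_aard(eos),
            "mean_r2_adj": float(np.mean([f.stats.r2_adj for f in fits])),
        }
    if report.pcsaft_fits:
        out["pcsaft"] = {
            "isotherms": [
                {"T_K": f.T, "k_ij": f.k_ij, "aard_pct": f.stats.aard_pct, "r2_adj": f.stats.r2_adj}
                for f in report.pcsaft_fits
            ],
            "mean_aard_pct": report.pcsaft_mean_aard(),
        }
    return out


def render_text(report: AnalysisReport) -> str:
    """Human-readable rendering of the report tables."""
    doc = report_to_json(report)
    lines = ["scfsol analysis report", "=" * 40]
    if doc.get("density_models"):
        lines.append("\nDensity-based correlations:")
        lines.append(f"{'model':<10}{'a0':>12}{'a1':>12}{'a2':>12}{'AARD%':>9}{'R2adj':>8}")
        for mid, row in doc["density_models"].items():
            lines.append(
                f"{mid:<10}{row['a0']:>12.4g}{row['a1']:>12.4g}{row['a2']:>12.4g}"
                f"{row['aard_pct']:>9.2f}{row['r2_adj']:>8.3f}"
            )
    if "enthalpies_kJ_mol" in doc:
        e = doc["enthalpies_kJ_mol"]
        lines.append(
            f"\nEnthalpies (kJ/mol): dH_total={e['dH_total']:.2f}  dH_vap={e['dH_vap']:.2f}  dH_sol={e['dH_sol']:.2f}"
        )
    if doc.get("crossover_MPa"):
        lo, hi = doc["crossover_MPa"]
        lines.append(f"Crossover pressure interval: {lo:g}-{hi:g} MPa")
    for eos, block in doc.get("cubic_eos", {}).items():
        lines.append(f"\n{eos.upper()}-vdW2 isotherm fits:")
        lines.append(f"{'T (K)':>8}{'k_ij':>10}{'l_ij':>10}{'AARD%':>9}{'R2adj':>8}")
        for row in block["isotherms"]:
            lines.append(
                f"{row['T_K']:>8.1f}{row['k_ij']:>10.4f}{row['l_ij']:>10.4f}"
                f"{row['aard_pct']:>9.2f}{row['r2_adj']:>8.3f}"
            )
        lines.append(f"{'mean':>8}{'':>20}{block['mean_aard_pct']:>9.2f}{block['mean_r2_adj']:>8.3f}")
    if "pcsaft" in doc:
        lines.append("\nPC-SAFT isotherm fits:")
        lines.append(f"{'T (K)':>8}{'k_ij':>10}{'AARD%':>9}{'R2adj':>8}")
        for row in doc["pcsaft"]["isotherms"]:
            lines.append(f"{row['T_K']:>8.1f}{row['k_ij']:>10.4f}{row['aard_pct']:>9.2f}{row['r2_adj']:>8.3f}")
        lines.append(f"{'mean':>8}{'':>10}{doc['pcsaft']['mean_aard_pct']:>9.2f}")
    if doc.get("failures"):
        lines.append("\nStage failures:")
        for k, v in doc["failures"].items():
            lines.append(f"  {k}: {v}")
    return "\n".join(lines)
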