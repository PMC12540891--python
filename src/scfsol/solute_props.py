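"""Pure-component property sets and sublimation-pressure evaluation.

Solid solutes dissolved in supercritical CO2 are characterised by critical
constants (estimated by group contribution for large drug molecules), an
acentric factor, the solid molar volume (for the Poynting correction), and
a sublimation-pressure curve. The curve is anchored by (T, P_sub) reference
points and evaluated with the Clausius-Clapeyron form: ln P_sub linear in
1/T through the anchors (exact for two anchors, least squares for more).
Extrapolation more than 5 K beyond the anchor range is refused.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "SolutePropertySet",
    "SolventPropertySet",
    "sublimation_pressure",
    "builtin_sumatriptan",
    "builtin_co2",
    "to_yaml",
    "from_yaml",
]

_EXTRAP_SLACK_K = 5.0


@dataclass(frozen=True)
class SolutePropertySet:
    name: str
    Mw: float  # g/mol
    Tb: float  # K
    Tc: float  # K
    Pc: float  # Pa
    omega: float
    v_solid: float  # m3/mol
    pvap_anchors: tuple[tuple[float, float], ...]  # (T [K], P_sub [Pa])

    def __post_init__(self) -> None:
        if not (self.Tc > self.Tb > 0):
            raise ValueError("need Tc > Tb > 0")
        if self.Pc <= 0 or self.v_solid <= 0 or self.Mw <= 0:
            raise ValueError("Pc, v_solid, Mw must be positive")
        if len(self.pvap_anchors) < 2:
            raise ValueError("need at least 2 sublimation-pressure anchors")
        Ts = [a[0] for a in self.pvap_anchors]
        Ps = [a[1] for a in self.pvap_anchors]
        if not all(t2 > t1 for t1, t2 in zip(Ts, Ts[1:])):
            raise ValueError("anchors must be strictly increasing in T")
        if not all(p2 > p1 > 0 for p1, p2 in zip(Ps, Ps[1:])):
            raise ValueError("anchors must be strictly increasing and positive in P")

    @property
    def clausius_slope(self) -> float:
        """Slope d(ln P)/d(1/T) of the anchor line (K); equals -dH_sub/R."""
        slope, _ = _anchor_line(self.pvap_anchors)
        return slope


@dataclass(frozen=True)
class SolventPropertySet:
    name: str
    Mw: float
    Tc: float
    Pc: float
    omega: float

    def __post_init__(self) -> None:
        if min(self.Mw, self.Tc, self.Pc) <= 0:
            raise ValueError("Mw, Tc, Pc must be positive")


def _anchor_line(anchors) -> tuple[float, float]:
    invT = np.array([1.0 / a[0] for a in anchors])
    lnP = np.array([np.log(a[1]) for a in anchors])
    slope, intercept = np.polyfit(invT, lnP, 1)
    return float(slope), float(intercept)


def sublimation_pressure(props: SolutePropertySet, T: float) -> float:
    """Sublimation pressure (Pa) at T (K) from the Clausius-Clapeyron line
    through the anchors. Exact at the anchors in the two-anchor case."""
    t_lo = props.pvap_anchors[0][0] - _EXTRAP_SLACK_K
    t_hi = props.pvap_anchors[-1][0] + _EXTRAP_SLACK_K
    if not t_lo <= T <= t_hi:
        raise ValueError(f"T={T} K outside the supported range [{t_lo}, {t_hi}] K (anchors +/- {_EXTRAP_SLACK_K} K)")
    slope, intercept = _anchor_line(props.pvap_anchors)
    return float(np.exp(intercept + slope / T))


def builtin_sumatriptan() -> SolutePropertySet:
    """Sumatriptan properties: group-contribution critical constants and
    acentric factor, solid molar volume, and two sublimation-pressure
    anchors at 308.2 and 338.2 K."""
    return SolutePropertySet(
        name="sumatriptan",
        Mw=295.40,
        Tb=830.5,
        Tc=1160.3,
        Pc=3.39e6,
        omega=0.647,
        v_solid=3.052e-4,
        pvap_anchors=((308.2, 2.88e-8), (338.2, 3.45e-6)),
    )


def builtin_co2() -> SolventPropertySet:
    """CO2 critical constants; the acentric factor 0.225 is a standard
    literature value (a non-measured input of this analysis)."""
    return SolventPropertySet(name="CO2", Mw=44.01, Tc=304.1, Pc=7.38e6, omega=0.225)


def to_yaml(props: SolutePropertySet, path: str | Path) -> None:
    doc = {
        "name": props.name,
        "Mw_g_mol": props.Mw,
        "Tb_K": props.Tb,
        "Tc_K": props.Tc,
        "Pc_Pa": props.Pc,
        "omega": props.omega,
        "v_solid_m3_mol": props.v_solid,
        "pvap_anchors": [[t, p] for t, p in props.pvap_anchors],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def from_yaml(path: str | Path) -> SolutePropertySet:
    doc = yaml.safe_load(Path(path).read_text())
    return SolutePropertySet(
        name=doc["name"],
        Mw=float(doc["Mw_g_mol"]),
        Tb=float(doc["Tb_K"]),
        Tc=float(doc["Tc_K"]),
        Pc=float(doc["Pc_Pa"]),
        omega=float(doc["omega"]),
        v_solid=float(doc["v_solid_m3_mol"]),
        pvap_anchors=tuple((float(t), float(p)) for t, p in doc["pvap_anchors"]),
    )
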