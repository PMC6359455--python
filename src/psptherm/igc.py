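"""Reduction of inverse-gas-chromatography (IGC) raw data.

The probe vapor (solute, index 1) elutes through a column packed with the
drug (stationary phase, index 2).  The chain is

    retention times -> net retention volume V_N (per unit stationary mass)
                    -> mass activity coefficient Omega at infinite dilution
                    -> mole-fraction residual activity coefficient gamma^inf.

SI units throughout the library layer (Pa, kg/mol, m^3/kg, m^3/mol); the
command-line layer converts from common lab units (sccm, mg, mL/g).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .constants import R, T_STANDARD
from .descriptors import LSERDescriptors, bundled_table
from .exceptions import DomainError, ParseError

__all__ = [
    "ProbeProperties",
    "IGCRun",
    "james_martin",
    "net_retention_volume",
    "mass_activity_coefficient",
    "mole_fraction_gamma",
    "load_probe_properties",
    "bundled_probe_properties",
]

_DATA_DIR = Path(__file__).parent / "data"


@dataclass(frozen=True)
class ProbeProperties:
    """Physical constants of one probe gas at the column temperature."""

    name: str
    M1: float               # molar mass, kg/mol
    p0: float               # saturation vapor pressure, Pa
    B11: float              # second virial coefficient, m^3/mol
    V1: float               # liquid molar volume, m^3/mol
    lser: LSERDescriptors | None = None

    def __post_init__(self):
        if not self.M1 > 0 or not self.p0 > 0:
            raise DomainError(f"{self.name}: M1 and p0 must be positive")


@dataclass(frozen=True)
class IGCRun:
    """One probe injection: raw chromatographic data.

    Either ``j`` (James--Martin correction) or the inlet/outlet pressures
    ``Pi``/``Po`` must be given.
    """

    probe: str
    tR: float               # retention time, s
    t0: float               # dead time, s
    F: float                # carrier flow at 1 atm and 273.15 K, m^3/s
    m: float                # stationary-phase mass, kg
    T: float                # column temperature, K
    j: float | None = None
    Pi: float | None = None  # inlet pressure, Pa
    Po: float | None = None  # outlet pressure, Pa

    def __post_init__(self):
        if self.tR < self.t0:
            raise DomainError(f"{self.probe}: retention time {self.tR} < dead time {self.t0}")
        if not self.m > 0 or not self.F > 0:
            raise DomainError(f"{self.probe}: mass and flow must be positive")
        if self.j is None and (self.Pi is None or self.Po is None):
            raise DomainError(f"{self.probe}: supply j or both Pi and Po")
        if self.j is not None and not 0.0 < self.j <= 1.0:
            raise DomainError(f"{self.probe}: j must lie in (0, 1], got {self.j}")

    def correction(self) -> float:
        return self.j if self.j is not None else james_martin(self.Pi, self.Po)


def james_martin(Pi: float, Po: float) -> float:
    """James--Martin gas-compressibility correction.

    j = (3/2) * ((Pi/Po)^2 - 1) / ((Pi/Po)^3 - 1), with j -> 1 as Pi -> Po.
    """
    if not (Pi >= Po > 0):
        raise DomainError(f"pressures must satisfy Pi >= Po > 0, got Pi={Pi}, Po={Po}")
    ratio = Pi / Po
    if ratio == 1.0:
        return 1.0
    return 1.5 * (ratio ** 2 - 1.0) / (ratio ** 3 - 1.0)


def net_retention_volume(run: IGCRun) -> float:
    """Net retention volume per unit stationary-phase mass, m^3/kg.

    V_N = (j/m) * F * (tR - t0) * T / 273.15
    """
    return run.correction() / run.m * run.F * (run.tR - run.t0) * run.T / T_STANDARD


def mass_activity_coefficient(VN: float, probe: ProbeProperties, T: float) -> float:
    """ln Omega at infinite dilution from the net retention volume.

    ln Omega = ln(273.15*R / (p0*M1*VN)) - p0*(B11 - V1)/(R*T), all SI; the
    second term corrects for gas-phase nonideality of the probe vapor.
    """
    if not VN > 0:
        raise DomainError(f"net retention volume must be positive, got {VN} (no retention)")
    return (math.log(T_STANDARD * R / (probe.p0 * probe.M1 * VN))
            - probe.p0 * (probe.B11 - probe.V1) / (R * T))


def mole_fraction_gamma(ln_omega: float, M1: float, M2: float,
                        r1: float, r2: float) -> tuple[float, float]:
    """Convert ln Omega to the residual mole-fraction ln gamma^inf and chi12.

    ln gamma^res,inf = ln(Omega * M1/M2) - (ln(r1/r2) + 1 - r1/r2);
    the subtracted bracket is the Flory--Huggins combinatorial term at
    infinite dilution.  Returns (ln_gamma_inf, chi12) with
    chi12 = ln_gamma_inf / r1 (phi2 = 1).
    """
    if not (M1 > 0 and M2 > 0 and r1 > 0 and r2 > 0):
        raise DomainError("molar masses and segment numbers must be positive")
    ln_gamma = ln_omega + math.log(M1 / M2) - (math.log(r1 / r2) + 1.0 - r1 / r2)
    return ln_gamma, ln_gamma / r1


def load_probe_properties(source: str | Path) -> dict[str, ProbeProperties]:
    """Load probe physical properties from a CSV table.

    Header: ``name,M_kg_mol,p0_Pa,B11_m3_mol,V1_m3_mol``; lines starting with
    '#' are comments.  LSER descriptors are attached from the bundled solvent
    table when the probe name matches.
    """
    frame = pd.read_csv(Path(source), comment="#")
    solvents = bundled_table("solvents")
    out = {}
    for i, (_, row) in enumerate(frame.iterrows(), start=1):
        try:
            name = str(row["name"])
            rec = solvents.get(name)
            out[name] = ProbeProperties(
                name=name,
                M1=float(row["M_kg_mol"]),
                p0=float(row["p0_Pa"]),
                B11=float(row["B11_m3_mol"]),
                V1=float(row["V1_m3_mol"]),
                lser=rec.lser if rec is not None else None,
            )
        except (DomainError, ValueError, KeyError) as exc:
            raise ParseError(f"invalid probe row: {exc}", row=i) from exc
    return out


def bundled_probe_properties() -> dict[str, ProbeProperties]:
    """Bundled synthetic probe-property table (nominal values at 303.15 K).

    The values are editable literature-magnitude stand-ins; override them for
    quantitative work by loading a custom table.
    """
    return load_probe_properties(_DATA_DIR / "probe_properties_synthetic.csv")
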