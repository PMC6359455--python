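"""LSER descriptors, compound records, and partial solvation parameters.

The partial solvation parameters (PSPs) decompose the cohesive energy of a
compound into dispersion (sigma_d), polarity (sigma_p), Lewis-acidity
(sigma_Ga) and Lewis-basicity (sigma_Gb) components, each in MPa^0.5.  They
are defined from Abraham-type LSER descriptors (Vx, E, S, A, B) and the molar
volume Vm (cm^3/mol):

    sigma_d  = 100 * sqrt((3.1*Vx + E) / Vm)
    sigma_p  = 100 * sqrt(S / Vm)
    sigma_Ga = 100 * sqrt(A / Vm)
    sigma_Gb = 100 * sqrt(B / Vm)

with Vx in the conventional (cm^3/mol)/100 McGowan units.  The
hydrogen-bonding component sigma_hb is computed in :mod:`psptherm.hbond`
because it requires the self-association equilibrium.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .constants import DISPERSION_VX_COEFF, PSP_SCALE, SEGMENT_MCGOWAN_VOLUME
from .exceptions import ConfigurationError, DomainError, ParseError

__all__ = [
    "LSERDescriptors",
    "FusionData",
    "PSPSet",
    "CompoundRecord",
    "segments_from_mcgowan",
    "psp_from_lser",
    "vm_from_sigma_d",
    "load_compound_table",
    "load_fusion_table",
    "bundled_table",
]

_DATA_DIR = Path(__file__).parent / "data"


@dataclass(frozen=True)
class LSERDescriptors:
    """Abraham-style molecular descriptors of one compound.

    Parameters
    ----------
    Vx : float
        McGowan characteristic volume in (cm^3/mol)/100.
    E : float
        Excess molar refraction.
    S : float
        Dipolarity/polarizability descriptor.
    A : float
        Hydrogen-bond acidity descriptor.
    B : float
        Hydrogen-bond basicity descriptor.
    """

    Vx: float
    E: float = 0.0
    S: float = 0.0
    A: float = 0.0
    B: float = 0.0

    def __post_init__(self):
        if not self.Vx > 0:
            raise DomainError(f"McGowan volume must be positive, got Vx={self.Vx}")
        for name in ("E", "S", "A", "B"):
            v = getattr(self, name)
            if v < 0:
                raise DomainError(f"LSER descriptor {name} must be >= 0, got {v}")

    @property
    def r(self) -> float:
        """Segment number r = Vx / 0.213."""
        return segments_from_mcgowan(self.Vx)


@dataclass(frozen=True)
class FusionData:
    """Melting onset temperature (K) and enthalpy of fusion (J/mol)."""

    Tm: float
    dHm: float

    def __post_init__(self):
        if not self.Tm > 0:
            raise DomainError(f"melting temperature must be positive, got {self.Tm}")
        if not self.dHm > 0:
            raise DomainError(f"fusion enthalpy must be positive, got {self.dHm}")


@dataclass(frozen=True)
class PSPSet:
    """Partial solvation parameters of one compound, MPa^0.5.

    sigma_hb and sigma_tot default to 0 / quadrature-of-available until the
    hydrogen-bonding component is attached (see :func:`psptherm.hbond.hb_ced`).
    """

    sigma_d: float
    sigma_p: float
    sigma_Ga: float
    sigma_Gb: float
    sigma_hb: float = 0.0

    @property
    def sigma_tot(self) -> float:
        """Total solubility parameter: quadrature of d, p and hb components."""
        return math.sqrt(self.sigma_d ** 2 + self.sigma_p ** 2 + self.sigma_hb ** 2)


def segments_from_mcgowan(Vx: float) -> float:
    """Number of lattice segments of a molecule from its McGowan volume.

    r = Vx / 0.213, with Vx in (cm^3/mol)/100.
    """
    if not Vx > 0:
        raise DomainError(f"McGowan volume must be positive, got {Vx}")
    return Vx / SEGMENT_MCGOWAN_VOLUME


def psp_from_lser(lser: LSERDescriptors, Vm: float, name: str = "compound") -> PSPSet:
    """Dispersion, polarity, acidity and basicity PSPs from LSER descriptors.

    Parameters
    ----------
    lser : LSERDescriptors
    Vm : float
        Molar volume in cm^3/mol.
    name : str
        Used in error messages only.

    Returns
    -------
    PSPSet
        With sigma_hb left at 0 (see :func:`psptherm.hbond.hb_ced`).
    """
    if Vm is None or not Vm > 0:
        raise ConfigurationError(
            f"{name}: a positive molar volume is required to compute PSPs (got {Vm!r})"
        )
    return PSPSet(
        sigma_d=PSP_SCALE * math.sqrt((DISPERSION_VX_COEFF * lser.Vx + lser.E) / Vm),
        sigma_p=PSP_SCALE * math.sqrt(lser.S / Vm),
        sigma_Ga=PSP_SCALE * math.sqrt(lser.A / Vm),
        sigma_Gb=PSP_SCALE * math.sqrt(lser.B / Vm),
    )


def vm_from_sigma_d(sigma_d: float, Vx: float, E: float) -> float:
    """Molar volume (cm^3/mol) implied by a dispersion PSP.

    Algebraic inversion of the sigma_d definition:
    Vm = 10000 * (3.1*Vx + E) / sigma_d^2.  Useful because solid drugs rarely
    have tabulated molar volumes while their sigma_d is reported.
    """
    if not sigma_d > 0:
        raise DomainError(f"sigma_d must be positive, got {sigma_d}")
    return PSP_SCALE ** 2 * (DISPERSION_VX_COEFF * Vx + E) / sigma_d ** 2


@dataclass
class CompoundRecord:
    """A named compound: LSER descriptors plus optional physical data.

    Molar volume resolution order: an explicitly supplied ``Vm`` wins;
    otherwise ``Vm`` is inverted from a supplied dispersion PSP ``sigma_d``;
    otherwise requesting PSPs raises a :class:`ConfigurationError`.
    """

    name: str
    lser: LSERDescriptors
    Vm: float | None = None
    M: float | None = None        # molar mass, kg/mol
    fusion: FusionData | None = None
    gamma_d: float | None = None  # dispersive surface energy, mJ/m^2
    sigma_d: float | None = None  # dispersion PSP, MPa^0.5 (Vm fallback)

    def __post_init__(self):
        if self.Vm is not None and not self.Vm > 0:
            raise DomainError(f"{self.name}: molar volume must be positive, got {self.Vm}")

    @property
    def r(self) -> float:
        return self.lser.r

    def molar_volume(self) -> float:
        """Resolved molar volume in cm^3/mol (explicit value or sigma_d inversion)."""
        if self.Vm is not None:
            return self.Vm
        if self.sigma_d is not None:
            return vm_from_sigma_d(self.sigma_d, self.lser.Vx, self.lser.E)
        raise ConfigurationError(
            f"{self.name}: no molar volume available (supply Vm or sigma_d)"
        )

    def psp(self) -> PSPSet:
        return psp_from_lser(self.lser, self.molar_volume(), name=self.name)


_DESCRIPTOR_COLS = ("Vx", "E", "S", "A", "B")
_OPTIONAL_COLS = {
    "Vm": "Vm",
    "M": "M",
    "gamma_d_mJ_m2": "gamma_d",
    "sigma_d_MPa05": "sigma_d",
}


def _record_from_row(row: pd.Series, index: int) -> CompoundRecord:
    try:
        name = str(row["name"])
        descr = {}
        for col in _DESCRIPTOR_COLS:
            v = row.get(col)
            descr[col] = 0.0 if v is None or pd.isna(v) else float(v)
        lser = LSERDescriptors(**descr)
        kwargs = {}
        for col, attr in _OPTIONAL_COLS.items():
            v = row.get(col)
            if v is not None and not pd.isna(v):
                kwargs[attr] = float(v)
        tm, dhm = row.get("Tm_K"), row.get("dHm_J_mol")
        fusion = None
        if tm is not None and dhm is not None and not pd.isna(tm) and not pd.isna(dhm):
            fusion = FusionData(Tm=float(tm), dHm=float(dhm))
        return CompoundRecord(name=name, lser=lser, fusion=fusion, **kwargs)
    except (DomainError, ValueError, KeyError) as exc:
        raise ParseError(f"invalid compound row {row.to_dict()!r}: {exc}", row=index) from exc


def load_compound_table(source: str | Path) -> dict[str, CompoundRecord]:
    """Load compound records from a CSV (or JSON mirror) table.

    Expected header: ``name,Vx,E,S,A,B`` plus optional columns
    ``Vm,M,Tm_K,dHm_J_mol,gamma_d_mJ_m2,sigma_d_MPa05``.  Blank descriptor
    cells are read as exactly zero (dispersion-only probes such as alkanes
    leave E, S, A, B blank).

    Returns
    -------
    dict mapping compound name to :class:`CompoundRecord` (insertion ordered).
    """
    source = Path(source)
    if source.suffix.lower() == ".json":
        frame = pd.DataFrame(json.loads(source.read_text()))
    else:
        frame = pd.read_csv(source)
    if frame.empty:
        return {}
    if "name" not in frame.columns:
        raise ParseError(f"{source}: missing required 'name' column")
    records = {}
    for i, (_, row) in enumerate(frame.iterrows(), start=1):
        rec = _record_from_row(row, i)
        records[rec.name] = rec
    return records


def load_fusion_table(source: str | Path) -> dict[str, FusionData | None]:
    """Load a fusion-data table with header ``name,Tm_K,dHm_J_mol``.

    Rows with blank cells map to None (amorphous solids without fusion data).
    """
    frame = pd.read_csv(Path(source))
    out: dict[str, FusionData | None] = {}
    for i, (_, row) in enumerate(frame.iterrows(), start=1):
        try:
            tm, dhm = row["Tm_K"], row["dHm_J_mol"]
            if pd.isna(tm) or pd.isna(dhm):
                out[str(row["name"])] = None
            else:
                out[str(row["name"])] = FusionData(Tm=float(tm), dHm=float(dhm))
        except (DomainError, ValueError, KeyError) as exc:
            raise ParseError(f"invalid fusion row: {exc}", row=i) from exc
    return out


def bundled_table(which: str):
    """Load a bundled table: 'solvents' or 'drugs' (compound records) or
    'fusion' (name -> FusionData)."""
    files = {
        "solvents": "solvents_table2.csv",
        "drugs": "drugs_table3.csv",
        "fusion": "fusion_table4.csv",
    }
    try:
        fname = files[which]
    except KeyError:
        raise ConfigurationError(
            f"unknown bundled table {which!r}; choose from {sorted(files)}"
        ) from None
    if which == "fusion":
        return load_fusion_table(_DATA_DIR / fname)
    return load_compound_table(_DATA_DIR / fname)
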