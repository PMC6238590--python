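"""Physicochemical constants, culture geometry and unit conversions.

The canonical internal unit for all rates is nmol·h⁻¹·cm⁻² of culture
area; every other basis (per cell, per µg protein, mass per area) is a
view obtained through :func:`convert_rate`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace
from typing import Literal


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (display convention for flux tables)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass(frozen=True)
class ModelConstants:
    """Stoichiometric and energetic constants of the flux model.

    Attributes
    ----------
    pka_co2:
        Overall pKa of CO₂ in aqueous solution at 37 °C.
    rq_palmitate:
        Respiratory quotient (mol CO₂ per mol O₂) for pure palmitate
        oxidation; the exact stoichiometric value is 16/23 ≈ 0.696.
    h_per_o2_net:
        Net H⁺ released to the medium per O₂ consumed during complete
        palmitate oxidation, after accounting for incomplete CO₂
        hydration: (16/23) × 0.934 ≈ 0.65.
    caloric_equiv_o2:
        Energy liberated per O₂ consumed, µJ per nmol O₂.
    gibbs_palmitate:
        Gibbs energy of palmitate combustion, µJ per pmol.
    o2_per_palmitate:
        mol O₂ required per mol palmitate for complete oxidation.
    lactate_per_glucose:
        mol lactate produced per mol glucose through glycolysis.
    dna_per_cell:
        pg DNA per cell, used to convert DNA content to cell number.
    mw_tripalmitin:
        Molar mass of tripalmitin, g/mol.
    mw_anhydroglucose:
        Molar mass of the glucose residue within glycogen, g/mol.
    """

    pka_co2: float = 6.093
    rq_palmitate: float = 0.7
    h_per_o2_net: float = 0.65
    caloric_equiv_o2: float = 431.0
    gibbs_palmitate: float = 9.8
    o2_per_palmitate: float = 23.0
    lactate_per_glucose: float = 2.0
    dna_per_cell: float = 6.0
    mw_tripalmitin: float = 807.3
    mw_anhydroglucose: float = 162.0

    #: CO₂/O₂ ratio that reproduces the published flux table's CO₂ rows
    #: (every printed CO₂/OCR ratio lies in 0.613–0.625, not at the
    #: stated RQ of 0.7). Exposed as an explicit opt-in mode.
    TABLE_CALIBRATED_CO2_PER_O2 = 0.62

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if not (value > 0 and math.isfinite(value)):
                raise ValueError(f"{f.name} must be strictly positive, got {value!r}")
        if self.h_per_o2_net > self.rq_palmitate:
            raise ValueError(
                "h_per_o2_net must not exceed rq_palmitate: net acidification "
                "cannot exceed CO2 produced per O2"
            )

    def with_overrides(self, **kwargs: float) -> "ModelConstants":
        unknown = set(kwargs) - {f.name for f in fields(self)}
        if unknown:
            raise ValueError(f"unknown constant override(s): {sorted(unknown)}")
        return replace(self, **kwargs)


@dataclass(frozen=True)
class CultureGeometry:
    """Per-well culture geometry and normalisation densities.

    Defaults reflect XF-96 plates seeded with primary brown adipocytes:
    89 µg protein and 82,916 pg DNA (= 13,819 cells at 6 pg/cell) per cm².
    """

    area_cm2: float = 0.106
    protein_ug_per_cm2: float = 89.0
    dna_pg_per_cm2: float = 82916.0
    cells_per_cm2: int = 13819
    medium_volume_uL: float = 180.0
    exposure_h: float = 1.0

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if not value > 0:
                raise ValueError(f"{f.name} must be strictly positive, got {value!r}")

    @classmethod
    def from_dna(
        cls, dna_pg_per_cm2: float, constants: ModelConstants | None = None, **kwargs
    ) -> "CultureGeometry":
        """Build a geometry deriving cell density from DNA density."""
        constants = constants or ModelConstants()
        cells = cells_from_dna(dna_pg_per_cm2, constants.dna_per_cell)
        return cls(dna_pg_per_cm2=dna_pg_per_cm2, cells_per_cm2=cells, **kwargs)


def cells_from_dna(dna_pg_per_cm2: float, pg_per_cell: float) -> int:
    """Cell density (cells/cm²) from areal DNA density and DNA per cell."""
    if not (dna_pg_per_cm2 > 0 and pg_per_cell > 0):
        raise ValueError("dna_pg_per_cm2 and pg_per_cell must be strictly positive")
    return round(dna_pg_per_cm2 / pg_per_cell)


RateBasis = Literal["per_cell", "per_ug_protein", "mass_per_cm2"]


def convert_rate(
    rate: float,
    geometry: CultureGeometry,
    basis: RateBasis,
    molar_mass: float | None = None,
) -> float:
    """Re-express an areal rate on another normalisation basis.

    Parameters
    ----------
    rate:
        Rate in nmol·h⁻¹·cm⁻² (or, for ``per_cell``/``per_ug_protein``,
        any areal numerator — the division is unit-agnostic).
    basis:
        ``per_cell`` divides by cells/cm²; ``per_ug_protein`` divides by
        µg protein/cm²; ``mass_per_cm2`` multiplies by the molar mass
        (nmol × g/mol → ng·h⁻¹·cm⁻²).
    molar_mass:
        Required for (and only for) the mass basis.
    """
    if basis == "mass_per_cm2":
        if molar_mass is None:
            raise ValueError("molar_mass is required for a mass basis")
        return rate * molar_mass
    if molar_mass is not None:
        raise ValueError(f"molar_mass is meaningless for basis {basis!r}")
    if basis == "per_cell":
        divisor = geometry.cells_per_cm2
    elif basis == "per_ug_protein":
        divisor = geometry.protein_ug_per_cm2
    else:
        raise ValueError(f"unknown basis {basis!r}")
    if divisor == 0:
        raise ValueError(f"geometry divisor for basis {basis!r} is zero")
    return rate / divisor


def sphere_mass(diameter_um: float, density_g_per_ml: float) -> float:
    """Mass in ng of a sphere of given diameter (µm) and density (g/mL).

    A 50-µm water sphere weighs 65.45 ng — a useful mental yardstick for
    per-cell glycogen contents of order 1 ng.
    """
    if not (diameter_um > 0 and density_g_per_ml > 0):
        raise ValueError("diameter and density must be strictly positive")
    volume_um3 = (4.0 / 3.0) * math.pi * (diameter_um / 2.0) ** 3
    # 1 µm³ = 1e-12 mL; g → ng is 1e9, net factor 1e-3
    return volume_um3 * density_g_per_ml * 1e-3
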