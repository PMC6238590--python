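"""Proton-production bookkeeping.

Extracellular acidification of an unbuffered assay medium has three
metabolic sources in adipocytes:

1. respiratory CO₂, hydrated to carbonic acid which dissociates to
   HCO₃⁻ + H⁺ at physiological pH (governed by the overall pKa 6.093
   at 37 °C);
2. lactic acid from glycolysis;
3. exported free fatty acids.

Lactate and FFAs are quantitatively dissociated at physiological pH and
release one H⁺ per molecule. The CO₂ route uses a fixed net H⁺/O₂ of
0.65 for complete palmitate oxidation — the stoichiometric CO₂/O₂ of
16/23 times a realized hydrated fraction of 0.934. Only *exported* FFAs
acidify the medium; oxidized and re-esterified FFAs never leave the cell.
"""

from __future__ import annotations

from dataclasses import dataclass

from .constants import ModelConstants


@dataclass(frozen=True)
class PprDecomposition:
    """Measured vs modeled proton production, nmol H⁺·h⁻¹·cm⁻²."""

    from_co2: float
    from_lactate: float
    from_ffa: float
    measured_total: float | None = None

    @property
    def modeled_total(self) -> float:
        return self.from_co2 + self.from_lactate + self.from_ffa

    @property
    def residual(self) -> float | None:
        if self.measured_total is None:
            return None
        return self.measured_total - self.modeled_total


def hydrated_fraction(ph: float, pka: float = 6.093) -> float:
    """Equilibrium fraction of dissolved CO₂ present as HCO₃⁻ + H⁺.

    Henderson–Hasselbalch: 1 / (1 + 10^(pKa − pH)). At pH 7.4 with the
    overall pKa of 6.093 the fraction is 0.953.
    """
    return 1.0 / (1.0 + 10.0 ** (pka - ph))


def co2_from_ocr(ocr: float, co2_per_o2: float = 0.7) -> float:
    """CO₂ production rate from O₂ consumption via a respiratory quotient.

    ``co2_per_o2`` defaults to 0.7 (pure fat oxidation); pass
    ``ModelConstants.TABLE_CALIBRATED_CO2_PER_O2`` (0.62) to match the
    published flux table's CO₂ rows instead.
    """
    if ocr < 0:
        raise ValueError("ocr must be non-negative")
    if co2_per_o2 <= 0:
        raise ValueError("co2_per_o2 must be positive")
    return ocr * co2_per_o2


def ppr_from_co2(ocr: float, h_per_o2: float = 0.65) -> float:
    """Proton production attributable to respiratory CO₂.

    The default 0.65 H⁺ per O₂ is the fixed model constant; see
    :func:`net_h_per_o2` for its derivation from the CO₂/O₂ ratio and
    the hydrated fraction.
    """
    if ocr < 0:
        raise ValueError("ocr must be non-negative")
    return ocr * h_per_o2


def net_h_per_o2(co2_per_o2: float = 16.0 / 23.0, hydrated: float = 0.934) -> float:
    """Net H⁺ per O₂: CO₂ per O₂ times the fraction of CO₂ hydrated.

    (16/23) × 0.934 = 0.6497 ≈ 0.65 for complete palmitate oxidation.
    """
    return co2_per_o2 * hydrated


def ppr_from_metabolite(release_rate: float, protons_per_molecule: int = 1) -> float:
    """Proton production from a quantitatively dissociating organic acid."""
    if release_rate < 0:
        raise ValueError("release_rate must be non-negative")
    return release_rate * protons_per_molecule


def decompose_ppr(
    ocr: float,
    lactate_release: float,
    ffa_release: float,
    measured_ppr: float | None = None,
    constants: ModelConstants | None = None,
) -> PprDecomposition:
    """Decompose proton production into its three metabolic sources."""
    constants = constants or ModelConstants()
    for name, value in (
        ("ocr", ocr),
        ("lactate_release", lactate_release),
        ("ffa_release", ffa_release),
    ):
        if value < 0:
            raise ValueError(f"{name} must be non-negative, got {value}")
    return PprDecomposition(
        from_co2=ppr_from_co2(ocr, constants.h_per_o2_net),
        from_lactate=ppr_from_metabolite(lactate_release),
        from_ffa=ppr_from_metabolite(ffa_release),
        measured_total=measured_ppr,
    )


def ecar_to_ppr(
    ecar_mph_min: float,
    buffer_power_mph_per_nmol: float,
    well_area_cm2: float | None = None,
) -> float:
    """Convert a raw acidification rate (mpH/min) to proton production.

    Division by the medium buffer power gives nmol H⁺/min/well; if a
    well area is supplied the result is further normalized to
    nmol·h⁻¹·cm⁻² (×60/area).
    """
    if buffer_power_mph_per_nmol <= 0:
        raise ValueError("buffer_power must be positive")
    ppr = ecar_mph_min / buffer_power_mph_per_nmol
    if well_area_cm2 is not None:
        if well_area_cm2 <= 0:
            raise ValueError("well_area_cm2 must be positive")
        ppr = ppr * 60.0 / well_area_cm2
    return ppr
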