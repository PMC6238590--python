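"""Assembly of per-well measurements into the per-condition flux table.

Derived quantities (CO₂ production, FFA oxidized / re-esterified, TAG
hydrolyzed) are computed per well first and aggregated to mean ± SD
afterwards, mirroring how the reference dataset was produced (per
replicate, then averaged) — the two orders differ whenever wells differ.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .acidification import co2_from_ocr
from .constants import ModelConstants
from .lipid import OxidationMode, ffa_oxidation_bound, reesterification_rate, tag_hydrolysis_rate

#: Row order of the published table; o2_consumption is the measured OCR.
QUANTITIES = (
    "glycerol_release",
    "ffa_release",
    "ffa_oxidized",
    "ffa_reesterified",
    "tag_hydrolyzed",
    "o2_consumption",
    "co2_production",
    "glucose_uptake",
    "lactate_release",
)

MEASURED = (
    "glycerol_release",
    "ffa_release",
    "o2_consumption",
    "glucose_uptake",
    "lactate_release",
)

REQUIRED_COLUMNS = (
    "well",
    "genotype",
    "block",
    "glycerol_release",
    "ffa_release",
    "lactate_release",
    "o2_consumption",
)


@dataclass
class FluxTable:
    """Per-condition mean ± SD flux table with below-zero flags.

    ``means``/``sds`` are indexed by (genotype, block) with one column
    per quantity; missing measurements are NaN (absent, not zero).
    """

    means: pd.DataFrame
    sds: pd.DataFrame
    n_wells: pd.Series
    below_zero: pd.DataFrame = field(default_factory=pd.DataFrame)

    def cell(self, genotype: str, block: str, quantity: str) -> tuple[float, float]:
        key = (genotype, block)
        return float(self.means.loc[key, quantity]), float(self.sds.loc[key, quantity])

    def to_tidy(self) -> pd.DataFrame:
        """Long-format view: genotype, block, quantity, mean, sd, below_zero."""
        rows = []
        for key in self.means.index:
            genotype, block = key
            for quantity in self.means.columns:
                mean = self.means.loc[key, quantity]
                if pd.isna(mean):
                    continue
                rows.append(
                    {
                        "genotype": genotype,
                        "block": block,
                        "quantity": quantity,
                        "mean": float(mean),
                        "sd": float(self.sds.loc[key, quantity]),
                        "below_zero": bool(self.below_zero.loc[key, quantity])
                        if quantity in self.below_zero.columns
                        else False,
                    }
                )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class ConditionContrast:
    """B/A fold change and B − A difference of condition means."""

    fold: float | None
    difference: float


def derive_per_well(
    per_well: pd.DataFrame,
    constants: ModelConstants | None = None,
    oxidation_mode: OxidationMode = "stoichiometric",
    co2_per_o2: float | None = None,
) -> pd.DataFrame:
    """Append derived flux columns to a per-well measurement frame."""
    constants = constants or ModelConstants()
    if co2_per_o2 is None:
        co2_per_o2 = constants.rq_palmitate
    missing = [c for c in REQUIRED_COLUMNS if c not in per_well.columns]
    if missing:
        raise ValueError(f"per-well frame is missing column(s): {missing}")

    out = per_well.copy()
    if "glucose_uptake" not in out.columns:
        out["glucose_uptake"] = np.nan
    derived = {q: [] for q in ("ffa_oxidized", "ffa_reesterified", "tag_hydrolyzed", "co2_production")}
    flags = []
    for row in out.itertuples():
        ocr = float(row.o2_consumption)
        oxidized = ffa_oxidation_bound(ocr, mode=oxidation_mode, constants=constants)
        reest, below = reesterification_rate(
            float(row.glycerol_release), float(row.ffa_release), oxidized
        )
        derived["ffa_oxidized"].append(oxidized)
        derived["ffa_reesterified"].append(reest)
        derived["tag_hydrolyzed"].append(
            tag_hydrolysis_rate(float(row.ffa_release), oxidized, reest)
        )
        derived["co2_production"].append(co2_from_ocr(ocr, co2_per_o2))
        flags.append(below)
    for name, values in derived.items():
        out[name] = values
    out["reesterified_below_zero"] = flags
    return out


def build_flux_table(
    per_well: pd.DataFrame,
    constants: ModelConstants | None = None,
    oxidation_mode: OxidationMode = "stoichiometric",
    co2_per_o2: float | None = None,
) -> FluxTable:
    """Build the per-condition flux table from per-well measurements.

    ``per_well`` needs one row per well with the measured rates (all in
    nmol·h⁻¹·cm⁻²; ``o2_consumption`` is the well's block-level OCR) and
    ``genotype``/``block`` labels. Glucose uptake may be absent (NaN)
    for oligomycin blocks. Raises if any condition has no wells.
    """
    derived = derive_per_well(
        per_well, constants=constants, oxidation_mode=oxidation_mode, co2_per_o2=co2_per_o2
    )
    if derived.empty:
        raise ValueError("no wells supplied")

    grouped = derived.groupby(["genotype", "block"], sort=True)
    means = grouped[list(QUANTITIES)].mean()
    # sample SD (ddof=1); a single well gives SD 0 rather than NaN
    sds = grouped[list(QUANTITIES)].std(ddof=1)
    counts = grouped[list(QUANTITIES)].count()
    sds = sds.where(counts != 1, 0.0)
    n_wells = grouped.size()

    below_zero = pd.DataFrame(
        {"ffa_reesterified": means["ffa_reesterified"] < 0}, index=means.index
    )
    return FluxTable(means=means, sds=sds, n_wells=n_wells, below_zero=below_zero)


def compare_conditions(
    table: FluxTable,
    quantity: str,
    contrast: tuple[tuple[str, str], tuple[str, str]],
) -> ConditionContrast:
    """Fold change (B/A) and difference (B − A) of a quantity's means."""
    (gen_a, block_a), (gen_b, block_b) = contrast
    mean_a, _ = table.cell(gen_a, block_a, quantity)
    mean_b, _ = table.cell(gen_b, block_b, quantity)
    if np.isnan(mean_a) or np.isnan(mean_b):
        raise ValueError(f"{quantity} is absent for one side of the contrast")
    fold = mean_b / mean_a if mean_a != 0 else None
    return ConditionContrast(fold=fold, difference=mean_b - mean_a)
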