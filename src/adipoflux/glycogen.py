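"""Glycolysis / glycogen bookkeeping.

Lactate release implies a minimal glycolytic glucose demand (2 lactate
per glucose). When that demand exceeds measured glucose uptake, the
difference must come from an internal store — glycogen. A measured
glycogen time course yields the mobilization flux directly, in glucose
units via the 162 g/mol anhydroglucose residue.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .respirometry import Condition


@dataclass(frozen=True)
class GlycogenTimepoint:
    """Glycogen content (µg per cm²) at one time point."""

    time_h: float
    content_ug: float
    condition: Condition | None = None

    def __post_init__(self) -> None:
        if self.content_ug < 0:
            raise ValueError("content_ug must be non-negative")


def glucose_demand_from_lactate(
    lactate_release: float, lactate_per_glucose: float = 2.0
) -> float:
    """Lower bound on glycolytic glucose use implied by lactate output.

    Deliberately conservative: pyruvate oxidized rather than reduced to
    lactate is ignored, so true glucose consumption is at least this.
    """
    if lactate_release < 0:
        raise ValueError("lactate_release must be non-negative")
    return lactate_release / lactate_per_glucose


def glycogen_mobilization_inferred(
    glucose_demand: float, glucose_uptake: float
) -> float:
    """Net internal glucose-store mobilization required to meet demand.

    Positive values mean glucose uptake cannot supply the glycolytic
    flux and glycogen must be consumed.
    """
    if glucose_demand < 0 or glucose_uptake < 0:
        raise ValueError("inputs must be non-negative")
    return glucose_demand - glucose_uptake


def glycogen_flux_from_timecourse(
    points: Sequence[GlycogenTimepoint],
    mw_anhydroglucose: float = 162.0,
) -> float:
    """Glycogen flux in glucose units from a content time course.

    Least-squares slope of content (µg/cm²) vs time (h), converted to
    nmol glucose-units·h⁻¹·cm⁻² (µg·h⁻¹ × 1000 / (g/mol) = nmol·h⁻¹).
    Negative = depletion.
    """
    if len(points) < 2:
        raise ValueError("at least two time points are required")
    t = np.array([p.time_h for p in points], dtype=float)
    c = np.array([p.content_ug for p in points], dtype=float)
    if np.unique(t).size < 2:
        raise ValueError("time points must not be coincident")
    slope_ug_per_h = np.polyfit(t, c, 1)[0]
    return float(slope_ug_per_h * 1000.0 / mw_anhydroglucose)
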