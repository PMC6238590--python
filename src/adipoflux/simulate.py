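"""Synthetic plate-experiment generator with known ground truth.

Emulates the three raw inputs of the flux pipeline — injection-protocol
respirometry traces, per-well supernatant metabolite rates, and glycogen
time courses — from a :class:`SyntheticTruth` whose defaults are the
published condition means. PPR traces are generated *from* the
acidification model (CO₂ + lactate + FFA sources), so a decomposition of
simulated data has zero structural residual in expectation and any
residual isolates a pipeline bug; an optional ``unexplained_ppr`` term
exercises residual reporting.

Noise model: one multiplicative lognormal factor per well and quantity
(strictly positive rates; default CV 10%), plus additive Gaussian jitter
on individual trace measurements. A fixed seed makes every draw
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .acidification import decompose_ppr
from .assembly import FluxTable, build_flux_table
from .constants import CultureGeometry, ModelConstants
from .lipid import OxidationMode
from .reference import MEASURED_QUANTITIES, PUBLISHED_RATES
from .respirometry import Condition, RespirationTrace, segment_phases

#: injection order name -> agent sequence
PROTOCOLS = {
    "iso_first": ("isoproterenol", "oligomycin", "FCCP", "antimycinA"),
    "oligo_first": ("oligomycin", "isoproterenol", "FCCP", "antimycinA"),
}

#: (order, phase name) -> treatment block whose truth sets the phase level
PHASE_BLOCK = {
    ("iso_first", "basal"): "Basal",
    ("iso_first", "post_isoproterenol"): "Iso",
    ("iso_first", "post_oligomycin"): "Oligo iso",
    ("oligo_first", "basal"): "Basal",
    ("oligo_first", "post_oligomycin"): "Oligo basal",
    ("oligo_first", "post_isoproterenol"): "Oligo iso",
}

_CYCLE_MIN = 6.0
_CYCLES_PER_PHASE = 4


@dataclass
class SyntheticTruth:
    """Ground-truth condition fluxes and the noise model.

    ``ocr`` and ``metabolites`` are keyed by (genotype, block); rates in
    nmol·h⁻¹·cm⁻². ``glycogen_flux`` is in glucose-unit nmol·h⁻¹·cm⁻²
    (negative = depletion).
    """

    ocr: dict[tuple[str, str], float]
    metabolites: dict[tuple[str, str], dict[str, float]]
    fccp_ocr: dict[str, float]
    antimycin_ocr: dict[str, float]
    seed: int
    glycogen_initial_ug: float = 13.8
    glycogen_flux: dict[tuple[str, str], float] = field(default_factory=dict)
    noise_sd: float = 0.10
    trace_jitter_sd: float = 1.0
    wells_per_condition: int = 6
    unexplained_ppr: float = 0.0

    def validate(self) -> None:
        for key, value in self.ocr.items():
            if value < 0:
                raise ValueError(f"true OCR for {key} is negative")
        for key, rates in self.metabolites.items():
            for quantity, value in rates.items():
                if value < 0:
                    raise ValueError(f"true {quantity} for {key} is negative")
        if self.noise_sd < 0 or self.trace_jitter_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")
        if self.wells_per_condition < 1:
            raise ValueError("wells_per_condition must be at least 1")
        if self.glycogen_initial_ug < 0:
            raise ValueError("glycogen_initial_ug must be non-negative")

    def noise_free(self) -> "SyntheticTruth":
        return replace(self, noise_sd=0.0, trace_jitter_sd=0.0)


@dataclass
class SimulatedDataset:
    """Raw synthetic plate data plus the truth that generated it."""

    traces: pd.DataFrame  # well, genotype, order, time_min, ocr_pmol_min, ppr_pmol_min
    injections: pd.DataFrame  # well_group, time_min, agent
    wells: pd.DataFrame  # well, genotype, block, measured rates
    glycogen: pd.DataFrame  # genotype, block, time_h, content_ug
    truth: SyntheticTruth

    def trace_objects(self) -> list[RespirationTrace]:
        """Materialise traces as :class:`RespirationTrace` objects."""
        out = []
        inj = {
            group: [(float(r.time_min), r.agent) for r in g.itertuples()]
            for group, g in self.injections.groupby("well_group")
        }
        for (well, genotype, order), g in self.traces.groupby(
            ["well", "genotype", "order"], sort=True
        ):
            g = g.sort_values("time_min")
            out.append(
                RespirationTrace(
                    well_id=str(well),
                    condition=Condition(genotype=genotype),
                    timepoints=g["time_min"].to_numpy(),
                    ocr=g["ocr_pmol_min"].to_numpy(),
                    ppr=g["ppr_pmol_min"].to_numpy(),
                    injections=inj[f"{genotype}:{order}"],
                )
            )
        return out


def default_truth(seed: int, **overrides) -> SyntheticTruth:
    """Truth parameterised to the published condition means.

    FCCP (maximal) OCR is set 25% above each genotype's highest block
    OCR and antimycin A (non-mitochondrial) OCR to 3 nmol·h⁻¹·cm⁻²;
    neither has a printed reference value. The isoproterenol glycogen
    flux defaults to −54 glucose-unit nmol·h⁻¹·cm⁻² (net depletion of
    the internal store); basal flux to 0.
    """
    ocr = {key: cells["o2_consumption"][0] for key, cells in PUBLISHED_RATES.items()}
    metabolites = {
        key: {
            q: cells[q][0]
            for q in MEASURED_QUANTITIES
            if q != "o2_consumption" and q in cells
        }
        for key, cells in PUBLISHED_RATES.items()
    }
    genotypes = sorted({g for g, _ in PUBLISHED_RATES})
    fccp = {
        g: 1.25 * max(v for (gg, _), v in ocr.items() if gg == g) for g in genotypes
    }
    antimycin = {g: 3.0 for g in genotypes}
    glycogen_flux = {}
    for g in genotypes:
        glycogen_flux[(g, "Basal")] = 0.0
        glycogen_flux[(g, "Iso")] = -54.0
    truth = SyntheticTruth(
        ocr=ocr,
        metabolites=metabolites,
        fccp_ocr=fccp,
        antimycin_ocr=antimycin,
        glycogen_flux=glycogen_flux,
        seed=seed,
    )
    return replace(truth, **overrides) if overrides else truth


def _phase_levels(
    truth: SyntheticTruth, genotype: str, order: str, constants: ModelConstants
) -> list[tuple[str, float, float]]:
    """(phase, true OCR, true PPR) per phase of one protocol order."""
    names = ["basal"] + [f"post_{a}" for a in PROTOCOLS[order]]
    levels = []
    last_block = "Basal"
    for name in names:
        block = PHASE_BLOCK.get((order, name))
        if block is not None:
            ocr = truth.ocr[(genotype, block)]
            last_block = block
        elif name == "post_FCCP":
            ocr = truth.fccp_ocr[genotype]
        else:  # post_antimycinA
            ocr = truth.antimycin_ocr[genotype]
        rates = truth.metabolites[(genotype, last_block)]
        ppr = (
            decompose_ppr(
                ocr, rates["lactate_release"], rates["ffa_release"], constants=constants
            ).modeled_total
            + truth.unexplained_ppr
        )
        levels.append((name, ocr, ppr))
    return levels


def simulate_experiment(
    truth: SyntheticTruth,
    geometry: CultureGeometry | None = None,
    constants: ModelConstants | None = None,
) -> SimulatedDataset:
    """Generate one full synthetic plate experiment.

    Traces are piecewise-constant at the phase-true levels (converted to
    the instrument's pmol·min⁻¹·well⁻¹) plus additive jitter; each well
    carries one multiplicative size factor shared by its OCR and PPR.
    Metabolite rates are drawn per well and quantity around the condition
    truth. Deterministic given ``truth.seed``.
    """
    truth.validate()
    geometry = geometry or CultureGeometry()
    constants = constants or ModelConstants()
    rng = np.random.default_rng(truth.seed)
    to_pmol_min = geometry.area_cm2 * 1000.0 / 60.0

    def lognormal_factor(size=None):
        if truth.noise_sd == 0:
            return np.ones(size) if size is not None else 1.0
        # mean-one multiplicative noise
        sigma = truth.noise_sd
        return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)

    genotypes = sorted({g for g, _ in truth.ocr})

    # --- respirometry traces ---------------------------------------------
    trace_rows = []
    injection_rows = []
    n_phases = 5
    for genotype in genotypes:
        for order, agents in PROTOCOLS.items():
            for i, agent in enumerate(agents, start=1):
                injection_rows.append(
                    {
                        "well_group": f"{genotype}:{order}",
                        "time_min": (i * _CYCLES_PER_PHASE) * _CYCLE_MIN + _CYCLE_MIN / 2.0,
                        "agent": agent,
                    }
                )
            levels = _phase_levels(truth, genotype, order, constants)
            for w in range(truth.wells_per_condition):
                well = f"{genotype}-{order}-w{w + 1:02d}"
                size_factor = lognormal_factor()
                for p, (phase, ocr_level, ppr_level) in enumerate(levels):
                    times = (
                        np.arange(1, _CYCLES_PER_PHASE + 1) + p * _CYCLES_PER_PHASE
                    ) * _CYCLE_MIN
                    ocr_pmol = ocr_level * size_factor * to_pmol_min
                    ppr_pmol = ppr_level * size_factor * to_pmol_min
                    jitter = (
                        rng.normal(0.0, truth.trace_jitter_sd, size=(2, times.size))
                        if truth.trace_jitter_sd > 0
                        else np.zeros((2, times.size))
                    )
                    for k, t in enumerate(times):
                        trace_rows.append(
                            {
                                "well": well,
                                "genotype": genotype,
                                "order": order,
                                "time_min": float(t),
                                "ocr_pmol_min": max(0.0, ocr_pmol + jitter[0, k]),
                                "ppr_pmol_min": max(0.0, ppr_pmol + jitter[1, k]),
                            }
                        )
    assert len(trace_rows) == (
        len(genotypes) * len(PROTOCOLS) * truth.wells_per_condition * n_phases * _CYCLES_PER_PHASE
    )

    # --- per-well metabolite rates (+ the well's block OCR) ---------------
    well_rows = []
    for (genotype, block), rates in sorted(truth.metabolites.items()):
        for w in range(truth.wells_per_condition):
            row = {
                "well": f"{genotype}-{block}-m{w + 1:02d}",
                "genotype": genotype,
                "block": block,
                "o2_consumption": truth.ocr[(genotype, block)] * lognormal_factor(),
            }
            for quantity, value in rates.items():
                row[quantity] = value * lognormal_factor()
            well_rows.append(row)
    wells = pd.DataFrame(well_rows)

    # --- glycogen time courses -------------------------------------------
    glycogen_rows = []
    # one hour of accumulation (the supernatant exposure window); with the
    # default initial store the depleting condition stays positive throughout
    times_h = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
    slope_ug = {
        key: flux * constants.mw_anhydroglucose / 1000.0
        for key, flux in truth.glycogen_flux.items()
    }
    for (genotype, block), slope in sorted(slope_ug.items()):
        for t in times_h:
            content = truth.glycogen_initial_ug + slope * t
            content *= lognormal_factor()
            glycogen_rows.append(
                {
                    "genotype": genotype,
                    "block": block,
                    "time_h": float(t),
                    "content_ug": max(0.0, float(content)),
                }
            )

    return SimulatedDataset(
        traces=pd.DataFrame(trace_rows),
        injections=pd.DataFrame(injection_rows),
        wells=wells,
        glycogen=pd.DataFrame(glycogen_rows),
        truth=truth,
    )


def block_ocr_from_traces(
    dataset: SimulatedDataset,
    geometry: CultureGeometry | None = None,
    skip_first: int = 1,
) -> pd.DataFrame:
    """Per-well block OCR recovered from the traces via phase segmentation."""
    geometry = geometry or CultureGeometry()
    rows = []
    for trace in dataset.trace_objects():
        order = trace.well_id.split("-")[1]
        phases = segment_phases(trace, well_area_cm2=geometry.area_cm2, skip_first=skip_first)
        for phase, ocr in phases.ocr.items():
            block = PHASE_BLOCK.get((order, phase))
            if block is not None:
                rows.append(
                    {
                        "well": trace.well_id,
                        "genotype": trace.condition.genotype,
                        "order": order,
                        "block": block,
                        "o2_consumption": ocr,
                    }
                )
    return pd.DataFrame(rows)


def recover_flux_table(
    dataset: SimulatedDataset,
    constants: ModelConstants | None = None,
    oxidation_mode: OxidationMode = "stoichiometric",
    co2_per_o2: float | None = None,
) -> FluxTable:
    """Run the bookkeeping pipeline on a simulated dataset."""
    return build_flux_table(
        dataset.wells,
        constants=constants,
        oxidation_mode=oxidation_mode,
        co2_per_o2=co2_per_o2,
    )


def save_truth(truth: SyntheticTruth, path) -> None:
    """Serialize ground truth to JSON (condition keys as "genotype/block")."""
    import json
    from pathlib import Path

    payload = {
        "ocr": {f"{g}/{b}": v for (g, b), v in truth.ocr.items()},
        "metabolites": {f"{g}/{b}": v for (g, b), v in truth.metabolites.items()},
        "fccp_ocr": truth.fccp_ocr,
        "antimycin_ocr": truth.antimycin_ocr,
        "glycogen_flux": {f"{g}/{b}": v for (g, b), v in truth.glycogen_flux.items()},
        "glycogen_initial_ug": truth.glycogen_initial_ug,
        "seed": truth.seed,
        "noise_sd": truth.noise_sd,
        "trace_jitter_sd": truth.trace_jitter_sd,
        "wells_per_condition": truth.wells_per_condition,
        "unexplained_ppr": truth.unexplained_ppr,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def load_truth(path) -> SyntheticTruth:
    """Inverse of :func:`save_truth`."""
    import json
    from pathlib import Path

    payload = json.loads(Path(path).read_text())

    def unkey(d):
        return {tuple(k.split("/")): v for k, v in d.items()}

    return SyntheticTruth(
        ocr=unkey(payload["ocr"]),
        metabolites=unkey(payload["metabolites"]),
        fccp_ocr=payload["fccp_ocr"],
        antimycin_ocr=payload["antimycin_ocr"],
        glycogen_flux=unkey(payload["glycogen_flux"]),
        glycogen_initial_ug=payload["glycogen_initial_ug"],
        seed=payload["seed"],
        noise_sd=payload["noise_sd"],
        trace_jitter_sd=payload["trace_jitter_sd"],
        wells_per_condition=payload["wells_per_condition"],
        unexplained_ppr=payload["unexplained_ppr"],
    )


def recovery_report(truth: SyntheticTruth, estimates: FluxTable) -> pd.DataFrame:
    """Bias and relative RMSE of recovered measured rates per quantity.

    Bias is mean(estimate − truth) across conditions; relative RMSE is
    the root-mean-square of (estimate − truth)/truth.
    """
    est_keys = set(estimates.means.index)
    truth_keys = set(truth.metabolites)
    if not truth_keys <= est_keys:
        raise ValueError(
            f"estimates are missing condition(s): {sorted(truth_keys - est_keys)}"
        )
    records: dict[str, list[tuple[float, float]]] = {}
    for key, rates in truth.metabolites.items():
        pairs = dict(rates)
        pairs["o2_consumption"] = truth.ocr[key]
        for quantity, true_value in pairs.items():
            est = estimates.means.loc[key, quantity]
            records.setdefault(quantity, []).append((float(est), true_value))
    rows = []
    for quantity, pairs in sorted(records.items()):
        est = np.array([p[0] for p in pairs])
        true = np.array([p[1] for p in pairs])
        rel = (est - true) / np.where(true == 0, np.nan, true)
        rows.append(
            {
                "quantity": quantity,
                "bias": float(np.mean(est - true)),
                "rel_rmse": float(np.sqrt(np.nanmean(rel**2))),
                "n_conditions": len(pairs),
            }
        )
    return pd.DataFrame(rows).set_index("quantity")
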