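"""Segmentation of injection-protocol respirometry traces and
decomposition into respiration components.

A plate assay measures O₂ consumption (OCR) and proton production (PPR)
in repeated cycles; sequential injections of oligomycin (ATP-synthase
inhibitor), isoproterenol (β-adrenergic agonist), FCCP (protonophore)
and antimycin A (complex-III inhibitor) partition the trace into phases
whose means carry distinct physiological meaning:

* coupled respiration  = basal − post-oligomycin
* iso-induced          = post-isoproterenol − phase preceding the injection
* maximal capacity     = post-FCCP
* non-mitochondrial    = post-antimycin A
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

AGENTS = ("oligomycin", "isoproterenol", "FCCP", "antimycinA")

#: pmol·min⁻¹·well⁻¹ → nmol·h⁻¹·cm⁻² (before dividing by well area)
_PMOL_MIN_TO_NMOL_H = 60.0 / 1000.0


@dataclass(frozen=True)
class Condition:
    """Genotype × treatment cell of the experimental design."""

    genotype: str  # "WT" | "UCP1KO"
    stimulated: bool = False  # isoproterenol present
    oligomycin_present: bool = False

    GENOTYPES = ("WT", "UCP1KO")
    BLOCKS = ("Basal", "Iso", "Oligo basal", "Oligo iso")

    def __post_init__(self) -> None:
        if self.genotype not in self.GENOTYPES:
            raise ValueError(f"genotype must be one of {self.GENOTYPES}")

    @property
    def block(self) -> str:
        """The treatment-block label used in the published flux table."""
        if self.oligomycin_present:
            return "Oligo iso" if self.stimulated else "Oligo basal"
        return "Iso" if self.stimulated else "Basal"

    @classmethod
    def from_block(cls, genotype: str, block: str) -> "Condition":
        if block not in cls.BLOCKS:
            raise ValueError(f"block must be one of {cls.BLOCKS}")
        return cls(
            genotype=genotype,
            stimulated="iso" in block.lower(),
            oligomycin_present=block.lower().startswith("oligo"),
        )


@dataclass
class RespirationTrace:
    """One well's OCR (and optionally PPR) time series with injections.

    Rates are instrument-native pmol·min⁻¹·well⁻¹; times in minutes.
    """

    well_id: str
    condition: Condition
    timepoints: np.ndarray
    ocr: np.ndarray
    injections: list[tuple[float, str]]
    ppr: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.ocr = np.asarray(self.ocr, dtype=float)
        if self.ppr is not None:
            self.ppr = np.asarray(self.ppr, dtype=float)
            if self.ppr.shape != self.timepoints.shape:
                raise ValueError("ppr must have the same length as timepoints")
        if self.ocr.shape != self.timepoints.shape:
            raise ValueError("ocr must have the same length as timepoints")
        if len(self.timepoints) and np.any(np.diff(self.timepoints) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        times = [t for t, _ in self.injections]
        if times != sorted(times):
            raise ValueError("injection times must be ordered")
        for t, agent in self.injections:
            if agent not in AGENTS:
                raise ValueError(f"unknown agent {agent!r}; expected one of {AGENTS}")
            if len(self.timepoints) and not (
                self.timepoints[0] <= t <= self.timepoints[-1]
            ):
                raise ValueError(
                    f"injection at {t} min lies outside the trace time range"
                )


@dataclass
class RespirationPhases:
    """Inter-injection phase means in nmol·h⁻¹·cm⁻².

    ``order`` records the phase sequence (``basal`` then ``post_<agent>``);
    ``ocr``/``ppr`` map phase name → mean rate.
    """

    ocr: dict[str, float]
    order: list[str]
    ppr: dict[str, float] | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        # Non-mitochondrial OCR exceeding basal is physiologically
        # impossible; flag it but never silently clamp.
        post_aa = self.ocr.get("post_antimycinA")
        basal = self.ocr.get("basal")
        if post_aa is not None and basal is not None and post_aa > basal:
            self.flags.append("non_mito_exceeds_basal")


@dataclass
class RespirationComponents:
    """Derived respiration components (nmol·h⁻¹·cm⁻²)."""

    total_basal: float
    non_mito: float | None = None
    mito_basal: float | None = None
    coupled: float | None = None
    iso_induced: float | None = None
    max_capacity: float | None = None
    iso_percent_of_basal: float | None = None
    flags: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class OligoSensitivity:
    """Fraction of iso-induced respiration abolished by oligomycin."""

    value: float
    clamped: bool = False


def segment_phases(
    trace: RespirationTrace,
    well_area_cm2: float = 0.106,
    skip_first: int = 1,
) -> RespirationPhases:
    """Average each inter-injection interval into a phase mean.

    The first ``skip_first`` measurement cycles after every injection are
    discarded as mixing transients. Rates are converted from the
    instrument's pmol·min⁻¹·well⁻¹ to nmol·h⁻¹·cm⁻² (×60/1000/area).
    """
    if well_area_cm2 <= 0:
        raise ValueError("well_area_cm2 must be positive")
    if skip_first < 0:
        raise ValueError("skip_first must be non-negative")
    if len(trace.timepoints) == 0:
        raise ValueError(f"well {trace.well_id}: empty trace")

    bounds = [trace.timepoints[0] - 1.0] + [t for t, _ in trace.injections]
    bounds.append(trace.timepoints[-1] + 1.0)
    names = ["basal"] + [f"post_{agent}" for _, agent in trace.injections]

    scale = _PMOL_MIN_TO_NMOL_H / well_area_cm2
    ocr_means: dict[str, float] = {}
    ppr_means: dict[str, float] | None = {} if trace.ppr is not None else None
    for name, lo, hi in zip(names, bounds[:-1], bounds[1:]):
        mask = (trace.timepoints > lo) & (trace.timepoints <= hi)
        idx = np.flatnonzero(mask)
        if name != "basal":
            idx = idx[skip_first:]
        if idx.size == 0:
            raise ValueError(
                f"well {trace.well_id}: phase {name!r} has no usable "
                f"timepoints after skipping {skip_first}"
            )
        ocr_means[name] = float(trace.ocr[idx].mean()) * scale
        if ppr_means is not None:
            ppr_means[name] = float(trace.ppr[idx].mean()) * scale

    return RespirationPhases(ocr=ocr_means, order=names, ppr=ppr_means)


def decompose_respiration(
    phases: RespirationPhases, protocol_order: list[str] | None = None
) -> RespirationComponents:
    """Derive respiration components from phase means.

    ``protocol_order`` is the injection order; it defaults to the order
    recorded in ``phases``. The iso-induced component uses the phase
    immediately preceding the isoproterenol injection as its reference,
    so both injection orders (oligomycin-then-iso and iso-then-oligomycin)
    are handled by the same rule.
    """
    if protocol_order is None:
        protocol_order = [p.removeprefix("post_") for p in phases.order[1:]]
    expected = ["basal"] + [f"post_{agent}" for agent in protocol_order]
    for name in expected:
        if name not in phases.ocr:
            raise ValueError(f"phase {name!r} required by protocol order is missing")

    ocr = phases.ocr
    basal = ocr["basal"]
    comp = RespirationComponents(total_basal=basal, flags=list(phases.flags))

    if "post_antimycinA" in ocr:
        comp.non_mito = ocr["post_antimycinA"]
        comp.mito_basal = basal - comp.non_mito
    if "post_oligomycin" in ocr:
        comp.coupled = basal - ocr["post_oligomycin"]
        if comp.coupled < 0:
            comp.flags.append("negative_coupled")
        if protocol_order[0] != "oligomycin":
            # oligomycin injected after iso: basal-minus-oligo mixes the
            # iso response into the coupled estimate
            comp.flags.append("coupled_reference_not_basal")
    if "post_isoproterenol" in ocr:
        i = expected.index("post_isoproterenol")
        reference = ocr[expected[i - 1]]
        post_iso = ocr["post_isoproterenol"]
        comp.iso_induced = post_iso - reference
        if basal != 0:
            comp.iso_percent_of_basal = 100.0 * post_iso / basal
    if "post_FCCP" in ocr:
        comp.max_capacity = ocr["post_FCCP"]
    return comp


def oligo_sensitivity(
    iso_induced_free: float, iso_induced_under_oligo: float
) -> OligoSensitivity:
    """Oligomycin sensitivity of the isoproterenol response.

    1 means the iso-induced respiration is fully ATP-synthesis dependent
    (abolished under oligomycin); 0 means fully insensitive. Raw values
    outside [0, 1] — e.g. when the response under oligomycin exceeds the
    free response — are clamped, with ``clamped`` set.
    """
    if iso_induced_free <= 0:
        raise ValueError(
            "iso_induced_free must be positive: sensitivity is undefined "
            "without an isoproterenol response"
        )
    raw = 1.0 - iso_induced_under_oligo / iso_induced_free
    clamped = min(1.0, max(0.0, raw))
    return OligoSensitivity(value=clamped, clamped=clamped != raw)
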