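"""Readers and writers for the pipeline's tabular formats.

All inputs are plain CSV (comma-separated, UTF-8, header row required,
"." decimal separator); outputs are TSV for display and JSON for
machine consumption. Validation errors name the offending row and
column so plate files can be fixed quickly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .assembly import FluxTable, QUANTITIES
from .constants import CultureGeometry, ModelConstants
from .glycogen import GlycogenTimepoint
from .respirometry import Condition, RespirationTrace

_RATE_COLUMNS = (
    "glycerol_release",
    "ffa_release",
    "lactate_release",
    "glucose_uptake",
    "o2_consumption",
)


class SchemaError(ValueError):
    """A tabular input violates its schema."""


def _read_csv(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path)
    if frame.empty:
        raise SchemaError(f"{path}: file contains no data rows")
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return frame


def _check_numeric(frame: pd.DataFrame, path: Path | str, columns, allow_nan=()):
    for column in columns:
        if column not in frame.columns:
            continue
        values = pd.to_numeric(frame[column], errors="coerce")
        bad = values.isna() & ~frame[column].isna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # 1-based, plus header line
            raise SchemaError(
                f"{path}: non-numeric value in column {column!r} at line {row}"
            )
        if column not in allow_nan and frame[column].isna().any():
            row = int(frame[column].isna().idxmax()) + 2
            raise SchemaError(f"{path}: empty cell in column {column!r} at line {row}")
        frame[column] = values


def read_measurements(path: str | Path) -> pd.DataFrame:
    """Read per-well measured rates (nmol·h⁻¹·cm⁻²).

    Required columns: well, genotype, block, glycerol_release,
    ffa_release, lactate_release, o2_consumption; optional
    glucose_uptake (empty cells = not measured, e.g. oligomycin blocks).
    Negative rates are rejected with the offending line number.
    """
    frame = _read_csv(
        path,
        (
            "well",
            "genotype",
            "block",
            "glycerol_release",
            "ffa_release",
            "lactate_release",
            "o2_consumption",
        ),
    )
    _check_numeric(frame, path, _RATE_COLUMNS, allow_nan=("glucose_uptake",))
    for column in _RATE_COLUMNS:
        if column not in frame.columns:
            continue
        negative = frame[column] < 0
        if negative.any():
            row = int(negative.idxmax()) + 2
            raise SchemaError(
                f"{path}: negative rate in column {column!r} at line {row}"
            )
    for row in frame.itertuples():
        Condition.from_block(str(row.genotype), str(row.block))  # validates labels
    return frame


def read_traces(
    traces_path: str | Path, injections_path: str | Path
) -> list[RespirationTrace]:
    """Read respirometry traces plus their sidecar injection schedule.

    Trace columns: well, well_group, genotype, time_min, ocr_pmol_min,
    optional ppr_pmol_min. Injection columns: well_group, time_min,
    agent. Wells are matched to injections through ``well_group``.
    """
    traces = _read_csv(
        traces_path, ("well", "well_group", "genotype", "time_min", "ocr_pmol_min")
    )
    _check_numeric(
        traces, traces_path, ("time_min", "ocr_pmol_min", "ppr_pmol_min"),
        allow_nan=("ppr_pmol_min",),
    )
    injections = _read_csv(injections_path, ("well_group", "time_min", "agent"))
    _check_numeric(injections, injections_path, ("time_min",))
    schedule = {
        group: [(float(r.time_min), str(r.agent)) for r in g.itertuples()]
        for group, g in injections.groupby("well_group")
    }
    out = []
    for (well, group, genotype), g in traces.groupby(
        ["well", "well_group", "genotype"], sort=True
    ):
        if group not in schedule:
            raise SchemaError(
                f"{traces_path}: well {well!r} references unknown well_group {group!r}"
            )
        g = g.sort_values("time_min")
        ppr = None
        if "ppr_pmol_min" in g.columns and g["ppr_pmol_min"].notna().all():
            ppr = g["ppr_pmol_min"].to_numpy()
        out.append(
            RespirationTrace(
                well_id=str(well),
                condition=Condition(genotype=str(genotype)),
                timepoints=g["time_min"].to_numpy(),
                ocr=g["ocr_pmol_min"].to_numpy(),
                ppr=ppr,
                injections=schedule[group],
            )
        )
    return out


def read_glycogen(path: str | Path) -> dict[tuple[str, str], list[GlycogenTimepoint]]:
    """Read glycogen time courses keyed by (genotype, block)."""
    frame = _read_csv(path, ("genotype", "block", "time_h", "content_ug"))
    _check_numeric(frame, path, ("time_h", "content_ug"))
    negative = frame["content_ug"] < 0
    if negative.any():
        row = int(negative.idxmax()) + 2
        raise SchemaError(f"{path}: negative content_ug at line {row}")
    out: dict[tuple[str, str], list[GlycogenTimepoint]] = {}
    for row in frame.itertuples():
        condition = Condition.from_block(str(row.genotype), str(row.block))
        out.setdefault((str(row.genotype), str(row.block)), []).append(
            GlycogenTimepoint(
                time_h=float(row.time_h),
                content_ug=float(row.content_ug),
                condition=condition,
            )
        )
    return out


def _display_cell(mean: float, sd: float, below_zero: bool) -> str:
    if below_zero:
        return "<0"
    return f"{mean:.1f} ± {sd:.1f}"


def write_flux_table(table: FluxTable, path: str | Path, format: str = "tsv") -> Path:
    """Write a flux table as display TSV or machine-readable JSON.

    The TSV renders negative re-esterification as ``<0`` (the numeric
    value and flag are preserved in the JSON form). Output is
    deterministic: fixed quantity order, conditions sorted.
    """
    path = Path(path)
    tidy = table.to_tidy()
    order = {q: i for i, q in enumerate(QUANTITIES)}
    tidy = tidy.sort_values(
        ["genotype", "block", "quantity"],
        key=lambda col: col.map(order) if col.name == "quantity" else col,
    ).reset_index(drop=True)
    if format == "tsv":
        tidy["display"] = [
            _display_cell(r.mean, r.sd, r.below_zero) for r in tidy.itertuples()
        ]
        tidy.to_csv(path, sep="\t", index=False, float_format="%.6g")
    elif format == "json":
        payload = {
            "conditions": tidy.to_dict(orient="records"),
            "n_wells": {
                f"{g}/{b}": int(n) for (g, b), n in table.n_wells.items()
            },
        }
        path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def read_flux_table_json(path: str | Path) -> FluxTable:
    """Inverse of :func:`write_flux_table` for the JSON format."""
    payload = json.loads(Path(path).read_text())
    tidy = pd.DataFrame(payload["conditions"])
    means = tidy.pivot_table(
        index=["genotype", "block"], columns="quantity", values="mean"
    )
    sds = tidy.pivot_table(index=["genotype", "block"], columns="quantity", values="sd")
    below = (
        tidy.pivot_table(
            index=["genotype", "block"], columns="quantity", values="below_zero",
            aggfunc="first",
        )
        .astype("boolean")
        .fillna(False)
        .astype(bool)
    )
    means = means.rename_axis(columns=None)
    sds = sds.rename_axis(columns=None)
    below = below.rename_axis(columns=None)
    n_wells = pd.Series(
        {tuple(k.split("/")): v for k, v in payload["n_wells"].items()}
    )
    quantities = [q for q in QUANTITIES if q in means.columns]
    return FluxTable(
        means=means[quantities],
        sds=sds[quantities],
        n_wells=n_wells,
        below_zero=below[["ffa_reesterified"]]
        if "ffa_reesterified" in below.columns
        else below,
    )


@dataclass
class RunConfig:
    """Effective configuration of one pipeline run.

    Unknown keys in the config file are rejected rather than ignored so
    that a typo never silently falls back to a default.
    """

    constants: ModelConstants = field(default_factory=ModelConstants)
    geometry: CultureGeometry = field(default_factory=CultureGeometry)
    oxidation_mode: str = "stoichiometric"
    co2_per_o2: float | None = None  # None -> constants.rq_palmitate
    skip_first: int = 1
    seed: int = 0
    wells_per_condition: int = 6
    noise_sd: float = 0.10
    trace_jitter_sd: float = 1.0
    relative_tolerance: float = 0.02

    def describe(self) -> str:
        parts = [
            f"constants={dataclasses.asdict(self.constants)}",
            f"geometry={dataclasses.asdict(self.geometry)}",
        ]
        for name in (
            "oxidation_mode",
            "co2_per_o2",
            "skip_first",
            "seed",
            "wells_per_condition",
            "noise_sd",
            "trace_jitter_sd",
            "relative_tolerance",
        ):
            parts.append(f"{name}={getattr(self, name)}")
        return "effective config: " + " ".join(parts)


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML run configuration; missing path gives pure defaults."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: config must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise SchemaError(f"{path}: unknown config key(s) {sorted(unknown)}")
    kwargs = dict(raw)
    if "constants" in kwargs:
        kwargs["constants"] = ModelConstants().with_overrides(**(kwargs["constants"] or {}))
    if "geometry" in kwargs:
        geo = kwargs["geometry"] or {}
        unknown_geo = set(geo) - {f.name for f in dataclasses.fields(CultureGeometry)}
        if unknown_geo:
            raise SchemaError(f"{path}: unknown geometry key(s) {sorted(unknown_geo)}")
        kwargs["geometry"] = CultureGeometry(**geo)
    if kwargs.get("co2_per_o2") == "table_calibrated":
        kwargs["co2_per_o2"] = ModelConstants.TABLE_CALIBRATED_CO2_PER_O2
    return RunConfig(**kwargs)
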