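"""File formats and configuration.

Traces travel as plain CSV (columns ``time_ms,counts[,temperature_C]``,
header required, one trace per file) with acquisition metadata in a JSON
sidecar named ``<trace>.meta.json`` — sample id/type, lamp voltage,
dilution factor, dark-subtraction state and any warnings.  Calibration
curves, result records and run configuration are JSON, serialized at full
float precision; display rounding (activity to 0.1%, relative difference
to 0.1% half-up) is applied only when printing.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd

from . import __version__
from .errors import ParseError
from .photometry import OpticalConfig
from .quantify import CalibrationCurve
from .simulator import DEFAULT_SEED, InstrumentNoise
from .traces import PhotonTrace

TRACE_COLUMNS = ("time_ms", "counts")


def sidecar_path(path: str | Path) -> Path:
    return Path(str(path) + ".meta.json")


def read_trace(path: str | Path, **overrides: Any) -> PhotonTrace:
    """Read a photon-trace CSV plus its metadata sidecar (if present).

    Keyword overrides (``sample_type=...`` etc.) take precedence over the
    sidecar.  Parse errors name the offending 1-based file line.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file (missing header)") from exc
    for col in TRACE_COLUMNS:
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    if len(df) == 0:
        raise ParseError(f"{path}: trace has a header but no data rows")
    numeric = {}
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.index[vals.isna() & df[col].notna()]
        if len(bad):
            # +2: one for the header row, one for 0- vs 1-based indexing
            raise ParseError(
                f"{path}: non-numeric value {df[col][bad[0]]!r} in column "
                f"{col!r} at line {bad[0] + 2}"
            )
        if vals.isna().any():
            raise ParseError(
                f"{path}: missing value in column {col!r} at line "
                f"{int(vals.index[vals.isna()][0]) + 2}"
            )
        numeric[col] = vals.to_numpy(dtype=float)
    times = numeric["time_ms"]
    non_mono = np.nonzero(np.diff(times) <= 0)[0]
    if len(non_mono):
        raise ParseError(
            f"{path}: time_ms not strictly increasing at line {int(non_mono[0]) + 3}"
        )
    meta: dict[str, Any] = {}
    sp = sidecar_path(path)
    if sp.exists():
        meta.update(json.loads(sp.read_text()))
    if "temperature_C" in numeric and "temperature_C" not in meta:
        meta["temperature_C"] = float(numeric["temperature_C"][0])
    if "warnings" in meta:
        meta["warnings"] = tuple(meta["warnings"])
    meta.update(overrides)
    return PhotonTrace(times_ms=times, counts=numeric["counts"], **meta)


def write_trace(trace: PhotonTrace, path: str | Path) -> Path:
    """Write a trace CSV plus its metadata sidecar; returns the CSV path."""
    path = Path(path)
    df = pd.DataFrame({"time_ms": trace.times_ms, "counts": trace.counts})
    if trace.temperature_C is not None:
        df["temperature_C"] = trace.temperature_C
    df.to_csv(path, index=False)
    meta = {
        "sample_id": trace.sample_id,
        "sample_type": trace.sample_type,
        "lamp_voltage_V": trace.lamp_voltage_V,
        "temperature_C": trace.temperature_C,
        "dark_subtracted": trace.dark_subtracted,
        "dilution_factor": trace.dilution_factor,
        "warnings": list(trace.warnings),
    }
    sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


@dataclass(frozen=True)
class RunConfig:
    """Pipeline-wide configuration: optics, noise model and QC bounds."""

    optical: OpticalConfig = field(default_factory=OpticalConfig)
    noise: InstrumentNoise = field(default_factory=InstrumentNoise)
    r2_bound: float = 0.985
    cv_bound_percent: float = 10.0
    source_cv_bound_percent: float = 0.5
    t0_s: float = 0.0
    t1_s: float = 60.0
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.r2_bound <= 0 or self.cv_bound_percent <= 0:
            raise ParseError("acceptance bounds must be positive")
        if not self.t1_s > self.t0_s:
            raise ParseError("rate window must be increasing")

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=1))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        if "optical" in raw:
            raw["optical"] = OpticalConfig(**raw["optical"])
        if "noise" in raw:
            raw["noise"] = InstrumentNoise(**raw["noise"])
        return cls(**raw)


@dataclass(frozen=True)
class ResultRecord:
    """One sample's pipeline result with its QC flags; JSON round-trips
    losslessly (timestamps are deliberately excluded)."""

    sample_id: str
    sample_type: str
    dilution_factor: float
    rate_per_min: Optional[float] = None
    activity_percent: Optional[float] = None
    saturated: bool = False
    negative_counts_warning: bool = False
    linearity_pass: Optional[bool] = None
    calibration_id: str = ""
    software_version: str = __version__

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ResultRecord":
        return cls(**d)


def save_calibration(curve: CalibrationCurve, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(dataclasses.asdict(curve), indent=1))
    return path


def load_calibration(path: str | Path) -> CalibrationCurve:
    return CalibrationCurve(**json.loads(Path(path).read_text()))
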