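"""Reading, writing and conditioning of force-platform recordings.

An instrumented treadmill samples the three components of the ground
reaction force (GRF) on a uniform time grid (nominally 1000 Hz).  This
module defines the in-memory container :class:`ForceRecording`, a plain
CSV interchange format for raw traces, the zero-phase Butterworth
conditioning filter applied before any event detection, and a JSON results
document for downstream summaries.

Sign conventions
----------------
* ``f_v``  — vertical force, positive upward (N).
* ``f_ap`` — fore-aft (anteroposterior) force, positive in the direction
  of progression, so braking forces are negative (N).
* ``f_ml`` — mediolateral force (N).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "ForceRecording",
    "GrfIOError",
    "MissingChannelError",
    "NonUniformSamplingError",
    "EmptyRecordingError",
    "read_grf_csv",
    "write_grf_csv",
    "lowpass_filter",
    "write_results",
    "read_results",
    "validate_results_document",
    "RESULTS_SCHEMA_ID",
]

#: column names of the CSV interchange dialect (comma separated, dot
#: decimal, mandatory header, UTF-8).
CSV_COLUMNS = ("time_s", "f_ap_N", "f_ml_N", "f_v_N")

STANDARD_GRAVITY = 9.81  # m/s^2


class GrfIOError(ValueError):
    """Base class for recording I/O failures."""


class MissingChannelError(GrfIOError):
    """A required force/time column is absent from the input file."""


class NonUniformSamplingError(GrfIOError):
    """Time stamps deviate from a uniform grid by more than the tolerance."""


class EmptyRecordingError(GrfIOError):
    """The input file contains no samples."""


@dataclass(frozen=True)
class ForceRecording:
    """Uniformly sampled 3-channel GRF time series plus trial metadata.

    Parameters
    ----------
    time : ndarray
        Sample times in seconds, strictly increasing with a constant step
        of ``1/rate`` (within 1e-9 s).
    f_v, f_ap, f_ml : ndarray
        Vertical, fore-aft and mediolateral force channels in newtons.
    rate : float
        Sampling frequency in Hz.
    mass : float
        Body mass of the runner in kg.
    belt_speed : float
        Treadmill belt speed in m/s.
    gravity : float
        Gravitational acceleration in m/s^2 (default 9.81).
    """

    time: np.ndarray
    f_v: np.ndarray
    f_ap: np.ndarray
    f_ml: np.ndarray
    rate: float
    mass: float
    belt_speed: float
    gravity: float = STANDARD_GRAVITY

    def __post_init__(self) -> None:
        for name in ("time", "f_v", "f_ap", "f_ml"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
        n = self.time.size
        if n < 2:
            raise ValueError("recording must contain at least 2 samples")
        for name in ("f_v", "f_ap", "f_ml"):
            if getattr(self, name).size != n:
                raise ValueError(f"channel {name!r} length differs from time")
        if not (self.mass > 0):
            raise ValueError("mass must be positive")
        if self.belt_speed < 0:
            raise ValueError("belt_speed must be non-negative")
        if not (self.rate > 0):
            raise ValueError("rate must be positive")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            raise ValueError("time must be strictly increasing")
        if np.max(np.abs(dt - 1.0 / self.rate)) > 1e-9:
            raise ValueError("time grid is not uniform at 1/rate within 1e-9 s")

    def __len__(self) -> int:
        return int(self.time.size)

    @property
    def duration(self) -> float:
        """Span of the recording in seconds (first to last sample)."""
        return float(self.time[-1] - self.time[0])

    @property
    def body_weight(self) -> float:
        """Body weight ``mass * gravity`` in newtons."""
        return self.mass * self.gravity

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time,
                "f_ap_N": self.f_ap,
                "f_ml_N": self.f_ml,
                "f_v_N": self.f_v,
            }
        )


def read_grf_csv(
    path: str | Path,
    mass: float,
    belt_speed: float,
    gravity: float = STANDARD_GRAVITY,
) -> ForceRecording:
    """Read a GRF time series from a delimited text file.

    The file must be comma separated with a header naming the columns
    ``time_s, f_ap_N, f_ml_N, f_v_N`` (any order, extra columns ignored).
    The sampling rate is inferred from the median time step; time stamps
    may jitter by at most 1% of that step and are snapped to the exact
    uniform grid.

    Raises
    ------
    EmptyRecordingError, MissingChannelError, NonUniformSamplingError
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise EmptyRecordingError(f"{path}: file contains no data") from exc
    if df.empty:
        raise EmptyRecordingError(f"{path}: file contains no samples")
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise MissingChannelError(
            f"{path}: missing channel column(s) {', '.join(missing)}"
        )
    if len(df) < 2:
        raise EmptyRecordingError(f"{path}: need at least 2 samples")
    t = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise NonUniformSamplingError(f"{path}: time stamps not increasing")
    step = float(np.median(dt))
    if np.max(np.abs(dt - step)) > 0.01 * step:
        raise NonUniformSamplingError(
            f"{path}: sampling jitter exceeds 1% of the median step {step:g} s"
        )
    rate = 1.0 / step
    time = t[0] + np.arange(len(df)) / rate
    return ForceRecording(
        time=time,
        f_v=df["f_v_N"].to_numpy(dtype=float),
        f_ap=df["f_ap_N"].to_numpy(dtype=float),
        f_ml=df["f_ml_N"].to_numpy(dtype=float),
        rate=rate,
        mass=mass,
        belt_speed=belt_speed,
        gravity=gravity,
    )


def write_grf_csv(rec: ForceRecording, path: str | Path) -> None:
    """Write a recording to the CSV interchange dialect (lossless floats)."""
    rec.to_dataframe().to_csv(path, index=False)


def lowpass_filter(
    rec: ForceRecording, cutoff_hz: float = 20.0, order: int = 5
) -> ForceRecording:
    """Zero-phase Butterworth low-pass of all three force channels.

    An order-``order`` Butterworth design is applied forward and backward
    (``filtfilt``), i.e. a "fifth-order bidirectional" filter with doubled
    effective magnitude roll-off and no phase lag.  No cutoff-frequency
    compensation is applied.  Metadata and the time grid are unchanged.
    """
    if not (0 < cutoff_hz < rec.rate / 2):
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={rec.rate / 2} Hz)"
        )
    sos = signal.butter(order, cutoff_hz, btype="low", fs=rec.rate, output="sos")
    return replace(
        rec,
        f_v=signal.sosfiltfilt(sos, rec.f_v),
        f_ap=signal.sosfiltfilt(sos, rec.f_ap),
        f_ml=signal.sosfiltfilt(sos, rec.f_ml),
    )


# ---------------------------------------------------------------------------
# Results document

RESULTS_SCHEMA_ID = "runmech-results/1"

#: required keys of a per-window record and of the document root; this is
#: the packaged schema against which documents are validated.
_WINDOW_KEYS = frozenset({"label", "t_start_s", "n_strides", "means", "steps"})
_ROOT_KEYS = frozenset({"schema", "units", "meta", "windows"})

UNITS = {
    "t_c": "s", "t_f": "s", "t_s": "s", "t_b": "s", "t_p": "s",
    "t_step": "s", "sf": "Hz", "df": "1",
    "f_v_max": "N", "f_v_impact": "N", "f_h_b": "N", "f_h_p": "N",
    "lr_v": "N/s", "lr_b": "N/s", "lr_p": "N/s",
    "i_v": "N*s", "i_b": "N*s", "i_p": "N*s",
    "delta_z": "m", "k_v": "N/m",
    "w_pot": "J/kg/m", "w_kin": "J/kg/m", "w_ext": "J/kg/m",
    "w_int": "J/kg/m", "w_tot": "J/kg/m",
}


def validate_results_document(doc: dict) -> None:
    """Structural validation of a results document.

    Raises ``ValueError`` naming the first offending element.
    """
    if not isinstance(doc, dict):
        raise ValueError("results document must be a mapping")
    missing = _ROOT_KEYS - doc.keys()
    if missing:
        raise ValueError(f"results document missing key(s): {sorted(missing)}")
    if doc["schema"] != RESULTS_SCHEMA_ID:
        raise ValueError(f"unknown schema id {doc['schema']!r}")
    if not isinstance(doc["windows"], list):
        raise ValueError("'windows' must be a list")
    for i, win in enumerate(doc["windows"]):
        if not isinstance(win, dict):
            raise ValueError(f"window {i} must be a mapping")
        miss = _WINDOW_KEYS - win.keys()
        if miss:
            raise ValueError(f"window {i} missing key(s): {sorted(miss)}")
        if not isinstance(win["steps"], list):
            raise ValueError(f"window {i}: 'steps' must be a list")


def write_results(results: dict, path: str | Path) -> None:
    """Serialize a results document to JSON with stable key order."""
    validate_results_document(results)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(results, fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")


def read_results(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    validate_results_document(doc)
    return doc


def empty_results_document(meta: dict | None = None) -> dict:
    """A minimal valid document with an empty window list."""
    return {
        "schema": RESULTS_SCHEMA_ID,
        "units": dict(UNITS),
        "meta": dict(meta or {}),
        "windows": [],
    }
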