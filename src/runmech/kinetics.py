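"""Per-step kinetic variables: force peaks, loading rates and impulses.

The active vertical peak ``F_v,max`` is the stance maximum of the vertical
GRF.  The impact peak ``F_v,impact`` — the early local maximum produced by
the collision of a rearfoot strike — is detected as the value at the first
sample between foot-strike and the ``F_v,max`` sample at which the central
-difference derivative of the vertical GRF becomes negative.  The vertical
loading rate is the least-squares slope of the vertical force between 20%
and 80% of the interval from foot-strike to 15% of contact time.
Horizontal loading rates are peak-over-time ratios; impulses are
trapezoidal integrals over the contact, braking and propulsive phases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .events import StepEvents
from .io import ForceRecording

__all__ = [
    "KineticVars",
    "vertical_peaks",
    "horizontal_peaks",
    "vertical_loading_rate",
    "horizontal_loading_rates",
    "impulses",
    "kinetic_variables",
]


@dataclass(frozen=True)
class KineticVars:
    """Kinetic variables of one step (``None`` where undefined)."""

    f_v_max: float
    f_v_impact: float | None
    has_impact: bool
    f_h_b: float | None
    f_h_p: float | None
    lr_v: float
    lr_b: float | None
    lr_p: float | None
    i_v: float
    i_b: float | None
    i_p: float | None


def vertical_peaks(
    rec: ForceRecording, step: StepEvents
) -> tuple[float, float | None, bool]:
    """Active peak and (optional) impact peak of the vertical GRF.

    The derivative test uses central differences and starts 2 samples
    after foot-strike to avoid edge artifacts; only samples strictly
    before the ``F_v,max`` sample qualify.
    """
    seg = rec.f_v[step.i_fs : step.i_to]
    if seg.size < 3:
        raise ValueError("stance must contain at least 3 samples")
    imax = int(np.argmax(seg))
    f_v_max = float(seg[imax])
    # central difference d[i] ~ seg[i+1] - seg[i-1]; candidates i in [2, imax)
    if imax > 2:
        i = np.arange(2, imax)
        deriv = seg[i + 1] - seg[i - 1]
        neg = np.flatnonzero(deriv < 0)
        if neg.size:
            return f_v_max, float(seg[i[neg[0]]]), True
    return f_v_max, None, False


def horizontal_peaks(
    rec: ForceRecording, step: StepEvents
) -> tuple[float | None, float | None]:
    """Braking (negative) and propulsive peaks of the fore-aft GRF.

    Braking peak is the minimum over ``[i_fs, i_ms)``; propulsive peak the
    maximum over ``[i_ms, i_to)``.  Both are ``None`` when mid-stance was
    not detected for the step.
    """
    if step.i_ms is None:
        return None, None
    f_h_b = float(np.min(rec.f_ap[step.i_fs : step.i_ms]))
    f_h_p = float(np.max(rec.f_ap[step.i_ms : step.i_to]))
    return f_h_b, f_h_p


def vertical_loading_rate(rec: ForceRecording, step: StepEvents) -> float:
    """Least-squares slope of ``f_v`` over 20-80% of [foot-strike, 0.15 t_c].

    Uses the step's own contact time.  Raises when the early-stance
    interval is sampled too sparsely to hold two samples.
    """
    t_c = (step.i_to - step.i_fs) / rec.rate
    if 0.15 * t_c * rec.rate < 4:
        raise ValueError(
            "15% of contact time covers fewer than 4 samples at this rate"
        )
    t15 = 0.15 * t_c
    lo = step.i_fs / rec.rate + 0.2 * t15
    hi = step.i_fs / rec.rate + 0.8 * t15
    ia = int(np.ceil(lo * rec.rate - 1e-9))
    ib = int(np.floor(hi * rec.rate + 1e-9))
    if ib - ia + 1 < 2:
        raise ValueError(
            f"loading-rate window [{lo:.4f}, {hi:.4f}] s holds fewer than 2 "
            f"samples at {rec.rate:g} Hz"
        )
    idx = np.arange(ia, ib + 1)
    slope = np.polyfit(idx / rec.rate, rec.f_v[idx], 1)[0]
    return float(slope)


def horizontal_loading_rates(
    rec: ForceRecording, step: StepEvents
) -> tuple[float | None, float | None]:
    """Braking and propulsive loading rates (peak over time-to-peak).

    ``lr_b = f_h_b / (t_peak_b - t_fs)`` (negative) and
    ``lr_p = f_h_p / (t_peak_p - t_ms)``.  A peak coinciding with the
    start of its interval (zero elapsed time) yields ``None``.
    """
    if step.i_ms is None:
        return None, None
    i_pk_b = step.i_fs + int(np.argmin(rec.f_ap[step.i_fs : step.i_ms]))
    i_pk_p = step.i_ms + int(np.argmax(rec.f_ap[step.i_ms : step.i_to]))
    lr_b = lr_p = None
    if i_pk_b > step.i_fs:
        lr_b = float(rec.f_ap[i_pk_b] / ((i_pk_b - step.i_fs) / rec.rate))
    if i_pk_p > step.i_ms:
        lr_p = float(rec.f_ap[i_pk_p] / ((i_pk_p - step.i_ms) / rec.rate))
    return lr_b, lr_p


def impulses(
    rec: ForceRecording, step: StepEvents
) -> tuple[float, float | None, float | None]:
    """Trapezoidal impulses: vertical over contact, fore-aft per phase.

    Integrals include both boundary samples of their phase, so the
    braking and propulsive integrals share the mid-stance sample and sum
    to the full-stance fore-aft integral.
    """
    dt = 1.0 / rec.rate
    i_v = float(np.trapezoid(rec.f_v[step.i_fs : step.i_to + 1], dx=dt))
    if step.i_ms is None:
        return i_v, None, None
    i_b = float(np.trapezoid(rec.f_ap[step.i_fs : step.i_ms + 1], dx=dt))
    i_p = float(np.trapezoid(rec.f_ap[step.i_ms : step.i_to + 1], dx=dt))
    return i_v, i_b, i_p


def kinetic_variables(
    rec: ForceRecording, steps: list[StepEvents]
) -> pd.DataFrame:
    """All kinetic variables for a list of steps, one row per step.

    Columns mirror :class:`KineticVars`; absolute-value mirrors
    ``abs_f_h_b``, ``abs_lr_b``, ``abs_i_b`` are added for reporting under
    the magnitude sign convention.
    """
    rows = []
    for st in steps:
        f_v_max, f_v_impact, has_impact = vertical_peaks(rec, st)
        f_h_b, f_h_p = horizontal_peaks(rec, st)
        lr_v = vertical_loading_rate(rec, st)
        lr_b, lr_p = horizontal_loading_rates(rec, st)
        i_v, i_b, i_p = impulses(rec, st)
        rows.append(
            {
                "f_v_max": f_v_max,
                "f_v_impact": np.nan if f_v_impact is None else f_v_impact,
                "has_impact": has_impact,
                "f_h_b": np.nan if f_h_b is None else f_h_b,
                "f_h_p": np.nan if f_h_p is None else f_h_p,
                "lr_v": lr_v,
                "lr_b": np.nan if lr_b is None else lr_b,
                "lr_p": np.nan if lr_p is None else lr_p,
                "i_v": i_v,
                "i_b": np.nan if i_b is None else i_b,
                "i_p": np.nan if i_p is None else i_p,
            }
        )
    df = pd.DataFrame(rows)
    for col in ("f_h_b", "lr_b", "i_b"):
        df[f"abs_{col}"] = df[col].abs()
    return df
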