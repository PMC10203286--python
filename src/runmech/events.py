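"""Gait-event detection and temporal (spatiotemporal) variables.

Foot-strike and toe-off are defined by a 20 N threshold on the vertical
GRF; mid-stance is the instant the fore-aft GRF changes from negative
(braking) to positive (propulsion).  Steps alternate between feet on a
single platform; feet are not labelled because no downstream formula uses
left/right identity.  A stride is two consecutive steps.

Temporal definitions (per step)::

    t_c    contact time        = (i_to - i_fs) / rate
    t_f    flight time         = (i_fs_next - i_to) / rate
    t_s    swing time          = stride time - t_c
    t_b    braking time        = (i_ms - i_fs) / rate
    t_p    propulsive time     = (i_to - i_ms) / rate
    SF     stride frequency    = (t_c + t_s)^-1
    DF     duty factor         = t_c / (t_c + t_s)

where the stride time spans to the next ipsilateral foot-strike (two
steps on).  Indices are 0-based; contact intervals are half-open
``[i_fs, i_to)``; times are ``index / rate``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ForceRecording

__all__ = [
    "StepEvents",
    "StrideWindow",
    "detect_steps",
    "detect_midstance",
    "temporal_variables",
    "select_stride_window",
]

#: debounce defaults: phases shorter than these cannot occur at running
#: speeds, so shorter excursions across the threshold are treated as noise.
MIN_CONTACT_S = 0.080
MIN_FLIGHT_S = 0.020

#: a negative-to-positive fore-aft crossing counts as mid-stance only if
#: followed by at least this long of non-negative fore-aft force.
MIDSTANCE_HOLD_S = 0.010


@dataclass(frozen=True)
class StepEvents:
    """Detected events of one step (contact + following flight).

    ``i_ms`` is ``None`` when no braking-to-propulsion sign change was
    found within stance; such steps are excluded from braking/propulsive
    outputs but keep their vertical variables.
    """

    i_fs: int
    i_ms: int | None
    i_to: int
    i_fs_next: int

    def __post_init__(self) -> None:
        if not (self.i_fs < self.i_to <= self.i_fs_next):
            raise ValueError("require i_fs < i_to <= i_fs_next")
        if self.i_ms is not None and not (self.i_fs < self.i_ms < self.i_to):
            raise ValueError("require i_fs < i_ms < i_to")

    @property
    def has_midstance(self) -> bool:
        return self.i_ms is not None


@dataclass(frozen=True)
class StrideWindow:
    """A run of ``n_strides`` consecutive strides (2 steps each).

    ``i_start``/``i_end`` delimit an integer number of strides: from the
    first foot-strike of the first stride to the foot-strike that begins
    the stride after the last one.
    """

    steps: tuple[StepEvents, ...]
    n_strides: int
    i_start: int
    i_end: int
    rate: float
    label: str = "window"

    def __post_init__(self) -> None:
        if len(self.steps) != 2 * self.n_strides:
            raise ValueError("window must contain exactly 2*n_strides steps")
        for a, b in zip(self.steps, self.steps[1:]):
            if a.i_fs_next != b.i_fs:
                raise ValueError("window steps must be consecutive (no gaps)")

    @property
    def t_start(self) -> float:
        return self.i_start / self.rate

    @property
    def t_end(self) -> float:
        return self.i_end / self.rate

    @property
    def center_time(self) -> float:
        return 0.5 * (self.t_start + self.t_end)


def _contact_segments(
    above: np.ndarray, min_contact: int, min_flight: int
) -> list[tuple[int, int]]:
    """Half-open [start, end) contact segments after debouncing."""
    padded = np.concatenate(([False], above, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    segments: list[list[int]] = []
    for s, e in zip(starts, ends):
        if segments and s - segments[-1][1] < min_flight:
            segments[-1][1] = int(e)  # gap too short to be flight: merge
        else:
            segments.append([int(s), int(e)])
    return [(s, e) for s, e in segments if e - s >= min_contact]


def detect_steps(
    rec: ForceRecording,
    threshold_n: float = 20.0,
    min_contact_s: float = MIN_CONTACT_S,
    min_flight_s: float = MIN_FLIGHT_S,
    midstance_hold_s: float = MIDSTANCE_HOLD_S,
) -> list[StepEvents]:
    """Detect steps by thresholding the vertical GRF.

    Foot-strike is the first sample with ``f_v >= threshold_n`` after a
    flight; toe-off is the first sample below the threshold after a
    contact.  Sub-debounce excursions across the threshold are merged or
    rejected.  Contacts that begin at the first sample or end at the last
    sample are incomplete and dropped.  Returns one :class:`StepEvents`
    per contact that is followed by another contact; an empty list when no
    contacts are found.
    """
    if threshold_n <= 0:
        raise ValueError("threshold_n must be positive")
    above = rec.f_v >= threshold_n
    contacts = _contact_segments(
        above,
        min_contact=int(round(min_contact_s * rec.rate)),
        min_flight=int(round(min_flight_s * rec.rate)),
    )
    n = len(rec)
    if contacts and contacts[0][0] == 0:
        contacts = contacts[1:]
    if contacts and contacts[-1][1] == n:
        contacts = contacts[:-1]
    steps: list[StepEvents] = []
    for (s, e), (s_next, _) in zip(contacts, contacts[1:]):
        i_ms = detect_midstance(rec, s, e, hold_s=midstance_hold_s)
        steps.append(StepEvents(i_fs=s, i_ms=i_ms, i_to=e, i_fs_next=s_next))
    return steps


def detect_midstance(
    rec: ForceRecording,
    i_fs: int,
    i_to: int,
    hold_s: float = MIDSTANCE_HOLD_S,
) -> int | None:
    """Index of the braking-to-propulsion transition within a stance.

    The first negative-to-positive crossing of the fore-aft force that is
    followed by at least ``hold_s`` of non-negative force (clipped to the
    stance) is accepted; the hold makes the rule robust to noise around
    zero.  Returns ``None`` when the sign change never occurs.
    """
    fa = rec.f_ap[i_fs:i_to]
    hold = max(1, int(round(hold_s * rec.rate)))
    crossings = np.flatnonzero((fa[:-1] < 0) & (fa[1:] >= 0)) + 1
    for c in crossings:
        if np.all(fa[c : min(c + hold, fa.size)] >= 0):
            return int(i_fs + c)
    return None


def temporal_variables(steps: list[StepEvents], rate: float) -> pd.DataFrame:
    """Per-step temporal variables as a DataFrame indexed by step number.

    Stride-based quantities (``t_s``, ``sf``, ``df``) need the foot-strike
    two steps on; they are NaN for the final step.  Braking/propulsive
    times are NaN for steps without a detected mid-stance.
    """
    if len(steps) < 3:
        raise ValueError("need at least 3 consecutive steps to form a stride")
    rows = []
    for j, st in enumerate(steps):
        t_c = (st.i_to - st.i_fs) / rate
        t_f = (st.i_fs_next - st.i_to) / rate
        t_step = (st.i_fs_next - st.i_fs) / rate
        if j + 1 < len(steps):
            stride = (steps[j + 1].i_fs_next - st.i_fs) / rate
            t_s = stride - t_c
            sf = 1.0 / (t_c + t_s)
            df = t_c / (t_c + t_s)
        else:
            t_s = sf = df = np.nan
        if st.i_ms is not None:
            t_b = (st.i_ms - st.i_fs) / rate
            t_p = (st.i_to - st.i_ms) / rate
        else:
            t_b = t_p = np.nan
        rows.append(
            {
                "t_c": t_c, "t_f": t_f, "t_s": t_s, "t_b": t_b, "t_p": t_p,
                "t_step": t_step, "sf": sf, "df": df,
            }
        )
    return pd.DataFrame(rows)


def select_stride_window(
    steps: list[StepEvents],
    target_time_s: float,
    rate: float,
    n: int = 10,
    label: str = "window",
) -> StrideWindow:
    """The run of ``n`` consecutive strides centred nearest a target time.

    Candidate windows start at every step; the one whose temporal centre
    is closest to ``target_time_s`` wins, ties broken toward earlier time.
    Targets before the first or after the last candidate clamp to the
    first/last window.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    n_steps = 2 * n
    if len(steps) < n_steps:
        raise ValueError(
            f"need {n} consecutive strides ({n_steps} steps), found only "
            f"{len(steps) // 2} strides ({len(steps)} steps)"
        )
    best_j, best_d = 0, np.inf
    for j in range(len(steps) - n_steps + 1):
        i_start = steps[j].i_fs
        i_end = steps[j + n_steps - 1].i_fs_next
        center = 0.5 * (i_start + i_end) / rate
        d = abs(center - target_time_s)
        if d < best_d:
            best_j, best_d = j, d
    j = best_j
    chosen = tuple(steps[j : j + n_steps])
    return StrideWindow(
        steps=chosen,
        n_strides=n,
        i_start=chosen[0].i_fs,
        i_end=chosen[-1].i_fs_next,
        rate=rate,
        label=label,
    )
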