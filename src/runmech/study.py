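"""Published group-level summaries of the exhaustive-run study conditions.

Thirteen male recreational runners (body mass 68 +/- 5 kg, peak aerobic
speed PS = 5.3 +/- 0.3 m/s) each ran to volitional exhaustion at 90, 100,
110 and 120% of PS on an instrumented treadmill; ten consecutive strides
were analyzed at the start, mid and end of each run.  This module embeds
the printed group-level numbers those analyses produced — times to
exhaustion, window timings, perceived exertion and the impact-peak census
— as input data for the study-level statistics, together with small
derived conveniences.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "N_RUNNERS",
    "STRIDES_PER_WINDOW",
    "STEPS_PER_STRIDE",
    "MEAN_PS",
    "SPEED_CONDITIONS",
    "TIME_TO_EXHAUSTION_MIN",
    "WINDOW_TIMING_MIN",
    "RPE",
    "IMPACT_COUNTS",
    "IMPACT_RUNNERS",
    "WINDOW_LABELS",
    "step_denominator",
    "rpe_grand_mean",
    "distance_km",
]

N_RUNNERS = 13
STRIDES_PER_WINDOW = 10
STEPS_PER_STRIDE = 2
#: group-mean peak aerobic speed, m/s
MEAN_PS = 5.3

SPEED_CONDITIONS = (90, 100, 110, 120)
WINDOW_LABELS = ("start", "mid", "end")

#: group means, minutes, per %PS condition
TIME_TO_EXHAUSTION_MIN = {90: 15.25, 100: 5.68, 110: 2.65, 120: 1.58}

#: timing of the first selected stride, minutes (start was always 0.5 min)
WINDOW_TIMING_MIN = {
    90: {"start": 0.5, "mid": 7.39, "end": 14.57},
    100: {"start": 0.5, "mid": 2.68, "end": 5.18},
    110: {"start": 0.5, "mid": 1.28, "end": 2.33},
    120: {"start": 0.5, "mid": 0.73, "end": 1.26},
}

#: rating of perceived exertion (6-20 scale) right after each run
RPE = {90: 18.8, 100: 19.1, 110: 19.1, 120: 18.9}

#: steps showing an impact peak, per condition and window (of 260 steps)
IMPACT_COUNTS = {
    90: {"start": 17, "mid": 54, "end": 129},
    100: {"start": 34, "mid": 92, "end": 133},
    110: {"start": 60, "mid": 101, "end": 158},
    120: {"start": 90, "mid": 106, "end": 127},
}

#: runners (of 13) showing at least one impact peak
IMPACT_RUNNERS = {
    90: {"start": 4, "mid": 9, "end": 12},
    100: {"start": 5, "mid": 12, "end": 11},
    110: {"start": 10, "mid": 10, "end": 13},
    120: {"start": 10, "mid": 13, "end": 12},
}


def step_denominator() -> int:
    """Total steps per window across the group: runners x strides x 2."""
    return N_RUNNERS * STRIDES_PER_WINDOW * STEPS_PER_STRIDE


def rpe_grand_mean() -> float:
    """Grand mean RPE over the four exhaustive runs."""
    return float(np.mean(list(RPE.values())))


def distance_km(pct_ps: int = 90) -> float:
    """Group-mean distance run at a condition, km.

    Approximated from group means: ``(pct/100) * PS * time to exhaustion``.
    """
    speed = (pct_ps / 100.0) * MEAN_PS
    return speed * TIME_TO_EXHAUSTION_MIN[pct_ps] * 60.0 / 1000.0
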