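"""Study-level statistics: peak aerobic speed, impact-peak census,
chi-squared goodness of fit, Holm adjustment and group summaries.

Peak aerobic speed (PS) from a maximal incremental test is the speed of
the last fully completed increment plus the completed fraction of the
final, uncompleted increment times the speed increment (0.28 m/s).

The impact census counts, per analysis window (start/mid/end of an
exhaustive run), how many steps show a vertical impact peak — at most one
per step — and how many runners show at least one.  Window counts are
compared against a uniform distribution with a chi-squared goodness-of-fit
test; families of p-values are adjusted with the step-down Holm procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SPEED_INCREMENT",
    "TrialRecord",
    "ImpactCensus",
    "peak_aerobic_speed",
    "impact_census",
    "chisq_uniform",
    "holm_adjust",
    "summarize_trials",
    "trials_to_frame",
]

#: incremental-test speed increment, m/s
SPEED_INCREMENT = 0.28


@dataclass(frozen=True)
class TrialRecord:
    """Metadata and scalar outcomes of one exhaustive run.

    ``windows_min`` maps window label -> timing of the first selected
    stride in minutes; ``results`` may carry per-window analysis output.
    """

    speed_pct_ps: int
    time_to_exhaustion_min: float
    rpe: float
    windows_min: dict = field(default_factory=dict)
    results: object | None = None

    def __post_init__(self) -> None:
        if self.speed_pct_ps not in (90, 100, 110, 120):
            raise ValueError("speed_pct_ps must be one of 90, 100, 110, 120")
        if not (6 <= self.rpe <= 20):
            raise ValueError("RPE must lie on the 6-20 scale")
        times = [self.windows_min[k] for k in ("start", "mid", "end")
                 if k in self.windows_min]
        if times != sorted(times):
            raise ValueError("window timings must be ordered start < mid < end")


@dataclass(frozen=True)
class ImpactCensus:
    """Counts of impact-peak steps per window label."""

    counts: dict          # label -> number of steps with an impact peak
    runners: dict         # label -> number of runners with >= 1 impact peak
    total_steps: dict     # label -> total steps observed

    def percentages(self) -> dict:
        return {
            k: 100.0 * self.counts[k] / self.total_steps[k]
            for k in self.counts
        }


def peak_aerobic_speed(
    s_last_inc: float, alpha: float, delta_s: float = SPEED_INCREMENT
) -> float:
    """PS = s_last_inc + alpha * delta_s, m/s.

    ``alpha`` is the fraction of the uncompleted final increment that was
    sustained (0 = none, 1 = all of it).
    """
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0, 1]")
    if s_last_inc <= 0 or delta_s <= 0:
        raise ValueError("speeds must be positive")
    return s_last_inc + alpha * delta_s


def impact_census(flags: pd.DataFrame) -> ImpactCensus:
    """Census of impact peaks from per-step flags.

    ``flags`` must have columns ``runner``, ``label`` and boolean
    ``has_impact``, one row per analyzed step.
    """
    counts: dict = {}
    runners: dict = {}
    totals: dict = {}
    for label, grp in flags.groupby("label", sort=False):
        counts[label] = int(grp["has_impact"].sum())
        totals[label] = int(len(grp))
        runners[label] = int(
            grp.groupby("runner")["has_impact"].any().sum()
        )
    return ImpactCensus(counts=counts, runners=runners, total_steps=totals)


def chisq_uniform(counts) -> tuple[float, int, float]:
    """Chi-squared goodness of fit of counts against a uniform expectation.

    Returns ``(chi2, dof, p)`` with ``chi2 = sum((obs - exp)^2 / exp)``,
    ``exp = total / k`` and ``dof = k - 1``.
    """
    obs = np.asarray(counts, dtype=float)
    if obs.size < 2:
        raise ValueError("need at least 2 categories")
    if np.any(obs < 0):
        raise ValueError("counts must be non-negative")
    if obs.sum() <= 0:
        raise ValueError("counts must not all be zero")
    chi2, p = sps.chisquare(obs)
    return float(chi2), int(obs.size - 1), float(p)


def holm_adjust(pvals) -> np.ndarray:
    """Step-down Holm-adjusted p-values, original order preserved."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="holm")[1]


def trials_to_frame(records: list[TrialRecord]) -> pd.DataFrame:
    """Scalar trial outcomes as a tidy frame, one row per trial."""
    return pd.DataFrame(
        {
            "speed_pct_ps": [r.speed_pct_ps for r in records],
            "time_to_exhaustion_min": [r.time_to_exhaustion_min for r in records],
            "rpe": [r.rpe for r in records],
        }
    )


def summarize_trials(records) -> pd.DataFrame:
    """Mean and sample SD of each variable per %PS condition.

    Accepts a list of :class:`TrialRecord` or a tidy DataFrame whose first
    column groups conditions.  SD uses the n-1 convention; for a single
    record per group SD is reported as 0.0 (insufficient data to estimate
    spread).
    """
    df = records if isinstance(records, pd.DataFrame) else trials_to_frame(records)
    if df.empty:
        raise ValueError("no trial records to summarize")
    by = df.columns[0]
    grouped = df.groupby(by, sort=True)
    mean = grouped.mean()
    sd = grouped.std(ddof=1).fillna(0.0)
    out = pd.concat({"mean": mean, "sd": sd}, axis=1)
    return out.swaplevel(axis=1).sort_index(axis=1)
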