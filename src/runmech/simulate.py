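"""Synthetic treadmill GRF trials with known ground truth.

The generator emits the signal structure the analysis pipeline assumes:

* vertical force: per step, a half-sine lobe ``Fmax sin(pi t / t_c)`` with
  ``Fmax = pi m g / (4 DF)``, so each step's vertical impulse equals body
  weight times step time (momentum balance at steady state) and the active
  peak is inversely proportional to the duty factor;
* fore-aft force: a biphasic full-sine ``-A sin(2 pi t / t_c)`` (braking
  then propulsion) with zero net impulse, amplitude ``0.15 m g`` by
  default;
* optional early-stance impact transient: a Gaussian bump of amplitude
  ``impact_amp`` body weights centred at ``impact_time_frac * t_c``, drawn
  per step with probability ``impact_prob``;
* additive Gaussian noise on all channels;
* exhaustion drift: duty factor and impact probability interpolate
  linearly from their start to optional end values over the trial while
  stride frequency stays constant — contact time rises, flight time falls,
  the active peak falls and the impulse balance is preserved step by step.

All randomness derives from ``SimParams.seed``; identical parameters give
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import STANDARD_GRAVITY, ForceRecording

__all__ = ["SimParams", "GroundTruth", "simulate_trial"]


@dataclass(frozen=True)
class SimParams:
    """Ground-truth parameters of one simulated trial.

    Defaults reproduce the study conditions of an exhaustive treadmill run
    near 90% of peak aerobic speed: 70 kg runner, belt at 4.77 m/s, stride
    frequency 1.4 Hz, duty factor 0.28, sampled at 1000 Hz.
    """

    mass: float = 70.0           # kg
    belt_speed: float = 4.77     # m/s
    sf: float = 1.4              # stride frequency, Hz
    df: float = 0.28             # duty factor
    duration: float = 60.0       # s
    rate: float = 1000.0         # Hz
    ap_amp_bw: float = 0.15      # fore-aft amplitude, body weights
    impact_amp: float = 0.0      # transient amplitude, body weights (0 = off)
    impact_time_frac: float = 0.08   # transient centre as fraction of t_c
    impact_width_s: float = 0.005    # transient Gaussian sigma, s
    impact_prob: float = 1.0     # per-step probability of a transient
    noise_sd: float = 0.0        # N, all channels
    df_end: float | None = None          # drift target for duty factor
    impact_prob_end: float | None = None  # drift target for impact prob.
    gravity: float = STANDARD_GRAVITY
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.df <= 0.5):
            raise ValueError("duty factor must lie in (0, 0.5]")
        if self.df_end is not None and not (0 < self.df_end <= 0.5):
            raise ValueError("df_end must lie in (0, 0.5]")
        if self.sf <= 0:
            raise ValueError("stride frequency must be positive")
        if self.rate < 200:
            raise ValueError("rate must be at least 200 Hz")
        if not (0 <= self.impact_prob <= 1):
            raise ValueError("impact_prob must lie in [0, 1]")
        if self.impact_prob_end is not None and not (
            0 <= self.impact_prob_end <= 1
        ):
            raise ValueError("impact_prob_end must lie in [0, 1]")
        if self.mass <= 0 or self.duration <= 0:
            raise ValueError("mass and duration must be positive")

    @property
    def t_step(self) -> float:
        """Step time: half the stride time, s."""
        return 1.0 / (2.0 * self.sf)


@dataclass(frozen=True)
class GroundTruth:
    """Per-step truth emitted alongside the samples."""

    table: pd.DataFrame  # step, t_start, t_c, t_f, df, f_v_max, impact

    def __getitem__(self, col: str) -> np.ndarray:
        return self.table[col].to_numpy()

    def __len__(self) -> int:
        return len(self.table)


def simulate_trial(p: SimParams) -> tuple[ForceRecording, GroundTruth]:
    """Generate one trial; returns the recording and its ground truth.

    Steps start at multiples of the (constant) step time; the final
    partial step, if any, is omitted.  Impact Bernoulli draws consume one
    uniform variate per step regardless of amplitude, so trials differing
    only in ``impact_amp`` place transients on the same steps.
    """
    rng = np.random.default_rng(p.seed)
    g = p.gravity
    n = int(round(p.duration * p.rate))
    t = np.arange(n) / p.rate
    f_v = np.zeros(n)
    f_ap = np.zeros(n)
    f_ml = np.zeros(n)

    n_steps = int(np.floor(p.duration / p.t_step))
    rows = []
    for k in range(n_steps):
        t0 = k * p.t_step
        u = t0 / p.duration
        df_k = p.df if p.df_end is None else p.df + (p.df_end - p.df) * u
        prob_k = (
            p.impact_prob
            if p.impact_prob_end is None
            else p.impact_prob + (p.impact_prob_end - p.impact_prob) * u
        )
        t_c = 2.0 * df_k * p.t_step
        if t_c * p.rate < 4:
            raise ValueError(
                f"contact time {t_c:.4f} s spans fewer than 4 samples at "
                f"{p.rate:g} Hz"
            )
        f_max = np.pi * p.mass * g / (4.0 * df_k)
        i0 = int(np.ceil(t0 * p.rate - 1e-9))
        i1 = min(n, int(np.ceil((t0 + t_c) * p.rate - 1e-9)))
        tau = t[i0:i1] - t0
        f_v[i0:i1] += f_max * np.sin(np.pi * tau / t_c)
        f_ap[i0:i1] += -p.ap_amp_bw * p.mass * g * np.sin(2.0 * np.pi * tau / t_c)
        draw = rng.random() < prob_k
        has_impact = bool(draw and p.impact_amp > 0)
        if has_impact:
            t_cen = p.impact_time_frac * t_c
            f_v[i0:i1] += (
                p.impact_amp
                * p.mass
                * g
                * np.exp(-((tau - t_cen) ** 2) / (2.0 * p.impact_width_s**2))
            )
        rows.append(
            {
                "step": k,
                "t_start": t0,
                "t_c": t_c,
                "t_f": p.t_step - t_c,
                "df": df_k,
                "f_v_max": f_max,
                "impact": has_impact,
            }
        )
    if p.noise_sd > 0:
        f_v = f_v + rng.normal(0.0, p.noise_sd, n)
        f_ap = f_ap + rng.normal(0.0, p.noise_sd, n)
        f_ml = f_ml + rng.normal(0.0, p.noise_sd, n)
    rec = ForceRecording(
        time=t,
        f_v=f_v,
        f_ap=f_ap,
        f_ml=f_ml,
        rate=p.rate,
        mass=p.mass,
        belt_speed=p.belt_speed,
        gravity=g,
    )
    return rec, GroundTruth(table=pd.DataFrame(rows))
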