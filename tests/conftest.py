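"""Shared fixtures: simulated trials, truth alignment, quadrature oracle.

The quadrature oracle re-derives centre-of-mass quantities from the
analytic sine-model forces on a much finer grid with independently written
integration code; it shares no code path with the package pipeline.
"""

from __future__ import annotations

import numpy as np
import pytest

from runmech import TrialModel, detect_steps, simulate_trial
from runmech.simulate import SimParams


@pytest.fixture(scope="session")
def baseline_params() -> SimParams:
    """Noiseless steady trial at the study conditions (60 s, 1000 Hz)."""
    return SimParams(duration=60.0, seed=1)


@pytest.fixture(scope="session")
def baseline_trial(baseline_params):
    rec, truth = simulate_trial(baseline_params)
    return rec, truth


@pytest.fixture(scope="session")
def baseline_steps(baseline_trial):
    rec, _ = baseline_trial
    return detect_steps(rec)


@pytest.fixture(scope="session")
def baseline_fit(baseline_trial):
    """Full unconditioned pipeline fit on start/mid/end windows."""
    rec, _ = baseline_trial
    return TrialModel(rec, lowpass_hz=None).fit(
        windows={"start": 5.0, "mid": 30.0, "end": 55.0}
    )


@pytest.fixture(scope="session")
def align_truth():
    """Map detected steps onto ground-truth rows via foot-strike times."""

    def _align(steps, truth, params):
        fs_t = np.array([s.i_fs for s in steps]) / params.rate
        return np.round(fs_t / params.t_step).astype(int)

    return _align


def sine_model_com_oracle(p: SimParams, t0: float, t1: float, nfine: int = 200_000):
    """Independent quadrature of the analytic sine-model COM mechanics.

    Returns ``(dz_mean, k_v, w_pot, w_kin, w_ext)`` for the steady model
    over ``[t0, t1]`` under the same steady-state constraints as the
    pipeline (zero-mean vertical velocity, belt-speed mean fore-aft
    velocity, closed vertical displacement).
    """
    g = p.gravity
    t = np.linspace(t0, t1, nfine)
    dt = t[1] - t[0]
    t_step = p.t_step
    t_c = 2.0 * p.df * t_step
    f_max = np.pi * p.mass * g / (4.0 * p.df)
    phase = np.mod(t, t_step)
    f_v = np.where(phase < t_c, f_max * np.sin(np.pi * phase / t_c), 0.0)
    f_ap = np.where(
        phase < t_c,
        -p.ap_amp_bw * p.mass * g * np.sin(2.0 * np.pi * phase / t_c),
        0.0,
    )

    def cumtrap(y):
        return np.concatenate(([0.0], np.cumsum((y[1:] + y[:-1]) * 0.5 * dt)))

    a_v = f_v / p.mass - g
    a_ap = f_ap / p.mass
    a_v = a_v - a_v.mean()
    a_ap = a_ap - a_ap.mean()
    v_v = cumtrap(a_v)
    v_v -= v_v.mean()
    v_ap = cumtrap(a_ap)
    v_ap += p.belt_speed - v_ap.mean()
    z = cumtrap(v_v)
    z -= np.linspace(0.0, z[-1] - z[0], z.size)
    z -= z.mean()

    k0 = int(np.ceil(t0 / t_step))
    k1 = int(np.floor(t1 / t_step))
    dzs = []
    for k in range(k0, k1):
        mask = (t >= k * t_step) & (t < k * t_step + t_c)
        idx = np.flatnonzero(mask)
        dzs.append(z[idx[0]] - z[idx].min())
    dz = float(np.mean(dzs))
    k_v = f_max / dz

    e_pot = g * z
    e_kin = 0.5 * (v_v**2 + v_ap**2)
    dist = p.belt_speed * (t1 - t0)

    def w_pos(e):
        d = np.diff(e)
        return float(d[d > 0].sum()) / dist

    return dz, k_v, w_pos(e_pot), w_pos(e_kin), w_pos(e_pot + e_kin)


@pytest.fixture(scope="session")
def com_oracle():
    return sine_model_com_oracle
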