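"""Centre-of-mass mechanics from forces: velocities, displacement,
vertical stiffness and positive mechanical work.

COM kinematics follow the classical force-platform method: accelerations
are obtained from Newton's second law (``a_v = (f_v - m g)/m``,
``a_ap = f_ap/m``, ``a_ml = f_ml/m``), integrated once for velocity and
twice (vertical) for displacement.  On a treadmill at constant belt speed
the net impulse over an integer number of strides is zero, so any residual
mean acceleration is drift: the window mean of each acceleration is
removed, the integration constants are fixed by the steady-state means
(``mean(v_v) = 0``, ``mean(v_ap) = belt speed``, ``mean(v_ml) = 0``) and
the vertical displacement is linearly detrended so the window closes on
itself.

Vertical stiffness is the spring-mass ratio ``k_v = F_v,max / dz`` with
``dz`` the downward COM excursion from touchdown to the stance minimum.

Positive external work is the sum of the positive increments of the COM
energy ``E_ext = E_pot + E_kin`` per unit mass; internal work is estimated
from stride frequency, speed and duty factor as

    W_int = 0.08 * SF * s * [1 + (DF / (1 - DF))^2]

and total work is their sum.  Work is reported in J/kg/m (division by the
distance ``belt_speed x window duration``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .events import StrideWindow
from .io import ForceRecording

__all__ = [
    "ComTrajectory",
    "WorkSummary",
    "com_kinematics",
    "stance_excursions",
    "vertical_stiffness",
    "mechanical_work",
    "internal_work",
    "total_work",
]

#: downward excursions at or below this are treated as degenerate for the
#: stiffness ratio (flat trajectory, no meaningful spring compression).
MIN_DELTA_Z = 1e-4  # m


@dataclass(frozen=True)
class ComTrajectory:
    """COM kinematics over one integer-stride window.

    ``v_ap`` is the absolute fore-aft velocity (belt speed plus
    fluctuation, ground frame); ``z`` is the vertical displacement
    relative to the window mean.
    """

    time: np.ndarray
    v_v: np.ndarray
    v_ap: np.ndarray
    v_ml: np.ndarray
    z: np.ndarray
    i_start: int
    rate: float


@dataclass(frozen=True)
class WorkSummary:
    """Positive mechanical work per unit mass and distance (J/kg/m)."""

    w_pot: float
    w_kin: float
    w_ext: float
    w_int: float | None = None
    w_tot: float | None = None
    k_v: float | None = None        # N/m, window mean of per-step values
    k_v_per_kg: float | None = None  # N/m/kg
    delta_z: float | None = None     # m, window mean downward excursion


def com_kinematics(rec: ForceRecording, window: StrideWindow) -> ComTrajectory:
    """Integrate GRF to COM velocities and vertical displacement.

    The window must span an integer number of strides (guaranteed by
    :class:`StrideWindow`); samples ``i_start .. i_end`` inclusive are
    used so the integration closes the last stride.
    """
    if window.i_end > len(rec) - 1:
        raise ValueError("window extends beyond the recording")
    sl = slice(window.i_start, window.i_end + 1)
    m, g, dt = rec.mass, rec.gravity, 1.0 / rec.rate
    a_v = (rec.f_v[sl] - m * g) / m
    a_ap = rec.f_ap[sl] / m
    a_ml = rec.f_ml[sl] / m

    def integrate(a: np.ndarray, mean_v: float) -> np.ndarray:
        a = a - a.mean()  # steady state: residual mean acceleration is drift
        v = cumulative_trapezoid(a, dx=dt, initial=0.0)
        return v - v.mean() + mean_v

    v_v = integrate(a_v, 0.0)
    v_ap = integrate(a_ap, rec.belt_speed)
    v_ml = integrate(a_ml, 0.0)
    z = cumulative_trapezoid(v_v, dx=dt, initial=0.0)
    ramp = np.linspace(0.0, z[-1] - z[0], z.size)  # close the window
    z = z - ramp
    z = z - z.mean()
    return ComTrajectory(
        time=rec.time[sl],
        v_v=v_v,
        v_ap=v_ap,
        v_ml=v_ml,
        z=z,
        i_start=window.i_start,
        rate=rec.rate,
    )


def stance_excursions(traj: ComTrajectory, window: StrideWindow) -> np.ndarray:
    """Per-step downward COM excursion during contact.

    ``dz = z(foot-strike) - min z over the stance``; positive in normal
    running (the COM descends after touchdown).
    """
    dz = np.empty(len(window.steps))
    for k, st in enumerate(window.steps):
        a = st.i_fs - traj.i_start
        b = st.i_to - traj.i_start
        dz[k] = traj.z[a] - np.min(traj.z[a:b])
    return dz


def vertical_stiffness(
    f_v_max: np.ndarray, delta_z: np.ndarray, min_delta_z: float = MIN_DELTA_Z
) -> np.ndarray:
    """Per-step spring-mass vertical stiffness ``F_v,max / dz`` (N/m).

    Steps with ``dz <= min_delta_z`` are degenerate and returned as NaN.
    """
    f = np.asarray(f_v_max, dtype=float)
    dz = np.asarray(delta_z, dtype=float)
    out = np.full(f.shape, np.nan)
    ok = dz > min_delta_z
    out[ok] = f[ok] / dz[ok]
    return out


def mechanical_work(
    traj: ComTrajectory, rec: ForceRecording, window: StrideWindow
) -> tuple[float, float, float]:
    """Positive potential, kinetic and external work in J/kg/m.

    Per unit mass, ``E_pot = g z`` and ``E_kin = (v_v^2 + v_ap^2 +
    v_ml^2)/2``; each work is the sum of positive sample-to-sample
    increments of its energy curve, divided by the distance travelled
    (belt speed x window duration).  External work uses the summed energy
    ``E_ext = E_pot + E_kin``, so pendulum-like exchange between the two
    forms never increases it: ``w_ext <= w_pot + w_kin``.
    """
    if rec.belt_speed <= 0:
        raise ValueError("belt_speed must be positive to normalize per metre")
    e_pot = rec.gravity * traj.z
    e_kin = 0.5 * (traj.v_v**2 + traj.v_ap**2 + traj.v_ml**2)
    distance = rec.belt_speed * (window.i_end - window.i_start) / rec.rate

    def positive_increments(e: np.ndarray) -> float:
        de = np.diff(e)
        return float(np.sum(de[de > 0]))

    w_pot = positive_increments(e_pot) / distance
    w_kin = positive_increments(e_kin) / distance
    w_ext = positive_increments(e_pot + e_kin) / distance
    return w_pot, w_kin, w_ext


def internal_work(
    sf: float, df: float, belt_speed: float, per_distance: bool = True
) -> float:
    """Positive internal work estimated from SF, speed and duty factor.

    The estimate ``0.08 * SF * s * [1 + (DF/(1-DF))^2]`` is evaluated
    literally; with ``per_distance`` (the default) it is additionally
    divided by the running speed ``s`` so that the result carries the same
    J/kg/m normalization as the external work.  Both readings are exposed
    via the flag because the literal expression is power-like while the
    reported unit is per-distance.
    """
    if not (0 < df < 1):
        raise ValueError("duty factor must lie in (0, 1)")
    if sf <= 0 or belt_speed <= 0:
        raise ValueError("sf and belt_speed must be positive")
    w = 0.08 * sf * belt_speed * (1.0 + (df / (1.0 - df)) ** 2)
    return w / belt_speed if per_distance else w


def total_work(w_ext: float, w_int: float) -> float:
    """Positive total work: the exact sum of external and internal work."""
    if w_ext < 0 or w_int < 0:
        raise ValueError("work components must be non-negative")
    return w_ext + w_int
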