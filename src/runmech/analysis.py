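"""End-to-end trial analysis with a model/results interface.

``TrialModel`` wraps one force-platform recording together with the
analysis configuration; ``fit`` runs the full pipeline — conditioning
filter, step detection, window selection, temporal and kinetic variables,
COM mechanics, vertical stiffness and positive mechanical work — and
returns a ``TrialResults`` carrying per-step tables, per-window work
summaries and a printable summary table.

Example
-------
>>> from runmech import SimParams, simulate_trial, TrialModel
>>> rec, truth = simulate_trial(SimParams(seed=7))
>>> res = TrialModel(rec).fit(windows={"start": 5, "mid": 30, "end": 55})
>>> print(res.summary())                       # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .events import (
    StrideWindow,
    detect_steps,
    select_stride_window,
    temporal_variables,
)
from .io import (
    UNITS,
    RESULTS_SCHEMA_ID,
    ForceRecording,
    lowpass_filter,
    read_grf_csv,
    write_results,
)
from .kinetics import kinetic_variables
from .mechanics import (
    ComTrajectory,
    WorkSummary,
    com_kinematics,
    internal_work,
    mechanical_work,
    stance_excursions,
    total_work,
    vertical_stiffness,
)

__all__ = ["TrialModel", "TrialResults", "WindowResult"]

#: variables shown in the summary table, with display scaling
_SUMMARY_VARS = (
    ("t_c", "s", 1.0),
    ("t_f", "s", 1.0),
    ("sf", "Hz", 1.0),
    ("df", "", 1.0),
    ("f_v_max", "BW", None),  # scaled by body weight at render time
    ("k_v", "kN/m", 1e-3),
    ("w_ext", "J/kg/m", 1.0),
    ("w_tot", "J/kg/m", 1.0),
)


@dataclass(frozen=True)
class WindowResult:
    """All per-window output of one analysis window."""

    window: StrideWindow
    temporal: pd.DataFrame
    kinetics: pd.DataFrame
    trajectory: ComTrajectory
    delta_z: np.ndarray
    k_v: np.ndarray
    work: WorkSummary

    @property
    def label(self) -> str:
        return self.window.label


class TrialModel:
    """Analysis model for one treadmill trial.

    Parameters
    ----------
    recording : ForceRecording
        Raw trial recording (unfiltered).
    config : AnalysisConfig, optional
        Pipeline parameters; keyword overrides are applied on top, e.g.
        ``TrialModel(rec, lowpass_hz=None)``.
    """

    def __init__(
        self,
        recording: ForceRecording,
        config: AnalysisConfig | None = None,
        **overrides,
    ) -> None:
        self.config = (config or AnalysisConfig()).replace(**overrides)
        self.raw = recording
        if self.config.lowpass_hz is not None:
            self.recording = lowpass_filter(
                recording, self.config.lowpass_hz, self.config.filter_order
            )
        else:
            self.recording = recording

    @classmethod
    def from_csv(
        cls,
        path,
        mass: float,
        belt_speed: float,
        config: AnalysisConfig | None = None,
        **overrides,
    ) -> "TrialModel":
        cfg = (config or AnalysisConfig()).replace(**overrides)
        rec = read_grf_csv(path, mass=mass, belt_speed=belt_speed,
                           gravity=cfg.gravity)
        return cls(rec, config=cfg)

    def fit(self, windows: dict[str, float] | None = None) -> "TrialResults":
        """Run the pipeline on the requested analysis windows.

        ``windows`` maps window label to a target time in seconds; the run
        of consecutive strides centred nearest each target is analyzed.
        Default: one window centred mid-recording.
        """
        cfg = self.config
        rec = self.recording
        steps = detect_steps(
            rec,
            threshold_n=cfg.threshold_n,
            min_contact_s=cfg.min_contact_s,
            min_flight_s=cfg.min_flight_s,
            midstance_hold_s=cfg.midstance_hold_s,
        )
        if len(steps) < 2 * cfg.n_strides:
            raise ValueError(
                f"recording yields only {len(steps)} steps; "
                f"{2 * cfg.n_strides} needed for one window"
            )
        temporal_all = temporal_variables(steps, rec.rate)
        if windows is None:
            windows = {"all": rec.duration / 2.0}
        results: dict[str, WindowResult] = {}
        for label, target in windows.items():
            win = select_stride_window(
                steps, target, rec.rate, n=cfg.n_strides, label=label
            )
            j0 = next(
                i for i, s in enumerate(steps) if s.i_fs == win.i_start
            )
            temporal = temporal_all.iloc[j0 : j0 + len(win.steps)].reset_index(
                drop=True
            )
            kin = kinetic_variables(rec, list(win.steps))
            traj = com_kinematics(rec, win)
            dz = stance_excursions(traj, win)
            k_v = vertical_stiffness(kin["f_v_max"].to_numpy(), dz)
            w_pot, w_kin, w_ext = mechanical_work(traj, rec, win)
            sf = float(np.nanmean(temporal["sf"]))
            df_mean = float(np.nanmean(temporal["df"]))
            w_int = internal_work(sf, df_mean, rec.belt_speed)
            work = WorkSummary(
                w_pot=w_pot,
                w_kin=w_kin,
                w_ext=w_ext,
                w_int=w_int,
                w_tot=total_work(w_ext, w_int),
                k_v=float(np.nanmean(k_v)),
                k_v_per_kg=float(np.nanmean(k_v)) / rec.mass,
                delta_z=float(np.mean(dz)),
            )
            results[label] = WindowResult(
                window=win,
                temporal=temporal,
                kinetics=kin,
                trajectory=traj,
                delta_z=dz,
                k_v=k_v,
                work=work,
            )
        return TrialResults(self, results)


class TrialResults:
    """Fitted per-window results of a :class:`TrialModel`."""

    def __init__(self, model: TrialModel, windows: dict[str, WindowResult]):
        self.model = model
        self.windows = windows

    def __getitem__(self, label: str) -> WindowResult:
        return self.windows[label]

    @property
    def labels(self) -> list[str]:
        return list(self.windows)

    def per_step(self) -> pd.DataFrame:
        """Concatenated per-step temporal + kinetic table, all windows."""
        frames = []
        for label, wr in self.windows.items():
            df = pd.concat([wr.temporal, wr.kinetics], axis=1)
            df.insert(0, "label", label)
            df["delta_z"] = wr.delta_z
            df["k_v"] = wr.k_v
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def work_table(self) -> pd.DataFrame:
        """Per-window work summary (J/kg/m) and stiffness."""
        rows = {}
        for label, wr in self.windows.items():
            w = wr.work
            rows[label] = {
                "w_pot": w.w_pot, "w_kin": w.w_kin, "w_ext": w.w_ext,
                "w_int": w.w_int, "w_tot": w.w_tot,
                "k_v": w.k_v, "delta_z": w.delta_z,
            }
        return pd.DataFrame(rows).T

    def window_means(self) -> pd.DataFrame:
        """Window means of the per-step variables (NaN-aware)."""
        per = self.per_step()
        num = per.drop(columns=["has_impact"]).groupby("label", sort=False)
        means = num.mean()
        means["impact_steps"] = per.groupby("label", sort=False)[
            "has_impact"
        ].sum()
        return means

    def impact_flags(self) -> pd.DataFrame:
        """Per-step impact flags in census form (columns label, has_impact)."""
        per = self.per_step()
        return per[["label", "has_impact"]].copy()

    def summary(self) -> str:
        """Human-readable window summary (mean +/- SD per window)."""
        rec = self.model.recording
        bw = rec.body_weight
        lines = [
            "Treadmill trial analysis",
            f"  mass {rec.mass:.1f} kg | belt {rec.belt_speed:.2f} m/s | "
            f"{rec.rate:.0f} Hz | {rec.duration:.1f} s | "
            f"{len(self.windows)} window(s) of "
            f"{self.model.config.n_strides} strides",
            "",
        ]
        header = f"{'window':>8} {'steps':>5}"
        for name, unit, _ in _SUMMARY_VARS:
            col = f"{name}[{unit}]" if unit else name
            header += f" {col:>16}"
        lines.append(header)
        for label, wr in self.windows.items():
            per = pd.concat([wr.temporal, wr.kinetics], axis=1)
            per = per.assign(k_v=wr.k_v)
            row = f"{label:>8} {len(wr.window.steps):>5}"
            for name, unit, scale in _SUMMARY_VARS:
                if name in ("w_ext", "w_tot"):
                    val = getattr(wr.work, name)
                    row += f" {val:>16.3f}"
                    continue
                vals = per[name].to_numpy(dtype=float)
                s = 1.0 / bw if scale is None else scale
                m = np.nanmean(vals) * s
                sd = np.nanstd(vals, ddof=1) * s
                row += f" {m:>9.3f}±{sd:<6.3f}"
            lines.append(row)
        lines.append("")
        lines.append(
            "impact-peak steps per window: "
            + ", ".join(
                f"{label}={int(wr.kinetics['has_impact'].sum())}"
                for label, wr in self.windows.items()
            )
        )
        return "\n".join(lines)

    def to_document(self) -> dict:
        """Results as a schema-valid JSON document structure."""
        rec = self.model.recording
        doc = {
            "schema": RESULTS_SCHEMA_ID,
            "units": dict(UNITS),
            "meta": {
                "mass_kg": rec.mass,
                "belt_speed_m_s": rec.belt_speed,
                "rate_hz": rec.rate,
                "gravity_m_s2": rec.gravity,
                "n_strides": self.model.config.n_strides,
            },
            "windows": [],
        }
        for label, wr in self.windows.items():
            per = pd.concat([wr.temporal, wr.kinetics], axis=1)
            per = per.assign(delta_z=wr.delta_z, k_v=wr.k_v)
            steps = [
                {
                    k: (None if isinstance(v, float) and np.isnan(v) else v)
                    for k, v in row.items()
                }
                for row in per.to_dict(orient="records")
            ]
            means = {
                "w_pot": wr.work.w_pot, "w_kin": wr.work.w_kin,
                "w_ext": wr.work.w_ext, "w_int": wr.work.w_int,
                "w_tot": wr.work.w_tot, "k_v": wr.work.k_v,
                "delta_z": wr.work.delta_z,
            }
            doc["windows"].append(
                {
                    "label": label,
                    "t_start_s": wr.window.t_start,
                    "n_strides": wr.window.n_strides,
                    "means": means,
                    "steps": steps,
                }
            )
        return doc

    def save(self, path) -> None:
        write_results(self.to_document(), path)

    def plot_grf(self, label: str | None = None, ax=None):
        """Plot the vertical and fore-aft GRF of one analysis window."""
        import matplotlib.pyplot as plt

        label = label or next(iter(self.windows))
        wr = self.windows[label]
        rec = self.model.recording
        sl = slice(wr.window.i_start, wr.window.i_end + 1)
        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3))
        ax.plot(rec.time[sl], rec.f_v[sl], label="vertical")
        ax.plot(rec.time[sl], rec.f_ap[sl], label="fore-aft")
        ax.axhline(self.model.config.threshold_n, ls=":", c="grey", lw=0.8)
        ax.set_xlabel("time [s]")
        ax.set_ylabel("force [N]")
        ax.set_title(f"window {label!r}")
        ax.legend(frameon=False)
        return ax
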