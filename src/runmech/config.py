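"""Analysis configuration: detection thresholds, filter settings, gravity.

Round-trips to YAML so a whole pipeline run is reproducible from a small
text file.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .events import MIDSTANCE_HOLD_S, MIN_CONTACT_S, MIN_FLIGHT_S
from .io import STANDARD_GRAVITY

__all__ = ["AnalysisConfig"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable parameters of the analysis pipeline.

    ``lowpass_hz = None`` disables the conditioning filter (useful for
    noiseless synthetic data).
    """

    threshold_n: float = 20.0        # N, foot-strike/toe-off threshold
    lowpass_hz: float | None = 20.0  # Hz, conditioning cutoff
    filter_order: int = 5
    gravity: float = STANDARD_GRAVITY
    n_strides: int = 10              # strides per analysis window
    min_contact_s: float = MIN_CONTACT_S
    min_flight_s: float = MIN_FLIGHT_S
    midstance_hold_s: float = MIDSTANCE_HOLD_S

    def replace(self, **kw) -> "AnalysisConfig":
        return dataclasses.replace(self, **kw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)
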