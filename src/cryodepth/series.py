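"""Skin-temperature time series from the probe protocol.

Four thermocouple probes sit laterally on the operated thigh
(trochanter, mid femur, distal femur) and on the contralateral femur,
sampled every 10 s through a 30 min treatment phase and the passive
rewarming that follows wrap removal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PROBE_SITES", "SkinTemperatureSeries"]

PROBE_SITES = ("trochanter", "mid_femur", "distal_femur", "contralateral")
PHASES = ("treatment", "rewarming")


@dataclass
class SkinTemperatureSeries:
    """One probe site's timestamped temperatures with phase labels.

    `time_s` is a single clock from the start of treatment; rewarming
    samples carry later timestamps than treatment ones. `phase` labels
    each sample "treatment" or "rewarming".
    """

    subject_id: str
    site: str
    time_s: np.ndarray
    temp_C: np.ndarray
    phase: np.ndarray

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.temp_C = np.asarray(self.temp_C, dtype=float)
        self.phase = np.asarray(self.phase, dtype=object)
        if not (self.time_s.shape == self.temp_C.shape == self.phase.shape):
            raise ValueError("time_s, temp_C and phase must have equal shapes")
        if self.site not in PROBE_SITES:
            raise ValueError(f"unknown probe site {self.site!r}")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time_s must be strictly increasing")
        unknown = set(self.phase) - set(PHASES)
        if unknown:
            raise ValueError(f"unknown phase labels {sorted(unknown)}")

    @property
    def treatment_mask(self) -> np.ndarray:
        return self.phase == "treatment"

    @property
    def baseline_C(self) -> float:
        """Pre-treatment skin baseline: the first treatment-phase sample."""
        idx = np.flatnonzero(self.treatment_mask)
        if idx.size == 0:
            raise ValueError("series has no treatment phase")
        return float(self.temp_C[idx[0]])

    def treatment(self) -> tuple[np.ndarray, np.ndarray]:
        """(times from treatment start, temps) of the treatment phase."""
        m = self.treatment_mask
        t = self.time_s[m]
        return t - t[0], self.temp_C[m]

    def rewarming(self) -> tuple[np.ndarray, np.ndarray]:
        """(minutes elapsed since cessation, temps) of the rewarming phase.

        The cessation clock starts at the last treatment sample, so a
        rewarming sample 10 s after wrap removal sits at 1/6 min.
        """
        m = self.phase == "rewarming"
        if not m.any():
            raise ValueError("series has no rewarming phase")
        t_treat = self.time_s[self.treatment_mask]
        t_end = t_treat[-1] if t_treat.size else self.time_s[m][0]
        return (self.time_s[m] - t_end) / 60.0, self.temp_C[m]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "site": self.site,
                "time_s": self.time_s,
                "temp_C": self.temp_C,
                "phase": self.phase.astype(str),
            }
        )
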