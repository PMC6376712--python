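"""Depth-temperature summaries and threshold statistics.

Links the solved temperature field to the clinically relevant depths:
X-ray-derived skin-to-bone distances (calibrated against implants of
known size), per-depth min/mean/max over the treatment window, the
fraction of a cohort with thin soft-tissue cover, and the timing of
skin-analgesia threshold crossings during rewarming.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .series import SkinTemperatureSeries
from .solver import TemperatureField

__all__ = [
    "ANALGESIA_THRESHOLD_C",
    "XrayMeasurement",
    "DepthSummary",
    "ThresholdCrossings",
    "select_input_site",
    "calibrate_distance",
    "summarize_depth",
    "fraction_below",
    "threshold_crossing_times",
    "probe_not_covered",
]

logger = logging.getLogger(__name__)

#: Skin temperature below which skin analgesia is produced, degC.
ANALGESIA_THRESHOLD_C = 13.6

# Model input site per implant: most soft-tissue trauma sits at mid femur
# for DHS/HA/THA, but at the nail entry point (trochanter) for IMHN.
_SITE_BY_SURGERY = {
    "DHS": "mid_femur",
    "HA": "mid_femur",
    "THA": "mid_femur",
    "IMHN": "trochanter",
}


@dataclass
class XrayMeasurement:
    """Calibrated lateral soft-tissue distances for one subject, mm.

    Dimensions follow the radiograph protocol: A trochanter,
    B mid femur (central), C distal femur, D shortest skin-to-fracture.
    Missing measurements are NaN.
    """

    subject_id: str
    dist_trochanter_mm: float = math.nan
    dist_mid_mm: float = math.nan
    dist_distal_mm: float = math.nan
    dist_fracture_mm: float = math.nan

    def __post_init__(self) -> None:
        for name in ("dist_trochanter_mm", "dist_mid_mm", "dist_distal_mm", "dist_fracture_mm"):
            v = getattr(self, name)
            if not math.isnan(v) and v <= 0:
                raise ValueError(f"{name} must be positive or NaN (missing)")

    def distances(self) -> dict[str, float]:
        return {
            "trochanter": self.dist_trochanter_mm,
            "mid": self.dist_mid_mm,
            "distal": self.dist_distal_mm,
            "fracture": self.dist_fracture_mm,
        }


@dataclass(frozen=True)
class DepthSummary:
    """Min / time-mean / max temperature at a depth over the treatment window."""

    depth_mm: float
    min_temp_C: float
    mean_temp_C: float
    max_temp_C: float

    def __post_init__(self) -> None:
        if not self.min_temp_C <= self.mean_temp_C <= self.max_temp_C:
            raise ValueError("require min <= mean <= max")


@dataclass(frozen=True)
class ThresholdCrossings:
    """Timing statistics of one trace against a temperature threshold.

    All times in minutes. `time_below_min` is the total treatment time
    spent below the threshold; `reexceed_min` the time after cessation
    until the rewarming trace re-exceeds it (None if the trace was not
    below it at cessation); `baseline_return_min` the time after
    cessation until the trace comes within the tolerance of the
    pre-treatment baseline (None if it never does).
    """

    time_below_min: float
    reexceed_min: float | None
    baseline_return_min: float | None
    baseline_C: float


def select_input_site(surgery_type: str) -> str:
    """Probe site whose trace drives the model for a given implant."""
    try:
        return _SITE_BY_SURGERY[surgery_type]
    except KeyError:
        raise ValueError(f"unknown surgery type {surgery_type!r}") from None


def calibrate_distance(measured_px: float, implant_px: float, implant_mm: float) -> float:
    """Convert a pixel distance to mm using an implant of known size."""
    if implant_px <= 0 or implant_mm <= 0:
        raise ValueError("calibration lengths must be positive")
    if measured_px < 0:
        raise ValueError("measured length must be non-negative")
    return measured_px * (implant_mm / implant_px)


def summarize_depth(
    field: TemperatureField,
    depth_mm: float,
    window_s: tuple[float, float] | None = None,
) -> DepthSummary:
    """Min/mean/max temperature at a depth over the treatment window.

    The series at `depth_mm` is linearly interpolated between the two
    bracketing grid depths; the window (default the full solved span)
    is inclusive at both ends.
    """
    depth_m = depth_mm * 1e-3
    if not 0.0 <= depth_m <= field.depths[-1]:
        raise ValueError("depth outside the solved domain")
    trace = field.at_depth(depth_m)
    if window_s is not None:
        m = (field.times >= window_s[0]) & (field.times <= window_s[1])
        if not m.any():
            raise ValueError("window contains no solved time levels")
        trace = trace[m]
    return DepthSummary(
        depth_mm=depth_mm,
        min_temp_C=float(trace.min()),
        mean_temp_C=float(trace.mean()),
        max_temp_C=float(trace.max()),
    )


def fraction_below(
    distances_mm, threshold_mm: float, inclusive: bool = False
) -> float:
    """Proportion of distances below (or at) a threshold.

    Missing values (NaN) are dropped first. The `inclusive` flag picks
    between the "less than" and "or less" conventions; both appear in
    clinical reporting and the choice is made explicit here.
    """
    d = np.asarray(list(distances_mm), dtype=float)
    d = d[~np.isnan(d)]
    if d.size == 0:
        raise ValueError("no non-missing distances")
    hits = (d <= threshold_mm) if inclusive else (d < threshold_mm)
    return float(hits.sum() / d.size)


def _time_below(t_min: np.ndarray, y: np.ndarray, threshold: float) -> float:
    """Total time (min) a piecewise-linear trace spends strictly below a level."""
    total = 0.0
    for i in range(len(t_min) - 1):
        t0, t1, y0, y1 = t_min[i], t_min[i + 1], y[i], y[i + 1]
        if y0 < threshold and y1 < threshold:
            total += t1 - t0
        elif y0 < threshold <= y1:
            total += (t1 - t0) * (threshold - y0) / (y1 - y0)
        elif y1 < threshold <= y0:
            total += (t1 - t0) * (1.0 - (threshold - y0) / (y1 - y0))
    return total


def _first_upcrossing(t_min: np.ndarray, y: np.ndarray, level: float) -> float | None:
    """First time (min) a piecewise-linear trace reaches `level` from below."""
    if y[0] >= level:
        return float(t_min[0])
    idx = np.flatnonzero(y >= level)
    if idx.size == 0:
        return None
    i = int(idx[0])
    frac = (level - y[i - 1]) / (y[i] - y[i - 1])
    return float(t_min[i - 1] + frac * (t_min[i] - t_min[i - 1]))


def threshold_crossing_times(
    series: SkinTemperatureSeries,
    threshold_C: float = ANALGESIA_THRESHOLD_C,
    baseline_tolerance_C: float = 0.5,
) -> ThresholdCrossings:
    """Threshold timing of one skin trace across treatment and rewarming.

    Crossing instants are located by linear interpolation between the
    10-s samples. "Return to baseline" means coming within
    `baseline_tolerance_C` of the pre-treatment baseline (the first
    treatment-phase sample); a threshold that is never crossed is
    reported as None, not an error.
    """
    t_treat, y_treat = series.treatment()
    baseline = series.baseline_C
    below = _time_below(t_treat / 60.0, y_treat, threshold_C)

    t_rw, y_rw = series.rewarming()
    # prepend the cessation point so the first rewarming segment starts at 0
    t_full = np.concatenate([[0.0], t_rw])
    y_full = np.concatenate([[y_treat[-1]], y_rw])

    if y_full[0] >= threshold_C:
        reexceed = None  # was not below the threshold when the wrap came off
    else:
        reexceed = _first_upcrossing(t_full, y_full, threshold_C)

    baseline_return = _first_upcrossing(t_full, y_full, baseline - baseline_tolerance_C)

    return ThresholdCrossings(
        time_below_min=below,
        reexceed_min=reexceed,
        baseline_return_min=baseline_return,
        baseline_C=baseline,
    )


def probe_not_covered(series: SkinTemperatureSeries, cutoff_C: float = 30.0) -> bool:
    """Flag a treatment trace whose minimum never drops below `cutoff_C`.

    A probe that the wrap did not cover barely cools (observed as a
    30.8 degC minimum in the measurements); such traces are excluded
    from modelling with a logged warning.
    """
    _, y = series.treatment()
    if float(y.min()) > cutoff_C:
        logger.warning(
            "subject %s site %s: treatment minimum %.1f degC above %.1f degC cutoff; "
            "probe likely not covered by the wrap",
            series.subject_id,
            series.site,
            float(y.min()),
            cutoff_C,
        )
        return True
    return False
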