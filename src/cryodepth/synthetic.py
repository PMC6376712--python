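"""Synthetic hip-fracture cohort generator.

No public accession exists for the trial's raw measurements, so this
module emulates their statistical structure well enough to exercise
every pipeline stage: cohort anthropometrics (median BMI 22 in
[20, 34], ages ~80.5 truncated to [40, 95], 26/35 female), skin
traces that drop from a ~32.1 degC baseline toward ~18.2 degC within
30 min with the fastest decline in the first five minutes, exponential
rewarming with no overshoot, X-ray skin-to-bone distance distributions
per radiograph dimension, and NRS pain trajectories declining over the
first 72 postoperative hours.

Cooling and rewarming are single exponentials per phase — the simplest
shape consistent with every published summary anchor (initial decline
rate, ~11.5 degC minimum, re-crossing the 13.6 degC analgesia
threshold ~5.5 min after cessation, baseline regained around 179 min).
A 50-min rewarming time constant satisfies the last two anchors
simultaneously.

Pain scores are integers clamped to 0..10. Clamping censors a latent
normal at the floor, which would silently flatten a configured linear
trend; the generator therefore inverts the clamped-mean function so
the *emitted* scores follow the configured mean trajectory — the
configured decline is a property of the observable data, and trend
recovery is unbiased by construction.

All draws flow from one seed through named substreams per subject,
data kind and probe site, so adding subjects or sites never reshuffles
earlier draws.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
from scipy import optimize, stats

from .pain import TreatmentRecord
from .series import PROBE_SITES, SkinTemperatureSeries
from .solver import BoundaryCondition
from .thermal import Subject

__all__ = [
    "GeneratorParams",
    "generate_cohort",
    "generate_skin_series",
    "generate_trace",
    "generate_pain_records",
    "generate_dataset",
    "average_cooling_boundary",
]


@dataclass(frozen=True)
class GeneratorParams:
    """Study conditions the generator emulates.

    Temperatures in degC, times in seconds unless suffixed otherwise.
    """

    n_subjects: int = 35
    female_fraction: float = 26 / 35
    age_mean: float = 80.5
    age_sd: float = 8.0
    age_range: tuple[float, float] = (40.0, 95.0)
    bmi_median: float = 22.0
    bmi_range: tuple[float, float] = (20.0, 34.0)
    bmi_log_sd: float = 0.15
    height_mean_m: dict = field(
        default_factory=lambda: {"female": 1.62, "male": 1.76}
    )
    height_sd_m: dict = field(default_factory=lambda: {"female": 0.06, "male": 0.07})
    height_range_m: tuple[float, float] = (1.50, 1.92)
    core_temp_mean: float = 37.2
    core_temp_sd: float = 0.6
    core_temp_range: tuple[float, float] = (35.5, 39.0)
    # surgery mix: 9 DHS, 12 HA/THA (split evenly), 14 IMHN of 35
    surgery_weights: dict = field(
        default_factory=lambda: {"DHS": 9, "HA": 6, "THA": 6, "IMHN": 14}
    )

    # --- skin traces ---
    skin_baseline_mean: float = 32.1
    skin_baseline_sd: float = 2.0
    end_temp_mean: float = 18.2
    end_temp_sd: float = 4.0
    end_temp_floor: float = 10.0
    # per-site shift of the treatment end temperature; the contralateral
    # probe barely cools (wrap on the operated side only)
    site_end_offset: dict = field(
        default_factory=lambda: {"trochanter": 1.5, "mid_femur": 0.0, "distal_femur": -1.0}
    )
    contralateral_drop: float = 1.0
    tau_cool_s: float = 300.0     # 5 min: fastest decline in the first 5 min
    tau_rewarm_s: float = 3000.0  # 50 min
    rewarm_min_C: float | None = None  # None -> the trace's end-of-treatment temp
    noise_sd: float = 0.2
    sample_interval_s: float = 10.0
    treatment_duration_s: float = 1800.0
    rewarm_duration_s: float = 18000.0  # 300 min, past the ~179 min baseline return

    # --- X-ray distances, mm (dimension: (mean, sd)) ---
    distance_mean_sd: dict = field(
        default_factory=lambda: {
            "trochanter": (34.1, 13.8),
            "mid": (42.6, 13.6),
            "distal": (37.6, 11.6),
            "fracture": (59.6, 10.8),
        }
    )
    distance_floor_mm: float = 5.0

    # --- NRS pain ---
    n_cycles: int = 12
    cycle_spacing_h: float = 6.0
    nrs_start: float = 3.0
    nrs_decline_per_6h: float = 0.14
    nrs_noise_sd: float = 1.9
    improvement_mean: float = 1.5
    improvement_sd: float = 1.0
    beta_temp_drop: float = 0.0  # injected association effect, NRS per degC

    def __post_init__(self) -> None:
        for name in ("age_sd", "bmi_log_sd", "core_temp_sd", "skin_baseline_sd",
                     "end_temp_sd", "noise_sd", "nrs_noise_sd", "improvement_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ValueError("female_fraction must lie in [0, 1]")
        if self.tau_cool_s <= 0 or self.tau_rewarm_s <= 0:
            raise ValueError("time constants must be positive")
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be >= 0")


# ---------------------------------------------------------------------------
# seeded substreams

def _rng(seed: int, *keys) -> np.random.Generator:
    """Named substream: one Generator per (seed, key...) tuple."""
    entropy = [int(seed)] + [zlib.crc32(str(k).encode()) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _truncnorm(rng, mean, sd, low=-np.inf, high=np.inf, size=None):
    if sd == 0:
        return np.clip(mean if size is None else np.full(size, mean), low, high)
    a, b = (low - mean) / sd, (high - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


# ---------------------------------------------------------------------------
# clamped-integer latent calibration

def _phi(z: float) -> float:
    return 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))


def _clamped_round_mean(mu: float, sd: float) -> float:
    """E[min(10, max(0, round(X)))] for X ~ N(mu, sd), half-up rounding."""
    if sd == 0:
        return min(10.0, max(0.0, float(np.floor(mu + 0.5))))
    total = 0.0
    for k in range(1, 10):
        total += k * (_phi((k + 0.5 - mu) / sd) - _phi((k - 0.5 - mu) / sd))
    total += 10.0 * (1.0 - _phi((9.5 - mu) / sd))
    return total


@lru_cache(maxsize=8192)
def _latent_mean_for(target: float, sd: float) -> float:
    """Latent normal mean whose clamped-rounded expectation equals `target`."""
    target = min(10.0 - 1e-6, max(1e-6, target))
    if sd == 0:
        return target
    lo, hi = -10.0 * sd - 10.0, 10.0 * sd + 20.0
    return float(optimize.brentq(lambda m: _clamped_round_mean(m, sd) - target, lo, hi))


def _clamp_round(x: float) -> int:
    return int(min(10, max(0, math.floor(x + 0.5))))


# ---------------------------------------------------------------------------
# cohort

@lru_cache(maxsize=64)
def _log_bmi_loc(median: float, log_sd: float, bmi_range: tuple[float, float]) -> float:
    """Location of the truncated log-normal whose median equals `median`.

    The printed BMI range [20, 34] is asymmetric about the median 22;
    truncating a log-normal centred at log(22) would drag the median up,
    so the location is calibrated such that the truncated distribution's
    median lands on the configured value.
    """
    lo, hi, target = np.log(bmi_range[0]), np.log(bmi_range[1]), np.log(median)
    if log_sd == 0:
        return float(target)

    def med(loc):
        a, b = (lo - loc) / log_sd, (hi - loc) / log_sd
        return stats.truncnorm.ppf(0.5, a, b, loc=loc, scale=log_sd)

    return float(optimize.brentq(lambda m: med(m) - target, lo - 5 * log_sd, hi))


def generate_cohort(
    params: GeneratorParams, seed: int
):
    """Draw subjects and their X-ray distance measurements.

    Returns ``(subjects, xrays)``; reproducible for a fixed seed, and
    subject i's draws do not depend on n_subjects.
    """
    from .profiles import XrayMeasurement

    if params.n_subjects < 1:
        raise ValueError("need at least one subject")
    subjects, xrays = [], []
    surgeries = list(params.surgery_weights)
    w = np.array([params.surgery_weights[s] for s in surgeries], dtype=float)
    w /= w.sum()
    for i in range(params.n_subjects):
        sid = f"S{i + 1:03d}"
        rng = _rng(seed, i, "cohort")
        sex = "female" if rng.random() < params.female_fraction else "male"
        age = float(_truncnorm(rng, params.age_mean, params.age_sd, *params.age_range))
        loc = _log_bmi_loc(params.bmi_median, params.bmi_log_sd, params.bmi_range)
        bmi = float(
            np.exp(
                _truncnorm(
                    rng, loc, params.bmi_log_sd,
                    np.log(params.bmi_range[0]), np.log(params.bmi_range[1]),
                )
            )
        )
        height = float(
            _truncnorm(
                rng,
                params.height_mean_m[sex],
                params.height_sd_m[sex],
                *params.height_range_m,
            )
        )
        weight = bmi * height**2
        core = float(_truncnorm(rng, params.core_temp_mean, params.core_temp_sd,
                                *params.core_temp_range))
        surgery = str(rng.choice(surgeries, p=w))
        pressure = str(rng.choice(["low", "medium", "high"]))
        subjects.append(
            Subject(
                id=sid, age=age, sex=sex, weight=weight, height=height,
                core_temp_T0=core, surgery_type=surgery, pressure_setting=pressure,
            )
        )
        xr = _rng(seed, i, "xray")
        dist = {
            dim: float(_truncnorm(xr, m, s, params.distance_floor_mm))
            for dim, (m, s) in params.distance_mean_sd.items()
        }
        xrays.append(
            XrayMeasurement(
                subject_id=sid,
                dist_trochanter_mm=dist["trochanter"],
                dist_mid_mm=dist["mid"],
                dist_distal_mm=dist["distal"],
                dist_fracture_mm=dist["fracture"],
            )
        )
    return subjects, xrays


# ---------------------------------------------------------------------------
# skin traces

def _trace_from(
    baseline: float,
    end_temp: float,
    params: GeneratorParams,
    rng: np.random.Generator,
    subject_id: str,
    site: str,
    rewarm_min: float | None = None,
) -> SkinTemperatureSeries:
    """Double-exponential treatment + rewarming trace with sampling noise."""
    dt = params.sample_interval_s
    t_treat = np.arange(0.0, params.treatment_duration_s + 0.5 * dt, dt)
    clean_treat = end_temp + (baseline - end_temp) * np.exp(-t_treat / params.tau_cool_s)
    if rewarm_min is None:
        rewarm_min = float(clean_treat[-1])  # continuous at the phase junction
    elapsed = np.arange(dt, params.rewarm_duration_s + 0.5 * dt, dt)
    clean_rw = baseline - (baseline - rewarm_min) * np.exp(-elapsed / params.tau_rewarm_s)

    temps = np.concatenate([clean_treat, clean_rw])
    if params.noise_sd > 0:
        temps = temps + rng.normal(0.0, params.noise_sd, size=temps.size)
    times = np.concatenate([t_treat, params.treatment_duration_s + elapsed])
    phase = np.array(
        ["treatment"] * t_treat.size + ["rewarming"] * elapsed.size, dtype=object
    )
    return SkinTemperatureSeries(
        subject_id=subject_id, site=site, time_s=times, temp_C=np.clip(temps, 0.0, 45.0),
        phase=phase,
    )


def generate_skin_series(
    subject: Subject, params: GeneratorParams, seed: int, sites=PROBE_SITES
) -> dict[str, SkinTemperatureSeries]:
    """Per-site skin traces for one subject, keyed by probe site."""
    out = {}
    for site in sites:
        rng = _rng(seed, zlib.crc32(subject.id.encode()), "skin", site)
        baseline = float(
            _truncnorm(rng, params.skin_baseline_mean, params.skin_baseline_sd, 25.0, 40.0)
        )
        if site == "contralateral":
            end_temp = baseline - params.contralateral_drop
        else:
            offset = params.site_end_offset.get(site, 0.0)
            end_temp = float(
                _truncnorm(
                    rng,
                    params.end_temp_mean + offset,
                    params.end_temp_sd,
                    params.end_temp_floor,
                    baseline - 2.0,
                )
            )
        out[site] = _trace_from(
            baseline, end_temp, params, rng, subject.id, site,
            rewarm_min=params.rewarm_min_C,
        )
    return out


def generate_trace(
    params: GeneratorParams,
    seed: int,
    baseline_C: float,
    end_temp_C: float,
    subject_id: str = "trace",
    site: str = "mid_femur",
) -> SkinTemperatureSeries:
    """One trace with fixed baseline and end temperature (no cohort draws).

    Convenient for threshold-timing studies where the deterministic
    trace shape is prescribed and only sampling noise varies with the
    seed.
    """
    rng = _rng(seed, zlib.crc32(subject_id.encode()), "trace", site)
    return _trace_from(
        baseline_C, end_temp_C, params, rng, subject_id, site,
        rewarm_min=params.rewarm_min_C,
    )


# ---------------------------------------------------------------------------
# pain records

def generate_pain_records(
    subject: Subject,
    params: GeneratorParams,
    seed: int,
    simulated_temp_drop: float = 0.0,
) -> list[TreatmentRecord]:
    """Twelve treatment cycles of pre/post NRS at 6-h spacing.

    Post scores follow the configured declining mean trajectory;
    improvements (pre minus post) have mean `improvement_mean` plus
    `beta_temp_drop * simulated_temp_drop` for power and recovery
    studies. Latent normals are calibrated so the clamped integer
    scores keep those means (see module docstring).
    """
    rng = _rng(seed, zlib.crc32(subject.id.encode()), "pain")
    records = []
    pressure_schedule = ["low", "medium", "high"]
    for c in range(params.n_cycles):
        t_h = (c + 1) * params.cycle_spacing_h
        post_target = params.nrs_start - params.nrs_decline_per_6h * (t_h / 6.0)
        mu_post = _latent_mean_for(round(post_target, 9), params.nrs_noise_sd)
        post = _clamp_round(mu_post + rng.normal(0.0, params.nrs_noise_sd))

        impr_target = params.improvement_mean + params.beta_temp_drop * simulated_temp_drop
        mu_impr = _latent_mean_for(round(impr_target, 9), params.improvement_sd)
        impr = _clamp_round(mu_impr + rng.normal(0.0, params.improvement_sd))

        records.append(
            TreatmentRecord(
                subject_id=subject.id,
                pod=int(t_h // 24) + (1 if t_h % 24 else 0) if t_h <= 72 else 3,
                cycle_time_h=float(t_h),
                nrs_pre=min(10, post + impr),
                nrs_post=post,
                pressure=pressure_schedule[min(c // 4, 2)],
            )
        )
    return records


# ---------------------------------------------------------------------------
# bundles & boundaries

def generate_dataset(params: GeneratorParams, seed: int) -> dict:
    """Full synthetic dataset: subjects, X-rays, skin traces, pain records.

    The injected-association covariate for pain records is a cheap
    proxy (baseline minus mean treatment skin temperature at the
    model's input site); with the default beta of 0 it is inert.
    """
    from .profiles import select_input_site

    subjects, xrays = generate_cohort(params, seed)
    skin = {}
    pain = []
    for s in subjects:
        traces = generate_skin_series(s, params, seed)
        skin[s.id] = traces
        site = select_input_site(s.surgery_type)
        tr = traces[site]
        _, temps = tr.treatment()
        drop = tr.baseline_C - float(np.mean(temps))
        pain.extend(generate_pain_records(s, params, seed, simulated_temp_drop=drop))
    return {"subjects": subjects, "xrays": xrays, "skin": skin, "pain": pain}


def average_cooling_boundary(
    baseline_C: float = 32.1,
    end_temp_C: float = 18.2,
    tau_s: float = 300.0,
    duration_s: float = 1800.0,
    deep_temp_T0: float = 37.0,
    sample_interval_s: float = 10.0,
) -> BoundaryCondition:
    """Cohort-average noiseless cooling boundary through printed endpoints.

    Exponential decay with time constant `tau_s` from `baseline_C`
    toward the asymptote that makes the trace pass exactly through
    `end_temp_C` at `duration_s`.
    """
    decay = math.exp(-duration_s / tau_s)
    t_inf = (end_temp_C - baseline_C * decay) / (1.0 - decay)
    t = np.arange(0.0, duration_s + 0.5 * sample_interval_s, sample_interval_s)
    temps = t_inf + (baseline_C - t_inf) * np.exp(-t / tau_s)
    return BoundaryCondition(times=t, temps=temps, deep_temp_T0=deep_temp_T0)
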