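"""CSV readers and writers for the four pipeline input tables.

Formats (one row per record, plain CSV):

* cohort:  id, age_years, sex, weight_kg, height_cm, core_temp_C,
           surgery_type, pressure
* skin:    subject_id, site, time_s, temp_C, phase
* xray:    subject_id, dist_trochanter_mm, dist_mid_mm, dist_distal_mm,
           dist_fracture_mm   (empty cell = missing)
* nrs:     subject_id, pod, cycle_time_h, nrs_pre, nrs_post, pressure

Heights are stored in cm (as recorded clinically) and converted to
metres on read.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .pain import TreatmentRecord
from .profiles import XrayMeasurement
from .series import SkinTemperatureSeries
from .thermal import Subject

__all__ = [
    "read_cohort", "write_cohort",
    "read_skin_series", "write_skin_series",
    "read_xray", "write_xray",
    "read_nrs", "write_nrs",
    "write_dataset",
]


def read_cohort(path) -> list[Subject]:
    df = pd.read_csv(path)
    return [
        Subject(
            id=str(r.id),
            age=float(r.age_years),
            sex=str(r.sex),
            weight=float(r.weight_kg),
            height=float(r.height_cm) / 100.0,
            core_temp_T0=float(r.core_temp_C),
            surgery_type=str(r.surgery_type),
            pressure_setting=str(r.pressure),
        )
        for r in df.itertuples()
    ]


def write_cohort(subjects, path) -> None:
    pd.DataFrame(
        {
            "id": [s.id for s in subjects],
            "age_years": [s.age for s in subjects],
            "sex": [s.sex for s in subjects],
            "weight_kg": [s.weight for s in subjects],
            "height_cm": [s.height * 100.0 for s in subjects],
            "core_temp_C": [s.core_temp_T0 for s in subjects],
            "surgery_type": [s.surgery_type for s in subjects],
            "pressure": [s.pressure_setting for s in subjects],
        }
    ).to_csv(path, index=False)


def read_skin_series(path) -> dict[str, dict[str, SkinTemperatureSeries]]:
    """Nested mapping subject_id -> site -> series."""
    df = pd.read_csv(path)
    out: dict[str, dict[str, SkinTemperatureSeries]] = {}
    for (sid, site), g in df.groupby(["subject_id", "site"], sort=False):
        g = g.sort_values("time_s")
        out.setdefault(str(sid), {})[str(site)] = SkinTemperatureSeries(
            subject_id=str(sid),
            site=str(site),
            time_s=g["time_s"].to_numpy(dtype=float),
            temp_C=g["temp_C"].to_numpy(dtype=float),
            phase=g["phase"].to_numpy(dtype=object),
        )
    return out


def write_skin_series(skin: dict[str, dict[str, SkinTemperatureSeries]], path) -> None:
    frames = [tr.to_frame() for sites in skin.values() for tr in sites.values()]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_xray(path) -> list[XrayMeasurement]:
    df = pd.read_csv(path)

    def val(x):
        return float(x) if pd.notna(x) else math.nan

    return [
        XrayMeasurement(
            subject_id=str(r.subject_id),
            dist_trochanter_mm=val(r.dist_trochanter_mm),
            dist_mid_mm=val(r.dist_mid_mm),
            dist_distal_mm=val(r.dist_distal_mm),
            dist_fracture_mm=val(r.dist_fracture_mm),
        )
        for r in df.itertuples()
    ]


def write_xray(xrays, path) -> None:
    pd.DataFrame(
        {
            "subject_id": [x.subject_id for x in xrays],
            "dist_trochanter_mm": [x.dist_trochanter_mm for x in xrays],
            "dist_mid_mm": [x.dist_mid_mm for x in xrays],
            "dist_distal_mm": [x.dist_distal_mm for x in xrays],
            "dist_fracture_mm": [x.dist_fracture_mm for x in xrays],
        }
    ).to_csv(path, index=False)


def read_nrs(path) -> list[TreatmentRecord]:
    df = pd.read_csv(path)

    def score(x):
        return int(x) if pd.notna(x) else None

    return [
        TreatmentRecord(
            subject_id=str(r.subject_id),
            pod=int(r.pod),
            cycle_time_h=float(r.cycle_time_h),
            nrs_pre=score(r.nrs_pre),
            nrs_post=score(r.nrs_post),
            pressure=str(r.pressure),
        )
        for r in df.itertuples()
    ]


def write_nrs(records, path) -> None:
    pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "pod": [r.pod for r in records],
            "cycle_time_h": [r.cycle_time_h for r in records],
            "nrs_pre": [r.nrs_pre for r in records],
            "nrs_post": [r.nrs_post for r in records],
            "pressure": [r.pressure for r in records],
        }
    ).to_csv(path, index=False)


def write_dataset(dataset: dict, outdir) -> dict[str, Path]:
    """Write a generated dataset bundle as the four input CSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "cohort": outdir / "cohort.csv",
        "skin": outdir / "skin_series.csv",
        "xray": outdir / "xray.csv",
        "nrs": outdir / "nrs.csv",
    }
    write_cohort(dataset["subjects"], paths["cohort"])
    write_skin_series(dataset["skin"], paths["skin"])
    write_xray(dataset["xrays"], paths["xray"])
    write_nrs(dataset["pain"], paths["nrs"])
    return paths
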