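"""End-to-end pipeline: data -> solves -> depth tables -> pain stats.

For each subject the pipeline selects the model input probe site from
the implant type, screens the trace for an uncovered probe, builds the
Dirichlet boundary from the treatment-phase trace with the subject's
core temperature as the deep/initial condition, solves the heat
equation with the subject-specific diffusivity, and summarises the
field at that subject's X-ray distances. Cohort outputs are the
per-dimension depth-temperature table (mean and SD of the per-subject
min / time-mean / max), thin-soft-tissue fractions, the rewarming
threshold timings, and the pain statistics (improvement vs predicted
temperature drop; post-NRS trend per 6 h).

Every exclusion (missing trace, uncovered probe, missing X-ray,
incomplete pain records) is logged with its reason and counted in the
result so that subjects in = analysed + excluded per stage.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .pain import AssociationResult, nrs_improvement, nrs_trend, pearson_association
from .profiles import (
    ANALGESIA_THRESHOLD_C,
    fraction_below,
    probe_not_covered,
    select_input_site,
    summarize_depth,
    threshold_crossing_times,
)
from .solver import BoundaryCondition, SolverConfig, solve
from .synthetic import GeneratorParams, generate_dataset
from .thermal import BodyFatCoefficients, DEURENBERG, subject_thermal_properties

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

logger = logging.getLogger(__name__)

_DIM_LABELS = {
    "trochanter": "A-Trochanter",
    "mid": "B-Central",
    "distal": "C-Distal",
    "fracture": "D-Fracture",
}


@dataclass
class PipelineConfig:
    """Everything one analysis run needs, loadable from YAML/JSON.

    Either the four input CSV paths or a `generate` block (GeneratorParams
    fields) must be present. Thresholds: `analgesia_C` for skin analgesia,
    `probe_cutoff_C` for the uncovered-probe screen, `baseline_tol_C` for
    the return-to-baseline criterion.
    """

    cohort_csv: str | None = None
    skin_csv: str | None = None
    xray_csv: str | None = None
    nrs_csv: str | None = None
    generate: GeneratorParams | None = None
    seed: int = 0
    solver: SolverConfig = field(default_factory=SolverConfig)
    bf_coefficients: BodyFatCoefficients = DEURENBERG
    analgesia_C: float = ANALGESIA_THRESHOLD_C
    probe_cutoff_C: float = 30.0
    baseline_tol_C: float = 0.5
    temp_drop_dimension: str = "mid"  # central (B) distance by default
    outdir: str = "cryodepth_out"
    make_plots: bool = False

    def __post_init__(self) -> None:
        for name in ("analgesia_C", "probe_cutoff_C", "baseline_tol_C"):
            if not 0.0 <= getattr(self, name) <= 45.0:
                raise ValueError(f"{name} outside [0, 45] degC")
        has_files = all(
            p is not None for p in (self.cohort_csv, self.skin_csv, self.xray_csv, self.nrs_csv)
        )
        if self.generate is None and not has_files:
            raise ValueError("config needs either all four input CSVs or a generate block")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        if raw.get("generate") is not None:
            raw["generate"] = GeneratorParams(**raw["generate"])
        if "solver" in raw:
            raw["solver"] = SolverConfig(**raw["solver"])
        if "bf_coefficients" in raw:
            raw["bf_coefficients"] = BodyFatCoefficients(**raw["bf_coefficients"])
        return cls(**raw)


@dataclass
class PipelineResult:
    """Numeric outputs of one pipeline run (the tested surface)."""

    per_subject: pd.DataFrame       # one row per subject x dimension
    depth_table: pd.DataFrame       # cohort mean (SD) per dimension
    fractions: pd.DataFrame         # thin-soft-tissue proportions
    rewarming: pd.DataFrame         # threshold timings per subject
    association: AssociationResult | None
    trend: AssociationResult | None
    exclusions: dict                # stage -> list of subject ids
    n_subjects: int

    def counts(self) -> dict:
        analysed = len(set(self.per_subject["subject_id"])) if len(self.per_subject) else 0
        return {
            "subjects_in": self.n_subjects,
            "subjects_analysed": analysed,
            "excluded": {k: len(v) for k, v in self.exclusions.items()},
        }


def _load_inputs(config: PipelineConfig):
    if config.generate is not None:
        data = generate_dataset(config.generate, config.seed)
        return data["subjects"], data["skin"], data["xrays"], data["pain"]
    subjects = cio.read_cohort(config.cohort_csv)
    skin = cio.read_skin_series(config.skin_csv)
    xrays = cio.read_xray(config.xray_csv)
    pain = cio.read_nrs(config.nrs_csv)
    return subjects, skin, xrays, pain


def run_pipeline(config: PipelineConfig, write: bool = True) -> PipelineResult:
    """Run every stage; per-subject failures are logged, not fatal."""
    subjects, skin, xrays, pain = _load_inputs(config)
    xray_by_id = {x.subject_id: x for x in xrays}

    exclusions: dict[str, list[str]] = {
        "no_skin_series": [], "probe_not_covered": [], "no_xray": [], "stage_error": [],
    }
    rows, rewarm_rows = [], []
    temp_drop_by_id: dict[str, float] = {}

    for s in subjects:
        try:
            site = select_input_site(s.surgery_type)
            trace = skin.get(s.id, {}).get(site)
            if trace is None:
                logger.info("subject %s: no %s trace; excluded", s.id, site)
                exclusions["no_skin_series"].append(s.id)
                continue
            if probe_not_covered(trace, config.probe_cutoff_C):
                exclusions["probe_not_covered"].append(s.id)
                continue

            t_treat, y_treat = trace.treatment()
            duration = min(config.solver.duration, float(t_treat[-1]))
            cfg = (
                config.solver
                if duration == config.solver.duration
                else dataclasses.replace(config.solver, duration=duration)
            )
            props = subject_thermal_properties(s, config.bf_coefficients)
            boundary = BoundaryCondition(
                times=t_treat, temps=np.clip(y_treat, 0.0, 45.0), deep_temp_T0=s.core_temp_T0
            )
            field_ = solve(boundary, props.alpha, cfg)

            xr = xray_by_id.get(s.id)
            dists = xr.distances() if xr is not None else {}
            valid = {k: v for k, v in dists.items() if not math.isnan(v) and v <= cfg.L * 1e3}
            if not valid:
                logger.info("subject %s: no usable X-ray distances; excluded", s.id)
                exclusions["no_xray"].append(s.id)
                continue
            for dim, dist in valid.items():
                summ = summarize_depth(field_, dist)
                rows.append(
                    {
                        "subject_id": s.id,
                        "dimension": dim,
                        "distance_mm": dist,
                        "min_temp_C": summ.min_temp_C,
                        "mean_temp_C": summ.mean_temp_C,
                        "max_temp_C": summ.max_temp_C,
                        "alpha_m2_s": props.alpha,
                        "bf_percent": props.bf_percent,
                    }
                )
                if dim == config.temp_drop_dimension:
                    temp_drop_by_id[s.id] = trace.baseline_C - summ.mean_temp_C

            if (trace.phase == "rewarming").any():
                cr = threshold_crossing_times(
                    trace, config.analgesia_C, config.baseline_tol_C
                )
                rewarm_rows.append(
                    {
                        "subject_id": s.id,
                        "site": site,
                        "baseline_C": cr.baseline_C,
                        "time_below_min": cr.time_below_min,
                        "reexceed_min": cr.reexceed_min,
                        "baseline_return_min": cr.baseline_return_min,
                    }
                )
        except Exception:
            logger.exception("subject %s failed in the solve/profile stage", s.id)
            exclusions["stage_error"].append(s.id)

    per_subject = pd.DataFrame(rows)
    depth_table = _depth_table(per_subject)
    fractions = _fraction_table(xrays)
    rewarming = pd.DataFrame(rewarm_rows)
    association = _association(pain, temp_drop_by_id)
    trend = _trend(pain)

    result = PipelineResult(
        per_subject=per_subject,
        depth_table=depth_table,
        fractions=fractions,
        rewarming=rewarming,
        association=association,
        trend=trend,
        exclusions=exclusions,
        n_subjects=len(subjects),
    )
    summary = result.counts()
    logger.info("pipeline summary: %s", summary)
    if write:
        _write_outputs(config, result)
    return result


def _depth_table(per_subject: pd.DataFrame) -> pd.DataFrame:
    """Cohort depth-temperature table: mean (SD) per radiograph dimension."""
    if per_subject.empty:
        return pd.DataFrame()
    rows = []
    for dim, g in per_subject.groupby("dimension"):
        rows.append(
            {
                "dimension": _DIM_LABELS.get(dim, dim),
                "n": len(g),
                "distance_mean_mm": g["distance_mm"].mean(),
                "distance_sd_mm": g["distance_mm"].std(ddof=1),
                "min_temp_mean_C": g["min_temp_C"].mean(),
                "min_temp_sd_C": g["min_temp_C"].std(ddof=1),
                "mean_temp_mean_C": g["mean_temp_C"].mean(),
                "mean_temp_sd_C": g["mean_temp_C"].std(ddof=1),
                "max_temp_mean_C": g["max_temp_C"].mean(),
                "max_temp_sd_C": g["max_temp_C"].std(ddof=1),
            }
        )
    return pd.DataFrame(rows).sort_values("dimension").reset_index(drop=True)


def _fraction_table(xrays) -> pd.DataFrame:
    """Thin-soft-tissue fractions at the trochanter, both conventions."""
    dists = [x.dist_trochanter_mm for x in xrays]
    dists = [d for d in dists if not math.isnan(d)]
    if not dists:
        return pd.DataFrame()
    rows = []
    for thr in (20.0, 30.0):
        for inclusive in (False, True):
            rows.append(
                {
                    "threshold_mm": thr,
                    "convention": "le" if inclusive else "lt",
                    "fraction": fraction_below(dists, thr, inclusive=inclusive),
                    "n": len(dists),
                }
            )
    return pd.DataFrame(rows)


def _association(pain, temp_drop_by_id) -> AssociationResult | None:
    """Per-cycle NRS improvement vs the subject's predicted temperature drop."""
    x, y = [], []
    incomplete = 0
    for r in pain:
        if not r.complete:
            incomplete += 1
            continue
        drop = temp_drop_by_id.get(r.subject_id)
        if drop is None:
            continue
        x.append(nrs_improvement(r.nrs_pre, r.nrs_post))
        y.append(drop)
    if incomplete:
        logger.info("association: %d records with missing NRS dropped", incomplete)
    try:
        return pearson_association(np.array(x, float), np.array(y, float))
    except ValueError as e:
        logger.warning("association not computed: %s", e)
        return None


def _trend(pain) -> AssociationResult | None:
    try:
        return nrs_trend(pain)
    except ValueError as e:
        logger.warning("trend not computed: %s", e)
        return None


def _write_outputs(config: PipelineConfig, result: PipelineResult) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.per_subject.to_csv(outdir / "depth_summaries.csv", index=False)
    result.depth_table.to_csv(outdir / "depth_table.csv", index=False)
    result.fractions.to_csv(outdir / "fractions.csv", index=False)
    result.rewarming.to_csv(outdir / "rewarming.csv", index=False)
    stats = {
        "association_improvement_vs_temp_drop": (
            result.association.to_dict() if result.association else None
        ),
        "nrs_post_trend_per_6h": result.trend.to_dict() if result.trend else None,
        "counts": result.counts(),
        "exclusions": result.exclusions,
        "covariate": f"baseline - mean simulated temp at dimension "
                     f"{config.temp_drop_dimension!r}",
    }
    (outdir / "association.json").write_text(json.dumps(stats, indent=2))
    if config.make_plots:
        _plots(config, result, outdir)


def _plots(config: PipelineConfig, result: PipelineResult, outdir: Path) -> None:
    """Advisory figures: cooling/rewarming traces and depth profiles."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    subjects, skin, _, _ = _load_inputs(config)
    fig, ax = plt.subplots(figsize=(7, 4))
    for s in subjects[:10]:
        site = select_input_site(s.surgery_type)
        tr = skin.get(s.id, {}).get(site)
        if tr is not None:
            ax.plot(tr.time_s / 60.0, tr.temp_C, lw=0.6, alpha=0.6)
    ax.set_xlabel("time since treatment start (min)")
    ax.set_ylabel("skin temperature (degC)")
    ax.set_title("Skin cooling and passive rewarming")
    fig.tight_layout()
    fig.savefig(outdir / "fig_traces.png", dpi=120)
    plt.close(fig)

    if not result.per_subject.empty:
        fig, ax = plt.subplots(figsize=(6, 4))
        p = result.per_subject
        ax.scatter(p["distance_mm"], p["min_temp_C"], s=12)
        ax.set_xlabel("skin-to-bone distance (mm)")
        ax.set_ylabel("minimum simulated temperature (degC)")
        ax.set_title("Depth of cooling at X-ray distances")
        fig.tight_layout()
        fig.savefig(outdir / "fig_depth.png", dpi=120)
        plt.close(fig)
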