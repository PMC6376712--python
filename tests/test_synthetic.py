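"""Synthetic cohort generator: determinism, trace shape, emulation fidelity."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from cryodepth import (
    GeneratorParams,
    generate_cohort,
    generate_pain_records,
    generate_skin_series,
    generate_trace,
    nrs_trend,
    pearson_association,
)


# --- determinism ------------------------------------------------------------

def test_cohort_deterministic_for_fixed_seed():
    p = dataclasses.replace(GeneratorParams(), n_subjects=8)
    s1, x1 = generate_cohort(p, 42)
    s2, x2 = generate_cohort(p, 42)
    assert s1 == s2
    assert all(a.distances() == b.distances() for a, b in zip(x1, x2))
    s3, _ = generate_cohort(p, 43)
    assert s1 != s3


def test_adding_subjects_keeps_earlier_draws():
    small = dataclasses.replace(GeneratorParams(), n_subjects=5)
    big = dataclasses.replace(GeneratorParams(), n_subjects=9)
    s_small, _ = generate_cohort(small, 11)
    s_big, _ = generate_cohort(big, 11)
    assert s_small == s_big[:5]


def test_empty_cohort_rejected():
    with pytest.raises(ValueError):
        generate_cohort(dataclasses.replace(GeneratorParams(), n_subjects=0), 1)


# --- cohort fidelity --------------------------------------------------------

def test_large_sample_emulation_fidelity():
    """Empirical moments track the configured truncated distributions."""
    n = 1000
    p = dataclasses.replace(GeneratorParams(), n_subjects=n)
    subjects, xrays = generate_cohort(p, 1)
    ages = np.array([s.age for s in subjects])
    assert 78.0 <= np.median(ages) <= 83.0
    assert ages.min() >= 40.0 and ages.max() <= 95.0
    bmis = np.array([s.bmi for s in subjects])
    assert 20.0 <= bmis.min() and bmis.max() <= 34.0
    # median calibrated to the configured value despite asymmetric truncation
    assert abs(np.median(bmis) - 22.0) < 0.5
    frac_female = np.mean([s.sex == "female" for s in subjects])
    se = np.sqrt((26 / 35) * (9 / 35) / n)
    assert abs(frac_female - 26 / 35) < 3 * se
    # distance dimensions within 2 SE of the configured truncated normals
    for dim, (mean, sd) in p.distance_mean_sd.items():
        vals = np.array([x.distances()[dim] for x in xrays])
        a = (p.distance_floor_mm - mean) / sd
        expected = stats.truncnorm.mean(a, np.inf, loc=mean, scale=sd)
        assert abs(vals.mean() - expected) < 2 * sd / np.sqrt(n)


def test_surgery_mix_matches_weights():
    p = dataclasses.replace(GeneratorParams(), n_subjects=2000)
    subjects, _ = generate_cohort(p, 5)
    frac_imhn = np.mean([s.surgery_type == "IMHN" for s in subjects])
    assert abs(frac_imhn - 14 / 35) < 0.03


# --- skin traces ------------------------------------------------------------

def _noiseless_params(**kw):
    return dataclasses.replace(GeneratorParams(), noise_sd=0.0, **kw)


def test_noiseless_trace_is_exact_double_exponential():
    p = _noiseless_params()
    tr = generate_trace(p, 1, baseline_C=32.1, end_temp_C=18.2)
    t, y = tr.treatment()
    expected = 18.2 + (32.1 - 18.2) * np.exp(-t / 300.0)
    assert np.abs(y - expected).max() < 1e-9
    e, yr = tr.rewarming()
    t_min = y[-1]
    expected_r = 32.1 - (32.1 - t_min) * np.exp(-e * 60.0 / 3000.0)
    assert np.abs(yr - expected_r).max() < 1e-9
    # no reactive hyperthermia: rewarming never exceeds baseline
    assert yr.max() <= 32.1 + 1e-9
    # continuity at the phase junction
    assert abs(yr[0] - t_min) < 0.1


def test_fastest_decline_in_first_five_minutes():
    p = _noiseless_params()
    tr = generate_trace(p, 1, baseline_C=32.1, end_temp_C=18.2)
    t, y = tr.treatment()
    decrements = -np.diff(y)
    assert decrements.argmax() == 0
    assert t[decrements.argmax() + 1] <= 300.0


def test_skin_series_sites_and_baseline_stats():
    p = dataclasses.replace(GeneratorParams(), n_subjects=200)
    subjects, _ = generate_cohort(p, 3)
    baselines, ends = [], []
    for s in subjects:
        tr = generate_skin_series(s, p, 3, sites=("mid_femur",))["mid_femur"]
        t, y = tr.treatment()
        baselines.append(tr.baseline_C)
        ends.append(y[-1])
    baselines, ends = np.array(baselines), np.array(ends)
    # 2 SE of the configured means, plus the small truncation/noise shifts
    assert abs(baselines.mean() - 32.1) < 2 * 2.0 / np.sqrt(200) + 0.15
    assert abs(ends.mean() - 18.2) < 2 * 4.0 / np.sqrt(200) + 0.35


def test_rewarming_recrosses_analgesia_threshold_near_observed_time():
    from cryodepth import threshold_crossing_times

    p = _noiseless_params(rewarm_min_C=11.5)
    tr = generate_trace(p, 1, baseline_C=32.1, end_temp_C=11.5)
    c = threshold_crossing_times(tr, 13.6)
    assert c.reexceed_min == pytest.approx(5.5, rel=0.15)


# --- pain records -----------------------------------------------------------

def test_pain_records_structure():
    p = GeneratorParams()
    subjects, _ = generate_cohort(dataclasses.replace(p, n_subjects=1), 2)
    recs = generate_pain_records(subjects[0], p, 2)
    assert len(recs) == 12
    assert [r.cycle_time_h for r in recs] == [6.0 * k for k in range(1, 13)]
    assert all(0 <= r.nrs_post <= 10 and 0 <= r.nrs_pre <= 10 for r in recs)
    assert [r.pod for r in recs] == [1, 1, 1, 1, 2, 2, 2, 2, 3, 3, 3, 3]
    assert recs[0].pressure == "low" and recs[-1].pressure == "high"


def test_emitted_post_scores_follow_configured_trend():
    """Clamped-integer calibration keeps the observable mean trajectory."""
    p = dataclasses.replace(GeneratorParams(), n_subjects=400)
    subjects, _ = generate_cohort(p, 4)
    posts = {t: [] for t in range(1, 13)}
    for s in subjects:
        for k, r in enumerate(generate_pain_records(s, p, 4), start=1):
            posts[k].append(r.nrs_post)
    for k in (1, 6, 12):
        target = 3.0 - 0.14 * k
        se = 1.9 / np.sqrt(400)
        assert abs(np.mean(posts[k]) - target) < 3 * se


def test_null_improvements_independent_of_temp_drop():
    p = dataclasses.replace(GeneratorParams(), n_subjects=300)
    subjects, _ = generate_cohort(p, 6)
    rng = np.random.default_rng(6)
    drops = rng.normal(10.0, 3.0, len(subjects))
    x, y = [], []
    for s, d in zip(subjects, drops):
        recs = generate_pain_records(s, p, 6, simulated_temp_drop=d)
        x.append(np.mean([r.nrs_pre - r.nrs_post for r in recs]))
        y.append(d)
    res = pearson_association(x, y)
    assert res.ci_low <= 0.0 <= res.ci_high


def test_injected_effect_recovered():
    """OLS slope of improvement on temperature drop recovers injected beta."""
    beta = 0.1
    p = dataclasses.replace(GeneratorParams(), n_subjects=20, beta_temp_drop=beta)
    slopes = []
    for rep in range(100):
        subjects, _ = generate_cohort(p, 100 + rep)
        rng = np.random.default_rng(rep)
        drops = rng.normal(10.0, 3.0, len(subjects))
        x, y = [], []
        for s, d in zip(subjects, drops):
            for r in generate_pain_records(s, p, 100 + rep, simulated_temp_drop=d):
                x.append(d)
                y.append(r.nrs_pre - r.nrs_post)
        slopes.append(stats.linregress(x, y).slope)
    slopes = np.array(slopes)
    se = slopes.std(ddof=1) / np.sqrt(len(slopes))
    assert abs(slopes.mean() - beta) < 2 * se + 1e-3


def test_trend_recovery_at_cohort_scale():
    p = dataclasses.replace(GeneratorParams(), n_subjects=25)
    subjects, _ = generate_cohort(p, 8)
    recs = [r for s in subjects for r in generate_pain_records(s, p, 8)]
    res = nrs_trend(recs)
    # single-replicate check: within ~3 per-replicate SE of the configured decline
    assert res.estimate == pytest.approx(-0.14, abs=3 * (res.ci_high - res.estimate) / 2)
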