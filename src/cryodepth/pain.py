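"""Pain-score analysis: treatment effect, 72-h trend, association.

Treatment effect for one cryotherapy cycle is NRS improvement,
pre-treatment NRS minus post-treatment NRS. The pipeline's statistics
are deliberately simple and fully specified: a Pearson correlation
(Fisher-z confidence interval) between per-cycle improvement and the
model-predicted temperature drop, and an ordinary-least-squares trend
of post-treatment NRS over the first 72 postoperative hours, reported
per 6 h (the treatment cycle spacing). The per-record table is exposed
so covariate-adjusted mixed models can be fitted externally if needed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "TreatmentRecord",
    "AssociationResult",
    "nrs_improvement",
    "pearson_association",
    "nrs_trend",
]

logger = logging.getLogger(__name__)


@dataclass
class TreatmentRecord:
    """One cryotherapy cycle's pain scores and timing."""

    subject_id: str
    pod: int                 # postoperative day, 1-3
    cycle_time_h: float      # hours since surgery
    nrs_pre: int | None
    nrs_post: int | None
    pressure: str = "low"

    def __post_init__(self) -> None:
        for v in (self.nrs_pre, self.nrs_post):
            if v is not None and not 0 <= v <= 10:
                raise ValueError("NRS scores must lie in 0..10")
        if not 0.0 <= self.cycle_time_h <= 72.0:
            raise ValueError("cycle_time_h must lie in [0, 72]")

    @property
    def complete(self) -> bool:
        return self.nrs_pre is not None and self.nrs_post is not None


@dataclass(frozen=True)
class AssociationResult:
    """A point estimate (correlation or slope) with 95% CI and p-value."""

    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    kind: str = ""

    def __post_init__(self) -> None:
        if not self.ci_low <= self.estimate <= self.ci_high:
            raise ValueError("require ci_low <= estimate <= ci_high")

    def to_dict(self) -> dict:
        return {
            "estimate": self.estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "n": self.n,
            "kind": self.kind,
        }


def nrs_improvement(nrs_pre: int, nrs_post: int) -> int:
    """Pre-treatment NRS minus post-treatment NRS (negative = worsening)."""
    for v in (nrs_pre, nrs_post):
        if not 0 <= v <= 10:
            raise ValueError("NRS scores must lie in 0..10")
    return nrs_pre - nrs_post


def pearson_association(x, y, confidence: float = 0.95) -> AssociationResult:
    """Pearson correlation with Fisher-z confidence interval.

    Pairs with a missing element are dropped with a logged count.
    Raises on fewer than 3 complete pairs or zero variance in either
    variable.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    dropped = int((~keep).sum())
    if dropped:
        logger.info("pearson_association: dropped %d incomplete pairs", dropped)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y")

    r, p = stats.pearsonr(x, y)
    r = float(r)
    if n > 3 and abs(r) < 1.0:
        z = math.atanh(r)
        se = 1.0 / math.sqrt(n - 3)
        zcrit = stats.norm.ppf(0.5 + confidence / 2.0)
        lo, hi = math.tanh(z - zcrit * se), math.tanh(z + zcrit * se)
    else:
        lo = hi = r
    return AssociationResult(
        estimate=r, ci_low=lo, ci_high=hi, p_value=float(p), n=n, kind="pearson_r"
    )


def nrs_trend(
    records, confidence: float = 0.95, per_hours: float = 6.0
) -> AssociationResult:
    """OLS trend of post-treatment NRS over time, per `per_hours` hours.

    Fits nrs_post on cycle_time_h across all complete records (records
    missing either score are dropped with a logged count) and rescales
    slope and CI to the treatment-cycle spacing. A perfectly flat
    response is reported as slope 0 with p = 1.
    """
    recs = [r for r in records if r.complete]
    dropped = len(list(records)) - len(recs)
    if dropped:
        logger.info("nrs_trend: dropped %d records with missing scores", dropped)
    if len(recs) < 2:
        raise ValueError("need at least 2 complete records")
    t = np.array([r.cycle_time_h for r in recs], dtype=float)
    y = np.array([r.nrs_post for r in recs], dtype=float)
    if np.ptp(t) == 0:
        raise ValueError("all records share one time point; trend undefined")

    n = t.size
    if np.ptp(y) == 0:
        return AssociationResult(0.0, 0.0, 0.0, 1.0, n, kind="ols_slope_per_6h")

    fit = stats.linregress(t, y)
    slope = fit.slope * per_hours
    se = fit.stderr * per_hours
    tcrit = stats.t.ppf(0.5 + confidence / 2.0, df=n - 2)
    p = fit.pvalue if se > 0 else (0.0 if slope != 0 else 1.0)
    return AssociationResult(
        estimate=float(slope),
        ci_low=float(slope - tcrit * se),
        ci_high=float(slope + tcrit * se),
        p_value=float(p),
        n=n,
        kind="ols_slope_per_6h",
    )
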