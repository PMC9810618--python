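"""Pathological response classification and exact binomial response rates.

Response to neoadjuvant therapy is graded from the percentage of residual
viable tumor cells found in the resected tumor bed:

* CPR  (complete pathological response)  — 0% viable tumor,
* MPR  (major pathological response)     — no more than 10%,
* PPR+                                    — no more than 30%,
* PPR  (partial pathological response)   — no more than 50%,

so the four labels are nested (CPR ⊂ MPR ⊂ PPR+ ⊂ PPR).  The Becker tumor
regression grading (TRG) system is reported alongside: TRG1a (no residual
tumor), TRG1b (<10%), TRG2 (10–50%), TRG3 (≥50%).  Note the deliberate
asymmetry at exactly 10%: such a tumor is MPR ("no more than 10%") but TRG2
(TRG1b is strictly "<10%").

Cohort rates come with exact (Clopper–Pearson) binomial confidence
intervals, the standard choice for small single-arm trials.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .errors import ValidationError

__all__ = [
    "ResponseCall",
    "RateEstimate",
    "classify_response",
    "becker_trg",
    "clopper_pearson_ci",
    "response_rate_table",
]

#: Response endpoints in nesting order with their viable-tumor thresholds (%).
RESPONSE_THRESHOLDS = {"CPR": 0.0, "MPR": 10.0, "PPR+": 30.0, "PPR": 50.0}

TRG_GRADES = ("TRG1a", "TRG1b", "TRG2", "TRG3")


@dataclass(frozen=True)
class ResponseCall:
    """One patient's pathological response labels."""

    patient: str
    viable_pct: float
    regression_pct: float
    is_cpr: bool
    is_mpr: bool
    is_ppr_plus: bool
    is_ppr: bool
    trg: str


@dataclass(frozen=True)
class RateEstimate:
    """A binomial rate k/n (as %) with an exact confidence interval (%)."""

    endpoint: str
    k: int
    n: int
    rate: float
    ci_low: float
    ci_high: float
    conf: float


def _check_viable(viable_pct: float) -> float:
    v = float(viable_pct)
    if not 0.0 <= v <= 100.0:
        raise ValidationError(f"viable_pct must be in [0, 100], got {viable_pct!r}")
    return v


def classify_response(viable_pct: float, patient: str = "") -> ResponseCall:
    """Classify a % residual viable tumor into nested response labels + TRG.

    Thresholds are inclusive ("no more than"): CPR iff 0, MPR iff ≤10,
    PPR+ iff ≤30, PPR iff ≤50.
    """
    v = _check_viable(viable_pct)
    return ResponseCall(
        patient=patient,
        viable_pct=v,
        regression_pct=100.0 - v,
        is_cpr=v == 0.0,
        is_mpr=v <= 10.0,
        is_ppr_plus=v <= 30.0,
        is_ppr=v <= 50.0,
        trg=becker_trg(v),
    )


def becker_trg(viable_pct: float) -> str:
    """Becker tumor regression grade for a % residual viable tumor.

    0 → TRG1a; (0, 10) → TRG1b; [10, 50) → TRG2; [50, 100] → TRG3.
    """
    v = _check_viable(viable_pct)
    if v == 0.0:
        return "TRG1a"
    if v < 10.0:
        return "TRG1b"
    if v < 50.0:
        return "TRG2"
    return "TRG3"


def clopper_pearson_ci(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper–Pearson) binomial CI for k successes out of n, in %.

    The interval comes from beta-distribution quantiles; by construction the
    lower bound is exactly 0 when k = 0 and the upper exactly 100 when k = n.
    """
    if not 0 < conf < 1:
        raise ValidationError(f"conf must be in (0, 1), got {conf!r}")
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n!r}")
    if not 0 <= k <= n:
        raise ValidationError(f"k must satisfy 0 <= k <= n, got k={k!r}, n={n!r}")
    lo, hi = proportion_confint(k, n, alpha=1.0 - conf, method="beta")
    # statsmodels returns NaN rather than the degenerate bound at k=0 / k=n
    lo = 0.0 if k == 0 else float(lo)
    hi = 1.0 if k == n else float(hi)
    return 100.0 * lo, 100.0 * hi


def _rate(endpoint: str, k: int, n: int, conf: float) -> RateEstimate:
    lo, hi = clopper_pearson_ci(k, n, conf)
    return RateEstimate(endpoint, k, n, 100.0 * k / n, lo, hi, conf)


def response_rate_table(
    calls: Sequence[ResponseCall] | Iterable[ResponseCall], conf: float = 0.95
) -> pd.DataFrame:
    """Cohort response-rate table with exact CIs, one row per endpoint.

    Endpoints: CPR, MPR, PPR+, PPR, TRG1a, TRG1b, TRG1a/b, TRG2, TRG3.
    The denominator is the number of calls supplied; excluding unresected
    patients is the caller's responsibility (pass only evaluable patients).
    """
    calls = list(calls)
    if not calls:
        raise ValidationError("response_rate_table requires at least one call")
    n = len(calls)
    counts = {
        "CPR": sum(c.is_cpr for c in calls),
        "MPR": sum(c.is_mpr for c in calls),
        "PPR+": sum(c.is_ppr_plus for c in calls),
        "PPR": sum(c.is_ppr for c in calls),
        "TRG1a": sum(c.trg == "TRG1a" for c in calls),
        "TRG1b": sum(c.trg == "TRG1b" for c in calls),
        "TRG2": sum(c.trg == "TRG2" for c in calls),
        "TRG3": sum(c.trg == "TRG3" for c in calls),
    }
    counts["TRG1a/b"] = counts["TRG1a"] + counts["TRG1b"]
    order = ["CPR", "MPR", "PPR+", "PPR", "TRG1a", "TRG1b", "TRG1a/b", "TRG2", "TRG3"]
    rows = [_rate(e, counts[e], n, conf) for e in order]
    return pd.DataFrame(
        {
            "endpoint": [r.endpoint for r in rows],
            "k": [r.k for r in rows],
            "n": [r.n for r in rows],
            "rate_pct": [r.rate for r in rows],
            "ci_low_pct": [r.ci_low for r in rows],
            "ci_high_pct": [r.ci_high for r in rows],
            "conf": [r.conf for r in rows],
        }
    )
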