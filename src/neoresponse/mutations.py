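"""Purity-corrected VAF dynamics of paired pre/post-treatment somatic calls.

The observed variant allele fraction (VAF) of a somatic mutation scales with
tumor purity, so comparing pre- and post-treatment VAFs directly confounds
tumor kill with sampling: a biopsy after effective therapy contains fewer
tumor cells, deflating every VAF.  All pre/post comparisons here therefore
use a purity-adjusted VAF, adj = min(1, vaf / purity) by default (the
diploid-heterozygous cancer-cell-fraction variant 2·vaf/purity is available
via ``ccf=True``; the sign of any pre/post change is identical under both).

Each mutation, keyed by chrom:pos:ref:alt within a patient, is assigned one
of five fates across the treatment:

* ``gain``     — absent pre, present post,
* ``lost``     — present pre, absent post,
* ``increase`` / ``decrease`` — present in both, adjusted VAF moved,
* ``stable``   — present in both, |Δ adjusted VAF| ≤ tie_tol.

The fraction of pre-treatment mutations that are lost tracks pathological
regression.  The module also carries tumor mutational burden (TMB,
nonsynonymous mutations per megabase) and tumor neoantigen burden (TNB)
accounting, a read-dilution simulation that balances purity between a pair
of samples before comparing burdens, a subclone-consistency check, and a
Fisher-exact biomarker contingency analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, ValidationError

__all__ = [
    "MUTATION_COLUMNS",
    "SampleMeta",
    "BurdenSummary",
    "adjust_vaf",
    "apply_call_filters",
    "classify_fates",
    "lost_fraction",
    "compute_burden",
    "purity_balance_dilution",
    "clonal_consistency",
    "biomarker_contingency",
]

#: Schema of a MAF-like mutation table (one row = one call in one sample).
MUTATION_COLUMNS = [
    "patient", "timepoint", "gene", "chrom", "pos", "ref", "alt",
    "alt_reads", "depth", "vaf", "nonsyn", "neoantigen",
]

KEY_COLUMNS = ["chrom", "pos", "ref", "alt"]

FATES = ("gain", "lost", "increase", "decrease", "stable")


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample metadata needed for purity correction and burden."""

    patient: str
    timepoint: str
    purity: float
    exome_mb: float = 35.0
    msi_score: float = 0.0
    msi_status: str = "MSS"

    def __post_init__(self):
        if not 0.0 < self.purity <= 1.0:
            raise ValidationError(f"purity must be in (0, 1], got {self.purity!r}")
        if self.exome_mb <= 0:
            raise ValidationError(f"exome_mb must be > 0, got {self.exome_mb!r}")


@dataclass(frozen=True)
class BurdenSummary:
    """Mutation (TMB) and neoantigen (TNB) burden per megabase."""

    patient: str
    timepoint: str
    tmb: float
    tnb: float


def adjust_vaf(vaf, purity: float, ccf: bool = False):
    """Purity-adjusted VAF: min(1, vaf/purity), or min(1, 2·vaf/purity).

    Monotone in vaf, identity at purity 1 (default mode), capped at 1.
    Accepts scalars or arrays.
    """
    if purity <= 0 or purity > 1:
        raise ValidationError(f"purity must be in (0, 1], got {purity!r}")
    factor = 2.0 if ccf else 1.0
    out = np.minimum(1.0, factor * np.asarray(vaf, dtype=float) / purity)
    return float(out) if np.isscalar(vaf) else out


def apply_call_filters(
    records: pd.DataFrame,
    min_vaf: float = 0.02,
    min_depth: int = 0,
    min_alt: int = 0,
) -> pd.DataFrame:
    """Drop calls below the VAF/depth/alt-read floors (boundaries inclusive).

    The default floor VAF ≥ 0.02 mirrors the usual removal of sub-2% calls
    as likely artifacts; `records.attrs['n_filtered']` records how many rows
    were removed.
    """
    keep = (
        (records["vaf"] >= min_vaf)
        & (records["depth"] >= min_depth)
        & (records["alt_reads"] >= min_alt)
    )
    out = records.loc[keep].copy()
    out.attrs["n_filtered"] = int(len(records) - len(out))
    return out


def _keyed_vaf(records: pd.DataFrame, label: str) -> pd.Series:
    keys = records[KEY_COLUMNS].astype(str).agg(":".join, axis=1)
    if keys.duplicated().any():
        dup = keys[keys.duplicated()].iloc[0]
        raise DataError(f"duplicate mutation key {dup!r} in {label} table")
    return pd.Series(records["vaf"].to_numpy(), index=keys.to_numpy())


def classify_fates(
    pre_records: pd.DataFrame,
    post_records: pd.DataFrame,
    purity_pre: float,
    purity_post: float,
    tie_tol: float = 0.0,
    ccf: bool = False,
) -> pd.DataFrame:
    """Assign a pre→post fate to every mutation seen in either sample.

    Returns a frame indexed by mutation key with columns adj_vaf_pre,
    adj_vaf_post (NaN where absent) and fate.  The five fates partition the
    union of keys.
    """
    if tie_tol < 0:
        raise ValidationError(f"tie_tol must be >= 0, got {tie_tol!r}")
    vaf_pre = _keyed_vaf(pre_records, "pre") if len(pre_records) else pd.Series(dtype=float)
    vaf_post = _keyed_vaf(post_records, "post") if len(post_records) else pd.Series(dtype=float)
    union = vaf_pre.index.union(vaf_post.index)
    a = pd.Series(np.nan, index=union, dtype=float)
    b = a.copy()
    if len(vaf_pre):
        a[vaf_pre.index] = adjust_vaf(vaf_pre.to_numpy(), purity_pre, ccf=ccf)
    if len(vaf_post):
        b[vaf_post.index] = adjust_vaf(vaf_post.to_numpy(), purity_post, ccf=ccf)
    delta = b - a
    fate = np.where(
        a.isna(), "gain",
        np.where(
            b.isna(), "lost",
            np.where(delta > tie_tol, "increase",
                     np.where(delta < -tie_tol, "decrease", "stable")),
        ),
    )
    return pd.DataFrame(
        {"adj_vaf_pre": a, "adj_vaf_post": b, "fate": fate}, index=union
    ).rename_axis("mutation")


def lost_fraction(fates: pd.DataFrame) -> float:
    """Fraction of pre-treatment mutations eradicated by therapy.

    lost / (lost + increase + decrease + stable), i.e. the denominator is
    everything present pre-treatment.  Raises if no pre-treatment mutation
    exists (the ratio is undefined, never silently 0).
    """
    if fates.empty:
        raise ValidationError("empty fate table")
    counts = fates["fate"].value_counts()
    n_pre = int(counts.reindex(["lost", "increase", "decrease", "stable"], fill_value=0).sum())
    if n_pre == 0:
        raise ValidationError("no pre-treatment mutations: lost fraction undefined")
    return float(counts.get("lost", 0) / n_pre)


def compute_burden(records: pd.DataFrame, meta: SampleMeta) -> BurdenSummary:
    """TMB = nonsynonymous calls / exome Mb; TNB = neoantigen calls / exome Mb.

    Expects an already-filtered single-sample table.
    """
    n_nonsyn = int(records["nonsyn"].astype(bool).sum()) if len(records) else 0
    n_neo = int(records["neoantigen"].astype(bool).sum()) if len(records) else 0
    return BurdenSummary(
        patient=meta.patient,
        timepoint=meta.timepoint,
        tmb=n_nonsyn / meta.exome_mb,
        tnb=n_neo / meta.exome_mb,
    )


def purity_balance_dilution(
    records: pd.DataFrame,
    meta_high: SampleMeta,
    target_purity: float,
    seed: int,
    min_vaf: float = 0.02,
    min_depth: int = 0,
    min_alt: int = 0,
) -> tuple[pd.DataFrame, BurdenSummary]:
    """Simulate diluting a high-purity sample down to ``target_purity``.

    Emulates blending tumor reads with matched-normal reads: with mixing
    fraction m = 1 − target_purity/purity, each call's alt-read count is
    redrawn Binomial(depth, vaf·(1−m)) — depth is preserved, the expected
    VAF shrinks by (1−m).  Call filters are then re-applied and the burden
    recomputed, so calls diluted below the VAF floor drop out exactly as
    they would in a re-called, lower-purity sample.  m = 0 is an exact
    identity (no resampling).  Deterministic given ``seed``.
    """
    if target_purity <= 0:
        raise ValidationError(f"target_purity must be > 0, got {target_purity!r}")
    if target_purity > meta_high.purity:
        raise ValidationError(
            f"target_purity {target_purity} exceeds sample purity "
            f"{meta_high.purity}: dilution only"
        )
    if len(records) and (records["depth"] <= 0).any():
        raise ValidationError("all calls must have depth > 0 for dilution")
    m = 1.0 - target_purity / meta_high.purity
    if m == 0.0:
        diluted = records.copy()
    else:
        rng = np.random.default_rng(seed)
        diluted = records.copy()
        depth = diluted["depth"].to_numpy(dtype=np.int64)
        p = np.clip(diluted["vaf"].to_numpy(dtype=float) * (1.0 - m), 0.0, 1.0)
        alt = rng.binomial(depth, p)
        diluted["alt_reads"] = alt
        diluted["vaf"] = alt / depth
    filtered = apply_call_filters(diluted, min_vaf=min_vaf, min_depth=min_depth,
                                  min_alt=min_alt)
    filtered = filtered.loc[filtered["alt_reads"] > 0]
    burden = compute_burden(filtered, meta_high)
    return filtered, burden


def clonal_consistency(
    adj_vaf_pre: float,
    adj_vaf_post: float,
    prevalence_pre: float,
    prevalence_post: float,
    tol: float = 0.0,
) -> bool:
    """True iff the mutation's adjusted-VAF change agrees in sign with its
    subclone's cellular-prevalence change.

    Changes with magnitude ≤ tol count as zero; zero-vs-zero is consistent
    (a lost mutation in an eradicated subclone agrees).  Absence is coded as
    VAF/prevalence 0 by the caller.
    """
    if tol < 0:
        raise ValidationError(f"tol must be >= 0, got {tol!r}")

    def sign(x: float) -> int:
        return 0 if abs(x) <= tol else (1 if x > 0 else -1)

    return sign(adj_vaf_post - adj_vaf_pre) == sign(prevalence_post - prevalence_pre)


def biomarker_contingency(
    mutated: Sequence[bool], responder: Sequence[bool]
) -> dict:
    """2×2 association between a mutation flag and a response flag.

    Rows are response groups (responder first), columns mutated/not.
    Returns the table, the odds ratio (``inf`` when a margin cell is 0 and
    the association is positive) and the two-sided Fisher exact p.  The
    p-value is unadjusted for multiple testing; screens over many genes
    should treat it as exploratory.
    """
    mutated = np.asarray(mutated, dtype=bool)
    responder = np.asarray(responder, dtype=bool)
    if mutated.shape != responder.shape:
        raise DataError(
            f"flag lists differ in length: {mutated.shape[0]} vs {responder.shape[0]}"
        )
    table = np.array(
        [
            [int((mutated & responder).sum()), int((~mutated & responder).sum())],
            [int((mutated & ~responder).sum()), int((~mutated & ~responder).sum())],
        ]
    )
    odds_ratio, p = stats.fisher_exact(table, alternative="two-sided")
    return {
        "table": table,
        "odds_ratio": float(odds_ratio),
        "p_value": float(p),
        "p_adjusted": False,
    }
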