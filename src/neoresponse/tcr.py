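"""TCR repertoire statistics: clone expansion, size classes, diversity, V/J usage.

A repertoire is a clonotype table — one row per unique rearrangement, keyed
by (CDR3 amino-acid sequence, V segment, J segment) — with read counts and
normalized frequencies.  The central statistic is the clone-expansion (CE)
score: the summed pre→post frequency change of a patient's top-20 clonotypes.
A positive CE means the dominant peripheral clones expanded under therapy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, ValidationError

__all__ = [
    "COLUMNS",
    "RepertoirePair",
    "load_clonotypes",
    "normalize_clonotypes",
    "ce_score",
    "size_class_partition",
    "diversity_metrics",
    "vj_usage",
    "pairwise_overlap",
]

#: VDJtools-style column order used by all clonotype tables in this package.
COLUMNS = ["cdr3aa", "v_segment", "j_segment", "count", "frequency"]

KEY = ["cdr3aa", "v_segment", "j_segment"]

#: Clonotype size classes by frequency: label -> (low, high], half-open.
SIZE_CLASSES = {
    "small": (0.0, 1e-4),
    "medium": (1e-4, 1e-3),
    "large": (1e-3, 1e-2),
    "hyperexpanded": (1e-2, 1.0),
}


@dataclass
class RepertoirePair:
    """Pre- and post-treatment clonotype tables for one patient."""

    patient: str
    pre: pd.DataFrame
    post: pd.DataFrame


def _check_table(table: pd.DataFrame, normalized: bool = True) -> pd.DataFrame:
    missing = [c for c in COLUMNS if c not in table.columns]
    if missing:
        raise DataError(f"clonotype table missing columns: {missing}")
    if table.empty:
        raise ValidationError("clonotype table is empty")
    if normalized and abs(table["frequency"].sum() - 1.0) > 1e-9:
        raise ValidationError(
            "clonotype table is not normalized (frequencies sum to "
            f"{table['frequency'].sum():.6g}); call normalize_clonotypes first"
        )
    return table


def normalize_clonotypes(table: pd.DataFrame) -> pd.DataFrame:
    """Recompute frequencies as count/total and sort deterministically.

    Rows with count 0 are dropped; order is descending frequency with a
    lexicographic (cdr3aa, v, j) tie-break.  Idempotent.
    """
    missing = [c for c in COLUMNS[:4] if c not in table.columns]
    if missing:
        raise DataError(f"clonotype table missing columns: {missing}")
    if (table["count"] < 0).any():
        bad = table.index[table["count"] < 0][0]
        raise DataError(f"negative count at row {bad}")
    dup = table.duplicated(subset=KEY)
    if dup.any():
        raise DataError(f"duplicate clonotype key at row {table.index[dup][0]}")
    out = table.loc[table["count"] > 0, COLUMNS[:4]].copy()
    total = out["count"].sum()
    if total <= 0:
        raise ValidationError("all clonotype counts are zero")
    out["frequency"] = out["count"] / total
    out = out.sort_values(
        ["frequency", "cdr3aa", "v_segment", "j_segment"],
        ascending=[False, True, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return out[COLUMNS]


def load_clonotypes(path) -> pd.DataFrame:
    """Read a VDJtools-style clonotype TSV and normalize it."""
    table = pd.read_csv(path, sep="\t")
    return normalize_clonotypes(table)


def _keyed_freq(table: pd.DataFrame) -> pd.Series:
    return table.set_index(KEY)["frequency"]


def ce_score(pair: RepertoirePair, k: int = 20, mode: str = "pooled") -> float:
    """Clone-expansion score: summed pre→post frequency change of top-k clones.

    mode="pooled" (default): the top-k set is the k clonotypes with the
    largest mean of pre and post frequency (absent = 0); the score is
    Σ (freq_post − freq_pre) over that one shared set.  This makes the score
    antisymmetric (swapping pre/post negates it) and bounded in [−1, 1].

    mode="per-sample": (sum of post's own top-k frequencies) − (sum of pre's
    own top-k frequencies), the literal reading of "frequency of top 20
    clones post − that pre".
    """
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k!r}")
    pre = _check_table(pair.pre)
    post = _check_table(pair.post)
    if mode == "per-sample":
        return float(post["frequency"].head(k).sum() - pre["frequency"].head(k).sum())
    if mode != "pooled":
        raise ValidationError(f"unknown mode {mode!r}; use 'pooled' or 'per-sample'")
    f_pre = _keyed_freq(pre)
    f_post = _keyed_freq(post)
    union = f_pre.index.union(f_post.index)
    a = f_pre.reindex(union, fill_value=0.0)
    b = f_post.reindex(union, fill_value=0.0)
    pooled = (a + b) / 2.0
    ranked = pooled.sort_index().sort_values(ascending=False, kind="mergesort")
    top = ranked.index[:k]
    return float((b[top] - a[top]).sum())


def size_class_partition(table: pd.DataFrame) -> pd.DataFrame:
    """Partition clonotypes into four frequency classes and sum their mass.

    Classes (half-open, (low, high]): small ≤ 1e-4 < medium ≤ 1e-3 <
    large ≤ 1e-2 < hyperexpanded ≤ 1.  Returns one row per class with
    clonotype count and summed frequency mass; masses sum to 1.
    """
    table = _check_table(table)
    f = table["frequency"].to_numpy()
    rows = []
    for label, (lo, hi) in SIZE_CLASSES.items():
        mask = (f > lo) & (f <= hi)
        rows.append({"size_class": label, "n_clonotypes": int(mask.sum()),
                     "mass": float(f[mask].sum())})
    return pd.DataFrame(rows)


def diversity_metrics(table: pd.DataFrame) -> dict:
    """Richness, Shannon entropy (nats), Pielou evenness and D50.

    D50 is the smallest number of top clonotypes whose cumulative frequency
    reaches 0.5; it is reported both as a count and as % of richness.
    Evenness is H/ln(richness), defined as 0 for a single-clone repertoire.
    """
    table = _check_table(table)
    f = np.sort(table["frequency"].to_numpy())[::-1]
    richness = int(len(f))
    h = float(-(f * np.log(f)).sum())
    evenness = float(h / np.log(richness)) if richness > 1 else 0.0
    d50 = int(np.searchsorted(np.cumsum(f), 0.5 - 1e-12) + 1)
    return {
        "richness": richness,
        "shannon": h,
        "evenness": evenness,
        "d50": d50,
        "d50_pct_of_richness": 100.0 * d50 / richness,
    }


def vj_usage(table: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Summed clonotype frequency per V segment and per J segment."""
    table = _check_table(table)
    v = table.groupby("v_segment")["frequency"].sum().sort_index()
    j = table.groupby("j_segment")["frequency"].sum().sort_index()
    return v, j


def pairwise_overlap(tables: dict[str, pd.DataFrame] | list[pd.DataFrame]) -> pd.DataFrame:
    """Symmetric matrix of shared-clonotype counts; diagonal = richness."""
    if isinstance(tables, dict):
        names, tabs = list(tables.keys()), list(tables.values())
    else:
        names, tabs = [str(i) for i in range(len(tables))], list(tables)
    if len(tabs) < 2:
        raise ValidationError("pairwise_overlap needs at least two tables")
    keysets = [set(map(tuple, t[KEY].itertuples(index=False))) for t in tabs]
    n = len(keysets)
    mat = np.zeros((n, n), dtype=int)
    for i in range(n):
        mat[i, i] = len(keysets[i])
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = len(keysets[i] & keysets[j])
    return pd.DataFrame(mat, index=names, columns=names)
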