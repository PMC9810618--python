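"""Immune gene-set signature scoring on a TPM matrix, with group contrasts.

A signature score for a sample is the unweighted mean of log2(TPM+1) over
the genes of a set — a deliberately simple, transparent stand-in for
weighted published scores (a ``weights`` hook is provided for users who
have them).  Default sets below are curated short lists of canonical
markers (cytolytic effectors, interferon-gamma response, T-cell exhaustion,
CD8 effector), editable via YAML; they are defaults, not an authoritative
panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .errors import ValidationError

__all__ = [
    "GeneSet",
    "DEFAULT_GENE_SETS",
    "load_gene_sets",
    "score_gene_set",
    "score_all",
    "compare_groups",
]

#: Curated default immune signatures (gene symbols).
DEFAULT_GENE_SETS = {
    "cytolytic": ["GZMA", "GZMB", "GZMH", "GZMK", "PRF1", "NKG7", "GNLY"],
    "ifn_gamma": ["IFNG", "STAT1", "IDO1", "CXCL9", "CXCL10", "CXCL11", "HLA-DRA"],
    "t_cell_exhaustion": ["PDCD1", "CTLA4", "LAG3", "HAVCR2", "TIGIT", "BTLA"],
    "cd8_effector": ["CD8A", "CD8B", "EOMES", "TBX21", "IL2RB", "KLRD1"],
}


@dataclass(frozen=True)
class GeneSet:
    """A named list of gene symbols, optionally weighted."""

    name: str
    genes: tuple
    weights: tuple | None = field(default=None)

    def __post_init__(self):
        if not self.genes:
            raise ValidationError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError(f"gene set {self.name!r} has duplicate symbols")
        if self.weights is not None and len(self.weights) != len(self.genes):
            raise ValidationError(
                f"gene set {self.name!r}: {len(self.weights)} weights for "
                f"{len(self.genes)} genes"
            )


def default_gene_sets() -> list[GeneSet]:
    return [GeneSet(n, tuple(g)) for n, g in DEFAULT_GENE_SETS.items()]


def load_gene_sets(path) -> list[GeneSet]:
    """Load gene sets from a YAML mapping of name -> list of symbols."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValidationError("gene-set file must be a mapping name -> [genes]")
    return [GeneSet(name, tuple(genes)) for name, genes in raw.items()]


def score_gene_set(expr: pd.DataFrame, gene_set: GeneSet) -> pd.Series:
    """Per-sample signature score: mean log2(TPM+1) over the set's genes.

    ``expr`` is gene × sample, TPM scale, non-negative.  Genes absent from
    the matrix are skipped and listed in ``result.attrs['missing_genes']``;
    if none of the set's genes are present the score is undefined and a
    ValidationError names the set.
    """
    present = [g for g in gene_set.genes if g in expr.index]
    missing = [g for g in gene_set.genes if g not in expr.index]
    if not present:
        raise ValidationError(
            f"no gene of set {gene_set.name!r} is present in the expression matrix"
        )
    sub = expr.loc[present]
    if (sub.to_numpy() < 0).any():
        raise ValidationError("expression matrix contains negative TPM values")
    logged = np.log2(sub + 1.0)
    if gene_set.weights is not None:
        w = np.array([w for g, w in zip(gene_set.genes, gene_set.weights) if g in expr.index])
        scores = logged.mul(w, axis=0).sum(axis=0) / w.sum()
    else:
        scores = logged.mean(axis=0)
    scores.name = gene_set.name
    scores.attrs["missing_genes"] = missing
    return scores


def score_all(expr: pd.DataFrame, gene_sets: list[GeneSet]) -> pd.DataFrame:
    """Score every set; returns a signature × sample frame."""
    return pd.DataFrame({s.name: score_gene_set(expr, s) for s in gene_sets}).T


def compare_groups(
    scores: pd.Series,
    groups: pd.Series,
    paired: bool = False,
) -> dict:
    """Two-group contrast of signature scores by Wilcoxon rank tests.

    Unpaired: two-sided Wilcoxon rank-sum (Mann–Whitney) between the two
    group labels.  Paired: two-sided Wilcoxon signed-rank over samples
    aligned by index across the two labels (exact null distribution when
    feasible).  Reports the median difference (second group − first, label
    sort order) and an unadjusted p-value — no multiplicity correction is
    applied, and the output says so.
    """
    groups = groups.reindex(scores.index)
    labels = sorted(groups.dropna().unique())
    if len(labels) != 2:
        raise ValidationError(f"need exactly 2 group labels, got {labels!r}")
    a = scores[groups == labels[0]]
    b = scores[groups == labels[1]]
    if paired:
        if len(a) != len(b) or len(a) < 2:
            raise ValidationError(
                f"paired comparison needs >= 2 aligned pairs, got {len(a)} vs {len(b)}"
            )
        diff = b.to_numpy() - a.to_numpy()
        if np.all(diff == 0):
            p = 1.0
        else:
            _, p = stats.wilcoxon(diff, alternative="two-sided")
        med_diff = float(np.median(diff))
    else:
        if len(a) < 2 or len(b) < 2:
            raise ValidationError(
                f"each group needs >= 2 samples, got {len(a)} and {len(b)}"
            )
        if a.nunique() == 1 and b.nunique() == 1 and a.iloc[0] == b.iloc[0]:
            p = 1.0
        else:
            _, p = stats.mannwhitneyu(b.to_numpy(), a.to_numpy(),
                                      alternative="two-sided")
        med_diff = float(np.median(b.to_numpy()) - np.median(a.to_numpy()))
    return {
        "group_low": labels[0],
        "group_high": labels[1],
        "n_low": int(len(a)),
        "n_high": int(len(b)),
        "median_difference": med_diff,
        "p_value": float(p),
        "paired": bool(paired),
        "p_adjusted": False,
    }
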