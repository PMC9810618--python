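"""Cohort-directory pipeline: pathology → mutations → TCR → signatures → report.

Runs every analysis stage on the tables of a cohort directory (the layout
``simulate`` writes) and emits the per-stage TSVs plus a deterministic
``report.md``.  All p-values in the report are two-sided and unadjusted for
multiple comparisons; the report carries an explicit caveat line.
"""

from __future__ import annotations

import hashlib
import itertools
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import mutations as mut
from . import pathology as path_mod
from . import signatures as sig
from . import tcr
from .errors import ManifestError, ValidationError

__all__ = ["run_pipeline", "correlate_with_regression"]

STAGES = ("pathology", "mutations", "tcr", "signatures")


def correlate_with_regression(values, regression, exact: bool | None = None
                              ) -> tuple[float, float]:
    """Spearman rank correlation (rho, two-sided p) against % regression.

    Mid-ranks for ties.  For n ≤ 8 the two-sided p is exact, computed by
    enumerating all n! rank permutations (``exact=None`` auto-selects;
    pass True/False to force); larger n uses the usual t approximation.
    A constant input vector makes rho undefined and raises rather than
    returning NaN silently.
    """
    values = np.asarray(values, dtype=float)
    regression = np.asarray(regression, dtype=float)
    if values.shape != regression.shape:
        raise ValidationError("value and regression vectors differ in length")
    n = len(values)
    if n < 3:
        raise ValidationError(f"need >= 3 pairs, got {n}")
    if np.all(values == values[0]) or np.all(regression == regression[0]):
        raise ValidationError("constant input vector: Spearman rho undefined")
    rho, p = stats.spearmanr(values, regression)
    rho = float(rho)
    if exact is None:
        exact = n <= 8
    if exact:
        if n > 9:
            raise ValidationError(f"exact permutation p only supported for n <= 9, got {n}")
        rx = stats.rankdata(values) - (n + 1) / 2.0
        ry = stats.rankdata(regression) - (n + 1) / 2.0
        perms = np.array(list(itertools.permutations(range(n))))
        rhos = (rx[perms] @ ry) / np.sqrt((rx**2).sum() * (ry**2).sum())
        p = float(np.mean(np.abs(rhos) >= abs(rhos[0]) - 1e-12))
    return rho, float(p)


def _check_manifest(indir: Path, skip: set[str]) -> None:
    required = ["patients.tsv"]
    if "mutations" not in skip:
        required += ["mutations_pre.tsv", "mutations_post.tsv"]
    if "signatures" not in skip:
        required += ["expression_tpm.tsv"]
    missing = [name for name in required if not (indir / name).exists()]
    if missing:
        raise ManifestError(missing)


def _stage_pathology(patients: pd.DataFrame, outdir: Path, conf: float):
    calls = [path_mod.classify_response(row.viable_pct, row.patient)
             for row in patients.itertuples()]
    table = path_mod.response_rate_table(calls, conf=conf)
    table.to_csv(outdir / "response_rates.tsv", sep="\t", index=False)
    return calls, table


def _stage_mutations(indir: Path, patients: pd.DataFrame, outdir: Path):
    pre_all = pd.read_csv(indir / "mutations_pre.tsv", sep="\t")
    post_all = pd.read_csv(indir / "mutations_post.tsv", sep="\t")
    fate_frames, burden_rows, lost_rows = [], [], []
    for row in patients.itertuples():
        pre = mut.apply_call_filters(pre_all[pre_all["patient"] == row.patient])
        post = mut.apply_call_filters(post_all[post_all["patient"] == row.patient])
        fates = mut.classify_fates(pre, post, row.purity_pre, row.purity_post)
        fates = fates.assign(patient=row.patient)
        fate_frames.append(fates.reset_index())
        try:
            lf = mut.lost_fraction(fates)
        except ValidationError:
            lf = np.nan
        lost_rows.append({"patient": row.patient, "lost_fraction": lf,
                          "regression_pct": row.regression_pct})
        for tp, table in (("pre", pre), ("post", post)):
            meta = mut.SampleMeta(row.patient, tp,
                                  purity=getattr(row, f"purity_{tp}"),
                                  exome_mb=row.exome_mb)
            b = mut.compute_burden(table, meta)
            burden_rows.append({"patient": b.patient, "timepoint": b.timepoint,
                                "tmb": b.tmb, "tnb": b.tnb})
    pd.concat(fate_frames, ignore_index=True).to_csv(
        outdir / "fates.tsv", sep="\t", index=False)
    pd.DataFrame(burden_rows).to_csv(outdir / "burden.tsv", sep="\t", index=False)
    lost = pd.DataFrame(lost_rows)
    lost.to_csv(outdir / "lost_fractions.tsv", sep="\t", index=False)
    ok = lost.dropna()
    corr = None
    if len(ok) >= 3 and ok["lost_fraction"].nunique() > 1:
        corr = correlate_with_regression(ok["lost_fraction"], ok["regression_pct"])
    return lost, corr


def _stage_tcr(indir: Path, patients: pd.DataFrame, outdir: Path,
               k: int = 20, mode: str = "pooled"):
    ce_rows, metric_rows, tables = [], [], {}
    for row in patients.itertuples():
        paths = {tp: indir / f"clonotypes_{row.patient}_{tp}.tsv"
                 for tp in ("pre", "post")}
        if not all(p.exists() for p in paths.values()):
            continue
        pair = tcr.RepertoirePair(row.patient,
                                  tcr.load_clonotypes(paths["pre"]),
                                  tcr.load_clonotypes(paths["post"]))
        tables[f"{row.patient}_pre"] = pair.pre
        tables[f"{row.patient}_post"] = pair.post
        ce_rows.append({"patient": row.patient,
                        "ce_score": tcr.ce_score(pair, k=k, mode=mode),
                        "regression_pct": row.regression_pct})
        for tp, table in (("pre", pair.pre), ("post", pair.post)):
            m = tcr.diversity_metrics(table)
            classes = tcr.size_class_partition(table)
            m.update({f"mass_{r.size_class}": r.mass for r in classes.itertuples()})
            metric_rows.append({"patient": row.patient, "timepoint": tp, **m})
    if not ce_rows:
        return None, None
    ce = pd.DataFrame(ce_rows)
    ce.to_csv(outdir / "ce_scores.tsv", sep="\t", index=False)
    pd.DataFrame(metric_rows).to_csv(outdir / "tcr_metrics.tsv", sep="\t", index=False)
    tcr.pairwise_overlap(tables).to_csv(outdir / "overlap_matrix.tsv", sep="\t")
    corr = None
    if len(ce) >= 3 and ce["ce_score"].nunique() > 1:
        corr = correlate_with_regression(ce["ce_score"], ce["regression_pct"])
    return ce, corr


def _stage_signatures(indir: Path, patients: pd.DataFrame, calls, outdir: Path):
    expr = pd.read_csv(indir / "expression_tpm.tsv", sep="\t", index_col=0)
    scores = sig.score_all(expr, sig.default_gene_sets())
    scores.to_csv(outdir / "signature_scores.tsv", sep="\t")
    ppr_plus = {c.patient: c.is_ppr_plus for c in calls}
    meta = pd.DataFrame({"sample": scores.columns})
    meta["patient"] = meta["sample"].str.rsplit("_", n=1).str[0]
    meta["timepoint"] = meta["sample"].str.rsplit("_", n=1).str[1]
    meta["group"] = meta["patient"].map(ppr_plus).map({True: "PPR+", False: "non-PPR+"})
    rows = []
    base = meta[meta["timepoint"] == "pre"].set_index("sample")
    for name in scores.index:
        s = scores.loc[name, base.index]
        if base["group"].nunique() == 2 and base["group"].value_counts().min() >= 2:
            res = sig.compare_groups(s, base["group"])
            rows.append({"signature": name, "contrast": "baseline PPR+ vs non-PPR+",
                         **{k: v for k, v in res.items() if k != "paired"}})
        pre_ids = meta.loc[meta["timepoint"] == "pre", "sample"]
        post_ids = meta.loc[meta["timepoint"] == "post", "sample"]
        if len(pre_ids) == len(post_ids) and len(pre_ids) >= 2:
            paired = pd.concat([scores.loc[name, pre_ids], scores.loc[name, post_ids]])
            labels = pd.Series(["a_pre"] * len(pre_ids) + ["b_post"] * len(post_ids),
                               index=paired.index)
            res = sig.compare_groups(paired, labels, paired=True)
            rows.append({"signature": name, "contrast": "post vs pre (paired)",
                         **{k: v for k, v in res.items() if k != "paired"}})
    contrasts = pd.DataFrame(rows)
    contrasts.to_csv(outdir / "signature_contrasts.tsv", sep="\t", index=False)
    return contrasts


def _config_hash(indir: Path, seed: int) -> str:
    h = hashlib.sha256()
    cfg = indir / "config.yaml"
    if cfg.exists():
        h.update(cfg.read_bytes())
    h.update(str(seed).encode())
    return h.hexdigest()[:16]


def run_pipeline(indir, outdir, conf: float = 0.95, seed: int = 0,
                 skip: tuple = ()) -> Path:
    """Run all stages on a cohort directory; returns the report path.

    ``skip`` names stages to omit ("tcr", "signatures", "mutations"); the
    report then simply lacks those sections.  Deterministic: same inputs,
    config and seed give byte-identical report text.
    """
    indir, outdir = Path(indir), Path(outdir)
    skip = set(skip)
    unknown = skip - set(STAGES)
    if unknown:
        raise ValidationError(f"unknown stage(s) to skip: {sorted(unknown)}")
    _check_manifest(indir, skip)
    outdir.mkdir(parents=True, exist_ok=True)
    patients = pd.read_csv(indir / "patients.tsv", sep="\t")

    lines = ["# Neoadjuvant cohort report", "",
             f"- patients: {len(patients)}",
             f"- config hash: `{_config_hash(indir, seed)}`",
             f"- seed: {seed}",
             "- all p-values are two-sided and UNADJUSTED for multiple comparisons",
             ""]

    calls, rate_table = _stage_pathology(patients, outdir, conf)
    lines += ["## Pathological response", "", "```",
              rate_table.round(4).to_string(index=False), "```", ""]

    if "mutations" not in skip:
        lost, corr = _stage_mutations(indir, patients, outdir)
        lines += ["## Mutation dynamics", "",
                  f"- patients with defined lost fraction: {int(lost['lost_fraction'].notna().sum())}"]
        if corr:
            lines += [f"- Spearman rho(lost fraction, regression) = {corr[0]:.4f} "
                      f"(p = {corr[1]:.3g})"]
        else:
            lines += ["- WARNING: lost-fraction correlation undefined on this cohort"]
        lines += [""]

    if "tcr" not in skip:
        ce, corr = _stage_tcr(indir, patients, outdir)
        if ce is not None:
            lines += ["## TCR repertoire", "",
                      f"- patients with paired repertoires: {len(ce)}",
                      f"- positive CE scores: {int((ce['ce_score'] > 0).sum())}/{len(ce)}"]
            if corr:
                lines += [f"- Spearman rho(CE score, regression) = {corr[0]:.4f} "
                          f"(p = {corr[1]:.3g})"]
            else:
                lines += ["- WARNING: CE-score correlation undefined on this cohort"]
            lines += [""]

    if "signatures" not in skip:
        contrasts = _stage_signatures(indir, patients, calls, outdir)
        lines += ["## Immune signatures", "", "```",
                  contrasts.round(4).to_string(index=False), "```", ""]

    report = outdir / "report.md"
    report.write_text("\n".join(lines))
    return report
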