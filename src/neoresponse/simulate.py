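"""Synthetic neoadjuvant-therapy cohort generator.

Produces a fully synthetic multi-omics cohort with the statistical structure
the downstream analysis assumes, so the whole pipeline runs and is testable
without any controlled-access patient data:

* per-patient pathology — % pathological regression drawn from a Beta
  distribution whose parameters differ between responders and
  non-responders;
* paired pre/post somatic mutation tables — each tumor is a mixture of
  subclones with cellular prevalences; a mutation's true VAF under a
  copy-neutral heterozygous diploid model is prevalence × purity / 2, and
  alt-read counts are drawn binomially at Poisson depths.  Therapy
  eradicates each subclone with a responder-dependent probability, which is
  what makes "lost" mutations track regression;
* paired TCR repertoires — Zipf-distributed clonotype counts; after
  therapy the top clones are multiplied by a responder-dependent expansion
  factor and the table renormalized;
* a TPM expression matrix — log-normal baseline with an additive
  log2-scale shift on immune-signature genes in responder post-treatment
  samples;
* a truth table (responder flag, true regression, true lost fraction, true
  clone-expansion direction) for parameter-recovery checks.

Determinism: one integer seed in the config; each patient gets an
independent substream derived by stable hashing (CRC-32) of the patient id,
so any subset of the cohort reproduces identically.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, ValidationError
from .signatures import DEFAULT_GENE_SETS
from .tcr import COLUMNS as TCR_COLUMNS, normalize_clonotypes

__all__ = [
    "CohortConfig",
    "SubcloneCluster",
    "CohortData",
    "generate_cohort",
    "generate_mutation_pair",
    "generate_repertoire_pair",
    "generate_expression",
    "write_cohort",
    "load_config",
]

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
BASES = np.array(list("ACGT"))

V_SEGMENTS = [
    "TRBV2", "TRBV4-1", "TRBV5-1", "TRBV6-5", "TRBV7-2", "TRBV7-9",
    "TRBV9", "TRBV11-2", "TRBV12-3", "TRBV15", "TRBV19", "TRBV20-1",
    "TRBV27", "TRBV28", "TRBV30",
]
J_SEGMENTS = [
    "TRBJ1-1", "TRBJ1-2", "TRBJ1-4", "TRBJ1-5", "TRBJ2-1", "TRBJ2-2",
    "TRBJ2-3", "TRBJ2-5", "TRBJ2-7",
]


@dataclass(frozen=True)
class CohortConfig:
    """All generator parameters; identical config + seed → identical tables."""

    n_patients: int = 19
    frac_responders: float = 0.4
    regression_responder: tuple = (8.0, 2.0)     # Beta(a, b) on regression/100
    regression_nonresponder: tuple = (2.0, 5.0)
    n_subclones: int = 4
    muts_per_clone: int = 25
    depth_mean: float = 200.0
    purity_range_pre: tuple = (0.4, 0.8)
    purity_range_post: tuple = (0.2, 0.6)
    exome_mb: float = 35.0
    lost_subclone_prob_responder: float = 0.6
    lost_subclone_prob_nonresponder: float = 0.15
    repertoire_size: int = 3000
    zipf_exponent: float = 1.0
    expansion_factor_responder: float = 2.0
    expansion_factor_nonresponder: float = 0.9
    n_genes: int = 2000
    signature_shift: float = 1.0
    seed: int = 0

    def __post_init__(self):
        def check(name, cond, msg):
            if not cond:
                raise ConfigError(name, msg)

        check("n_patients", self.n_patients >= 1, "must be >= 1")
        check("frac_responders", 0.0 <= self.frac_responders <= 1.0, "must be in [0, 1]")
        for name in ("regression_responder", "regression_nonresponder"):
            a, b = getattr(self, name)
            check(name, a > 0 and b > 0, "Beta parameters must be positive")
        check("n_subclones", self.n_subclones >= 1, "must be >= 1")
        check("muts_per_clone", self.muts_per_clone >= 1, "must be >= 1")
        check("depth_mean", self.depth_mean >= 1, "must be >= 1")
        for name in ("purity_range_pre", "purity_range_post"):
            lo, hi = getattr(self, name)
            check(name, 0.0 < lo <= hi <= 1.0, "must be an interval in (0, 1]")
        check("exome_mb", self.exome_mb > 0, "must be > 0")
        for name in ("lost_subclone_prob_responder", "lost_subclone_prob_nonresponder"):
            check(name, 0.0 <= getattr(self, name) <= 1.0, "must be in [0, 1]")
        check("repertoire_size", self.repertoire_size >= 21,
              "must be >= 21 (clone-expansion score needs a top-20)")
        check("zipf_exponent", self.zipf_exponent > 0, "must be > 0")
        for name in ("expansion_factor_responder", "expansion_factor_nonresponder"):
            check(name, getattr(self, name) > 0, "must be > 0")
        check("n_genes", self.n_genes >= 1, "must be >= 1")
        check("seed", int(self.seed) == self.seed and 0 <= self.seed < 2**31,
              "must be an integer in [0, 2^31)")


@dataclass(frozen=True)
class SubcloneCluster:
    """A mutational cluster with pre/post cellular prevalence."""

    cluster_id: str
    prevalence_pre: float
    prevalence_post: float
    member_mutations: tuple = ()

    def __post_init__(self):
        for name in ("prevalence_pre", "prevalence_post"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v!r}")


@dataclass
class CohortData:
    """Everything generate_cohort produces, in memory."""

    config: CohortConfig
    patients: pd.DataFrame
    mutations_pre: pd.DataFrame
    mutations_post: pd.DataFrame
    clonotypes: dict          # (patient, timepoint) -> clonotype DataFrame
    expression: pd.DataFrame  # gene x sample TPM
    truth: pd.DataFrame
    clusters: dict            # patient -> list[SubcloneCluster]


def _patient_rng(seed: int, patient: str, stream: str) -> np.random.Generator:
    """Independent, reproducible substream for one patient and one stage."""
    entropy = [int(seed), zlib.crc32(patient.encode()), zlib.crc32(stream.encode())]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# mutation tables


def _mutation_catalog(rng: np.random.Generator, patient: str,
                      clusters: list[SubcloneCluster], muts_per_clone: int) -> pd.DataFrame:
    """Invent the patient's somatic mutations and assign each to one cluster."""
    n = len(clusters) * muts_per_clone
    chrom = rng.integers(1, 23, size=n).astype(str)
    pos = rng.integers(1, 10**8, size=n)
    ref = BASES[rng.integers(0, 4, size=n)]
    shift = rng.integers(1, 4, size=n)
    alt = BASES[(np.searchsorted(BASES, ref) + shift) % 4]
    gene = np.array([f"G{g:04d}" for g in rng.integers(1, 600, size=n)])
    nonsyn = rng.random(n) < 0.75
    neo = nonsyn & (rng.random(n) < 0.15)
    cat = pd.DataFrame({
        "patient": patient, "gene": gene, "chrom": chrom, "pos": pos,
        "ref": ref, "alt": alt, "nonsyn": nonsyn.astype(int),
        "neoantigen": neo.astype(int),
        "cluster": np.repeat([c.cluster_id for c in clusters], muts_per_clone),
        "prevalence_pre": np.repeat([c.prevalence_pre for c in clusters], muts_per_clone),
        "prevalence_post": np.repeat([c.prevalence_post for c in clusters], muts_per_clone),
    })
    # locus keys must be unique within the patient
    cat = cat.drop_duplicates(subset=["chrom", "pos", "ref", "alt"]).reset_index(drop=True)
    return cat


def _sample_reads(cat: pd.DataFrame, prevalence: np.ndarray, purity: float,
                  depth_mean: float, timepoint: str,
                  rng: np.random.Generator) -> pd.DataFrame:
    """Binomial read sampling for one timepoint; VAF_true = prev·purity/2."""
    depth = np.maximum(1, rng.poisson(depth_mean, size=len(cat)))
    p = np.clip(prevalence * purity / 2.0, 0.0, 1.0)
    alt = rng.binomial(depth, p)
    out = cat[["patient", "gene", "chrom", "pos", "ref", "alt",
               "nonsyn", "neoantigen"]].copy()
    out.insert(1, "timepoint", timepoint)
    out["alt_reads"] = alt
    out["depth"] = depth
    out["vaf"] = alt / depth
    out = out.loc[out["alt_reads"] > 0].reset_index(drop=True)
    cols = ["patient", "timepoint", "gene", "chrom", "pos", "ref", "alt",
            "alt_reads", "depth", "vaf", "nonsyn", "neoantigen"]
    return out[cols]


def generate_mutation_pair(
    patient: str,
    clusters: list[SubcloneCluster],
    purity_pre: float,
    purity_post: float,
    depth_mean: float,
    seed,
    muts_per_clone: int = 25,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired pre/post MAF-like tables for one patient.

    Each mutation's alt count is Binomial(depth, prevalence × purity / 2)
    at a Poisson(depth_mean) depth (min 1); mutations of eradicated
    subclones (prevalence_post = 0) never appear in the post table, and a
    call with zero alt reads is not reported.  ``seed`` may be an int or a
    numpy Generator.
    """
    if depth_mean < 1:
        raise ValidationError(f"depth_mean must be >= 1, got {depth_mean!r}")
    for p, name in ((purity_pre, "purity_pre"), (purity_post, "purity_post")):
        if not 0.0 < p <= 1.0:
            raise ValidationError(f"{name} must be in (0, 1], got {p!r}")
    rng = _as_rng(seed)
    cat = _mutation_catalog(rng, patient, clusters, muts_per_clone)
    pre = _sample_reads(cat, cat["prevalence_pre"].to_numpy(), purity_pre,
                        depth_mean, "pre", rng)
    post = _sample_reads(cat, cat["prevalence_post"].to_numpy(), purity_post,
                         depth_mean, "post", rng)
    return pre, post


# ---------------------------------------------------------------------------
# TCR repertoires


def _random_cdr3(rng: np.random.Generator, n: int) -> np.ndarray:
    lengths = rng.integers(8, 13, size=n)
    chars = AMINO_ACIDS[rng.integers(0, 20, size=(n, 12))]
    out = np.empty(n, dtype=object)
    for i in range(n):
        out[i] = "CAS" + "".join(chars[i, : lengths[i]]) + "F"
    return out


def generate_repertoire_pair(
    patient: str,
    repertoire_size: int,
    zipf_exponent: float,
    expansion_factor: float,
    seed,
    n_top: int = 20,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired pre/post clonotype tables with a Zipf-shaped pre repertoire.

    Pre counts are proportional to 1/rank^zipf_exponent (scaled to ~10^6
    reads).  Post counts equal pre counts with the ``n_top`` most frequent
    clones multiplied by ``expansion_factor`` (rounded, min 1), then the
    table is renormalized — so expansion_factor = 1 reproduces the pre
    frequencies exactly.
    """
    if repertoire_size < n_top + 1:
        raise ValidationError(
            f"repertoire_size must be >= {n_top + 1}, got {repertoire_size!r}"
        )
    if expansion_factor <= 0:
        raise ValidationError(f"expansion_factor must be > 0, got {expansion_factor!r}")
    rng = _as_rng(seed)
    ranks = np.arange(1, repertoire_size + 1, dtype=float)
    weights = ranks ** -float(zipf_exponent)
    counts = np.maximum(1, np.rint(1e6 * weights / weights.sum()).astype(np.int64))

    cdr3 = _random_cdr3(rng, repertoire_size)
    while pd.Series(cdr3).duplicated().any():      # vanishing-probability guard
        dup = pd.Series(cdr3).duplicated()
        cdr3[dup.to_numpy()] = _random_cdr3(rng, int(dup.sum()))
    v = np.array(V_SEGMENTS)[rng.integers(0, len(V_SEGMENTS), size=repertoire_size)]
    j = np.array(J_SEGMENTS)[rng.integers(0, len(J_SEGMENTS), size=repertoire_size)]

    pre = pd.DataFrame({"cdr3aa": cdr3, "v_segment": v, "j_segment": j,
                        "count": counts})
    pre = normalize_clonotypes(pre)

    post = pre.copy()
    expanded = post["count"].to_numpy().astype(float)
    if expansion_factor != 1.0:
        expanded[:n_top] = np.maximum(1, np.rint(expanded[:n_top] * expansion_factor))
    post["count"] = expanded.astype(np.int64)
    post = normalize_clonotypes(post)
    return pre[TCR_COLUMNS], post[TCR_COLUMNS]


# ---------------------------------------------------------------------------
# expression


def generate_expression(
    n_genes: int,
    samples: pd.DataFrame,
    gene_sets: dict | None = None,
    signature_shift: float = 1.0,
    seed=0,
) -> pd.DataFrame:
    """Gene × sample TPM matrix with a signature shift in responder-post samples.

    ``samples`` needs columns sample, responder (bool), timepoint.  Values
    are generated in log2(TPM+1) space — Gaussian around a per-gene
    baseline — then responder post-treatment samples receive an additive
    ``signature_shift`` on every signature gene, and the matrix is mapped
    back to TPM (clipped at 0, so never negative).
    """
    gene_sets = dict(gene_sets) if gene_sets is not None else dict(DEFAULT_GENE_SETS)
    sig_genes = sorted({g for genes in gene_sets.values() for g in genes})
    if n_genes < len(sig_genes):
        raise ConfigError("n_genes", f"must cover the {len(sig_genes)} signature genes")
    for col in ("sample", "responder", "timepoint"):
        if col not in samples.columns:
            raise ConfigError("samples", f"missing column '{col}'")
    rng = _as_rng(seed)
    filler = [f"GENE{i:05d}" for i in range(1, n_genes - len(sig_genes) + 1)]
    genes = sig_genes + filler
    unknown = [g for g in sig_genes if g not in genes]
    if unknown:  # cannot happen with generated names; guards user-supplied lists
        raise ConfigError("gene_sets", f"unknown genes {unknown}")

    mu = rng.uniform(1.0, 8.0, size=len(genes))
    mu[: len(sig_genes)] = 5.0                      # headroom: shifts never clip
    log_expr = rng.normal(mu[:, None], 0.5, size=(len(genes), len(samples)))
    is_shifted = (samples["responder"].to_numpy(dtype=bool)
                  & (samples["timepoint"].to_numpy() == "post"))
    log_expr[: len(sig_genes), is_shifted] += signature_shift
    log_expr = np.clip(log_expr, 0.0, None)
    tpm = np.exp2(log_expr) - 1.0
    return pd.DataFrame(tpm, index=pd.Index(genes, name="gene"),
                        columns=samples["sample"].to_numpy())


# ---------------------------------------------------------------------------
# full cohort


def _generate_clusters(rng: np.random.Generator, n_subclones: int,
                       lost_prob: float) -> list[SubcloneCluster]:
    prev_pre = np.empty(n_subclones)
    prev_pre[0] = 1.0                               # truncal clone
    prev_pre[1:] = rng.uniform(0.2, 0.9, size=n_subclones - 1)
    eradicated = rng.random(n_subclones) < lost_prob
    jitter = np.exp(rng.normal(0.0, 0.3, size=n_subclones))
    prev_post = np.where(eradicated, 0.0, np.clip(prev_pre * jitter, 0.0, 1.0))
    return [
        SubcloneCluster(f"C{i}", float(prev_pre[i]), float(prev_post[i]))
        for i in range(n_subclones)
    ]


def generate_cohort(
    config: CohortConfig,
    include: tuple = ("mutations", "tcr", "expression"),
) -> CohortData:
    """Generate the full synthetic cohort described by ``config``.

    ``include`` restricts which omics layers are generated (pathology and
    truth always are); restricting layers never changes the tables of the
    layers that are generated, because every layer has its own per-patient
    RNG substream.
    """
    unknown = set(include) - {"mutations", "tcr", "expression"}
    if unknown:
        raise ConfigError("include", f"unknown layer(s) {sorted(unknown)}")
    n = config.n_patients
    width = max(2, len(str(n)))
    patients = [f"P{i:0{width}d}" for i in range(1, n + 1)]

    cohort_rng = _patient_rng(config.seed, "__cohort__", "labels")
    n_resp = int(round(config.frac_responders * n))
    responder = np.zeros(n, dtype=bool)
    responder[cohort_rng.permutation(n)[:n_resp]] = True

    patient_rows, truth_rows = [], []
    pre_tabs, post_tabs = [], []
    clonotypes, clusters_by_patient = {}, {}

    for i, pid in enumerate(patients):
        rng_path = _patient_rng(config.seed, pid, "pathology")
        a, b = (config.regression_responder if responder[i]
                else config.regression_nonresponder)
        regression = 100.0 * rng_path.beta(a, b)
        viable = 100.0 - regression
        purity_pre = rng_path.uniform(*config.purity_range_pre)
        purity_post = rng_path.uniform(*config.purity_range_post)
        msi_h = bool(rng_path.random() < 0.16)
        msi_score = float(rng_path.exponential(12.0) if msi_h else rng_path.exponential(1.0))
        pdl1_cps = float(np.round(rng_path.exponential(3.0), 1))

        lost_prob = (config.lost_subclone_prob_responder if responder[i]
                     else config.lost_subclone_prob_nonresponder)
        rng_mut = _patient_rng(config.seed, pid, "mutations")
        clusters = _generate_clusters(rng_mut, config.n_subclones, lost_prob)
        clusters_by_patient[pid] = clusters
        if "mutations" in include:
            pre, post = generate_mutation_pair(
                pid, clusters, purity_pre, purity_post, config.depth_mean,
                rng_mut, muts_per_clone=config.muts_per_clone,
            )
            pre_tabs.append(pre)
            post_tabs.append(post)

        factor = (config.expansion_factor_responder if responder[i]
                  else config.expansion_factor_nonresponder)
        if "tcr" in include:
            rng_tcr = _patient_rng(config.seed, pid, "tcr")
            rep_pre, rep_post = generate_repertoire_pair(
                pid, config.repertoire_size, config.zipf_exponent, factor, rng_tcr,
            )
            clonotypes[(pid, "pre")] = rep_pre
            clonotypes[(pid, "post")] = rep_post

        true_lost = float(np.mean([c.prevalence_post == 0.0 for c in clusters]))
        patient_rows.append({
            "patient": pid, "viable_pct": viable, "regression_pct": regression,
            "purity_pre": purity_pre, "purity_post": purity_post,
            "msi_status": "MSI-H" if msi_h else "MSS", "msi_score": msi_score,
            "pdl1_cps": pdl1_cps, "exome_mb": config.exome_mb,
        })
        truth_rows.append({
            "patient": pid, "responder": int(responder[i]),
            "regression_true": regression, "true_lost_fraction": true_lost,
            "ce_direction": int(np.sign(factor - 1.0)),
        })

    sample_rows = [
        {"sample": f"{pid}_{tp}", "patient": pid, "timepoint": tp,
         "responder": bool(responder[i])}
        for i, pid in enumerate(patients) for tp in ("pre", "post")
    ]
    samples = pd.DataFrame(sample_rows)
    if "expression" in include:
        rng_expr = _patient_rng(config.seed, "__cohort__", "expression")
        expression = generate_expression(
            config.n_genes, samples, DEFAULT_GENE_SETS, config.signature_shift,
            rng_expr,
        )
    else:
        expression = pd.DataFrame()

    empty = pd.DataFrame(columns=pd.Index(
        ["patient", "timepoint", "gene", "chrom", "pos", "ref", "alt",
         "alt_reads", "depth", "vaf", "nonsyn", "neoantigen"]))
    return CohortData(
        config=config,
        patients=pd.DataFrame(patient_rows),
        mutations_pre=pd.concat(pre_tabs, ignore_index=True) if pre_tabs else empty,
        mutations_post=pd.concat(post_tabs, ignore_index=True) if post_tabs else empty.copy(),
        clonotypes=clonotypes,
        expression=expression,
        truth=pd.DataFrame(truth_rows),
        clusters=clusters_by_patient,
    )


# ---------------------------------------------------------------------------
# I/O


def write_cohort(data: CohortData, outdir) -> None:
    """Write all cohort tables as TSV into ``outdir`` (created if absent)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    data.patients.to_csv(out / "patients.tsv", sep="\t", index=False)
    data.mutations_pre.to_csv(out / "mutations_pre.tsv", sep="\t", index=False)
    data.mutations_post.to_csv(out / "mutations_post.tsv", sep="\t", index=False)
    for (pid, tp), table in sorted(data.clonotypes.items()):
        table.to_csv(out / f"clonotypes_{pid}_{tp}.tsv", sep="\t", index=False)
    data.expression.to_csv(out / "expression_tpm.tsv", sep="\t")
    data.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    cfg = {k: (list(v) if isinstance(v, tuple) else v)
           for k, v in asdict(data.config).items()}
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def load_config(path) -> CohortConfig:
    """Read a YAML/JSON file mirroring CohortConfig; unknown keys are errors."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    valid = set(CohortConfig.__dataclass_fields__)
    unknown = sorted(set(raw) - valid)
    if unknown:
        raise ConfigError(unknown[0], "unknown configuration field")
    for key in ("regression_responder", "regression_nonresponder",
                "purity_range_pre", "purity_range_post"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return CohortConfig(**raw)
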