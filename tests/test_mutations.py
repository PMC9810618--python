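"""Purity-corrected VAF dynamics: fates, burden, dilution, contingency."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from neoresponse.errors import DataError, ValidationError
from neoresponse.mutations import (
    SampleMeta,
    adjust_vaf,
    apply_call_filters,
    biomarker_contingency,
    classify_fates,
    clonal_consistency,
    compute_burden,
    lost_fraction,
    purity_balance_dilution,
)
from neoresponse.simulate import SubcloneCluster, generate_mutation_pair


def mutation_table(vafs, depth=100, patient="P", timepoint="pre", start_pos=1):
    vafs = np.asarray(vafs, dtype=float)
    alt = np.rint(vafs * depth).astype(int)
    return pd.DataFrame({
        "patient": patient, "timepoint": timepoint,
        "gene": [f"G{i}" for i in range(len(vafs))],
        "chrom": "1", "pos": np.arange(start_pos, start_pos + len(vafs)),
        "ref": "A", "alt": "T",
        "alt_reads": alt, "depth": depth, "vaf": alt / depth,
        "nonsyn": 1, "neoantigen": 0,
    })


class TestAdjustVaf:
    @pytest.mark.parametrize("vaf, purity, expected",
                             [(0.25, 0.5, 0.5), (0.4, 1.0, 0.4), (0.8, 0.5, 1.0)])
    def test_formula_identity_and_cap(self, vaf, purity, expected):
        assert adjust_vaf(vaf, purity) == pytest.approx(expected)

    def test_ccf_variant_doubles(self):
        assert adjust_vaf(0.2, 0.8, ccf=True) == pytest.approx(0.5)

    @pytest.mark.parametrize("purity", [0.0, -0.5, 1.5])
    def test_bad_purity(self, purity):
        with pytest.raises(ValidationError):
            adjust_vaf(0.3, purity)

    @given(st.floats(min_value=0, max_value=1), st.floats(min_value=0.01, max_value=1))
    @settings(max_examples=200, deadline=None)
    def test_monotone_and_bounded(self, vaf, purity):
        a = adjust_vaf(vaf, purity)
        assert 0.0 <= a <= 1.0
        assert adjust_vaf(min(1.0, vaf + 0.05), purity) >= a


class TestCallFilters:
    def test_vaf_boundary(self):
        t = mutation_table([0.019, 0.02, 0.25], depth=1000)
        kept = apply_call_filters(t, min_vaf=0.02)
        assert kept["vaf"].tolist() == [0.02, 0.25]
        assert kept.attrs["n_filtered"] == 1

    def test_depth_and_alt_floors(self):
        t = mutation_table([0.5, 0.5], depth=30)
        assert len(apply_call_filters(t, min_depth=50)) == 0
        assert len(apply_call_filters(t, min_alt=16)) == 0

    def test_empty_in_empty_out(self):
        assert len(apply_call_filters(mutation_table([]))) == 0


def brute_force_fate(vaf_pre, vaf_post, purity_pre, purity_post, tie_tol=0.0):
    """Independent single-mutation reclassification: the definition, verbatim."""
    if vaf_pre is None:
        return "gain"
    if vaf_post is None:
        return "lost"
    a = min(1.0, vaf_pre / purity_pre)
    b = min(1.0, vaf_post / purity_post)
    if b - a > tie_tol:
        return "increase"
    if a - b > tie_tol:
        return "decrease"
    return "stable"


class TestClassifyFates:
    def test_caption_examples(self):
        pre = mutation_table([0.2, 0.3, 0.3], start_pos=1)
        post = mutation_table([0.4, 0.3], timepoint="post", start_pos=2)
        fates = classify_fates(pre, post, 1.0, 1.0)
        by_pos = {k.split(":")[1]: v for k, v in fates["fate"].items()}
        assert by_pos["1"] == "lost"       # present pre only
        assert by_pos["2"] == "increase"   # 0.2 → 0.4
        assert by_pos["3"] == "stable"     # 0.3 → 0.3, tie_tol 0
        assert len(fates) == 3

    def test_duplicate_key_rejected(self):
        pre = mutation_table([0.2, 0.3])
        pre.loc[1, "pos"] = pre.loc[0, "pos"]
        with pytest.raises(DataError):
            classify_fates(pre, mutation_table([]), 1.0, 1.0)

    def test_matches_brute_force_on_random_pairs(self):
        rng = np.random.default_rng(77)
        for _ in range(200):
            n_pre, n_post = rng.integers(0, 30, size=2)
            shared = min(n_pre, n_post) and rng.integers(0, min(n_pre, n_post))
            pre = mutation_table(rng.uniform(0.02, 0.9, n_pre), start_pos=1)
            post = mutation_table(rng.uniform(0.02, 0.9, n_post),
                                  timepoint="post", start_pos=n_pre - shared + 1)
            pp, qp = rng.uniform(0.2, 1.0, size=2)
            fates = classify_fates(pre, post, pp, qp)
            assert len(fates) == len(set(pre["pos"]) | set(post["pos"]))
            vp = dict(zip(pre["pos"].astype(str), pre["vaf"]))
            vq = dict(zip(post["pos"].astype(str), post["vaf"]))
            for key, row in fates.iterrows():
                pos = key.split(":")[1]
                expected = brute_force_fate(vp.get(pos), vq.get(pos), pp, qp)
                assert row["fate"] == expected


class TestLostFraction:
    def test_arithmetic(self):
        pre = mutation_table(np.full(10, 0.3), start_pos=1)
        post = mutation_table(np.full(7, 0.3), timepoint="post", start_pos=4)
        fates = classify_fates(pre, post, 1.0, 1.0)
        assert lost_fraction(fates) == pytest.approx(0.3)

    def test_all_lost(self):
        fates = classify_fates(mutation_table([0.2, 0.4]), mutation_table([]), 1.0, 1.0)
        assert lost_fraction(fates) == 1.0

    def test_undefined_without_pre_mutations(self):
        fates = classify_fates(mutation_table([]), mutation_table([0.2]), 1.0, 1.0)
        with pytest.raises(ValidationError):
            lost_fraction(fates)


class TestBurden:
    def test_tmb_per_megabase(self):
        t = mutation_table(np.full(70, 0.3))
        meta = SampleMeta("P", "pre", purity=0.5, exome_mb=35.0)
        b = compute_burden(t, meta)
        assert b.tmb == pytest.approx(2.0)
        assert b.tnb == 0.0

    def test_zero_records(self):
        b = compute_burden(mutation_table([]), SampleMeta("P", "pre", purity=0.5))
        assert (b.tmb, b.tnb) == (0.0, 0.0)

    def test_tnb_bounded_by_tmb(self, small_cohort):
        meta = SampleMeta("P01", "pre", purity=0.5, exome_mb=35.0)
        t = small_cohort.mutations_pre
        b = compute_burden(t[t.patient == "P01"], meta)
        assert b.tnb <= b.tmb

    def test_bad_exome(self):
        with pytest.raises(ValidationError):
            SampleMeta("P", "pre", purity=0.5, exome_mb=0.0)


class TestDilution:
    meta = SampleMeta("P", "pre", purity=0.8, exome_mb=35.0)

    def test_identity_at_equal_purity(self):
        t = apply_call_filters(mutation_table(np.linspace(0.05, 0.5, 40)))
        out, b = purity_balance_dilution(t, self.meta, 0.8, seed=1)
        pd.testing.assert_frame_equal(out, t)
        assert b.tmb == pytest.approx(len(t) / 35.0)

    def test_large_depth_limit(self):
        t = mutation_table([0.4] * 20, depth=10**6)
        out, _ = purity_balance_dilution(t, self.meta, 0.4, seed=2)
        m = 1 - 0.4 / 0.8
        assert np.allclose(out["vaf"], 0.4 * (1 - m), atol=1e-3)

    def test_deterministic_given_seed(self):
        t = mutation_table(np.linspace(0.05, 0.5, 30))
        a, _ = purity_balance_dilution(t, self.meta, 0.4, seed=9)
        b, _ = purity_balance_dilution(t, self.meta, 0.4, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_concentration_rejected(self):
        with pytest.raises(ValidationError):
            purity_balance_dilution(mutation_table([0.3]), self.meta, 0.9, seed=1)


class TestClonalConsistency:
    @pytest.mark.parametrize(
        "dv, dp, expected",
        [
            ((0.2, 0.5), (0.3, 0.8), True),    # both increase
            ((0.2, 0.5), (0.8, 0.3), False),   # VAF up, prevalence down
            ((0.5, 0.2), (0.8, 0.3), True),    # both decrease
            ((0.4, 0.0), (0.6, 0.0), True),    # lost mutation, eradicated clone
            ((0.3, 0.3), (0.5, 0.5), True),    # zero vs zero
        ],
    )
    def test_sign_agreement(self, dv, dp, expected):
        assert clonal_consistency(dv[0], dv[1], dp[0], dp[1]) is expected

    def test_tolerance_absorbs_jitter(self):
        assert clonal_consistency(0.30, 0.32, 0.5, 0.5, tol=0.05)


class TestBiomarkerContingency:
    def test_counts_match_quoted_frequencies(self):
        # mutated in 4/5 responders and 0/14 non-responders
        mutated = [True] * 4 + [False] + [False] * 14
        responder = [True] * 5 + [False] * 14
        res = biomarker_contingency(mutated, responder)
        assert res["table"].tolist() == [[4, 1], [0, 14]]
        assert np.isinf(res["odds_ratio"])
        assert res["p_value"] < 0.01
        assert res["p_adjusted"] is False

    def test_no_association(self):
        mutated = [True, False] * 6
        responder = [True] * 6 + [False] * 6
        res = biomarker_contingency(mutated, responder)
        assert res["p_value"] == 1.0

    def test_length_mismatch(self):
        with pytest.raises(DataError):
            biomarker_contingency([True], [True, False])

    def test_p_equals_hypergeometric_enumeration(self):
        """Fisher two-sided p == sum of hypergeometric probabilities <= observed."""
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = int(rng.integers(4, 20))
            mutated = rng.random(n) < 0.5
            responder = rng.random(n) < 0.5
            res = biomarker_contingency(mutated, responder)
            a = res["table"][0][0]
            row1 = res["table"][0].sum()
            col1 = res["table"][:, 0].sum()
            pmf = [stats.hypergeom.pmf(x, n, col1, row1)
                   for x in range(max(0, row1 + col1 - n), min(row1, col1) + 1)]
            obs = stats.hypergeom.pmf(a, n, col1, row1)
            expected = sum(p for p in pmf if p <= obs * (1 + 1e-9))
            assert res["p_value"] == pytest.approx(expected, rel=1e-6)


def test_quiescent_tumor_rarely_gains_or_loses():
    """With unchanged subclones and purity, gain+lost is pure filter noise."""
    clusters = [SubcloneCluster(f"C{i}", p, p, ()) for i, p in
                enumerate([1.0, 0.7, 0.5, 0.3])]
    rng = np.random.default_rng(21)
    fracs = []
    for _ in range(20):
        pre, post = generate_mutation_pair("P", clusters, 0.6, 0.6, 200, seed=rng)
        pre, post = apply_call_filters(pre), apply_call_filters(post)
        fates = classify_fates(pre, post, 0.6, 0.6)
        counts = fates["fate"].value_counts()
        fracs.append((counts.get("gain", 0) + counts.get("lost", 0)) / len(fates))
    assert np.mean(fracs) < 0.05
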