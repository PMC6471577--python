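"""Variant filter cascade: hard filters, ledger accounting, differential
AAF testing, BH-FDR and coding effects."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import editome as e
from editome.cascade import (
    CascadeConfig,
    QualityThresholds,
    VariantSite,
    apply_positional_filters,
    apply_quality_filters,
    apply_replicate_filters,
    bh_fdr,
    coding_effect,
    differential_aaf_test,
    differential_aaf_tests,
    fails_quality,
    fails_replicate_support,
    run_cascade,
)
from editome.context import GeneModel, MaskContext


def make_site(depths, alts, pos=1, ref="A", alt="G", **metrics):
    depths = np.asarray(depths)
    defaults = dict(total_depth=float(depths.sum()), mq=60.0, qd=25.0)
    defaults.update(metrics)
    return VariantSite("chr1", pos, ref, alt, depths, np.asarray(alts), **defaults)


def uniform_site(pos, depth=30, alt=10, n=10, **metrics):
    return make_site([depth] * n, [alt] * n, pos=pos, **metrics)


class TestQualityFilters:
    def test_low_depth_removed(self):
        site = uniform_site(1, total_depth=9.0)
        survivors, (name, removed) = apply_quality_filters([site])
        assert survivors == [] and removed == 1 and name == "quality"

    def test_boundary_values_retained(self):
        """Filters are strict inequalities: a variant sitting exactly on
        every threshold passes."""
        site = uniform_site(
            1, total_depth=10.0, mq=40.0, qd=2.0,
            mq_rank_sum=-12.5, read_pos_rank_sum=-8.0,
        )
        survivors, (_, removed) = apply_quality_filters([site])
        assert survivors == [site] and removed == 0

    def test_missing_rank_sums_pass(self):
        site = uniform_site(1, mq_rank_sum=None, read_pos_rank_sum=None)
        survivors, _ = apply_quality_filters([site])
        assert survivors == [site]

    def test_random_fixture_matches_predicate_oracle(self):
        """Survivors of a 1,000-site random-metric fixture equal an
        independent predicate-by-predicate re-evaluation."""
        rng = np.random.default_rng(0)
        sites = [
            uniform_site(
                i + 1,
                total_depth=float(rng.uniform(0, 30)),
                mq=float(rng.uniform(20, 70)),
                qd=float(rng.uniform(0, 10)),
                mq_rank_sum=float(rng.uniform(-20, 5)),
                read_pos_rank_sum=float(rng.uniform(-15, 5)),
            )
            for i in range(1000)
        ]
        survivors, (_, removed) = apply_quality_filters(sites)
        expected = [
            s for s in sites
            if not (
                s.total_depth < 10 or s.mq < 40 or s.qd < 2
                or s.mq_rank_sum < -12.5 or s.read_pos_rank_sum < -8
            )
        ]
        assert survivors == expected
        assert removed == 1000 - len(expected)


class TestReplicateFilters:
    def test_alt_in_all_samples_retained(self):
        site = make_site([20] * 10, [5] * 10)
        assert not fails_replicate_support(site)

    def test_zero_aaf_in_five_of_ten_removed(self):
        site = make_site([20] * 10, [5] * 5 + [0] * 5)
        assert fails_replicate_support(site)

    def test_support_in_exactly_half_removed(self):
        """'More than half' is strict: alt present in 5 of 10 fails even
        when fewer than five libraries are at zero."""
        # 5 supporting, 4 zero-AAF, one depth-0 sample -> counted as zero
        site = make_site([20] * 9 + [0], [5] * 5 + [0] * 5)
        assert fails_replicate_support(site)

    def test_depth_zero_counts_as_absent(self):
        site = make_site([20] * 4 + [0] * 6, [5] * 4 + [0] * 6)
        assert fails_replicate_support(site)

    def test_thresholds_scale_with_sample_count(self):
        # n = 6: fails when zeros >= 3 or support <= 3
        assert fails_replicate_support(make_site([20] * 6, [5, 5, 5, 0, 0, 0]))
        assert not fails_replicate_support(make_site([20] * 6, [5, 5, 5, 5, 0, 0]))


class TestPositionalFilters:
    def test_first_failing_stage_charged(self):
        """A site in several flagged contexts is charged to the earliest
        stage in the removal order."""
        both = uniform_site(5)   # bidirectional AND in a repeat
        repeat_only = uniform_site(6)
        clean = uniform_site(7)
        ctx = MaskContext(
            bidirectional=[("chr1", 4)],
            ssr=[("chr1", 4), ("chr1", 5)],
        )
        survivors, stages = apply_positional_filters([both, repeat_only, clean], ctx)
        assert survivors == [clean]
        assert stages == [
            ("bidirectional", 1), ("paralog", 0), ("repeat", 1),
            ("splice_proximity", 0),
        ]


class TestDifferentialAafTest:
    def test_identical_pooled_counts_give_p_one(self, labels_5v5):
        site = make_site([20] * 10, [6] * 10)
        result = differential_aaf_test(site, labels_5v5)
        assert result.p_value == 1.0
        assert result.fraction_difference == 0.0

    def test_complete_separation(self, labels_5v5):
        """All-alt cases vs all-ref controls at depth 20: the pooled
        G-test is overwhelming, and the exact permutation oracle gives
        2/252."""
        site = make_site([20] * 10, [0] * 5 + [20] * 5)
        g_result = differential_aaf_test(site, labels_5v5)
        assert g_result.p_value < 1e-6
        perm = differential_aaf_test(site, labels_5v5, method="permutation")
        assert perm.p_value == pytest.approx(2 / 252)

    def test_g_statistic_matches_scipy_log_likelihood(self, labels_5v5):
        """Pooled-count G-test p-values equal scipy's log-likelihood-ratio
        contingency test on the same 2x2 tables."""
        rng = np.random.default_rng(3)
        for _ in range(50):
            depths = rng.integers(5, 60, size=10)
            alts = rng.binomial(depths, rng.uniform(0.1, 0.9))
            site = make_site(depths, alts)
            res = differential_aaf_test(site, labels_5v5)
            case_alt = alts[5:].sum()
            ctrl_alt = alts[:5].sum()
            table = np.array(
                [
                    [case_alt, depths[5:].sum() - case_alt],
                    [ctrl_alt, depths[:5].sum() - ctrl_alt],
                ]
            )
            if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
                continue
            expected = stats.chi2_contingency(
                table, correction=False, lambda_="log-likelihood"
            ).pvalue
            assert res.p_value == pytest.approx(expected, rel=1e-9)

    def test_vectorised_matches_scalar(self, labels_5v5):
        rng = np.random.default_rng(4)
        sites = []
        for i in range(200):
            depths = rng.integers(1, 50, size=10)
            alts = rng.binomial(depths, 0.4)
            sites.append(make_site(depths, alts, pos=i + 1))
        batch = differential_aaf_tests(sites, labels_5v5)
        for site, br in zip(sites, batch):
            sr = differential_aaf_test(site, labels_5v5)
            assert br.p_value == pytest.approx(sr.p_value, rel=1e-12)
            assert br.fraction_difference == pytest.approx(
                sr.fraction_difference, nan_ok=True
            )

    def test_uncovered_group_flagged_undefined(self, labels_5v5):
        site = make_site([0] * 5 + [20] * 5, [0] * 5 + [5] * 5)
        result = differential_aaf_test(site, labels_5v5)
        assert result.undefined and np.isnan(result.p_value)


class TestBhFdr:
    def test_single_p(self):
        assert bh_fdr([0.01])[0] == pytest.approx(0.01)

    def test_hand_computed_step_up(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_empty(self):
        assert bh_fdr([]).size == 0

    def test_matches_statsmodels_on_random_vectors(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(8)
        for n in (1, 2, 10, 137, 1000):
            p = rng.uniform(size=n)
            expected = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(bh_fdr(p), expected)

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=50))
    def test_q_at_least_p_and_bounded(self, p):
        q = bh_fdr(p)
        assert np.all(q >= np.asarray(p) - 1e-12)
        assert np.all(q <= 1.0)


@pytest.fixture(scope="module")
def toy():
    # gene: exon 10..28 + exon 40..52, CDS 16..49 -> spliced CDS length 21
    seq = ("T" * 10 + "ACGTCA" + "GCTGCAGCTACA" + "TTTTTTTTTTTT"
           + "GCAGCTTAC" + "TAAT" * 12)
    gene = GeneModel("toy", "chr1", "+", ((10, 28), (40, 52)), cds=(16, 49))
    return gene, {"chr1": seq}


class TestCodingEffect:
    def test_outside_cds_is_noncoding(self, toy):
        gene, ref = toy
        site = make_site([10] * 10, [2] * 10, pos=12, ref=ref["chr1"][11], alt="T")
        assert coding_effect(site, gene, ref) == "noncoding"

    def test_third_position_synonymous(self, toy):
        """GCT -> GCC keeps alanine."""
        gene, ref = toy
        # CDS starts at 16 (0-based); first codon bases 16,17,18 = GCT
        assert ref["chr1"][16:19] == "GCT"
        site = make_site([10] * 10, [2] * 10, pos=19, ref="T", alt="C")
        assert coding_effect(site, gene, ref) == "synonymous"

    def test_second_position_missense(self, toy):
        """GCT -> GTT is Ala -> Val."""
        gene, ref = toy
        site = make_site([10] * 10, [2] * 10, pos=18, ref="C", alt="T")
        assert coding_effect(site, gene, ref) == "missense"

    def test_stop_gained_is_nonsense(self, toy):
        gene, ref = toy
        # last CDS codon (second exon) is TAC (Tyr); TAC -> TAA is a stop
        assert ref["chr1"][46:49] == "TAC"
        site = make_site([10] * 10, [2] * 10, pos=49, ref="C", alt="A")
        assert coding_effect(site, gene, ref) == "nonsense"

    def test_minus_strand_orientation(self):
        # minus-strand gene whose CDS reads ATGTAA on the transcript
        seq = "GGGG" + "TTACAT" + "GGGG"  # revcomp(ATGTAA)
        gene = GeneModel("m", "chr1", "-", ((4, 10),), cds=(4, 10))
        ref = {"chr1": seq}
        # genomic T at 0-based 9 is the transcript's start-codon A;
        # genome T>C reads A>G on the transcript: ATG -> GTG, Met -> Val
        site = make_site([10] * 10, [2] * 10, pos=10, ref="T", alt="C")
        assert coding_effect(site, gene, ref) == "missense"

    def test_cds_not_multiple_of_three_raises(self):
        seq = "A" * 30
        gene = GeneModel("bad", "chr1", "+", ((5, 15),), cds=(5, 12))
        site = make_site([10] * 10, [2] * 10, pos=7, ref="A", alt="G")
        with pytest.raises(ValueError, match="divisible by 3"):
            coding_effect(site, gene, {"chr1": seq})


class TestRunCascade:
    def test_empty_input_gives_zero_ledger(self, labels_5v5):
        result = run_cascade([], MaskContext(), CascadeConfig(labels_5v5))
        assert result.ledger.input_count == 0
        assert all(n == 0 for _, n in result.ledger.stages)
        assert result.results == []

    def test_random_fixture_matches_sequential_oracle(self, labels_5v5):
        """Cascade survivors equal brute-force sequential filtering."""
        rng = np.random.default_rng(12)
        sites = []
        for i in range(100):
            depths = rng.integers(0, 40, size=10)
            alts = rng.binomial(depths, 0.35)
            sites.append(
                make_site(
                    depths, alts, pos=i + 1,
                    total_depth=float(rng.uniform(5, 30)),
                    mq=float(rng.uniform(30, 70)),
                    qd=float(rng.uniform(0, 6)),
                )
            )
        flagged = lambda frac: {
            ("chr1", int(p)) for p in rng.choice(100, int(100 * frac), replace=False)
        }
        ctx = MaskContext(
            bidirectional=flagged(0.1), multimapping=flagged(0.1),
            ssr=flagged(0.1), splice_proximal=flagged(0.1),
        )
        result = run_cascade(sites, ctx, CascadeConfig(labels_5v5))
        expected = []
        for s in sites:
            p = s.pos - 1
            if fails_quality(s, QualityThresholds()):
                continue
            if ctx.is_bidirectional("chr1", p) or ctx.flank_multimaps("chr1", p):
                continue
            if ctx.in_ssr("chr1", p) or ctx.near_splice_boundary("chr1", p):
                continue
            if fails_replicate_support(s):
                continue
            expected.append(s)
        assert result.survivors == expected
        result.ledger.validate()

    def test_idempotence_on_survivors(self, labels_5v5):
        rng = np.random.default_rng(13)
        sites = [
            make_site(rng.integers(10, 40, size=10), rng.integers(1, 9, size=10), pos=i + 1)
            for i in range(50)
        ]
        ctx = MaskContext(ssr=[("chr1", 3), ("chr1", 17)])
        first = run_cascade(sites, ctx, CascadeConfig(labels_5v5))
        second = run_cascade(first.survivors, ctx, CascadeConfig(labels_5v5))
        assert second.survivors == first.survivors
        assert second.ledger.removed_total == 0

    def test_multiallelic_dropped_with_reason(self, labels_5v5):
        bad = make_site([20] * 10, [5] * 10, pos=1, alt="G,T")
        good = uniform_site(2)
        result = run_cascade([bad, good], MaskContext(), CascadeConfig(labels_5v5))
        assert result.ledger.stages[0] == ("multiallelic", 1)
        assert result.removal_reasons[bad.key] == "multiallelic"

    def test_removal_reasons_unique_and_conserved(self, planted_ledger_run):
        result = planted_ledger_run
        result.ledger.validate()
        assert (
            len(result.removal_reasons) + len(result.survivors)
            == result.ledger.input_count
        )

    def test_recovery_of_planted_differential_sites(self, labels_5v5):
        """Planted dAAF = 0.3 at depth >= 30 (5 vs 5): at least 80% of
        planted sites reach q < 0.05 and null sites stay controlled at
        q < 0.001."""
        rng = np.random.default_rng(20)
        n_planted, n_null = 200, 2000
        sites = []
        for i in range(n_planted + n_null):
            depths = np.maximum(rng.poisson(30, size=10), 30)
            aaf = np.where(np.arange(10) >= 5, 0.5, 0.2) if i < n_planted else 0.3
            alts = rng.binomial(depths, aaf)
            sites.append(make_site(depths, alts, pos=i + 1))
        results = differential_aaf_tests(sites, labels_5v5)
        q = e.bh_fdr([r.p_value for r in results])
        sensitivity = float((q[:n_planted] < 0.05).mean())
        assert sensitivity >= 0.8
        # BH at 0.001 over ~2200 tests admits few expected false positives
        assert int((q[n_planted:] < 0.001).sum()) <= max(1, int(0.001 * len(sites)))

    def test_null_calibration_near_nominal(self, labels_5v5):
        """Type-I error of the pooled G-test within [0.035, 0.065] at
        alpha = 0.05 under an equal-AAF null."""
        rng = np.random.default_rng(21)
        depths = np.maximum(rng.poisson(50, size=(10_000, 10)), 1)
        alts = rng.binomial(depths, 0.3)
        sites = [
            make_site(depths[i], alts[i], pos=i + 1) for i in range(10_000)
        ]
        results = differential_aaf_tests(sites, labels_5v5)
        p = np.array([r.p_value for r in results])
        assert 0.035 <= float((p < 0.05).mean()) <= 0.065
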