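import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom

from miredit.align import Assignment, Hit
from miredit.calling import (
    EditingCall,
    ErrorModel,
    SitePileup,
    aggregate_high_confidence,
    bh_adjust,
    call_sites,
    editing_level,
    estimate_error_rate,
    pileup,
    site_test,
)
from miredit.references import KnownEditSite

from conftest import make_collapsed


def unedited_assignment(seq, count=1, start=4, ref="hpA", qual=35.0):
    return Assignment(
        read=make_collapsed(seq, count=count, qual=qual),
        status="unedited",
        hits=[Hit(reference_id=ref, start=start)],
    )


def edited_assignment(seq, count=1, start=4, ref="hpA", site_id="siteA", qual=35.0):
    return Assignment(
        read=make_collapsed(seq, count=count, qual=qual),
        status="edited",
        hits=[Hit(reference_id=ref, start=start, site_id=site_id)],
    )


SITE = KnownEditSite(site_id="siteA", pre_id="hpA", mature_id="mA-5p", mature_pos=2, pre_pos=5)


class TestPileup:
    def test_basic_counts(self):
        assigns = [
            unedited_assignment("GACGAUGCUCGGCUCAGUCGA", count=8),
            edited_assignment("GGCGAUGCUCGGCUCAGUCGA", count=2),
        ]
        p = pileup(assigns, SITE)
        assert p.coverage == 10 and p.edited_count == 2

    def test_low_quality_g_masked_from_both(self):
        assigns = [
            unedited_assignment("GACGAUGCUCGGCUCAGUCGA", count=8),
            edited_assignment("GGCGAUGCUCGGCUCAGUCGA", count=2, qual=25.0),
        ]
        p = pileup(assigns, SITE)
        assert p.coverage == 8 and p.edited_count == 0

    def test_unedited_low_quality_still_covers(self):
        assigns = [unedited_assignment("GACGAUGCUCGGCUCAGUCGA", count=5, qual=10.0)]
        p = pileup(assigns, SITE)
        assert p.coverage == 5

    def test_fractional_weights(self):
        # A read matching two paralog edited sites contributes 0.5 to each;
        # weighted-pileup oracle: 0.5 + 0.5 = 1.0 on siteA from two such reads.
        read = make_collapsed("GGCGAUGCUCGGCUCAGUCGA", count=1)
        a = Assignment(
            read=read,
            status="edited",
            hits=[
                Hit(reference_id="hpA", start=4, site_id="siteA"),
                Hit(reference_id="hpB", start=4, site_id="siteB"),
            ],
        )
        p = pileup([a, a], SITE)
        assert p.edited_count == pytest.approx(1.0)
        assert p.coverage == pytest.approx(1.0)

    def test_zero_coverage(self):
        p = pileup([], SITE)
        assert p.coverage == 0 and p.edited_count == 0

    def test_unedited_not_covering_position_ignored(self):
        # Read starting downstream of pre_pos 5.
        a = unedited_assignment("UGCUCGGCUCAGUCGACUCG", start=8)
        assert pileup([a], SITE).coverage == 0


class TestEditingLevel:
    @pytest.mark.parametrize("cov,edited,expected", [(10, 2, 0.2), (5, 0, 0.0), (7, 7, 1.0)])
    def test_examples(self, cov, edited, expected):
        assert editing_level(SitePileup("s", cov, edited)) == pytest.approx(expected)

    def test_zero_coverage_undefined(self):
        with pytest.raises(ValueError):
            editing_level(SitePileup("s", 0, 0))


class TestSiteTest:
    def test_zero_edited_p_is_one(self):
        assert site_test(SitePileup("s", 100, 0), ErrorModel(0.001)) == 1.0

    def test_all_edited_p_is_epsilon_power(self):
        p = site_test(SitePileup("s", 10, 10), ErrorModel(0.001))
        assert p == pytest.approx(1e-30, rel=1e-9)

    def test_brute_force_tail_oracle(self):
        # Independent oracle: direct pmf summation of the upper tail.
        eps = 0.001
        n, k = 100, 10
        oracle = sum(binom.pmf(i, n, eps) for i in range(k, n + 1))
        assert site_test(SitePileup("s", n, k), ErrorModel(eps)) == pytest.approx(
            oracle, rel=1e-12
        )

    @pytest.mark.parametrize("n,k,eps", [(50, 3, 0.01), (7, 2, 0.2), (1000, 12, 0.005)])
    def test_more_oracle_points(self, n, k, eps):
        oracle = sum(binom.pmf(i, n, eps) for i in range(k, n + 1))
        assert site_test(SitePileup("s", n, k), ErrorModel(eps)) == pytest.approx(
            oracle, rel=1e-12
        )

    def test_fractional_counts_rounded_half_up(self):
        exact = site_test(SitePileup("s", 100, 3), ErrorModel(0.001))
        assert site_test(SitePileup("s", 100.2, 2.5), ErrorModel(0.001)) == exact

    def test_monotone_in_edited_count(self):
        model = ErrorModel(0.01)
        ps = [site_test(SitePileup("s", 50, k), model) for k in range(0, 51)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_epsilon_invariant_enforced(self):
        with pytest.raises(ValueError):
            ErrorModel(0.3)
        with pytest.raises(ValueError):
            ErrorModel(0.0)


class TestBHAdjust:
    def test_small_example(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_singleton_identity(self):
        assert bh_adjust([0.05]) == [0.05]

    def test_against_independent_step_up_oracle(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(5)
        for _ in range(20)  :
            p = rng.random(100)
            _, q_ref, _, _ = multipletests(p, method="fdr_bh")
            assert bh_adjust(p) == pytest.approx(list(q_ref), abs=1e-12)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_permutation_invariance(self, p):
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(p))
        q = bh_adjust(p)
        q_perm = bh_adjust([p[i] for i in perm])
        assert [q[i] for i in perm] == pytest.approx(q_perm)

    def test_empty(self):
        assert bh_adjust([]) == []

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestCallSites:
    MODEL = ErrorModel(0.001)

    def make_calls(self, pileups):
        return call_sites({p.site_id: p for p in pileups}, self.MODEL, "s1")

    def test_one_edited_read_fails_support_gate(self):
        (c,) = self.make_calls([SitePileup("a", 2, 1)])
        assert c.level == 0.5 and not c.passes

    def test_low_level_fails(self):
        (c,) = self.make_calls([SitePileup("a", 75, 3)])
        assert c.edited_count == 3 and c.level == pytest.approx(0.04)
        assert c.q_value < 0.05 and not c.passes

    def test_all_gates_met(self):
        (c,) = self.make_calls([SitePileup("a", 10, 3)])
        assert c.level == pytest.approx(0.3) and c.q_value < 0.05 and c.passes

    def test_zero_coverage_site_not_called(self):
        calls = self.make_calls([SitePileup("a", 0, 0), SitePileup("b", 10, 3)])
        assert [c.site_id for c in calls] == ["b"]

    def test_failing_sites_still_reported_with_levels(self):
        calls = self.make_calls([SitePileup("a", 100, 1)])
        assert len(calls) == 1 and calls[0].level == pytest.approx(0.01)


class TestAggregateHighConfidence:
    def make_call(self, sample, site="s1", passes=True, edited=3.0, level=0.2):
        return EditingCall(
            sample_id=sample, site_id=site, coverage=20, edited_count=edited,
            level=level, p_value=1e-9, q_value=1e-8, passes=passes,
        )

    def test_nine_samples_not_enough(self):
        calls = [self.make_call(f"s{i}") for i in range(9)]
        assert aggregate_high_confidence(calls) == []

    def test_ten_samples_enough(self):
        calls = [self.make_call(f"s{i}") for i in range(10)]
        ((site, n, lvl),) = aggregate_high_confidence(calls)
        assert site == "s1" and n == 10 and lvl == pytest.approx(0.2)

    def test_failing_calls_do_not_count(self):
        calls = [self.make_call(f"s{i}") for i in range(10)]
        calls[0] = self.make_call("s0", passes=False)
        assert aggregate_high_confidence(calls) == []

    def test_empty(self):
        assert aggregate_high_confidence([]) == []


class TestEstimateErrorRate:
    def test_uniform_q30(self):
        a = unedited_assignment("GACGAUGCUCGGCUCAGUCGA", count=500, qual=30.0)
        model = estimate_error_rate([a])
        assert model.epsilon_AG == pytest.approx(0.001 / 3)

    def test_uniform_q20(self):
        a = unedited_assignment("GACGAUGCUCGGCUCAGUCGA", count=500, qual=20.0)
        assert estimate_error_rate([a]).epsilon_AG == pytest.approx(0.01 / 3)

    def test_mixed_quality_direct_averaging_oracle(self, rng):
        assigns = []
        probs = []
        for i in range(30):
            quals = rng.integers(20, 41, size=20)
            read = make_collapsed("ACGUACGUACGUACGUACGU", count=30)
            read = read.__class__(
                sequence=read.sequence, count=30, mean_base_quality=tuple(float(q) for q in quals)
            )
            assigns.append(
                Assignment(read=read, status="unedited", hits=[Hit("h", 1)])
            )
            probs.extend([10 ** (-q / 10)] * 30 for q in quals)
        oracle = np.mean([p for chunk in probs for p in chunk]) / 3
        assert estimate_error_rate(assigns).epsilon_AG == pytest.approx(oracle)

    def test_insufficient_data_falls_back(self, caplog):
        import logging

        a = unedited_assignment("GACGAUGCUCGGCUCAGUCGA", count=1)
        with caplog.at_level(logging.WARNING, logger="miredit.calling"):
            model = estimate_error_rate([a])
        assert model.epsilon_AG == 0.001
        assert any("default epsilon" in r.message for r in caplog.records)
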