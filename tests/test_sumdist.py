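"""Sums of non-identical binomials: exact convolution and saddlepoint."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from exmort import (
    BinomialSpec,
    EventSpec,
    exact_sum_distribution,
    saddlepoint_sum,
    sum_event_probability,
)
from exmort.errors import SaddlepointError, SupportCapError
from exmort.sumdist import saddlepoint_pmf_order2


def brute_force_pmf(components):
    """Enumerate all 2^(sum n) Bernoulli outcomes; oracle for tiny sums."""
    ps = []
    for c in components:
        ps.extend([c.p] * c.n)
    pmf = np.zeros(len(ps) + 1)
    for bits in itertools.product([0, 1], repeat=len(ps)):
        pr = 1.0
        for b, p in zip(bits, ps):
            pr *= p if b else 1.0 - p
        pmf[sum(bits)] += pr
    return pmf


class TestExactConvolution:
    def test_small_identical_components_equal_plain_binomial(self):
        dist = exact_sum_distribution([BinomialSpec(2, 0.5), BinomialSpec(1, 0.5)])
        assert dist.pmf == pytest.approx([1 / 8, 3 / 8, 3 / 8, 1 / 8], abs=1e-15)

    def test_heterogeneous_against_enumeration(self):
        comps = [BinomialSpec(3, 0.2), BinomialSpec(4, 0.7), BinomialSpec(2, 0.5)]
        dist = exact_sum_distribution(comps)
        assert np.abs(dist.pmf - brute_force_pmf(comps)).max() < 1e-12

    def test_pooling_identity(self):
        comps = [BinomialSpec(37, 0.43)] * 6
        dist = exact_sum_distribution(comps)
        pooled = stats.binom.pmf(dist.support, 6 * 37, 0.43)
        assert np.abs(dist.pmf - pooled).max() < 1e-12

    def test_commutativity(self):
        comps = [BinomialSpec(11, 0.2), BinomialSpec(29, 0.8), BinomialSpec(17, 0.5)]
        a = exact_sum_distribution(comps).pmf
        b = exact_sum_distribution(comps[::-1]).pmf
        assert np.abs(a - b).max() < 1e-12

    def test_normalization_and_monotone_cdf(self):
        comps = [BinomialSpec(120, 0.31), BinomialSpec(200, 0.55), BinomialSpec(80, 0.9)]
        dist = exact_sum_distribution(comps)
        assert math.fsum(dist.pmf) == pytest.approx(1.0, abs=1e-9)
        assert (np.diff(dist.cdf) >= -1e-15).all()
        assert dist.cdf[-1] == pytest.approx(1.0, abs=1e-9)

    def test_mean_and_variance_identities(self):
        comps = [BinomialSpec(50, 0.2), BinomialSpec(70, 0.6), BinomialSpec(30, 0.9)]
        dist = exact_sum_distribution(comps)
        mean = float(dist.support @ dist.pmf)
        var = float(((dist.support - mean) ** 2) @ dist.pmf)
        assert mean == pytest.approx(dist.mean, abs=1e-8)
        assert var == pytest.approx(dist.variance, abs=1e-8)

    def test_cap_exceeded_directs_to_saddlepoint(self):
        with pytest.raises(SupportCapError, match="saddlepoint"):
            exact_sum_distribution([BinomialSpec(60_000, 0.5)] * 2)


class TestSaddlepoint:
    def test_pmf_close_to_exact_far_tail(self):
        comps = [BinomialSpec(50, 0.6)] * 5
        exact = exact_sum_distribution(comps).pmf[100]  # order 1e-10
        approx = saddlepoint_sum(comps, 100, "pmf")
        assert abs(approx / exact - 1.0) < 0.02

    def test_cdf_close_to_exact_at_mean(self):
        comps = [BinomialSpec(40, 0.5)] * 5  # pooled binomial(200, 0.5)
        exact = stats.binom.cdf(100, 200, 0.5)
        assert abs(saddlepoint_sum(comps, 100, "le") / exact - 1.0) < 0.01

    def test_integer_mean_hits_limit_branch_without_blowup(self):
        comps = [BinomialSpec(3, 0.5)] * 5  # mean 7.5; t=8 puts the saddle at 0
        exact_ge = math.fsum(exact_sum_distribution(comps).pmf[8:])
        got = saddlepoint_sum(comps, 8, "ge")
        assert np.isfinite(got)
        assert abs(got / exact_ge - 1.0) < 0.01

    @pytest.mark.parametrize(
        "comps",
        [
            [BinomialSpec(50, 0.6)] * 5,
            [BinomialSpec(50, 0.2)] * 5,
            [BinomialSpec(120, 0.31), BinomialSpec(200, 0.55),
             BinomialSpec(80, 0.9), BinomialSpec(300, 0.47)],
            [BinomialSpec(297, 0.475), BinomialSpec(297, 0.683), BinomialSpec(297, 0.431)],
        ],
    )
    def test_relative_error_under_5pct_over_full_support(self, comps):
        dist = exact_sum_distribution(comps)
        for t in dist.support:
            exact_pmf = dist.pmf[t]
            if exact_pmf > 1e-300:
                assert abs(saddlepoint_sum(comps, int(t), "pmf") / exact_pmf - 1) < 0.05
            exact_le = math.fsum(dist.pmf[: t + 1])
            if exact_le > 1e-300:
                assert abs(saddlepoint_sum(comps, int(t), "le") / exact_le - 1) < 0.05
            exact_ge = math.fsum(dist.pmf[t:])
            if exact_ge > 1e-300:
                assert abs(saddlepoint_sum(comps, int(t), "ge") / exact_ge - 1) < 0.05

    def test_second_order_correction_tightens_pmf(self):
        comps = [BinomialSpec(50, 0.6)] * 5
        exact = exact_sum_distribution(comps).pmf[130]
        err1 = abs(saddlepoint_sum(comps, 130, "pmf") / exact - 1)
        err2 = abs(saddlepoint_pmf_order2(comps, 130) / exact - 1)
        assert err2 < err1

    def test_degenerate_component_rejected(self):
        with pytest.raises(SaddlepointError, match="degenerate"):
            saddlepoint_sum([BinomialSpec(10, 1.0), BinomialSpec(10, 0.5)], 5, "pmf")

    def test_huge_support_tail_matches_pooled_binomial(self):
        """Beyond the exact cap the auto method must still be accurate: the
        pooled case has a closed form to compare against."""
        comps = [BinomialSpec(60_000, 0.3)] * 3  # support 180k > cap
        exact = float(stats.binom.sf(54_300 - 1, 180_000, 0.3))
        got = sum_event_probability(comps, EventSpec("ge", 54_300), method="auto")
        assert abs(got / exact - 1.0) < 0.01


class TestSumEvents:
    def test_eq_above_support_is_zero(self):
        comps = [BinomialSpec(5, 0.4)] * 2
        assert sum_event_probability(comps, EventSpec("eq", 11)) == 0.0

    def test_between_deep_tail_no_cancellation(self):
        comps = [BinomialSpec(50, 0.2)] * 5  # mean 50
        exact = float(
            stats.binom.cdf(110, 250, 0.2) - stats.binom.cdf(99, 250, 0.2)
        )
        got = sum_event_probability(
            comps, EventSpec("between", lo=100, hi=110), method="saddlepoint"
        )
        assert exact > 0
        assert abs(got / exact - 1.0) < 0.05

    def test_exact_and_saddlepoint_agree_on_tails(self):
        comps = [BinomialSpec(80, 0.45), BinomialSpec(60, 0.52)]
        for ev in [EventSpec("le", 55), EventSpec("ge", 75), EventSpec("gt", 80)]:
            ex = sum_event_probability(comps, ev, method="exact")
            sp = sum_event_probability(comps, ev, method="saddlepoint")
            assert abs(sp / ex - 1.0) < 0.05
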