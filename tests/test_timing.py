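"""Multiplicity assignment, CCF clustering, and gain timing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from tgctevo.model import GenomicSegment, ValidationError
from tgctevo.simulate import SegmentPlan, simulate_segment_variants
from tgctevo.timing import (
    GainTiming,
    assign_multiplicities,
    assign_multiplicity,
    cluster_ccf,
    expected_vaf,
    time_gain,
)

from conftest import make_variant


class TestExpectedVaf:
    def test_pure_diploid_heterozygous(self):
        assert expected_vaf(1, 1.0, 1.0, 2) == pytest.approx(0.5)

    def test_zero_purity_limit(self):
        assert expected_vaf(1, 1.0, 0.0, 2) == 0.0

    def test_gained_region_two_copies(self):
        assert expected_vaf(2, 1.0, 0.8, 3) == pytest.approx(1.6 / 2.8)

    def test_multiplicity_above_total_cn_rejected(self):
        with pytest.raises(ValidationError):
            expected_vaf(3, 1.0, 0.8, 2)


class TestAssignMultiplicity:
    SEG21 = GenomicSegment("1", 1, 10_000_000, 2, 1)

    def test_high_vaf_in_gain_is_early(self):
        call = assign_multiplicity(make_variant(alt_depth=57), self.SEG21, 0.8)
        assert call.multiplicity == 2
        assert call.timing_class == "early"

    def test_low_vaf_in_gain_is_late(self):
        call = assign_multiplicity(make_variant(alt_depth=29), self.SEG21, 0.8)
        assert call.multiplicity == 1
        assert call.timing_class == "late"

    def test_diploid_segment_not_informative(self):
        seg = GenomicSegment("1", 1, 10_000_000, 1, 1)
        call = assign_multiplicity(make_variant(alt_depth=40), seg, 0.8)
        assert call.timing_class == "not_informative"

    def test_missing_segment_not_informative(self):
        call = assign_multiplicity(make_variant(), None, 0.8)
        assert call.timing_class == "not_informative"

    def test_zero_depth_rejected(self):
        v = make_variant(alt_depth=0, depth=0)
        with pytest.raises(ValidationError, match="zero tumour depth"):
            assign_multiplicity(v, self.SEG21, 0.8)

    def test_agrees_with_exhaustive_likelihood_oracle(self):
        """Argmax of the binomial likelihood over m, ties to smaller m,
        recomputed independently per (alt, depth) table."""
        seg = GenomicSegment("1", 1, 10_000_000, 2, 2)
        purity = 0.7
        denom = 2 * (1 - purity) + 4 * purity
        for depth in range(1, 51):
            variants = [
                make_variant(pos=1 + alt, alt_depth=alt, depth=depth)
                for alt in range(depth + 1)
            ]
            calls = assign_multiplicities(variants, seg, purity)
            for alt, call in zip(range(depth + 1), calls):
                liks = [
                    stats.binom.pmf(alt, depth, m * purity / denom)
                    for m in (1, 2)
                ]
                expect = 1 if liks[0] >= liks[1] else 2
                assert call.multiplicity == expect, (alt, depth)

    def test_clonal_flag_tracks_ccf_interval(self):
        clonal = assign_multiplicity(make_variant(alt_depth=28), self.SEG21, 0.8)
        assert clonal.clonal
        sub = assign_multiplicity(make_variant(alt_depth=8), self.SEG21, 0.8)
        assert not sub.clonal


class TestClusterCcf:
    SEG = GenomicSegment("1", 1, 100_000_000, 1, 1)

    def _calls(self, ccfs, rng, depth=100, purity=0.9):
        f = np.clip(np.asarray(ccfs) * purity / 2.0, 0, 1)
        variants = [
            make_variant(pos=i + 1, alt_depth=int(rng.binomial(depth, fi)), depth=depth)
            for i, fi in enumerate(f)
        ]
        return assign_multiplicities(variants, self.SEG, purity)

    def test_single_clonal_cluster(self, rng):
        calls = self._calls(np.ones(200), rng)
        res = cluster_ccf(calls, purity=0.9)
        assert len(res.centres) == 1
        assert res.centres[0] == pytest.approx(1.0, abs=0.05)

    def test_two_separated_clusters_recovered(self, rng):
        calls = self._calls(np.r_[np.ones(500), np.full(500, 0.4)], rng)
        res = cluster_ccf(calls, purity=0.9)
        assert len(res.centres) == 2
        assert sorted(np.round(res.centres, 2)) == pytest.approx([0.4, 1.0], abs=0.05)
        assert res.centres[res.clonal_cluster] == pytest.approx(1.0, abs=0.05)

    def test_single_variant_single_cluster(self, rng):
        calls = self._calls([0.8], rng)
        res = cluster_ccf(calls, purity=0.9)
        assert len(res.centres) >= 1
        assert res.assignments.tolist() == [0]

    def test_no_finite_ccf_rejected(self):
        with pytest.raises(ValidationError):
            cluster_ccf([], purity=0.9)


class TestTimeGain:
    SEG22 = GenomicSegment("1", 1, 10_000_000, 2, 2)
    SEG21 = GenomicSegment("1", 1, 10_000_000, 2, 1)

    def _calls(self, seg, n2, n1, purity=0.9):
        n_t = seg.total_cn
        denom = 2 * (1 - purity) + n_t * purity
        out = []
        pos = 1
        for m, n in ((2, n2), (1, n1)):
            f = m * purity / denom
            for _ in range(n):
                v = make_variant(pos=pos, alt_depth=int(round(200 * f)), depth=200)
                pos += 1
                out.append(assign_multiplicities([v], seg, purity)[0])
        assert all(c.multiplicity == (2 if i < n2 else 1) for i, c in enumerate(out))
        return out

    def test_no_early_mutations_time_zero(self):
        gt = time_gain(self.SEG22, self._calls(self.SEG22, 0, 50))
        assert gt.t_hat == 0.0

    def test_no_late_mutations_time_one(self):
        gt = time_gain(self.SEG22, self._calls(self.SEG22, 40, 0))
        assert gt.t_hat == 1.0

    def test_two_one_closed_form(self):
        gt = time_gain(self.SEG21, self._calls(self.SEG21, 30, 240))
        assert gt.t_hat == pytest.approx(90 / 300)
        assert gt.ci_low <= gt.t_hat <= gt.ci_high

    def test_no_informative_mutations_returns_none(self):
        assert time_gain(self.SEG22, []) is None

    def test_untimeable_state_rejected(self):
        seg = GenomicSegment("1", 1, 100, 1, 1)
        with pytest.raises(ValidationError):
            time_gain(seg, [])

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        n1=st.integers(min_value=0, max_value=200),
        n2a=st.integers(min_value=0, max_value=200),
        delta=st.integers(min_value=1, max_value=50),
    )
    def test_monotone_in_early_count_and_bounded(self, n1, n2a, delta):
        """t_hat never decreases as early mutations are added, and stays
        within [0, 1]."""
        if n1 == 0 and n2a == 0:
            return
        a = time_gain(self.SEG22, self._calls(self.SEG22, n2a, n1))
        b = time_gain(self.SEG22, self._calls(self.SEG22, n2a + delta, n1))
        assert 0.0 <= a.t_hat <= 1.0
        assert b.t_hat >= a.t_hat


def test_gain_time_recovery_quick():
    """Simulated 2:1 segments at true t=0.2 recover the gain time with
    small bias (reduced-size version of the full recovery experiment)."""
    rng = np.random.default_rng(42)
    plan = SegmentPlan("2", 1, 50_000_000, 2, 1, event_time=0.2)
    seg = GenomicSegment("2", 1, 50_000_000, 2, 1)
    t_hats = []
    for rep in range(20):
        variants, _ = simulate_segment_variants(
            plan, purity=0.8, rng=rng, subclone_ccfs=(), n_informative=1000,
        )
        calls = assign_multiplicities(variants, seg, 0.8)
        t_hats.append(time_gain(seg, calls, seed=rep).t_hat)
    assert abs(np.mean(t_hats) - 0.2) <= 0.03
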