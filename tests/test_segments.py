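"""Closed-form segment-count expectations and segment-table rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

import founderfit as ff
from founderfit.segments import SegmentRecord


def rec(sample, chrom, start, end):
    return SegmentRecord(
        sample=sample, chromosome=chrom, start_cm=start, end_cm=end,
        length_cm=end - start,
    )


class TestExpectedCountsGivenTmrca:
    def test_chromosome_shorter_than_min_length(self):
        g = ff.GenomeMap((3.0,))
        assert ff.expected_counts_given_tmrca(10, g, ff.LengthBins((4.0, 15.0)))[0] == 0.0

    def test_one_morgan_chromosome_closed_form(self, tiny_genome):
        # F(0.15) - F(0.04) with a = 20, L = 1:
        # -18 e^{-3} + 20.2 e^{-0.8} = 8.18028 (verified by quadrature below)
        val = ff.expected_counts_given_tmrca(10, tiny_genome, ff.LengthBins((4.0, 15.0)))
        assert val[0] == pytest.approx(8.180278, rel=1e-6)

    def test_whole_chromosome_atom_included(self):
        g = ff.GenomeMap((5.0,))
        val = ff.expected_counts_given_tmrca(10, g, ff.LengthBins((4.0, 15.0)))
        # [F(0.05) - F(0.04)] + e^{-1}
        a, L = 20.0, 0.05
        F = lambda l: np.exp(-a * l) * (a * (l - L) - 1)
        assert val[0] == pytest.approx(F(0.05) - F(0.04) + np.exp(-1), rel=1e-9)

    def test_t_sep_below_one_rejected(self, tiny_genome):
        with pytest.raises(ValueError):
            ff.expected_counts_given_tmrca(0.5, tiny_genome, ff.LengthBins((4.0, 15.0)))

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        t=st.integers(1, 300),
        L_cm=st.floats(20.0, 300.0),
        lo=st.floats(0.5, 10.0),
        width=st.floats(0.5, 20.0),
    )
    def test_matches_numerical_quadrature(self, t, L_cm, lo, width):
        g = ff.GenomeMap((L_cm,))
        bins = ff.LengthBins((lo, lo + width))
        val = ff.expected_counts_given_tmrca(t, g, bins)[0]
        a, L = 2.0 * t, L_cm / 100.0
        hi = lo + width
        lo_m, hi_m = lo / 100.0, hi / 100.0
        if lo_m >= L:
            expected = 0.0
        else:
            expected, _ = quad(
                lambda l: (a * a * (L - l) + 2 * a) * np.exp(-a * l),
                lo_m, min(hi_m, L), epsabs=1e-13, epsrel=1e-12,
            )
            if lo_m <= L < hi_m:
                expected += np.exp(-a * L)
        assert val == pytest.approx(expected, rel=1e-8, abs=1e-12)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(t=st.integers(1, 100), L_cm=st.floats(30.0, 300.0))
    def test_total_count_identity(self, t, L_cm):
        # integrating the density over (0, L) plus the whole-chromosome atom
        # gives 1 + aL: expected segments = expected breakpoints + 1
        g = ff.GenomeMap((L_cm,))
        edges = tuple(np.linspace(0.0, L_cm + 5.0, 30))
        total = ff.expected_counts_given_tmrca(t, g, ff.LengthBins(edges)).sum()
        a, L = 2.0 * t, L_cm / 100.0
        assert total == pytest.approx(1 + a * L, rel=1e-10)

    def test_older_coalescence_gives_fewer_long_segments(self, genome, ibd_bins):
        older = ff.expected_counts_given_tmrca(80, genome, ibd_bins)
        younger = ff.expected_counts_given_tmrca(40, genome, ibd_bins)
        assert np.all(older < younger)


class TestExpectedBinCounts:
    def test_point_mass_reduces_to_conditional(self, genome, ibd_bins, study_model):
        import founderfit.demography as dem

        # degenerate PMF concentrated at u = 10
        q = np.zeros(50)
        q[9] = 1.0
        pmf = dem.CoalescentPMF(q=q, tail_mass=0.0, tail_rate=1e-4)
        lam = ff.expected_bin_counts(
            study_model, ff.SamplingSpec(), genome, ibd_bins, pair_count=1, pmf=pmf
        )
        np.testing.assert_allclose(
            lam, ff.expected_counts_given_tmrca(10, genome, ibd_bins), rtol=1e-12
        )

    def test_linear_in_pair_count(self, genome, ibd_bins, study_model):
        samp = ff.SamplingSpec()
        one = ff.expected_bin_counts(study_model, samp, genome, ibd_bins, 1)
        two = ff.expected_bin_counts(study_model, samp, genome, ibd_bins, 2)
        np.testing.assert_allclose(two, 2.0 * one, rtol=1e-12)

    def test_matches_segment_simulator(self, genome, ibd_bins, study_model):
        samp = ff.SamplingSpec()
        n_pairs = 100_000
        mat = ff.simulate_binned_counts_mc(
            study_model, samp, genome, ibd_bins, n_pairs, seed=5, max_tmrca=250
        )
        lam1 = ff.expected_bin_counts(study_model, samp, genome, ibd_bins, 1)
        mean = mat.mean(axis=0)
        se = mat.std(axis=0, ddof=1) / np.sqrt(n_pairs)
        np.testing.assert_array_less(np.abs(mean - lam1), 3 * se + 1e-9)

    def test_zero_lowest_edge_rejected(self, genome, study_model):
        with pytest.raises(ValueError):
            ff.expected_bin_counts(
                study_model, ff.SamplingSpec(), genome,
                ff.LengthBins((0.0, 4.0)), 1,
            )


class TestPairCount:
    @pytest.mark.parametrize(
        "n,mode,expected",
        [
            (1, "ibd", 0),
            (1, "roh", 1),
            (637, "ibd", 810_264),  # C(1274, 2) - 637
            (574, "roh", 574),
            (16, "roh", 16),
        ],
    )
    def test_values(self, n, mode, expected):
        assert ff.pair_count(n, mode) == expected

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            ff.pair_count(0, "ibd")


class TestMergeRohGaps:
    def test_merge_applies_with_anchor_segment(self):
        segs = [rec("s", "1", 3.0, 7.0), rec("s", "1", 7.4, 9.9)]
        out = ff.merge_roh_gaps(segs)
        assert len(out) == 1
        assert out[0].start_cm == 3.0 and out[0].end_cm == 9.9
        assert out[0].length_cm == pytest.approx(6.9)

    def test_no_merge_without_4cm_anchor(self):
        segs = [rec("s", "1", 0.0, 2.0), rec("s", "1", 2.3, 4.8)]
        assert len(ff.merge_roh_gaps(segs)) == 2

    def test_no_merge_when_gap_too_wide(self):
        segs = [rec("s", "1", 0.0, 4.0), rec("s", "1", 4.6, 7.0)]
        assert len(ff.merge_roh_gaps(segs)) == 2

    def test_no_merge_when_one_segment_short(self):
        segs = [rec("s", "1", 0.0, 5.0), rec("s", "1", 5.2, 6.2)]
        assert len(ff.merge_roh_gaps(segs)) == 2

    def test_cascading_merge_left_to_right(self):
        # after the first merge the product is long enough to anchor a
        # second merge that neither original segment could
        segs = [
            rec("s", "1", 0.0, 2.5),
            rec("s", "1", 2.9, 6.9),
            rec("s", "1", 7.2, 9.3),
        ]
        out = ff.merge_roh_gaps(segs)
        assert len(out) == 1
        assert out[0].end_cm == 9.3

    def test_idempotent(self):
        segs = [
            rec("s", "1", 0.0, 4.1),
            rec("s", "1", 4.5, 6.6),
            rec("s", "1", 9.0, 10.5),
            rec("s", "1", 20.0, 26.0),
        ]
        once = ff.merge_roh_gaps(segs)
        twice = ff.merge_roh_gaps(once)
        assert [(r.start_cm, r.end_cm) for r in once] == [
            (r.start_cm, r.end_cm) for r in twice
        ]

    def test_overlapping_input_rejected(self):
        segs = [rec("s", "1", 0.0, 5.0), rec("s", "1", 4.0, 9.0)]
        with pytest.raises(ValueError):
            ff.merge_roh_gaps(segs)


class TestFilterHighRohIndividuals:
    def test_single_long_segment_excludes(self):
        tables = {"a": [rec("a", "1", 0.0, 51.0)], "b": [rec("b", "1", 0.0, 10.0)]}
        retained, report = ff.filter_high_roh_individuals(tables)
        assert "a" not in retained and "b" in retained
        assert report[0]["sample"] == "a"

    def test_many_short_segments_retained(self):
        # fourteen 3.9-cM segments: 54.6 cM total but nothing above min_len
        segs = [rec("c", "1", 10 * i, 10 * i + 3.9) for i in range(14)]
        retained, report = ff.filter_high_roh_individuals({"c": segs})
        assert "c" in retained and not report

    def test_exactly_at_threshold_retained(self):
        tables = {"d": [rec("d", "1", 0.0, 50.0)]}
        retained, _ = ff.filter_high_roh_individuals(tables)
        assert "d" in retained


class TestBinSegments:
    def test_half_open_convention_and_drops(self, ibd_bins):
        segs = [rec("s", "1", 0, l) for l in (4.2, 4.9, 14.99, 15.0)]
        counts, dropped = ff.bin_segments(segs, ibd_bins)
        assert counts[0] == 2
        assert counts[-1] == 1
        assert dropped == 1
        assert counts.sum() + dropped == len(segs)

    def test_length_on_lower_edge(self, ibd_bins):
        counts, dropped = ff.bin_segments([rec("s", "1", 0, 5.0)], ibd_bins)
        assert counts[1] == 1 and dropped == 0

    def test_empty_input(self, ibd_bins):
        counts, dropped = ff.bin_segments([], ibd_bins)
        assert counts.sum() == 0 and dropped == 0
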