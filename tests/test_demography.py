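"""Size histories and pairwise coalescence-time distributions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import founderfit as ff
from founderfit.demography import FOUNDER, OTHER


class TestSizeAt:
    def test_epoch_boundaries_older_closed(self, study_model):
        # t = T_b belongs to the ancestral epoch, t = T_b - d to the bottleneck
        assert ff.size_at(study_model, 41.0) == 5000.0
        assert ff.size_at(study_model, 21.0) == 1563.0
        assert ff.size_at(study_model, 30.0) == 1563.0

    def test_exponential_midpoint_closed_form(self):
        m = ff.SinglePopModel(N_a=10000, N_b=100, T_b=41, d=20, N_c=10000)
        # N(10.5) = 100 * (10000/100)^{(21-10.5)/21} = 1000
        assert ff.size_at(m, 10.5) == pytest.approx(1000.0, rel=1e-12)
        assert ff.size_at(m, 0.0) == pytest.approx(10000.0)

    def test_negative_time_rejected(self, study_model):
        with pytest.raises(ValueError):
            ff.size_at(study_model, -1.0)

    def test_two_pop_split_epoch_requires_subpop(self, split_model):
        with pytest.raises(ValueError):
            ff.size_at(split_model, 30.0)
        assert ff.size_at(split_model, 30.0, subpop=FOUNDER) == 627.0
        assert ff.size_at(split_model, 30.0, subpop=OTHER) == 5000.0 - 627.0

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            ff.SinglePopModel(N_a=100, N_b=200, T_b=41, d=20, N_c=1e6)
        with pytest.raises(ValueError):
            ff.SinglePopModel(N_a=1000, N_b=100, T_b=10, d=20, N_c=1e6)
        with pytest.raises(ValueError):
            ff.TwoPopModel(N_a=500, N_b=500, T_b=41, d=20, N_c=1e6, f=0.5)


class TestCoalescentPMF:
    def test_constant_size_is_geometric(self):
        N = 500.0
        m = ff.SinglePopModel(N_a=N, N_b=N, T_b=41, d=20, N_c=N)
        pmf = ff.coalescent_pmf(m, ff.SamplingSpec(), U_max=200)
        u = np.arange(1, 201)
        geo = (1 / (2 * N)) * (1 - 1 / (2 * N)) ** (u - 1)
        np.testing.assert_allclose(pmf.q, geo, rtol=1e-13)
        assert pmf.tail_mass == pytest.approx((1 - 1 / (2 * N)) ** 200, rel=1e-12)

    def test_no_recent_coalescence_shifts_mass(self):
        m = ff.SinglePopModel(N_a=500, N_b=500, T_b=41, d=20, N_c=500)
        pmf = ff.coalescent_pmf(m, ff.SamplingSpec(mode="roh"), U_max=100)
        assert pmf.q[0] == 0.0 and pmf.q[1] == 0.0
        assert pmf.q[2] == pytest.approx(1 / 1000, abs=1e-15)

    def test_degenerate_size_rejected(self):
        m = ff.SinglePopModel(N_a=1000, N_b=1000, T_b=41, d=20, N_c=1000)
        bad = ff.SinglePopModel(N_a=1000, N_b=0.6, T_b=41, d=20, N_c=1000)
        ff.coalescent_pmf(m, ff.SamplingSpec(), U_max=100)
        with pytest.raises(ValueError):
            ff.coalescent_pmf(bad, ff.SamplingSpec(), U_max=100)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        n_a=st.floats(500, 20000),
        n_b_frac=st.floats(0.05, 1.0),
        t_b=st.integers(25, 80),
        d=st.integers(1, 20),
        n_c=st.floats(1e4, 1e7),
        t_s=st.sampled_from([0.0, 26.0]),
        mode=st.sampled_from(["ibd", "roh"]),
    )
    def test_normalization_property(self, n_a, n_b_frac, t_b, d, n_c, t_s, mode):
        m = ff.SinglePopModel(
            N_a=n_a, N_b=max(50.0, n_a * n_b_frac), T_b=t_b, d=d,
            N_c=max(n_c, n_a),
        )
        pmf = ff.coalescent_pmf(m, ff.SamplingSpec(sample_time=t_s, mode=mode), U_max=2000)
        assert pmf.total_mass() == pytest.approx(1.0, abs=1e-10)

    def test_halving_bottleneck_size_concentrates_mass(self, study_model):
        samp = ff.SamplingSpec()
        narrow = ff.SinglePopModel(
            N_a=study_model.N_a, N_b=study_model.N_b / 2,
            T_b=study_model.T_b, d=study_model.d, N_c=study_model.N_c,
        )
        lo = int(study_model.T_b - study_model.d)
        hi = int(study_model.T_b)
        wide_pmf = ff.coalescent_pmf(study_model, samp, U_max=500)
        narrow_pmf = ff.coalescent_pmf(narrow, samp, U_max=500)
        assert narrow_pmf.q[lo:hi].sum() >= wide_pmf.q[lo:hi].sum()

    def test_matches_lineage_monte_carlo(self):
        from _lineage_oracle import mc_lineage_pmf

        m = ff.SinglePopModel(N_a=40, N_b=15, T_b=20, d=8, N_c=120)
        samp = ff.SamplingSpec()
        u_max = 300
        pmf = ff.coalescent_pmf(m, samp, U_max=u_max)
        n = 1_000_000
        counts, beyond = mc_lineage_pmf(m, samp, u_max, n, seed=42)
        # compare cumulative mass at a few horizons within binomial error
        for h in (5, 12, 20, 50, 150, 300):
            p = pmf.q[:h].sum()
            se = np.sqrt(p * (1 - p) / n)
            assert counts[:h].sum() / n == pytest.approx(p, abs=4 * se + 1e-9)
        assert beyond / n == pytest.approx(pmf.tail_mass, abs=4 * np.sqrt(pmf.tail_mass / n))


class TestTwoPopPMF:
    def test_f_near_one_matches_single_population(self, split_model):
        # f -> 1 puts both lineages in the founder subgroup: identical to
        # the single-population model with N_b during the split epoch
        m = ff.TwoPopModel(N_a=5000, N_b=627, T_b=46, d=22, N_c=1e6,
                           f=1 - 1e-13, N_g=627)
        single = ff.SinglePopModel(N_a=5000, N_b=627, T_b=46, d=22, N_c=1e6)
        samp = ff.SamplingSpec()
        p2 = ff.two_pop_coalescent_pmf(m, samp, U_max=2000)
        p1 = ff.coalescent_pmf(single, samp, U_max=2000)
        np.testing.assert_allclose(p2.q, p1.q, atol=1e-12)
        assert p2.tail_mass == pytest.approx(p1.tail_mass, abs=1e-12)

    def test_roh_assignment_forced_in_split_epoch(self, split_model):
        samp = ff.SamplingSpec(sample_time=26.0, mode="roh")
        with pytest.raises(ValueError):
            ff.two_pop_coalescent_pmf(split_model, samp, U_max=2000)

    def test_ancient_sampling_inside_split_epoch(self, split_model):
        # sampled at 26 gbp inside the split epoch [24, 46): the founder
        # lineages feel hazard 1/(2*627) until the ancestral epoch
        samp = ff.SamplingSpec(sample_time=26.0, mode="roh", subpop_assignment=FOUNDER)
        pmf = ff.two_pop_coalescent_pmf(split_model, samp, U_max=2000)
        h = 1 / (2 * 627)
        # u = 3 is the first generation with non-zero hazard (no sib mating)
        assert pmf.q[2] == pytest.approx(h, rel=1e-12)
        assert pmf.total_mass() == pytest.approx(1.0, abs=1e-10)

    def test_normalization(self, split_model):
        for samp in (
            ff.SamplingSpec(),
            ff.SamplingSpec(sample_time=26.0, mode="roh", subpop_assignment=OTHER),
        ):
            pmf = ff.two_pop_coalescent_pmf(split_model, samp, U_max=3000)
            assert pmf.total_mass() == pytest.approx(1.0, abs=1e-10)

    def test_split_state_mass_structure(self):
        # With a huge "other" subgroup, coalescence during the split epoch is
        # dominated by the both-in-founder state: mass ~ f^2 x epoch mass
        m = ff.TwoPopModel(N_a=1e6, N_b=200, T_b=46, d=22, N_c=1e6, f=0.52, N_g=1e6)
        samp = ff.SamplingSpec()
        pmf = ff.two_pop_coalescent_pmf(m, samp, U_max=500)
        # split epoch covers generations u = 24..45 (t = u, epoch [24, 46))
        epoch_mass = pmf.q[23:45].sum()
        h = 1 / (2 * 200)
        # survival to the split epoch is ~1 (merged epoch huge)
        surv = (1 - h) ** np.arange(22)
        expected = 0.52**2 * (h * surv).sum()
        assert epoch_mass == pytest.approx(expected, rel=1e-3)

    def test_matches_lineage_monte_carlo(self):
        from _lineage_oracle import mc_lineage_pmf

        m = ff.TwoPopModel(N_a=60, N_b=12, T_b=25, d=10, N_c=200, f=0.6, N_g=12)
        samp = ff.SamplingSpec()
        u_max = 400
        pmf = ff.two_pop_coalescent_pmf(m, samp, U_max=u_max)
        n = 1_000_000
        counts, beyond = mc_lineage_pmf(m, samp, u_max, n, seed=11)
        for h in (10, 16, 20, 25, 60, 200):
            p = pmf.q[:h].sum()
            se = np.sqrt(p * (1 - p) / n)
            assert counts[:h].sum() / n == pytest.approx(p, abs=4 * se + 1e-9)
        assert beyond / n == pytest.approx(
            pmf.tail_mass, abs=4 * np.sqrt(max(pmf.tail_mass, 1e-12) / n) + 1e-9
        )


class TestConsanguinity:
    def test_identity_at_zero_fraction(self, study_model):
        samp = ff.SamplingSpec(mode="roh")
        pmf = ff.coalescent_pmf(study_model, samp, U_max=500)
        out = ff.apply_consanguinity(pmf, samp)
        np.testing.assert_array_equal(out.q, pmf.q)

    def test_full_consanguinity_mixture(self, study_model):
        samp = ff.SamplingSpec(mode="roh")
        base = ff.coalescent_pmf(study_model, samp, U_max=500)
        mixed = ff.apply_consanguinity(
            base, ff.SamplingSpec(mode="roh", consanguinity_fraction=1.0)
        )
        # q(3) gains 1/16; everything else scales by 15/16
        assert mixed.q[2] == pytest.approx(base.q[2] * 15 / 16 + 1 / 16, rel=1e-12)
        np.testing.assert_allclose(mixed.q[3:], base.q[3:] * 15 / 16, rtol=1e-12)
        assert mixed.total_mass() == pytest.approx(1.0, abs=1e-10)

    def test_half_fraction_preserves_normalization(self, study_model):
        samp = ff.SamplingSpec(mode="roh", consanguinity_fraction=0.5)
        pmf = ff.coalescent_pmf(study_model, samp, U_max=500)
        assert pmf.total_mass() == pytest.approx(1.0, abs=1e-10)

    def test_rejected_for_ibd_mode(self):
        with pytest.raises(ValueError):
            ff.SamplingSpec(mode="ibd", consanguinity_fraction=0.1)
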