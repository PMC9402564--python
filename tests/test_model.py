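"""Unit tests for the core model equations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from afhomeo import (
    ModelParams,
    dispersion_coefficients_closed_form,
    dispersion_coefficients_literal_sum,
    dispersion_entropy,
    expected_force,
    force_law,
    force_law_eval,
    formation_entropy,
    stationary_distribution,
    total_coverage,
    total_entropy,
)
from afhomeo.model import length_grid
from afhomeo.oracle import exact_log_states


class TestForceLaw:
    def test_midpoint_gives_half_maximum(self):
        p = ModelParams()
        assert force_law_eval(80, p) == pytest.approx(0.5e-12, rel=1e-12)

    def test_saturation_far_above_midpoint(self):
        p = ModelParams()
        assert force_law_eval(1000, p) == pytest.approx(1e-12, rel=1e-12)

    def test_short_filament_matches_high_precision_value(self):
        # 1e-12 / (1 + e^79), frozen from a 50-digit mpmath evaluation
        expected = 4.9060947306492806e-47
        p = ModelParams()
        assert force_law_eval(1, p) == pytest.approx(expected, rel=1e-12)

    def test_strictly_increasing_and_bounded(self):
        p = ModelParams()
        f = force_law(np.arange(1, 501), p)
        # strict increase is resolvable in double precision up to ~l0 + 36;
        # beyond that the sigmoid saturates to f0 at working precision
        assert np.all(np.diff(f[:110]) > 0)
        assert np.all(np.diff(f) >= 0)
        assert np.all(f > 0) and np.all(f <= p.f0)

    def test_rejects_index_below_one(self):
        with pytest.raises(ValueError):
            force_law_eval(0, ModelParams())

    def test_rejects_non_finite_parameters(self):
        with pytest.raises(ValueError):
            ModelParams(f0=float("nan"))
        with pytest.raises(ValueError):
            ModelParams(l0=float("inf"))


class TestDispersionCoefficients:
    @pytest.mark.parametrize("a,m,expected", [
        (10, 1, [1]),
        (10, 12, [1, 2, 2, 2, 2, 2, 2, 2, 2, 2, 2, 3]),
        (1, 4, [1, 2, 3, 4]),
        (2, 2, [1, 2]),
    ])
    def test_closed_form_examples(self, a, m, expected):
        geom = dispersion_coefficients_closed_form(a, m)
        assert geom.A.tolist() == expected

    def test_literal_sum_block_boundaries(self):
        # block j=1 covers classes 2..1+a, so the coefficient at i=11 is 2
        assert dispersion_coefficients_literal_sum(10, 11).A[-1] == 2
        A = dispersion_coefficients_literal_sum(10, 22).A
        assert np.all(A[11:21] == 3) and A[21] == 4

    @settings(derandomize=True, max_examples=60)
    @given(a=st.integers(1, 20), m=st.integers(1, 300))
    def test_closed_form_equals_literal_sum(self, a, m):
        A1 = dispersion_coefficients_closed_form(a, m).A
        A2 = dispersion_coefficients_literal_sum(a, m).A
        assert np.array_equal(A1, A2)

    @pytest.mark.parametrize("a", [1, 3, 10])
    def test_nondecreasing_with_unit_steps_every_a(self, a):
        A = dispersion_coefficients_closed_form(a, 200).A
        steps = np.diff(A)
        assert np.all((steps == 0) | (steps == 1))
        jumps = np.flatnonzero(steps == 1)
        assert np.all(np.diff(jumps) == a)

    def test_coverage_per_length_converges_to_reciprocal_a(self):
        for m in (100, 250, 1000):
            geom = dispersion_coefficients_closed_form(10, m)
            assert abs(geom.A[-1] / m - 0.1) <= 2.0 / m

    def test_rejects_bad_arguments(self):
        with pytest.raises(ValueError):
            dispersion_coefficients_closed_form(0, 10)
        with pytest.raises(ValueError):
            dispersion_coefficients_literal_sum(5, 0)


class TestTotalCoverage:
    def test_all_monomers_in_class_one(self):
        geom = dispersion_coefficients_closed_form(10, 5)
        n = np.array([1000.0, 0, 0, 0, 0])
        assert total_coverage(n, geom) == pytest.approx(1000.0)

    def test_all_monomers_in_class_two(self):
        # A_2 = 2 and l_2 = 2, so coverage equals N again
        geom = dispersion_coefficients_closed_form(10, 5)
        n = np.array([0.0, 1000.0, 0, 0, 0])
        assert total_coverage(n, geom, length_grid(5)) == pytest.approx(1000.0)

    def test_empty_cell(self):
        geom = dispersion_coefficients_closed_form(10, 3)
        assert total_coverage(np.zeros(3), geom) == 0.0

    def test_rejects_negative_counts(self):
        geom = dispersion_coefficients_closed_form(10, 3)
        with pytest.raises(ValueError):
            total_coverage(np.array([1.0, -1.0, 0.0]), geom)


class TestEntropies:
    def test_formation_entropy_uniform_maximum(self):
        p = ModelParams(m=100)
        uniform = np.full(100, 0.01)
        expected = p.kb * p.N * math.log(100)
        assert formation_entropy(uniform, p) == pytest.approx(expected,
                                                              rel=1e-12)

    def test_formation_entropy_concentrated_is_zero(self):
        p = ModelParams(m=4)
        conc = np.array([0.0, 1.0, 0.0, 0.0])
        assert formation_entropy(conc, p) == 0.0

    def test_stirling_form_vs_exact_count_small_N(self):
        # N=6 split (2,4): Stirling form overshoots the exact ln W = ln 15
        p = ModelParams(N=6, m=2)
        prob = np.array([1 / 3, 2 / 3])
        s_over_kb = formation_entropy(prob, p) / p.kb
        assert s_over_kb == pytest.approx(3.8190850, rel=1e-6)
        assert exact_log_states([2, 4]) == pytest.approx(math.log(15),
                                                         rel=1e-12)
        assert s_over_kb > exact_log_states([2, 4])

    def test_rejects_unnormalized(self):
        with pytest.raises(ValueError):
            formation_entropy(np.array([0.5, 0.4]), ModelParams(m=2))

    def test_dispersion_entropy_single_class(self):
        p = ModelParams(m=1, kb_ratio=3.0)
        geom = dispersion_coefficients_closed_form(p.a, 1)
        expected = p.kb_prime * p.N
        assert dispersion_entropy(np.array([1.0]), p, geom) == pytest.approx(
            expected, rel=1e-12)

    def test_dispersion_entropy_uniform_two_classes(self):
        # A_2/l_2 = 1 as well, so the value is kb'*N regardless of the split
        p = ModelParams(m=2, kb_ratio=2.0)
        geom = dispersion_coefficients_closed_form(10, 2)
        val = dispersion_entropy(np.array([0.5, 0.5]), p, geom)
        assert val == pytest.approx(p.kb_prime * p.N, rel=1e-12)

    def test_dispersion_entropy_long_filament(self):
        # A_1000 = floor(998/10) + 2 = 101
        p = ModelParams(kb_ratio=1.0, m=1000)
        geom = dispersion_coefficients_closed_form(10, 1000)
        prob = np.zeros(1000)
        prob[-1] = 1.0
        val = dispersion_entropy(prob, p, geom)
        assert val == pytest.approx(p.kb_prime * p.N * 101 / 1000, rel=1e-12)

    def test_total_entropy_decomposition(self, default_params, default_geom):
        dist = stationary_distribution(default_params, default_geom)
        rep = total_entropy(dist.p, default_params, default_geom)
        assert rep.S == rep.S_f + rep.S_d
        assert rep.S_f >= 0
        assert 0 < rep.F < default_params.f0

    def test_total_entropy_without_dispersion(self):
        p = ModelParams(kb_ratio=0.0, m=50)
        geom = dispersion_coefficients_closed_form(p.a, 50)
        prob = np.full(50, 0.02)
        rep = total_entropy(prob, p, geom)
        assert rep.S == rep.S_f and rep.S_d == 0.0


class TestExpectedForce:
    def test_concentrated_at_midpoint(self):
        p = ModelParams(m=100)
        prob = np.zeros(100)
        prob[79] = 1.0  # class index 80 = l0
        assert expected_force(prob, p) == pytest.approx(p.f0 / 2, rel=1e-12)

    def test_saturated_limit(self):
        p = ModelParams(l0=5.0, m=500)
        prob = np.zeros(500)
        prob[400:] = 0.01  # all mass far above l0
        assert expected_force(prob, p) == pytest.approx(p.f0, rel=1e-10)

    def test_matches_high_precision_composition(self, default_params):
        # frozen from a 50-digit evaluation of sum p_i f_i at the
        # stationary distribution with kb'/kb = 4
        import mpmath as mp

        from afhomeo import stationary_distribution_mp
        dist = stationary_distribution(default_params)
        val = expected_force(dist.p, default_params)
        p_mp, f_mp = stationary_distribution_mp(default_params, dps=50)
        with mp.workdps(50):
            ref = float(mp.fsum(pi * fi for pi, fi in zip(p_mp, f_mp)))
        assert val == pytest.approx(ref, rel=1e-12)


class TestStationaryDistribution:
    def test_single_class(self):
        dist = stationary_distribution(ModelParams(m=1))
        assert dist.p.tolist() == [1.0]

    def test_negligible_exponents_give_uniform(self):
        # kb' = 0 and f0 = 1 pN: exponent magnitude ~1e-11
        p = ModelParams(kb_ratio=0.0, f0=1e-12, m=100)
        dist = stationary_distribution(p)
        assert np.all(np.abs(dist.p - 0.01) < 1e-9)

    def test_monomer_counts_sum_to_N(self, default_params):
        dist = stationary_distribution(default_params)
        assert abs(dist.n.sum() - default_params.N) <= default_params.N * 1e-12

    def test_log_partition_consistent_with_p(self, default_params):
        dist = stationary_distribution(default_params)
        np.testing.assert_allclose(np.exp(dist.log_p), dist.p, rtol=1e-12)

    def test_monotone_skew_in_dispersion_weight(self):
        p1_low = stationary_distribution(ModelParams(kb_ratio=1.0)).p[0]
        p1_high = stationary_distribution(ModelParams(kb_ratio=10.0)).p[0]
        assert p1_high > p1_low

    @settings(derandomize=True, max_examples=40)
    @given(
        ratio=st.floats(0.0, 15.0),
        f0=st.floats(1e-12, 1.0),
        lam=st.floats(0.0, 1.0),
        a=st.integers(1, 20),
        m=st.integers(1, 400),
        l0=st.floats(1.0, 150.0),
    )
    def test_normalization_property(self, ratio, f0, lam, a, m, l0):
        p = ModelParams(kb_ratio=ratio, f0=f0, lam=lam, a=a, m=m, l0=l0)
        dist = stationary_distribution(p)
        assert abs(dist.p.sum() - 1.0) <= 1e-12
        assert np.all(dist.p >= 0)

    def test_m_cannot_exceed_N(self):
        with pytest.raises(ValueError):
            ModelParams(N=100, m=101)

    def test_force_suppresses_long_classes(self):
        # raising f0 to 1 N depletes classes longer than l0
        base = ModelParams(kb_ratio=4.0)
        lo = stationary_distribution(base.with_(f0=1e-12)).p
        hi = stationary_distribution(base.with_(f0=1.0)).p
        idx = np.arange(1, base.m + 1)
        above = idx > base.l0
        assert hi[above].mean() < lo[above].mean()

    def test_kbprime_zero_high_force_two_plateaus(self):
        # pure formation entropy + strong force: flat below l0, flat and
        # lower above l0
        p = ModelParams(kb_ratio=0.0, f0=1.0, m=200)
        dist = stationary_distribution(p)
        # the force exponent varies by ~14 e^(i-l0) in the short tail, so
        # 1e-6 flatness needs l0 - i > ln(1.4e7) ~ 17 classes of margin
        idx = np.arange(1, 201)
        short = dist.p[idx < p.l0 - 20]
        long_ = dist.p[idx > p.l0 + 20]
        assert short.max() / short.min() - 1 < 1e-6
        assert long_.max() / long_.min() - 1 < 1e-6
        assert short.mean() > long_.mean()
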