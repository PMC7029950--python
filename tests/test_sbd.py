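"""Single-species chain: generator structure, solvers, closed forms."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neutraldebt import (
    InvalidParameterError,
    ModelParams,
    NumericalError,
    build_generator,
    converge_truncation,
    extinction_cdf_closed,
    extinction_prob,
    extinction_prob_profile,
    pgf_closed_form,
    solve_distribution,
    stationary_empty_prob,
    survival_prob,
)
from neutraldebt.sbd import _p0_matrix


class TestModelParams:
    @pytest.mark.parametrize("kwargs", [{"u": -0.1}, {"u": 1.0}, {"u": 1.5}, {"v": -1e-9}])
    def test_invalid_rates_rejected(self, kwargs):
        with pytest.raises(InvalidParameterError):
            ModelParams(**kwargs)

    def test_unknown_variant_rejected(self):
        with pytest.raises(InvalidParameterError):
            ModelParams(variant="nope")


class TestGenerator:
    def test_printed_matrix_pattern(self):
        # row 0: (-v, 1, 0); row 1: (v, -(2-u), 2); row m: ((m-1)(1-u), -m(2-u))
        G = build_generator(ModelParams(u=0.0, v=0.0), 2).to_dense()
        expected = np.array([[0.0, 1.0, 0.0], [0.0, -2.0, 2.0], [0.0, 1.0, -4.0]])
        np.testing.assert_allclose(G, expected)

    def test_printed_entries_with_rates(self):
        G = build_generator(ModelParams(u=0.01, v=0.02), 3).to_dense()
        assert G[1, 0] == pytest.approx(0.02)
        assert G[1, 1] == pytest.approx(-1.99)
        assert G[2, 1] == pytest.approx(0.99)
        assert G[0, 0] == pytest.approx(-0.02)
        assert G[2, 3] == pytest.approx(3.0)

    @pytest.mark.parametrize("u,v,m", [(0.0, 0.0, 5), (0.01, 0.02, 8), (0.2, 0.1, 4)])
    def test_leaky_column_sums(self, u, v, m):
        # interior columns conserve; the top column leaks the birth rate m(1-u)
        G = build_generator(ModelParams(u=u, v=v), m).to_dense()
        sums = G.sum(axis=0)
        np.testing.assert_allclose(sums[:-1], 0.0, atol=1e-12)
        assert sums[-1] == pytest.approx(-m * (1.0 - u))

    def test_reflecting_conserves_all_columns(self):
        G = build_generator(ModelParams(u=0.05, v=0.1), 6, boundary="reflecting").to_dense()
        np.testing.assert_allclose(G.sum(axis=0), 0.0, atol=1e-12)

    def test_tridiagonal_sign_structure(self):
        G = build_generator(ModelParams(u=0.1, v=0.05), 10).to_dense()
        assert np.all(np.diag(G) <= 0)
        off = G - np.diag(np.diag(G))
        assert np.all(off >= 0)
        # no entries beyond the first off-diagonals
        assert np.all(np.triu(G, 2) == 0) and np.all(np.tril(G, -2) == 0)

    @pytest.mark.parametrize("m", [0, 1, -3])
    def test_invalid_truncation(self, m):
        with pytest.raises(InvalidParameterError):
            build_generator(ModelParams(), m)


class TestSolveDistribution:
    def test_t0_is_point_mass(self):
        gen = build_generator(ModelParams(u=0.01, v=0.02), 20)
        sd = solve_distribution(gen, 5, 0.0)
        expected = np.zeros(21)
        expected[5] = 1.0
        np.testing.assert_allclose(sd.probs, expected)

    def test_j0_outside_truncation(self):
        gen = build_generator(ModelParams(), 10)
        with pytest.raises(InvalidParameterError):
            solve_distribution(gen, 11, 1.0)

    def test_pure_drift_p0_matches_closed_form(self):
        gen = build_generator(ModelParams(), 512)
        sd = solve_distribution(gen, 1, 1.0)
        assert sd.p0 == pytest.approx(0.5, abs=1e-10)

    def test_leaky_mass_deficit_nonnegative_and_grows(self):
        gen = build_generator(ModelParams(), 16)  # deliberately tight truncation
        masses = [solve_distribution(gen, 4, t).mass for t in (0.5, 2.0, 8.0)]
        assert all(m <= 1 + 1e-12 for m in masses)
        assert masses[0] >= masses[1] >= masses[2]

    def test_reflecting_conserves_mass(self):
        gen = build_generator(ModelParams(u=0.02, v=0.05), 256, boundary="reflecting")
        sd = solve_distribution(gen, 3, 5.0)
        assert sd.mass == pytest.approx(1.0, abs=1e-10)

    def test_spectral_agrees_with_dense_expm(self):
        import scipy.linalg

        gen = build_generator(ModelParams(u=0.05, v=0.1), 60)
        direct = scipy.linalg.expm(gen.to_dense() * 3.0)
        sd = solve_distribution(gen, 7, 3.0)
        np.testing.assert_allclose(sd.probs, direct[:, 7], atol=1e-12)


class TestExtinctionProb:
    def test_hand_value_pure_drift(self):
        # (t/(1+t))^j at t=1, j=2
        assert extinction_prob(ModelParams(), 2, 1.0) == pytest.approx(0.25)

    def test_emigration_longtime_limit_is_one(self):
        assert extinction_prob(ModelParams(u=0.05), 1, 1e6) == pytest.approx(1.0, abs=1e-8)

    def test_empty_start_no_immigration_stays_empty(self):
        ts = np.array([0.0, 1.0, 100.0])
        np.testing.assert_allclose(extinction_prob(ModelParams(), 0, ts), 1.0)

    @pytest.mark.parametrize("u", [0.0, 0.01, 0.1, 0.2])
    def test_closed_form_equals_matrix_route(self, u):
        # two independent routes of this module agree to 1e-8
        params = ModelParams(u=u)
        ts = np.array([0.1, 1.0, 10.0])
        m = converge_truncation(params, 4, 10.0)
        closed = extinction_cdf_closed(u, 4, ts)
        matrix = _p0_matrix(params, 4, ts, 2 * m)
        np.testing.assert_allclose(matrix, closed, atol=1e-8)

    def test_monotone_decreasing_in_j0(self):
        params = ModelParams(u=0.02, v=0.05)
        vals = [extinction_prob(params, j, 5.0, m=256) for j in (1, 2, 5, 10)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_emigration_raises_and_immigration_lowers_risk(self):
        t = 10.0
        base = extinction_prob(ModelParams(u=0.01, v=0.01), 3, t, m=256)
        more_u = extinction_prob(ModelParams(u=0.1, v=0.01), 3, t, m=256)
        more_v = extinction_prob(ModelParams(u=0.01, v=0.2), 3, t, m=256)
        assert more_u > base
        assert more_v < base

    def test_survival_is_complement(self):
        params = ModelParams(u=0.01, v=0.02)
        p0 = extinction_prob(params, 2, 3.0, m=128)
        assert survival_prob(params, 2, 3.0, m=128) == pytest.approx(1.0 - p0)

    def test_survival_one_at_t0(self):
        assert survival_prob(ModelParams(u=0.1, v=0.3), 4, 0.0, m=64) == pytest.approx(1.0)

    def test_immigration_helps_survival_at_long_times(self):
        # state-0 re-seeding keeps the species around
        s_with = survival_prob(ModelParams(u=0.0, v=0.2), 1, 50.0, m=1024)
        s_without = survival_prob(ModelParams(u=0.0, v=0.0), 1, 50.0)
        assert s_with > s_without

    def test_stationary_limit_matches_spectral(self):
        params = ModelParams(u=0.1, v=0.05)
        lim = stationary_empty_prob(params)
        val = extinction_prob(params, 2, 2000.0, m=512)
        assert val == pytest.approx(lim, abs=1e-6)


class TestPGF:
    def test_normalization_at_z1(self):
        for u in (0.0, 0.05, 0.3):
            assert pgf_closed_form(u, 1.0, 7.3, 5) == pytest.approx(1.0)

    def test_z0_gives_extinction_probability(self):
        np.testing.assert_allclose(
            pgf_closed_form(0.0, 0.0, 2.0, 3), (2.0 / 3.0) ** 3, rtol=1e-12
        )

    def test_matches_series_from_matrix_solution(self):
        # H(z,t) = sum_n z^n p_n(t) with p_n from the truncated generator
        u, z, t, j0 = 0.05, 0.3, 2.0, 2
        gen = build_generator(ModelParams(u=u), 256)
        probs = solve_distribution(gen, j0, t).probs
        series = np.sum(probs * z ** np.arange(probs.size))
        assert pgf_closed_form(u, z, t, j0) == pytest.approx(series, abs=1e-6)

    def test_domain_error_outside_unit_interval(self):
        with pytest.raises(InvalidParameterError):
            pgf_closed_form(0.1, 1.5, 1.0, 2)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        u=st.floats(0.0, 0.5),
        z=st.floats(0.0, 1.0),
        t=st.floats(0.01, 50.0),
        j0=st.integers(0, 20),
    )
    def test_pgf_bounded_and_monotone_in_z(self, u, z, t, j0):
        val = pgf_closed_form(u, z, t, j0)
        assert 0.0 <= val <= 1.0 + 1e-12
        assert val >= pgf_closed_form(u, z * 0.5, t, j0) - 1e-12


class TestConvergeTruncation:
    def test_converged_m_matches_closed_form(self):
        params = ModelParams()
        m = converge_truncation(params, 1, 1.0, tol=1e-8)
        val = _p0_matrix(params, 1, np.array([1.0]), m)[0]
        assert val == pytest.approx(0.5, abs=1e-7)

    def test_absorbing_empty_start_returns_initial_guess(self):
        assert converge_truncation(ModelParams(), 0, 100.0, m0=8) == 8

    def test_self_consistency_large_j0(self):
        params = ModelParams(u=0.01, v=0.02)
        m = converge_truncation(params, 50, 100.0, tol=1e-8)
        assert m >= 50
        ts = np.array([25.0, 100.0])
        a = _p0_matrix(params, 50, ts, m)
        b = _p0_matrix(params, 50, ts, min(4 * m, 5000))
        np.testing.assert_allclose(a, b, atol=5e-8)

    def test_nonpositive_tolerance_rejected(self):
        with pytest.raises(InvalidParameterError):
            converge_truncation(ModelParams(), 1, 1.0, tol=0.0)


class TestNumericalGuards:
    def test_negative_probability_raises(self):
        from neutraldebt.sbd import _clip_probs

        with pytest.raises(NumericalError):
            _clip_probs(np.array([0.5, -1e-6]))

    def test_tiny_negative_clipped(self):
        from neutraldebt.sbd import _clip_probs

        out = _clip_probs(np.array([0.5, -1e-13]))
        assert out[1] == 0.0


@settings(deadline=None, derandomize=True, max_examples=20)
@given(
    u=st.floats(0.0, 0.3),
    j0=st.integers(1, 10),
    t=st.floats(0.05, 20.0),
)
def test_extinction_cdf_is_a_cdf_in_t(u, j0, t):
    """p0(t|j0) for v=0 is a hitting-time CDF: in [0,1] and non-decreasing."""
    a = float(extinction_cdf_closed(u, j0, t))
    b = float(extinction_cdf_closed(u, j0, 2.0 * t))
    assert 0.0 <= a <= b <= 1.0


def test_profile_matches_per_j_solves():
    params = ModelParams(u=0.02, v=0.05)
    ts = np.array([0.5, 2.0, 8.0])
    prof = extinction_prob_profile(params, ts, 128, j_max=6)
    gen = build_generator(params, 128)
    for j in range(7):
        per_j = [solve_distribution(gen, j, t).p0 for t in ts]
        np.testing.assert_allclose(prof[:, j], per_j, atol=1e-10)
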