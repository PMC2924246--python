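"""Analytic hard-rod gas: Erlang terms, barrier density, pair distribution."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

import nucbarrier as nb
from nucbarrier.tonks import barrier_density_binned, normalize_kernel


def brute_erlang_sum(x, b=147.0, dbar=177.0):
    """Independent re-evaluation of the finite Erlang sum, term by term.

    Plain powers/factorials (math.factorial), no log-space tricks: the
    oracle for the vectorized implementation.
    """
    ell = dbar - b
    total = 0.0
    k = 1
    while k * b <= x:
        dx = x - k * b
        total += dx ** (k - 1) * math.exp(-dx / ell) / (ell**k * math.factorial(k - 1))
        k += 1
    return total


class TestErlangTerm:
    def test_zero_left_of_support(self, tonks_params):
        assert nb.erlang_term(1, 100.0, tonks_params) == 0.0
        assert nb.erlang_term(3, 440.0, tonks_params) == 0.0

    def test_contact_value_is_inverse_mean_gap(self, tonks_params):
        assert nb.erlang_term(1, 147.0, tonks_params) == pytest.approx(1 / 30)

    @pytest.mark.parametrize("k", [1, 2, 3, 4, 5])
    def test_unit_mass_and_mean(self, k, tonks_params):
        norm, _ = quad(
            lambda t: nb.erlang_term(k, t, tonks_params), 0, 8000, limit=400
        )
        mean, _ = quad(
            lambda t: t * nb.erlang_term(k, t, tonks_params), 0, 8000, limit=400
        )
        assert norm == pytest.approx(1.0, abs=1e-6)
        assert mean == pytest.approx(k * 177.0, rel=1e-6)

    def test_rejects_bad_k(self, tonks_params):
        with pytest.raises(ValueError):
            nb.erlang_term(0, 100.0, tonks_params)

    @given(
        k=st.integers(min_value=1, max_value=8),
        x=st.floats(min_value=0, max_value=5000, allow_nan=False),
        dbar=st.floats(min_value=150, max_value=300),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_nonnegative_with_heaviside_support(self, k, x, dbar):
        tp = nb.TonksParams(b=147.0, dbar=dbar)
        v = nb.erlang_term(k, x, tp)
        assert v >= 0.0
        if x < k * 147.0:
            assert v == 0.0


class TestBarrierDensity:
    def test_depletion_layer(self, tonks_params):
        assert nb.barrier_density(100.0, tonks_params) == 0.0
        assert np.all(
            np.asarray(nb.barrier_density(np.arange(0.0, 147.0), tonks_params)) == 0.0
        )

    def test_first_layer_closed_form(self, tonks_params):
        # only k=1 contributes below 2b
        expected = (1 / 30) * math.exp(-13 / 30)
        assert nb.barrier_density(160.0, tonks_params) == pytest.approx(expected)

    def test_contact_discontinuity(self, tonks_params):
        assert nb.barrier_density(147.0, tonks_params) == pytest.approx(1 / 30)

    def test_asymptote(self, tonks_params):
        x = np.arange(30 * 177.0, 30 * 177.0 + 500.0)
        r = np.asarray(nb.barrier_density(x, tonks_params))
        assert np.all(np.abs(r - 1 / 177) < 1e-4 / 177)

    def test_matches_bruteforce_sum_on_grid(self, tonks_params):
        x = np.arange(200.0, 2001.0)
        fast = np.asarray(nb.barrier_density(x, tonks_params))
        slow = np.array([brute_erlang_sum(xi) for xi in x])
        np.testing.assert_allclose(fast, slow, rtol=1e-12)

    def test_finite_sum_is_exact(self, tonks_params):
        # terms beyond floor(x/b) vanish identically: adding them changes nothing
        x = np.arange(0.0, 2001.0)
        base = np.asarray(nb.barrier_density(x, tonks_params))
        extra = base + sum(
            np.asarray(nb.erlang_term(k, x, tonks_params)) for k in range(14, 20)
        )
        np.testing.assert_array_equal(base, extra)

    def test_oscillation_decay(self, tonks_params):
        x = np.arange(0.0, 2001.0)
        r = np.asarray(nb.barrier_density(x, tonks_params))
        peaks = [
            i
            for i in range(1, 2000)
            if r[i] > r[i - 1] and r[i] >= r[i + 1] and r[i] > 1 / 177
        ]
        amps = [abs(r[i] - 1 / 177) for i in peaks]
        assert len(amps) >= 4
        assert all(a > b for a, b in zip(amps, amps[1:]))

    def test_denser_packing_sharpens_oscillations(self):
        # third peak above the mean density, normalized by it
        def third_peak_amp(dbar):
            tp = nb.TonksParams(b=147.0, dbar=dbar)
            x = np.arange(0.0, 2001.0)
            r = np.asarray(nb.barrier_density(x, tp))
            rho = 1 / dbar
            peaks = [
                i
                for i in range(1, 2000)
                if r[i] > r[i - 1] and r[i] >= r[i + 1] and r[i] > rho
            ]
            return (r[peaks[2]] - rho) / rho

        assert third_peak_amp(160.0) > third_peak_amp(200.0)

    def test_rejects_negative_x(self, tonks_params):
        with pytest.raises(ValueError):
            nb.barrier_density(-1.0, tonks_params)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            nb.TonksParams(b=147.0, dbar=147.0)
        with pytest.raises(ValueError):
            nb.TonksParams(b=-1.0, dbar=177.0)


class TestPairDistribution:
    def test_values(self, tonks_params):
        assert nb.two_particle_g(100.0, tonks_params) == 0.0
        assert nb.two_particle_g(147.0, tonks_params) == pytest.approx(
            (1 / 177) * (1 / 30)
        )

    def test_large_distance_limit_is_density_squared(self, tonks_params):
        g = nb.two_particle_g(30 * 177.0, tonks_params)
        assert g == pytest.approx((1 / 177) ** 2, rel=1e-4)


class TestFitModel:
    def test_shift_identity(self, tonks_params):
        p = nb.FitModelParams(A=1.0, x0=200.0, tonks=tonks_params)
        assert nb.fit_model(347.0, p) == pytest.approx(1 / 30)

    def test_zero_left_of_support(self, tonks_params):
        p = nb.FitModelParams(A=5.0, x0=0.0, tonks=tonks_params)
        assert nb.fit_model(100.0, p) == 0.0
        p2 = nb.FitModelParams(A=5.0, x0=300.0, tonks=tonks_params)
        assert nb.fit_model(100.0, p2) == 0.0  # x - x0 < 0: total, not an error

    def test_grid_against_bruteforce(self, tonks_params):
        p = nb.FitModelParams(A=2.0, x0=-147.0, tonks=tonks_params)
        x = np.arange(200.0, 2001.0)
        model = np.asarray(nb.fit_model(x, p))
        oracle = np.array([2.0 * brute_erlang_sum(xi + 147.0) for xi in x])
        np.testing.assert_allclose(model, oracle, rtol=1e-12)

    def test_normalization_must_be_positive(self, tonks_params):
        with pytest.raises(ValueError):
            nb.FitModelParams(A=0.0, x0=0.0, tonks=tonks_params)


class TestConvolvedModel:
    def test_identity_kernel(self, tonks_params):
        p = nb.FitModelParams(A=1.3, x0=50.0, tonks=tonks_params)
        x = np.arange(0.0, 2500.0, 7.0)
        np.testing.assert_array_equal(
            np.asarray(nb.convolved_model(x, p, {0: 1.0})),
            np.asarray(nb.fit_model(x, p)),
        )

    def test_two_point_average(self, tonks_params):
        p = nb.FitModelParams(A=1.0, x0=200.0, tonks=tonks_params)
        got = nb.convolved_model(348.0, p, {-1: 0.5, 1: 0.5})
        expected = 0.5 * (
            nb.barrier_density(147.0, tonks_params)
            + nb.barrier_density(149.0, tonks_params)
        )
        assert got == pytest.approx(expected)

    def test_gaussian_kernel_lowers_first_peak(self, tonks_params):
        p = nb.FitModelParams(A=1.0, x0=0.0, tonks=tonks_params)
        offs = np.arange(-80, 81)
        masses = np.exp(-0.5 * (offs / 20.0) ** 2)
        x = np.arange(100.0, 400.0)
        conv = np.asarray(nb.convolved_model(x, p, (offs, masses)))
        unconv_sup = nb.barrier_density(147.0, tonks_params)  # sup at contact
        assert conv.max() < unconv_sup

    def test_negative_mass_rejected(self):
        with pytest.raises(ValueError):
            normalize_kernel({0: 1.0, 1: -0.1})

    def test_kernel_normalized_on_ingestion(self):
        offs, masses = normalize_kernel({-1: 2.0, 1: 2.0})
        assert masses.sum() == pytest.approx(1.0, abs=1e-12)


def test_binned_density_integrates_the_continuum(tonks_params):
    # sum of unit-bin averages over [a, a+n) equals the integral over it
    # range avoids the contact discontinuity at b, where a trapezoid on the
    # jump and adaptive quadrature disagree at the bin scale
    vals = barrier_density_binned(np.arange(150.0, 340.0), tonks_params)
    direct, _ = quad(lambda t: nb.barrier_density(t, tonks_params), 150.0, 340.0,
                     limit=300)
    assert vals.sum() == pytest.approx(direct, rel=1e-4)
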