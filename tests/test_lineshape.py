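"""Magnetization evolution, spin echo, FID propagation and spectra."""

import math

import numpy as np
import pytest

from mcshape import (
    AcquisitionSettings,
    ExchangeScheme,
    MixComposition,
    NoPeakError,
    SpinParameters,
    Spectrum1D,
    apply_spin_echo,
    evolution_matrix,
    initial_magnetization,
    measure_peak,
    propagate_fid,
    simulate_slice,
    solve_equilibrium,
    spectrum_from_fid,
)
from oracles import (
    hand_generator,
    process_fid,
    rk4_echo,
    rk4_propagate,
    two_site_fid,
    two_site_matrix_exp,
)

SCHEME_A = ExchangeScheme(k1_on=1e9, k1_off=300.0, k2=30.0, k2_prime=700.0)
SPIN_A = SpinParameters(omega_P=0.0, omega_PL=294.0, R2=60.0, echo_time=0.011)


def _random_scheme_spin(rng):
    scheme = ExchangeScheme(
        k1_on=10 ** rng.uniform(6, 9.5),
        k1_off=10 ** rng.uniform(-2, 4),
        k2=10 ** rng.uniform(0, 3),
        k2_prime=10 ** rng.uniform(1, 4),
    )
    spin = SpinParameters(
        omega_P=rng.uniform(-400, 400),
        omega_PL=rng.uniform(-400, 400),
        R2=rng.uniform(10, 150),
        echo_time=0.011,
    )
    return scheme, spin


class TestEvolutionMatrix:
    def test_no_exchange_limit_is_diagonal(self):
        scheme = ExchangeScheme(0.0, 0.0, 0.0, 0.0)
        spin = SpinParameters(omega_P=100.0, omega_PL=250.0, R2=40.0)
        G = evolution_matrix(scheme, spin, 0.0)
        expected = np.diag(
            [
                -2j * math.pi * 100.0 - 40.0,
                -2j * math.pi * 250.0 - 40.0,
                -2j * math.pi * 100.0 - 40.0,
            ]
        )
        np.testing.assert_allclose(G, expected, atol=0)

    def test_real_column_sums_equal_minus_r2(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            scheme, spin = _random_scheme_spin(rng)
            G = evolution_matrix(scheme, spin, 10 ** rng.uniform(-7, -4))
            np.testing.assert_allclose(
                G.sum(axis=0).real, -spin.R2 * np.ones(3), rtol=1e-12, atol=1e-9
            )

    def test_matches_hand_assembled_generator(self):
        # nanomolar preset at 1.3 equivalents
        eq = solve_equilibrium(SCHEME_A, MixComposition(P0=250e-6, L0=1.3 * 250e-6))
        G = evolution_matrix(SCHEME_A, SPIN_A, eq.L)
        ref = hand_generator(1e9, 300.0, 30.0, 700.0, 0.0, 294.0, 60.0, eq.L)
        np.testing.assert_allclose(G, ref, rtol=1e-15)


class TestInitialMagnetization:
    def test_apo_protein(self):
        from mcshape import EquilibriumState

        eq = EquilibriumState(P=250e-6, PL=0.0, PLstar=0.0, L=0.0)
        np.testing.assert_allclose(initial_magnetization(eq), [1.0, 0.0, 0.0])

    def test_component_ratio_follows_isomer_equilibrium(self):
        eq = solve_equilibrium(SCHEME_A, MixComposition(P0=250e-6, L0=200e-6))
        m = initial_magnetization(eq)
        assert m[2].real / m[1].real == pytest.approx(30.0 / 700.0, rel=1e-12)
        assert m.real.sum() == pytest.approx(1.0, rel=1e-12)

    def test_all_zero_rejected(self):
        from mcshape import EquilibriumState

        eq = EquilibriumState(P=0.0, PL=0.0, PLstar=0.0, L=0.0)
        with pytest.raises(ValueError):
            initial_magnetization(eq)


class TestSpinEcho:
    def test_no_exchange_attenuation_closed_form(self):
        scheme = ExchangeScheme(0.0, 0.0, 0.0, 0.0)
        spin = SpinParameters(omega_P=123.0, omega_PL=321.0, R2=50.0)
        G = evolution_matrix(scheme, spin, 0.0)
        M = apply_spin_echo(G, np.array([1.0, 0.0, 0.0], complex), 0.011)
        assert abs(M[0]) == pytest.approx(math.exp(-50.0 * 0.011), rel=1e-10)
        assert math.atan2(M[0].imag, M[0].real) == pytest.approx(0.0, abs=1e-10)

    def test_zero_duration_is_identity(self):
        G = evolution_matrix(SCHEME_A, SPIN_A, 1e-6)
        M0 = np.array([0.7, 0.25, 0.05], complex)
        np.testing.assert_array_equal(apply_spin_echo(G, M0, 0.0), M0)

    def test_matches_fine_step_integration_with_exchange(self):
        eq = solve_equilibrium(SCHEME_A, MixComposition(P0=250e-6, L0=325e-6))
        G = evolution_matrix(SCHEME_A, SPIN_A, eq.L)
        M0 = initial_magnetization(eq)
        got = apply_spin_echo(G, M0, 0.011)
        ref = rk4_echo(G, M0, 0.011)
        np.testing.assert_allclose(got, ref, rtol=0, atol=1e-10)
        # exchange between unequal shifts attenuates beyond pure relaxation
        assert np.abs(got).sum() < math.exp(-60.0 * 0.011) * np.abs(M0).sum()


class TestPropagateFid:
    def test_single_species_damped_oscillation(self):
        scheme = ExchangeScheme(0.0, 0.0, 0.0, 0.0)
        spin = SpinParameters(omega_P=294.0, omega_PL=0.0, R2=60.0)
        acq = AcquisitionSettings(n_points=512)
        G = evolution_matrix(scheme, spin, 0.0)
        fid = propagate_fid(G, np.array([1.0, 0.0, 0.0], complex), acq)
        t = np.arange(512) * acq.dwell
        ref = np.exp((-2j * math.pi * 294.0 - 60.0) * t)
        np.testing.assert_allclose(fid, ref, rtol=0, atol=1e-12)

    def test_fast_exchange_two_site_collapses_to_mean_shift(self):
        # exchange much faster than the shift difference: mono-exponential
        # decay at the population-weighted shift
        k_off, l_free, k_on = 2e5, 1e-3, 1e9
        k_on_l = k_on * l_free
        pb = k_on_l / (k_on_l + k_off)
        spin = SpinParameters(omega_P=0.0, omega_PL=100.0, R2=30.0)
        scheme = ExchangeScheme(k_on, k_off)
        acq = AcquisitionSettings(n_points=512)
        G = evolution_matrix(scheme, spin, l_free)
        M0 = np.array([1 - pb, pb, 0.0], complex)
        fid = propagate_fid(G, M0, acq)
        ref = two_site_fid(k_on_l, k_off, 0.0, 100.0, 30.0,
                           np.array([1 - pb, pb]), np.arange(512) * acq.dwell)
        np.testing.assert_allclose(fid, ref, rtol=0, atol=1e-10)
        # phase evolution rate equals the weighted mean shift
        mean_shift = np.angle(fid[1] / fid[0]) / (-2 * math.pi * acq.dwell)
        assert mean_shift == pytest.approx(pb * 100.0, rel=0.01)

    def test_matches_fine_step_integrator_on_random_draws(self):
        rng = np.random.default_rng(5)
        acq = AcquisitionSettings(n_points=256)
        for _ in range(10):
            scheme, spin = _random_scheme_spin(rng)
            eq = solve_equilibrium(
                scheme, MixComposition(250e-6, 250e-6 * rng.uniform(0.1, 5.0))
            )
            G = evolution_matrix(scheme, spin, eq.L)
            M0 = initial_magnetization(eq)
            fid = propagate_fid(G, M0, acq)
            ref = rk4_propagate(G, M0, acq.dwell, acq.n_points)
            scale = np.abs(ref).max()
            np.testing.assert_allclose(fid / scale, ref / scale, rtol=0, atol=1e-8)


class TestSpectrumFromFid:
    def test_single_species_lorentzian(self, acq_fine):
        t = np.arange(acq_fine.n_points) * acq_fine.dwell
        fid = np.exp((-2j * math.pi * 294.0 - 60.0) * t)
        spec = spectrum_from_fid(fid, acq_fine)
        pk = measure_peak(spec, (250.0, 350.0))
        assert pk.position == pytest.approx(294.0, abs=0.5 * spec.axis_step)
        assert pk.fwhm == pytest.approx(60.0 / math.pi, rel=0.01)

    def test_zero_fid_gives_zero_spectrum(self):
        acq = AcquisitionSettings(n_points=512)
        spec = spectrum_from_fid(np.zeros(512, complex), acq)
        assert np.all(spec.intensity == 0.0)
        assert len(spec.frequency) == 512 * acq.zero_fill_factor

    def test_axis_spans_half_open_window(self):
        acq = AcquisitionSettings(n_points=512, spectral_width=2000.0)
        spec = spectrum_from_fid(np.zeros(512, complex), acq)
        assert spec.frequency[0] == pytest.approx(-1000.0)
        assert spec.frequency[-1] == pytest.approx(1000.0 - spec.axis_step)

    def test_isomerization_broadens_saturated_peak(self, acq_fine):
        mix = MixComposition(P0=250e-6, L0=1.3 * 250e-6)
        spin = SpinParameters(0.0, 294.0, 60.0, echo_time=0.0)
        with_iso = simulate_slice(SCHEME_A, spin, mix, acq_fine)
        no_iso = simulate_slice(ExchangeScheme(1e9, 300.0), spin, mix, acq_fine)
        w_iso = measure_peak(with_iso, (150, 400)).fwhm
        w_two = measure_peak(no_iso, (150, 400)).fwhm
        assert w_iso > w_two > 60.0 / math.pi


class TestSimulateSlice:
    def test_apo_lorentzian_at_free_shift(self, acq_fine):
        spin = SpinParameters(omega_P=120.0, omega_PL=294.0, R2=60.0, echo_time=0.0)
        spec = simulate_slice(SCHEME_A, spin, MixComposition(250e-6, 0.0), acq_fine)
        pk = measure_peak(spec, (60.0, 180.0))
        assert pk.position == pytest.approx(120.0, abs=spec.axis_step)
        assert pk.fwhm == pytest.approx(60.0 / math.pi, rel=0.01)

    def test_slow_exchange_bound_peak_excess_width(self, acq_fine):
        # both exchange rates far below the shift difference: the bound
        # peak's extra width equals the off-rate over pi
        scheme = ExchangeScheme(k1_on=3e5, k1_off=30.0)
        spin = SpinParameters(0.0, 294.0, 60.0, echo_time=0.0)
        spec = simulate_slice(scheme, spin, MixComposition(250e-6, 500e-6), acq_fine)
        pk = measure_peak(spec, (250.0, 350.0))
        assert pk.fwhm - 60.0 / math.pi == pytest.approx(30.0 / math.pi, rel=0.05)

    def test_end_to_end_matches_fine_step_oracle(self):
        acq = AcquisitionSettings(n_points=512)
        mix = MixComposition(P0=250e-6, L0=1.3 * 250e-6)
        got = simulate_slice(SCHEME_A, SPIN_A, mix, acq)
        eq = solve_equilibrium(SCHEME_A, mix)
        G = hand_generator(1e9, 300.0, 30.0, 700.0, 0.0, 294.0, 60.0, eq.L)
        m0 = np.array([eq.P, eq.PL, eq.PLstar], complex) / 250e-6
        m_echo = rk4_echo(G, m0, 0.011)
        fid = rk4_propagate(G, m_echo, acq.dwell, acq.n_points)
        freq, ref = process_fid(fid, acq.dwell, acq.zero_fill_factor, apodize=True)
        np.testing.assert_allclose(got.frequency, freq, atol=1e-9)
        peak = np.abs(ref).max()
        np.testing.assert_allclose(got.intensity / peak, ref / peak, rtol=0, atol=1e-7)

    def test_two_state_pipeline_matches_closed_form_two_site(self, presets):
        # with the isomerization switched off, the full pipeline must
        # reproduce the hand-diagonalized two-site exchange line shape
        acq = AcquisitionSettings(n_points=1024)
        scheme = ExchangeScheme(k1_on=1e9, k1_off=300.0)
        spin = SPIN_A
        for equiv in (0.4, 0.9, 1.3):
            mix = MixComposition(250e-6, equiv * 250e-6)
            got = simulate_slice(scheme, spin, mix, acq)
            eq = solve_equilibrium(scheme, mix)
            m0 = np.array([eq.P, eq.PL], complex) / 250e-6
            k_on_l = 1e9 * eq.L
            U = two_site_matrix_exp(k_on_l, 300.0, 0.0, 294.0, 60.0, 0.011 / 2)
            m_echo = U @ np.conj(U @ m0)
            t = np.arange(acq.n_points) * acq.dwell
            fid = two_site_fid(k_on_l, 300.0, 0.0, 294.0, 60.0, m_echo, t)
            _, ref = process_fid(fid, acq.dwell, acq.zero_fill_factor, apodize=True)
            peak = np.abs(ref).max()
            np.testing.assert_allclose(
                got.intensity / peak, ref / peak, rtol=0, atol=1e-6
            )

    def test_signal_conservation_across_exchange_rates(self):
        # integral of the spectrum equals the (conserved) initial
        # magnetization, independent of exchange rates at fixed R2
        acq = AcquisitionSettings(n_points=2048, apodization="none")
        spin = SpinParameters(0.0, 294.0, 60.0, echo_time=0.0)
        mix = MixComposition(250e-6, 125e-6)
        integrals = []
        for k_off in (1e-3, 1.0, 300.0, 3e4):
            scheme = ExchangeScheme(k_off / 3e-7, k_off, 30.0, 700.0)
            spec = simulate_slice(scheme, spin, mix, acq)
            integrals.append(np.sum(spec.intensity) * spec.axis_step)
        ref = integrals[0]
        assert all(abs(v - ref) <= 1e-3 * abs(ref) for v in integrals)

    def test_peaks_outside_window_rejected(self):
        spin = SpinParameters(omega_P=0.0, omega_PL=2500.0, R2=60.0)
        with pytest.raises(ValueError, match="spectral_width"):
            simulate_slice(SCHEME_A, spin, MixComposition(250e-6, 0.0), AcquisitionSettings())


class TestMeasurePeak:
    def test_baseline_shift_preserves_position(self, acq_fine):
        spin = SpinParameters(0.0, 294.0, 60.0, echo_time=0.0)
        spec = simulate_slice(SCHEME_A, spin, MixComposition(250e-6, 325e-6), acq_fine)
        pk = measure_peak(spec, (150, 400))
        shifted = Spectrum1D(spec.frequency, spec.intensity + 0.3 * pk.height)
        pk2 = measure_peak(shifted, (150, 400))
        assert pk2.position == pytest.approx(pk.position, abs=1e-9)

    def test_fast_exchange_position_is_population_weighted(self, acq_fine):
        scheme = ExchangeScheme(k1_on=1e9, k1_off=1e5)
        spin = SpinParameters(0.0, 294.0, 60.0, echo_time=0.0)
        mix = MixComposition(250e-6, 125e-6)
        eq = solve_equilibrium(scheme, mix)
        expected = eq.bound_fraction * 294.0
        spec = simulate_slice(scheme, spin, mix, acq_fine)
        pk = measure_peak(spec, (-100.0, 394.0))
        assert pk.position == pytest.approx(expected, rel=0.01)

    def test_flat_window_raises(self):
        freq = np.linspace(-100, 100, 201)
        spec = Spectrum1D(freq, np.ones_like(freq))
        with pytest.raises(NoPeakError):
            measure_peak(spec, (-50.0, 50.0))
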