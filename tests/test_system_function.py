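"""Harmonic system function, finite-sample averaging and scan simulation."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from acoustic_mpi import (
    ConfigError,
    DomainError,
    FieldConfig,
    ParticleModel,
    acoustic_response,
    compute_system_function,
    convolve_sample,
    fit_diameter,
    read_profile_csv,
    simulate_scan,
    time_signal,
    write_profile_csv,
)


class TestTimeSignal:
    def test_zero_at_ffp_at_t0(self, field, particle):
        sig = time_signal(0.0, field, particle, n_samples=64)
        assert sig[0] == 0.0

    def test_half_wave_antisymmetry_at_ffp(self, field, particle):
        # pure sinusoidal field + odd response => f(t + T0/2) = -f(t)
        sig = time_signal(0.0, field, particle, n_samples=256)
        np.testing.assert_allclose(sig[128:], -sig[:128], rtol=0, atol=1e-13)

    def test_matches_pointwise_force_response(self, field, particle):
        n = 64
        sig = time_signal(0.3e-3, field, particle, n_samples=n)
        k = 17
        B = field.gradient_T_per_m * 0.3e-3 + field.drive_amplitude_T * math.sin(
            2 * math.pi * k / n
        )
        assert sig[k] == pytest.approx(acoustic_response(B, particle), rel=1e-14)

    @pytest.mark.parametrize("bad_n", [8, 15, 100, 0])
    def test_rejects_invalid_sample_count(self, field, particle, bad_n):
        with pytest.raises(ConfigError):
            time_signal(0.0, field, particle, n_samples=bad_n)


class TestSystemFunction:
    def test_even_harmonics_vanish_at_ffp(self, field, particle):
        sf = compute_system_function(np.array([0.0]), field, particle, 4, 1024)
        assert abs(sf.complex_amplitudes[0, 1]) < 1e-12  # 2nd harmonic
        assert abs(sf.complex_amplitudes[0, 3]) < 1e-12  # 4th harmonic

    def test_magnitude_symmetric_in_position(self, field, particle):
        x = np.linspace(-2e-3, 2e-3, 41)
        sf = compute_system_function(x, field, particle, 3, 1024)
        np.testing.assert_allclose(
            sf.magnitudes, sf.magnitudes[::-1], rtol=0, atol=1e-13
        )

    def test_matches_continuous_fourier_integral(self, field, particle):
        # brute-force quadrature of the continuous signal against sin/cos at 3*f0
        x, n = 0.5e-3, 3
        T0 = 1.0 / field.drive_frequency_Hz
        w = 2 * math.pi / T0

        def signal(t):
            B = field.gradient_T_per_m * x + field.drive_amplitude_T * math.sin(w * t)
            return acoustic_response(B, particle)

        a = quad(lambda t: signal(t) * math.sin(n * w * t), 0, T0, limit=200)[0] * 2 / T0
        b = quad(lambda t: signal(t) * math.cos(n * w * t), 0, T0, limit=200)[0] * 2 / T0
        sf = compute_system_function(np.array([x]), field, particle, 3, 1024)
        assert abs(sf.complex_amplitudes[0, 2]) == pytest.approx(
            math.hypot(a, b), rel=1e-6
        )

    def test_unit_sinusoid_normalization(self, field, particle):
        # the DFT scaling gives magnitude ~1 for a response close to a pure
        # unit sinusoid: tiny drive => s(u) ~ 2u/3, fundamental = 2*alpha*A/3
        tiny = FieldConfig(5.0, 1e-9, 700.0)
        sf = compute_system_function(np.array([0.0]), tiny, particle, 1, 1024)
        expected = 2.0 * particle.alpha_per_T * 1e-9 / 3.0
        assert abs(sf.complex_amplitudes[0, 0]) == pytest.approx(expected, rel=1e-9)

    def test_spectral_convergence_on_doubling(self, field, particle):
        x = np.linspace(-1e-3, 1e-3, 11)
        m1 = compute_system_function(x, field, particle, 3, 1024).magnitudes
        m2 = compute_system_function(x, field, particle, 3, 2048).magnitudes
        assert np.max(np.abs(m1 - m2)) < 1e-9

    def test_harmonics_vanish_in_saturation(self, field, particle):
        far = 20.0 * field.drive_amplitude_T / field.gradient_T_per_m
        sf = compute_system_function(np.array([-far, far]), field, particle, 3, 1024)
        assert np.max(sf.magnitudes) < 1e-8

    def test_scaling_invariance(self, field, particle):
        # response depends only on alpha*Gx*x and alpha*A: halving alpha while
        # doubling A and Gx (exact binary scalings) is bitwise neutral
        x = np.linspace(-1e-3, 1e-3, 21)
        half_alpha = ParticleModel(
            diameter_m=particle.diameter_m,
            core_magnetization_A_per_m=particle.core_magnetization_A_per_m / 2.0,
            temperature_K=particle.temperature_K,
        )
        doubled = FieldConfig(
            2.0 * field.gradient_T_per_m,
            2.0 * field.drive_amplitude_T,
            field.drive_frequency_Hz,
        )
        a = compute_system_function(x, field, particle, 3, 512)
        b = compute_system_function(x, doubled, half_alpha, 3, 512)
        np.testing.assert_array_equal(a.complex_amplitudes, b.complex_amplitudes)

    def test_rejects_too_many_harmonics(self, field, particle):
        with pytest.raises(ConfigError):
            compute_system_function(np.array([0.0]), field, particle, 8, 16)


class TestConvolveSample:
    def test_zero_width_is_identity(self, field, particle):
        x = np.linspace(-1e-3, 1e-3, 21)
        sf = compute_system_function(x, field, particle, 3, 256)
        prof = convolve_sample(sf, 0.0)
        np.testing.assert_array_equal(prof.magnitudes, sf.magnitudes)

    def test_constant_amplitude_unchanged(self):
        from acoustic_mpi import SystemFunctionGrid

        pos = np.linspace(-1e-3, 1e-3, 41)
        amp = np.full((41, 2), 0.3 - 0.4j)
        prof = convolve_sample(SystemFunctionGrid(pos, amp), 0.5e-3)
        np.testing.assert_allclose(prof.complex_amplitudes, 0.3 - 0.4j, rtol=1e-14)

    def test_interior_average_matches_direct_sum(self, field, particle):
        x = np.linspace(-2e-3, 2e-3, 81)  # 0.05 mm spacing
        sf = compute_system_function(x, field, particle, 3, 256)
        prof = convolve_sample(sf, 1e-3)  # 21-sample window
        i_out, i_in = 10, 20  # output index 10 maps to input index 20
        direct = sf.complex_amplitudes[i_in - 10 : i_in + 11].mean(axis=0)
        assert prof.positions_m[i_out] == pytest.approx(x[i_in], abs=1e-12)
        np.testing.assert_allclose(prof.complex_amplitudes[i_out], direct, rtol=1e-13)

    def test_window_wider_than_grid_rejected(self, field, particle):
        x = np.linspace(-1e-3, 1e-3, 11)
        sf = compute_system_function(x, field, particle, 3, 256)
        with pytest.raises(DomainError):
            convolve_sample(sf, 10e-3)


class TestSimulateScan:
    def test_default_protocol_has_53_positions(self, field, particle):
        prof = simulate_scan(field, particle)
        assert prof.positions_m.size == 53
        assert prof.positions_m[0] == pytest.approx(-3.25e-3, rel=1e-9)
        assert prof.positions_m[-1] == pytest.approx(3.25e-3, rel=1e-9)
        assert prof.n_harmonics == 3
        # acquisition ran top -> down over the ascending grid
        assert prof.acquisition_order[0] == 52 and prof.acquisition_order[-1] == 0

    def test_fundamental_peaks_center_even_harmonic_dips(self, field, particle):
        prof = simulate_scan(field, particle)
        center = 26
        assert np.argmax(prof.magnitudes[:, 0]) == center
        # 2nd harmonic: local minimum (near-null) at the center
        h2 = prof.magnitudes[:, 1]
        assert h2[center] < 0.05 * h2.max()

    def test_zero_sample_length_equals_point_system_function(self, field, particle):
        prof = simulate_scan(field, particle, sample_length_m=0.0)
        sf = compute_system_function(prof.positions_m, field, particle, 3, 1024)
        np.testing.assert_allclose(prof.magnitudes, sf.magnitudes, rtol=1e-12)

    def test_invalid_step_rejected(self, field, particle):
        with pytest.raises(ConfigError):
            simulate_scan(field, particle, step_m=0.0)
        with pytest.raises(ConfigError):
            simulate_scan(field, particle, step_m=0.1234e-3)

    def test_noise_is_seeded_and_reproducible(self, field, particle):
        a = simulate_scan(field, particle, noise_sigma_rel=0.01, rng=7)
        b = simulate_scan(field, particle, noise_sigma_rel=0.01, rng=7)
        c = simulate_scan(field, particle, noise_sigma_rel=0.01, rng=8)
        np.testing.assert_array_equal(a.complex_amplitudes, b.complex_amplitudes)
        assert np.any(a.complex_amplitudes != c.complex_amplitudes)


class TestDiameterRecovery:
    def test_recovers_16nm_from_noisy_scan(self, field):
        """Grid search over 14-19 nm recovers the true diameter of a scan
        with 1%-of-peak additive noise (mirrors bracketing the particle
        size of an experimental scan)."""
        truth = ParticleModel(diameter_m=16e-9)
        observed = simulate_scan(field, truth, noise_sigma_rel=0.01, rng=42)
        candidates = np.array([14, 15, 16, 17, 18, 19]) * 1e-9
        best = fit_diameter(observed, candidates, field)
        assert best == pytest.approx(16e-9)


class TestProfileCsv:
    def test_round_trip_is_lossless(self, field, particle, tmp_path):
        prof = simulate_scan(field, particle)
        path = tmp_path / "scan.csv"
        write_profile_csv(prof, path)
        back = read_profile_csv(path, sample_length_m=prof.sample_length_m)
        np.testing.assert_allclose(
            back.positions_m, prof.positions_m, rtol=0, atol=1e-18
        )
        np.testing.assert_array_equal(back.complex_amplitudes, prof.complex_amplitudes)

    def test_rows_ascend_by_position_then_harmonic(self, field, particle, tmp_path):
        prof = simulate_scan(field, particle)
        path = tmp_path / "scan.csv"
        write_profile_csv(prof, path)
        lines = path.read_text().splitlines()
        assert lines[0] == "position_mm,harmonic,magnitude,real,imag"
        first = [line.split(",")[:2] for line in lines[1:7]]
        assert [h for _, h in first] == ["1", "2", "3", "1", "2", "3"]
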