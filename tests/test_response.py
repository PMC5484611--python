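"""Closed-form linear response: means, covariances, decomposition, resonances."""

import numpy as np
import pytest

import oscibin as ob


def omega_of(f_hz: float) -> float:
    return 2 * np.pi * f_hz / 1000.0


class TestMeanResponse:
    def test_quasi_static_limit_scalar(self, single_st):
        m1 = ob.mean_response(0.0, single_st, 1.0)
        expect = single_st.S[0] / (1.0 - single_st.lam[0].real)
        assert m1[0].imag == pytest.approx(0.0, abs=1e-14)
        assert m1[0].real == pytest.approx(expect, rel=1e-12)
        assert m1[0].real > 0

    def test_high_frequency_asymptote(self, bio_st):
        tau = bio_st.spec.tau
        tw = 1e3
        m1 = ob.mean_response(tw / tau, bio_st, 1.0)
        assert np.allclose(np.abs(m1) * tw, bio_st.S, rtol=0.01)

    def test_phase_lags_behind_drive_for_real_spectrum(self, single_st):
        for f in ob.frequency_grid(1, 1000, 25):
            m1 = ob.mean_response(omega_of(f), single_st, 1.0)
            ph = np.angle(m1[0])
            assert -np.pi < ph <= 0.0

    def test_corner_frequency_phase(self, single_st):
        # scalar network at tau*omega = 1 - lambda: first-order low-pass
        # at its corner frequency lags by exactly pi/4
        tau = single_st.spec.tau
        omega = (1.0 - single_st.lam[0].real) / tau
        m1 = ob.mean_response(omega, single_st, 1.0)
        assert np.angle(m1[0]) == pytest.approx(-np.pi / 4, abs=1e-12)

    def test_peak_rate_modulations_biological(self, bio_st):
        # half-amplitude (two-sided Fourier coefficient) of the rate
        # modulation for h_ext = 1, the conventional headline numbers
        amps = ob.rate_modulation_sweep(bio_st, 1.0, ob.frequency_grid(1, 1000, 200))
        half = amps.max(axis=0) / 2.0
        assert half[0] == pytest.approx(0.8, rel=0.1)
        assert half[1] == pytest.approx(4.9, rel=0.1)


class TestCovarianceResponse:
    def test_zero_drive_gives_zero_response(self, bio_st):
        lr = ob.covariance_response(omega_of(80), bio_st, 0.0)
        for mat in (lr.C1, lr.C1_direct, lr.C1_recurrent, lr.C1_autocov):
            assert np.all(mat == 0)

    def test_decomposition_is_exact(self, bio_st):
        for f in (1.0, 30.0, 300.0):
            lr = ob.covariance_response(omega_of(f), bio_st, 1.0)
            total = lr.C1_direct + lr.C1_recurrent + lr.C1_autocov
            assert np.array_equal(lr.C1, total)

    def test_result_symmetric(self, bio_st):
        lr = ob.covariance_response(omega_of(80), bio_st, 1.0)
        assert np.array_equal(lr.C1, lr.C1.T)

    def test_quasi_static_solves_static_equation(self, bio_st):
        # at omega -> 0 the first harmonic satisfies the static linearized
        # covariance equation; cross-check by solving the vectorized
        # (Kronecker) linear system directly, independent of the eigenbasis
        omega = 1e-6
        lr = ob.covariance_response(omega, bio_st, 1.0)
        W = bio_st.W
        m1 = lr.M1
        spec = bio_st.spec
        n = spec.n
        Vc = lr.V @ bio_st.c_total
        R = (
            1.0 * Vc
            + (lr.T @ m1)[:, None] * Vc
            + W * ((1.0 - 2.0 * bio_st.m) / spec.N * m1)[None, :]
        )
        Rs = R + R.T
        # 2C - WC - CW^T = Rs, column-major vectorization
        eye = np.eye(n)
        A = 2 * np.eye(n * n) - np.kron(eye, W) - np.kron(W, eye)
        ref = np.linalg.solve(A, Rs.flatten(order="F")).reshape((n, n), order="F")
        assert np.max(np.abs(lr.C1 - ref)) < 1e-8

    def test_susceptibility_terms_cancel_at_low_frequency(self, single_st):
        lr = ob.covariance_response(omega_of(1.0), single_st, 1.0)
        sh, sm = lr.C1_direct[0, 0], lr.C1_recurrent[0, 0]
        assert abs(sh + sm) < min(abs(sh), abs(sm))

    def test_autocovariance_term_dominates_single_population(self, single_st):
        # the a-term overshadows the summed susceptibility terms throughout
        # the physiological band, so the intermediate peak of the S-terms is
        # not visible in the total: |C1| decays monotonically with f
        grid = ob.frequency_grid(1, 1000, 30)
        totals = []
        for f in grid:
            lr = ob.covariance_response(omega_of(f), single_st, 1.0)
            s_sum = lr.C1_direct[0, 0] + lr.C1_recurrent[0, 0]
            if f <= 200.0:
                assert abs(lr.C1_autocov[0, 0]) > abs(s_sum)
            totals.append(abs(lr.C1[0, 0]))
        assert np.all(np.diff(totals) < 0)

    def test_covariance_scales_like_mean_over_size(self):
        # |C1| = O(|M1| / N): N |C1| stable across sizes
        vals = []
        for n in (2500, 5000):
            spec = ob.calibrated(
                ob.NetworkSpec(
                    populations=(
                        ob.Population(
                            "I", n, sigma_noise=np.sqrt(105.0), target_m=0.3
                        ),
                    ),
                    p=[[0.1]],
                    J=[[-1.0]],
                    tau=10.0,
                )
            )
            st = ob.solve_stationary(spec)
            lr = ob.covariance_response(omega_of(10.0), st, 1.0)
            # dc = O(dm / N): compare N |C1| relative to |M1| (the mean
            # response itself shifts with K = pN, so normalize by it)
            vals.append(n * abs(lr.C1[0, 0]) / abs(lr.M1[0]))
        assert abs(vals[1] - vals[0]) / vals[0] < 0.3


class TestResonance:
    def test_real_spectrum_has_no_resonance(self, hom_spec):
        st = ob.solve_stationary(hom_spec)
        assert ob.resonance_frequencies(st).size == 0

    def test_biological_network_has_one_resonance(self, bio_st):
        fres = ob.resonance_frequencies(bio_st)
        assert fres.size == 1
        both = ob.resonance_frequencies(bio_st, include_covariance_modes=True)
        assert both.size == 2
        assert both[1] == pytest.approx(2 * both[0])

    def test_mean_response_peaks_near_resonance(self, bio_st):
        fres = ob.resonance_frequencies(bio_st)[0]
        grid = ob.frequency_grid(1, 1000, 120)
        amps = ob.rate_modulation_sweep(bio_st, 1.0, grid)
        fmax = grid[np.argmax(amps[:, 0])]
        assert 0.5 * fres <= fmax <= 2.0 * fres


class TestAmpPhase:
    def test_unit_coefficient(self):
        amp, ph = ob.amp_phase(1.0 + 0j)
        assert (amp, ph) == (1.0, 0.0)

    def test_quarter_cycle_lag(self):
        amp, ph = ob.amp_phase(-2j)
        assert amp == pytest.approx(2.0)
        assert ph == pytest.approx(-np.pi / 2)


class TestValidityMonitor:
    def test_biological_ratios_large(self, bio_st):
        ratios = ob.delta_sigma_validity(bio_st)
        assert np.all(ratios > 3.0)

    def test_warning_for_small_input_fluctuations(self):
        spec = ob.calibrated(
            ob.NetworkSpec(
                populations=(
                    ob.Population("I", 5000, sigma_noise=0.5, target_m=0.4),
                ),
                p=[[0.02]],
                J=[[-0.05]],
                tau=10.0,
            )
        )
        st = ob.solve_stationary(spec)
        if np.min(ob.delta_sigma_validity(st)) < 3.0:
            with pytest.warns(RuntimeWarning, match="sigma-modulation"):
                ob.covariance_response(omega_of(10.0), st, 0.01)
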