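import numpy as np
import pytest

import fractkit as fk
from fractkit import (
    GeneralizedHurstSet,
    cascade_tau_oracle,
    default_qgrid,
    delta_h,
    dfa,
    generate_fgn,
    legendre_spectrum,
    mf_dfa,
    mf_dma,
    spectrum_descriptors,
    tau_and_dimensions,
    wide_qgrid,
    wtmm,
)
from fractkit.core import moment_average
from fractkit.synthgen import generate_cascade, generate_signal


class TestQGrids:
    def test_default_contains_anchors(self):
        q = default_qgrid()
        assert 0.0 in q and 2.0 in q
        assert q[0] == -5.0 and q[-1] == 5.0
        assert np.all(np.diff(q) > 0)

    def test_wide_span(self):
        q = wide_qgrid()
        assert q[0] == -15.0 and q[-1] == 15.0


class TestMomentMachinery:
    def test_q0_is_log_average(self):
        fv = np.array([1.0, 2.0, 4.0])
        out = moment_average(fv, np.array([0.0]))
        assert out[0] == pytest.approx(2.0)  # geometric mean

    def test_monotone_in_q(self):
        rng = np.random.default_rng(0)
        fv = rng.lognormal(0, 1, 200)
        q = np.linspace(-15, 15, 31)
        out = moment_average(fv, q)
        assert np.all(np.diff(out) >= -1e-12)

    def test_zero_windows_excluded_with_warning(self):
        fv = np.array([0.0, 1.0, 2.0])
        with pytest.warns(RuntimeWarning, match="zero-fluctuation"):
            out = moment_average(fv, np.array([-2.0]))
        assert np.isfinite(out[0])


class TestMfDfa:
    def test_q2_equals_monofractal_dfa_exactly(self, white_noise):
        ws = fk.log_spaced_windows(white_noise.n, 16, white_noise.n // 8)
        alpha = dfa(white_noise, window_sizes=ws).exponent
        h2 = mf_dfa(white_noise, q=np.array([0.0, 2.0]), window_sizes=ws).h_at(2.0)
        assert h2 == alpha  # identical windows, detrending, and fit

    def test_monofractal_hq_constant(self):
        ts = generate_fgn(2**13, 0.7, seed=5)
        hq = mf_dfa(ts, q=default_qgrid())
        assert np.ptp(hq.hq) < 0.35
        assert hq.h_at(2.0) == pytest.approx(0.7, abs=0.1)

    def test_cascade_tau_matches_oracle(self, devil_cascade, devil_spec, triadic_windows):
        q = default_qgrid()
        hq = mf_dfa(devil_cascade, q=q, window_sizes=triadic_windows)
        tau = tau_and_dimensions(hq)
        np.testing.assert_allclose(
            tau.tau, cascade_tau_oracle(devil_spec, q), atol=0.05
        )

    def test_fq_monotone_in_q_per_scale(self):
        ts = generate_fgn(2**12, 0.6, seed=9)
        q = default_qgrid()
        hq = mf_dfa(ts, q=q)
        # reconstruct F_q at the smallest scale from the stored fits
        f_small = np.array([10.0 ** fit.log_measures[0] for fit in hq.fits])
        assert np.all(np.diff(f_small) >= -1e-12)


class TestMfDma:
    def test_backward_recovers_fgn(self):
        vals = [
            mf_dma(generate_fgn(2**13, 0.4, seed=s), q=np.array([0.0, 2.0])).h_at(2.0)
            for s in range(5)
        ]
        assert np.mean(vals) == pytest.approx(0.4, abs=0.07)

    def test_saturates_on_fbm(self):
        vals = [
            mf_dma(generate_signal(2**13, 1.5, seed=s), q=np.array([0.0, 2.0])).h_at(2.0)
            for s in range(3)
        ]
        assert np.mean(vals) == pytest.approx(1.0, abs=0.1)

    def test_q0_column_finite(self):
        hq = mf_dma(generate_fgn(2**11, 0.5, seed=1), q=np.array([-2.0, 0.0, 2.0]))
        assert np.all(np.isfinite(hq.hq))

    def test_theta_domain(self, white_noise):
        with pytest.raises(ValueError, match="theta"):
            mf_dma(white_noise, theta=1.5)

    @pytest.mark.parametrize("theta", [0.0, 0.5, 1.0])
    def test_all_positions_recover_white_noise(self, theta):
        hq = mf_dma(generate_fgn(2**13, 0.5, seed=2), q=np.array([0.0, 2.0]), theta=theta)
        assert hq.h_at(2.0) == pytest.approx(0.5, abs=0.1)


class TestFormalism:
    def test_tau_arithmetic(self):
        q = default_qgrid()
        hq = GeneralizedHurstSet(q, np.full(q.size, 0.7), (), "test")
        tau = tau_and_dimensions(hq)
        assert tau.tau_at(2.0) == pytest.approx(0.4)
        assert tau.tau_at(0.0) == -1.0

    def test_dq_interpolated_at_one(self):
        q = np.array([-1.0, 0.0, 1.0, 2.0, 3.0])
        hq = GeneralizedHurstSet(q, np.full(5, 0.6), (), "test")
        tau = tau_and_dimensions(hq)
        assert np.all(np.isfinite(tau.dq))

    def test_linear_tau_gives_point_spectrum(self):
        q = default_qgrid()
        tau = tau_and_dimensions(
            GeneralizedHurstSet(q, np.full(q.size, 0.6), (), "test")
        )
        spec = legendre_spectrum(tau)
        np.testing.assert_allclose(spec.h, 0.6, atol=1e-12)
        np.testing.assert_allclose(spec.d, 1.0, atol=1e-12)

    def test_cascade_spectrum_peak(self, devil_cascade, devil_spec, triadic_windows):
        hq = mf_dfa(devil_cascade, q=default_qgrid(), window_sizes=triadic_windows)
        spec = legendre_spectrum(tau_and_dimensions(hq))
        # maximum of D(h) sits at q = 0 and equals 1 by construction
        assert spec.d.max() == pytest.approx(1.0, abs=1e-9)
        h_at_peak = spec.h[np.argmax(spec.d)]
        assert h_at_peak == pytest.approx(1.1316, abs=0.03)

    def test_nonconcave_tau_flagged(self):
        q = np.linspace(-3, 3, 13)
        wavy = 0.7 * q - 1 + 0.3 * np.sin(3 * q)
        with pytest.warns(RuntimeWarning, match="non-concave"):
            spec = legendre_spectrum(
                fk.MultiscalingExponent(q, wavy, np.zeros_like(q), "test")
            )
        assert np.count_nonzero(~spec.concave) > 0

    def test_needs_five_points(self):
        q = np.array([0.0, 1.0, 2.0])
        with pytest.raises(ValueError, match="5 grid points"):
            legendre_spectrum(
                fk.MultiscalingExponent(q, q - 1, np.zeros_like(q), "t")
            )


class TestDescriptors:
    @staticmethod
    def _parabolic_spectrum(h_max=0.8, half_width=0.3):
        q = np.linspace(5, -5, 41)
        h = h_max - half_width * q / 5
        d = 1.0 - (h - h_max) ** 2 / (2 * half_width**2 / 4)
        return fk.SingularitySpectrum(h, d, q, np.ones(41, bool), "test")

    def test_symmetric_spectrum_w_is_one(self):
        desc = spectrum_descriptors(self._parabolic_spectrum())
        assert desc.w == pytest.approx(1.0, abs=1e-6)
        assert desc.fwhm == pytest.approx(desc.w_plus + desc.w_minus)
        assert desc.h_max == pytest.approx(0.8, abs=1e-9)

    def test_pc_arithmetic(self):
        # P_c = h_max / (D_max * FWHM): 1.13 / (1 * 0.5) = 2.26
        desc = spectrum_descriptors(self._parabolic_spectrum(h_max=1.13))
        manual = desc.h_max / (desc.d_max * desc.fwhm)
        assert desc.p_c == pytest.approx(manual)
        assert fk.SpectrumDescriptors(
            1.13, 1.0, 0.5, 0.25, 0.25, 1.13 / 0.5, 1.0
        ).p_c == pytest.approx(2.26)

    def test_cascade_width(self, devil_cascade, devil_spec, triadic_windows):
        hq_wide = mf_dfa(devil_cascade, q=wide_qgrid(), window_sizes=triadic_windows)
        dh = delta_h(hq_wide)
        # oracle: h(-15) - h(+15) ~ 1.4649 - 0.4650
        assert dh == pytest.approx(1.0, abs=0.1)

    def test_truncated_tail_gives_nulls(self):
        spec = self._parabolic_spectrum()
        # cut the right branch above half maximum
        keep = spec.d > 0.8
        trunc = fk.SingularitySpectrum(
            spec.h[keep], spec.d[keep], spec.q[keep],
            np.ones(keep.sum(), bool), "test",
        )
        with pytest.warns(RuntimeWarning, match="half maximum"):
            desc = spectrum_descriptors(trunc)
        assert desc.fwhm is None and desc.p_c is None


class TestWtmm:
    def test_brownian_tau_linear(self):
        q = default_qgrid(0.0, 3.0, 0.5)
        taus = [
            wtmm(generate_signal(2**13, 1.5, seed=s), q=q).tau for s in range(3)
        ]
        tau = np.mean(taus, axis=0)
        np.testing.assert_allclose(tau, 0.5 * q - 1.0, atol=0.15)

    def test_staircase_matches_oracle(self, devil_spec):
        stair = generate_cascade(devil_spec, staircase=True)
        q = default_qgrid(-2.0, 5.0, 0.5)
        tau = wtmm(stair, q=q)
        np.testing.assert_allclose(
            tau.tau, cascade_tau_oracle(devil_spec, q), atol=0.12
        )

    def test_maxima_lines_non_increasing(self, devil_spec):
        stair = generate_cascade(devil_spec, staircase=True)
        tau = wtmm(stair, q=np.array([0.0, 2.0]))
        lines = tau.n_lines[tau.n_lines > 0]
        assert np.all(np.diff(lines) <= 0)

    def test_scale_bound(self, white_noise):
        with pytest.raises(ValueError, match="n/4"):
            wtmm(white_noise, scales=np.array([4.0, white_noise.n]))

    def test_unsupported_wavelet(self, white_noise):
        with pytest.raises(ValueError, match="analyzing wavelet"):
            wtmm(white_noise, wavelet="db4")
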