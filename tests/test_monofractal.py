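import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fractkit as fk
from fractkit import (
    DegenerateSignalError,
    TimeSeries,
    autocovariance,
    awc,
    classify_hurst_prime,
    convert_exponents,
    dfa,
    disp,
    fa_raw,
    generate_fgn,
    preprocess,
    psd_low,
    ssc,
    swv,
)
from fractkit.synthgen import class_convert, generate_signal


class TestPreprocess:
    def test_demean(self, white_noise):
        out = preprocess(white_noise, ["demean"])
        assert abs(out.values.mean()) < 1e-12

    def test_endmatch_zeroes_ends(self, brownian):
        out = preprocess(brownian, ["demean", "endmatch"])
        assert out.values[0] == pytest.approx(0.0, abs=1e-9)
        assert out.values[-1] == pytest.approx(0.0, abs=1e-9)

    def test_endmatch_annihilates_ramp(self):
        ramp = TimeSeries(np.linspace(0, 5, 64))
        out = preprocess(ramp, ["endmatch"])
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_unknown_step(self, white_noise):
        with pytest.raises(ValueError, match="unknown"):
            preprocess(white_noise, ["smooth"])


class TestAutocovariance:
    def test_normalized_lag0_is_one(self, white_noise):
        c = autocovariance(white_noise, 4, normalize=True)
        assert c[0] == 1.0

    def test_iid_uncorrelated(self, white_noise):
        c = autocovariance(white_noise, 5, normalize=True)
        assert np.all(np.abs(c[1:]) < 0.05)

    def test_persistent_fgn_lag1(self):
        # expectation (2^1.8 - 2)/2 ~ 0.741; the sample estimator demeans,
        # which biases it slightly low under strong persistence
        vals = [
            autocovariance(generate_fgn(2**15, 0.9, seed=s), 1, normalize=True)[1]
            for s in range(5)
        ]
        assert np.mean(vals) == pytest.approx(0.741, abs=0.07)

    def test_max_lag_bound(self, white_noise):
        with pytest.raises(ValueError):
            autocovariance(white_noise, white_noise.n // 2)


class TestDfa:
    def test_white_noise_alpha_half(self):
        vals = [dfa(generate_fgn(4096, 0.5, seed=s)).exponent for s in range(5)]
        assert np.mean(vals) == pytest.approx(0.5, abs=0.05)

    def test_brownian_alpha_three_halves(self):
        vals = [
            dfa(class_convert(generate_fgn(4096, 0.5, seed=s), "sum")).exponent
            for s in range(5)
        ]
        assert np.mean(vals) == pytest.approx(1.5, abs=0.08)

    def test_recovers_fgn_hurst(self):
        vals = [dfa(generate_fgn(2**14, 0.8, seed=s)).exponent for s in range(5)]
        assert np.mean(vals) == pytest.approx(0.8, abs=0.05)

    def test_alpha_shift_between_classes(self):
        # the same increments analyzed raw vs cumulated: alpha rises by ~1
        for s in range(3):
            ts = generate_fgn(2**13, 0.6, seed=s)
            a_fgn = dfa(ts).exponent
            a_fbm = dfa(class_convert(ts, "sum")).exponent
            assert a_fbm - a_fgn == pytest.approx(1.0, abs=0.15)

    def test_constant_input_degenerate(self):
        with pytest.raises(DegenerateSignalError):
            dfa(TimeSeries(np.full(256, 3.0)))

    def test_window_floor_validation(self, white_noise):
        with pytest.raises(ValueError, match="window"):
            dfa(white_noise, window_sizes=np.array([2, 8, 32]), detrend_order=1)


class TestSwvAndSsc:
    def test_brownian_bridge_recovers_half(self, brownian):
        assert swv(brownian, variant="bridge").exponent == pytest.approx(0.5, abs=0.1)

    def test_summed_fgn_recovery(self):
        vals = [
            swv(class_convert(generate_fgn(2**13, 0.3, seed=s), "sum")).exponent
            for s in range(5)
        ]
        assert np.mean(vals) == pytest.approx(0.3, abs=0.05)

    def test_bridge_removes_exact_line(self):
        with pytest.raises(DegenerateSignalError):
            swv(TimeSeries(np.linspace(0.0, 10.0, 512)), variant="bridge")

    @pytest.mark.parametrize(
        "hp, expected_class", [(0.3, "fGn"), (0.8, "fGn"), (1.5, "fBm"), (1.8, "fBm")]
    )
    def test_ssc_classifies_both_classes(self, hp, expected_class):
        res = ssc(generate_signal(2**13, hp, seed=21))
        assert str(res.signal_class) == expected_class
        assert res.hurst_prime == pytest.approx(hp, abs=0.12)

    def test_boundary_band_flag(self):
        assert str(classify_hurst_prime(0.99)) == "boundary"
        assert str(classify_hurst_prime(1.02)) == "boundary"
        assert str(classify_hurst_prime(0.85)) == "fGn"
        assert str(classify_hurst_prime(1.2)) == "fBm"


class TestPsdLow:
    def test_brownian_beta_two(self):
        vals = [
            psd_low(class_convert(generate_fgn(4096, 0.5, seed=s), "sum"))[0].exponent
            for s in range(10)
        ]
        assert np.mean(vals) == pytest.approx(2.0, abs=0.15)

    def test_white_noise_flat(self):
        vals = [psd_low(generate_fgn(4096, 0.5, seed=s))[0].exponent for s in range(10)]
        assert np.mean(vals) == pytest.approx(0.0, abs=0.15)

    def test_fgn_beta_is_2h_minus_1(self):
        vals = [psd_low(generate_fgn(4096, 0.9, seed=s))[0].exponent for s in range(10)]
        assert np.mean(vals) == pytest.approx(0.8, abs=0.15)

    def test_spectrum_excludes_dc(self, white_noise):
        _, spectrum = psd_low(white_noise)
        assert spectrum.frequencies[0] > 0
        assert np.all(np.diff(spectrum.frequencies) > 0)

    def test_narrow_band_rejected(self, white_noise):
        with pytest.raises(ValueError, match="fewer than 4"):
            psd_low(white_noise, fit_band=(0.0, 0.0005))

    def test_agrees_with_ssc_through_conversion(self):
        # beta and H' measured independently should agree via H' = (beta+1)/2
        for s in range(3):
            ts = generate_fgn(2**13, 0.7, seed=s)
            hp_psd = psd_low(ts)[0].hurst_prime
            hp_ssc = ssc(ts).hurst_prime
            assert hp_psd == pytest.approx(hp_ssc, abs=0.1)


class TestDisp:
    def test_white_noise_half(self):
        vals = [disp(generate_fgn(4096, 0.5, seed=s)).exponent for s in range(5)]
        assert np.mean(vals) == pytest.approx(0.5, abs=0.05)

    def test_recovery(self):
        vals = [disp(generate_fgn(2**13, 0.8, seed=s)).exponent for s in range(5)]
        assert np.mean(vals) == pytest.approx(0.8, abs=0.07)

    def test_single_bin_size_rejected(self, white_noise):
        with pytest.raises(ValueError, match="2 bin sizes"):
            disp(white_noise, bin_sizes=np.array([8]))


class TestAwc:
    def test_brownian(self, brownian):
        res = awc(brownian)
        assert res.exponent == pytest.approx(0.5, abs=0.12)
        assert res.fit.slope == pytest.approx(1.0, abs=0.12)

    def test_summed_fgn_recovery(self):
        vals = [
            awc(class_convert(generate_fgn(2**13, 0.8, seed=s), "sum")).exponent
            for s in range(5)
        ]
        assert np.mean(vals) == pytest.approx(0.8, abs=0.07)

    def test_scale_bound(self, brownian):
        with pytest.raises(ValueError, match="n/4"):
            awc(brownian, scales=np.array([4.0, brownian.n / 2]))

    def test_constant_degenerate(self):
        with pytest.raises(DegenerateSignalError):
            awc(TimeSeries(np.full(512, 1.0)))


class TestFaRaw:
    def test_white_noise(self):
        vals = [fa_raw(generate_fgn(4096, 0.5, seed=s)).exponent for s in range(5)]
        assert np.mean(vals) == pytest.approx(0.5, abs=0.05)

    def test_recovery(self):
        vals = [fa_raw(generate_fgn(2**13, 0.8, seed=s)).exponent for s in range(5)]
        assert np.mean(vals) == pytest.approx(0.8, abs=0.07)

    def test_single_lag_rejected(self, white_noise):
        with pytest.raises(ValueError, match="2 lags"):
            fa_raw(white_noise, lags=np.array([16]))


UNITS = ["H'", "alpha", "beta", "H", "gamma", "D"]


class TestConvertExponents:
    def test_white_noise_anchor(self):
        assert convert_exponents(0.5, "H", "beta", "fGn") == 0.0

    def test_brownian_anchor(self):
        assert convert_exponents(2.0, "beta", "H", "fBm") == 0.5

    def test_dimension_anchor(self):
        assert convert_exponents(1.5, "D", "H", "fGn") == 0.5

    def test_extended_scale_identities(self):
        # beta = 2H' - 1 holds across both classes
        assert convert_exponents(0.3, "H'", "beta") == pytest.approx(-0.4)
        assert convert_exponents(1.5, "H'", "beta") == pytest.approx(2.0)
        assert convert_exponents(1.5, "H'", "alpha") == 1.5

    @pytest.mark.parametrize("a", UNITS)
    @pytest.mark.parametrize("b", UNITS)
    def test_round_trip_exact(self, a, b):
        if "gamma" in (a, b):
            classes = ["fGn"]
        else:
            classes = ["fGn", "fBm"]
        for sc in classes:
            for k in range(1, 16):
                h_prime = k / 16  # dyadic: conversions stay exact in binary
                if sc == "fBm":
                    h_prime += 1.0
                x = convert_exponents(h_prime, "H'", a, sc)
                y = convert_exponents(x, a, b, sc)
                assert convert_exponents(y, b, a, sc) == x

    def test_class_required(self):
        with pytest.raises(ValueError, match="class"):
            convert_exponents(0.5, "H", "beta")

    def test_gamma_undefined_for_fbm(self):
        with pytest.raises(ValueError, match="not defined"):
            convert_exponents(1.2, "H'", "gamma", "fBm")

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(
        hp=st.floats(0.05, 0.95),
        a=st.sampled_from(UNITS),
        b=st.sampled_from(UNITS),
    )
    def test_chained_conversion_consistent(self, hp, a, b):
        """A -> B directly equals A -> H' -> B within float tolerance."""
        x = convert_exponents(hp, "H'", a, "fGn")
        direct = convert_exponents(x, a, b, "fGn")
        via = convert_exponents(
            convert_exponents(x, a, "H'", "fGn"), "H'", b, "fGn"
        )
        assert direct == pytest.approx(via, abs=1e-12)


class TestClassGuards:
    def test_class_mismatch_rejected(self):
        ts = generate_fgn(512, 0.5, seed=0)
        with pytest.raises(fk.ClassMismatchError):
            swv(ts, signal_class="fGn")
        with pytest.raises(fk.ClassMismatchError):
            awc(ts, signal_class="fGn")
        with pytest.raises(fk.ClassMismatchError):
            disp(ts, signal_class="fBm")

    def test_matching_class_accepted(self, brownian):
        assert swv(brownian, signal_class="fBm").exponent == swv(brownian).exponent
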