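"""Circular autocorrelation and the ACC: oracle equivalence and invariances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import periotag as pt
from periotag.periodicity import AccConfig, AcfVector


def brute_force_circular_acf(x: np.ndarray) -> np.ndarray:
    """O(N^2) definition: r(k) = sum_t x(t) x((t+k) mod N), max-normalized."""
    n = x.size
    r = np.array([np.dot(x, np.roll(x, -k)) for k in range(n)])
    return r / r.max()


class TestCircularAcf:
    def test_matches_brute_force_on_random_series(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(8, 513))
            x = rng.standard_normal(n) + rng.uniform(0.0, 2.0)
            expected = brute_force_circular_acf(x)[: n // 2 + 1]
            got = pt.circular_acf(x).values
            np.testing.assert_allclose(got, expected, atol=1e-9)

    def test_symmetry_before_truncation(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(257)
        r = pt.circular_acf(x, cfg=AccConfig(full_lags=True)).values
        np.testing.assert_allclose(r[1:], r[1:][::-1], atol=1e-9)

    def test_lag0_is_max_and_one_after_normalization(self):
        rng = np.random.default_rng(2)
        x = np.abs(rng.standard_normal(300)) + 0.1
        r = pt.circular_acf(x).values
        assert r[0] == pytest.approx(1.0)
        assert np.all(r <= 1.0 + 1e-12)

    def test_constant_series_all_ones(self):
        r = pt.circular_acf(np.full(64, 3.5)).values
        np.testing.assert_allclose(r, 1.0)

    def test_impulse_train_peaks_at_multiples_of_period(self):
        period, m = 25, 8
        x = np.zeros(period * m)
        x[::period] = 1.0
        r = pt.circular_acf(x).values
        lags = np.arange(r.size)
        on_period = lags % period == 0
        np.testing.assert_allclose(r[on_period], 1.0, atol=1e-12)
        assert np.all(np.abs(r[~on_period]) < 1e-12)

    def test_all_zero_input_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            pt.circular_acf(np.zeros(64))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="short"):
            pt.circular_acf(np.ones(3))

    def test_half_truncation_length(self):
        for n in (64, 65):
            r = pt.circular_acf(np.random.default_rng(3).standard_normal(n) + 5)
            assert r.n_lags == n // 2 + 1


class TestAcc:
    def test_self_correlation_is_one(self):
        a = pt.circular_acf(np.abs(np.random.default_rng(4).standard_normal(100)) + 0.1)
        assert pt.acc(a, a) == pytest.approx(1.0)

    def test_anticorrelated_vectors(self):
        v = np.linspace(1.0, 0.0, 40)
        a = AcfVector(v, 1.0, 80)
        b = AcfVector(v.mean() - (v - v.mean()), 1.0, 80)
        assert pt.acc(a, b) == pytest.approx(-1.0)

    def test_hand_computed_pearson_fixture(self):
        # two fixed 10-element lag vectors; expected value is the Pearson r
        # computed from the definition sum formula, frozen here
        va = np.array([1.0, 0.8, 0.5, 0.3, 0.2, 0.15, 0.3, 0.5, 0.7, 0.9])
        vb = np.array([1.0, 0.7, 0.4, 0.35, 0.25, 0.1, 0.2, 0.55, 0.65, 0.8])
        a, b = AcfVector(va, 1.0, 20), AcfVector(vb, 1.0, 20)
        sa, sb = va - va.mean(), vb - vb.mean()
        expected = float(np.sum(sa * sb) / np.sqrt(np.sum(sa**2) * np.sum(sb**2)))
        assert pt.acc(a, b) == pytest.approx(expected, abs=1e-12)
        assert pt.acc(a, b) == pytest.approx(0.9753437018752, abs=1e-10)

    def test_zero_variance_rejected(self):
        a = AcfVector(np.ones(10), 1.0, 20)
        b = AcfVector(np.linspace(1, 0, 10), 1.0, 20)
        with pytest.raises(ValueError, match="variance"):
            pt.acc(a, b)

    def test_length_mismatch_rejected(self):
        a = AcfVector(np.linspace(1, 0, 10), 1.0, 20)
        b = AcfVector(np.linspace(1, 0, 11), 1.0, 22)
        with pytest.raises(ValueError, match="lengths"):
            pt.acc(a, b)

    def test_exclude_lag0_changes_value(self):
        rng = np.random.default_rng(5)
        a = pt.circular_acf(np.abs(rng.standard_normal(200)) + 0.1)
        b = pt.circular_acf(np.abs(rng.standard_normal(200)) + 0.1)
        with_0 = pt.acc(a, b)
        without_0 = pt.acc(a, b, AccConfig(exclude_lag0=True))
        assert with_0 != without_0


class TestPhaseInvariance:
    @given(shift=st.integers(1, 14399))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_acc_invariant_to_circular_shift(self, shift, listen_block):
        stim = pt.render_envelope(listen_block, 1200.0)
        rng = np.random.default_rng(6)
        x = np.abs(rng.standard_normal(stim.n)) + 0.2
        ref = pt.stimulus_acf(stim)
        base = pt.acc(pt.circular_acf(x), ref)
        shifted = pt.acc(pt.circular_acf(np.roll(x, shift)), ref)
        assert abs(shifted - base) < 1e-6


class TestMatchRates:
    def test_downsample_44100_to_1200(self, unsync_pattern):
        block = pt.StimulusBlock(unsync_pattern, 2)
        hi = pt.render_envelope(block, 44100.0)
        lo = pt.render_envelope(block, 1200.0)
        s, n = pt.match_rates(hi, lo)
        assert s.n == n.n == 4800
        assert s.rate_hz == 1200.0

    def test_equal_rates_returned_unchanged(self, unsync_pattern):
        block = pt.StimulusBlock(unsync_pattern, 2)
        e = pt.render_envelope(block, 1200.0)
        s, n = pt.match_rates(e, e)
        assert s is e and n is e

    def test_resampling_preserves_periodicity(self, unsync_pattern):
        block = pt.StimulusBlock(unsync_pattern, 4)
        hi = pt.render_envelope(block, 44100.0)
        lo = pt.render_envelope(block, 1200.0)
        s, _ = pt.match_rates(hi, lo)
        cycle = s.n // 4
        dev = np.max(np.abs(s.values - np.roll(s.values, cycle)))
        assert dev < 1e-3 * s.values.max()

    def test_cycle_count_mismatch_rejected(self, unsync_pattern):
        two = pt.render_envelope(pt.StimulusBlock(unsync_pattern, 2), 44100.0)
        six = pt.render_envelope(pt.StimulusBlock(unsync_pattern, 6), 1200.0)
        with pytest.raises(ValueError, match="mismatch"):
            pt.match_rates(two, six)


class TestAccForTrial:
    def test_stimulus_against_itself_gives_one(self, listen_block):
        stim = pt.render_envelope(listen_block, 1200.0)
        ref = pt.stimulus_acf(stim)
        assert pt.acc(ref, ref) == pytest.approx(1.0)

    def test_records_carry_all_keys(self, listen_block):
        from conftest import make_electrodes

        electrodes = make_electrodes(1, 2)
        gt = pt.GroundTruth.uniform(electrodes, 0.8)
        trial = pt.generate_trial(listen_block, electrodes, gt, seed=0)
        band_env = pt.extract_band_envelope(trial)
        stim = pt.render_envelope(listen_block, 1200.0)
        records = pt.acc_for_trial(band_env, stim)
        assert len(records) == 3
        rec = records[0]
        assert rec.participant == "P01"
        assert rec.rhythm == pt.UNSYNCOPATED
        assert rec.band == "high_gamma"
        assert -1.0 <= rec.acc <= 1.0

    def test_tracking_channel_shifted_in_time_same_acc(self, listen_block):
        """A lagged neural response yields the identical ACC (phase invariance)."""
        from conftest import make_electrodes

        electrodes = make_electrodes(1, 0)
        stim = pt.render_envelope(listen_block, 1200.0)
        for lag_ms in (0.0, 250.0):
            gt = pt.GroundTruth(
                {"T000": pt.ElectrodeTruth(0.8, lag_ms=lag_ms)}
            )
            trial = pt.generate_trial(listen_block, electrodes, gt, seed=11)
            band_env = pt.extract_band_envelope(trial)
            rec = pt.acc_for_trial(band_env, stim)[0]
            if lag_ms == 0.0:
                base = rec.acc
        # the channel is circularly shifted relative to lag 0; the ACF is
        # shift-invariant, and the zero-phase IIR filtering is
        # shift-equivariant up to its (non-circular) edge transients
        assert rec.acc == pytest.approx(base, abs=5e-3)


class TestManyToOne:
    def test_rectified_derivative_code_is_detected(self):
        """An onset code differing pointwise from the envelope shares its
        periodicities, so its autocorrelation still matches the rhythm's."""
        from periotag.synth_ecog import rectified_derivative_code

        for symbols, tempo in ((pt.UNSYNCOPATED, 120.0), (pt.SYNCOPATED, 140.0)):
            block = pt.StimulusBlock(pt.parse_pattern(symbols, tempo), 6)
            env = pt.render_envelope(block, 1200.0)
            code = rectified_derivative_code(env.values, 1200.0)
            # genuinely a different waveform...
            assert np.max(np.abs(code / code.max() - env.values / env.values.max())) > 0.2
            # ...with the same periodicity structure
            value = pt.acc(pt.circular_acf(code), pt.stimulus_acf(env))
            assert value > 0.8
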