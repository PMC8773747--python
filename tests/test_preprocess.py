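import numpy as np
import pytest

from nirstress import HemoTimeSeries, bandpass, baseline_correct, epoch, grand_average, temporal_mean
from nirstress.preprocess import average_trials, epoch_samples

FS = 8.138
N = int(np.floor(1220 * FS)) + 1
T = np.arange(N) / FS
CENTRAL = slice(N // 4, 3 * N // 4)


def _series(x):
    data = np.tile(x, (15, 1))
    return HemoTimeSeries(dhbo=data, dhbr=np.zeros_like(data), fs_hz=FS)


def test_passband_tone_preserved():
    """A 0.015 Hz tone (inside 0.01-0.02 Hz) keeps its amplitude within 5%
    over the central half of the record."""
    out = bandpass(_series(np.sin(2 * np.pi * 0.015 * T)))
    amp = np.abs(out.dhbo[0, CENTRAL]).max()
    assert amp == pytest.approx(1.0, rel=0.05)


def test_stopband_tone_attenuated():
    """A 0.2 Hz tone is attenuated by at least 20 dB."""
    out = bandpass(_series(np.sin(2 * np.pi * 0.2 * T)))
    amp = np.abs(out.dhbo[0, CENTRAL]).max()
    assert 20 * np.log10(amp) <= -20.0


def test_dc_removed():
    out = bandpass(_series(np.ones(N)))
    assert np.abs(out.dhbo[0, CENTRAL]).max() <= 1e-3


def test_filter_is_linear(rng):
    x = rng.standard_normal(N)
    y = rng.standard_normal(N)
    fx = bandpass(_series(x)).dhbo[0]
    fy = bandpass(_series(y)).dhbo[0]
    fxy = bandpass(_series(2.0 * x + 0.5 * y)).dhbo[0]
    assert np.allclose(fxy, 2.0 * fx + 0.5 * fy, atol=1e-9)


def test_zero_phase_peak_latency_preserved():
    """Filtering a pulse symmetric about its midpoint does not move the
    output peak (zero-phase property)."""
    x = np.exp(-0.5 * ((T - T[N // 2]) / 30.0) ** 2)  # slow Gaussian bump
    out = bandpass(_series(x))
    assert abs(int(np.argmax(out.dhbo[0])) - N // 2) <= 1


def test_invalid_band_rejected():
    with pytest.raises(ValueError, match="fs/2"):
        bandpass(_series(np.zeros(N)), low_hz=0.01, high_hz=5.0)
    with pytest.raises(ValueError):
        bandpass(_series(np.zeros(N)), low_hz=0.02, high_hz=0.01)


def test_too_short_signal_rejected():
    short = HemoTimeSeries(dhbo=np.zeros((15, 10)), dhbr=np.zeros((15, 10)), fs_hz=FS)
    with pytest.raises(ValueError, match="too short"):
        bandpass(short)


class TestEpoching:
    def test_window_sample_convention(self):
        pre, post = epoch_samples(FS)
        assert pre + post + 1 == 497  # floor(61 * 8.138) + 1

    def test_one_epoch_per_onset(self, rng):
        ts = _series(rng.standard_normal(N))
        onsets = [1.0 + 61.0 * k for k in range(20)]
        ep = epoch(ts, onsets)
        assert ep.n_trials == 20
        assert ep.n_samples == 497
        assert ep.onset_index == 8

    def test_epoch_t0_alignment(self):
        """The sample at the onset index is data[floor(onset*fs)]."""
        x = np.arange(N, dtype=float)
        ep = epoch(_series(x), [100.0])
        assert ep.data[0, 0, ep.onset_index] == float(int(np.floor(100.0 * FS)))

    def test_out_of_range_onset_rejected(self):
        ts = _series(np.zeros(N))
        with pytest.raises(ValueError, match="trial 1"):
            epoch(ts, [0.5])  # pre-window would start before the record
        with pytest.raises(ValueError, match="trial 2"):
            epoch(ts, [100.0, 1219.0])


class TestBaseline:
    def test_constant_epoch_zeroed(self):
        ep = epoch(_series(np.full(N, 3.7)), [100.0])
        out = baseline_correct(ep)
        assert np.allclose(out.data, 0.0, atol=1e-12)

    def test_baseline_mean_is_zero(self, rng):
        ep = epoch(_series(rng.standard_normal(N)), [100.0, 500.0])
        out = baseline_correct(ep)
        t = out.times
        mask = (t >= -1.0) & (t < 0.0)
        assert np.abs(out.data[:, :, mask].mean(axis=2)).max() < 1e-12

    def test_ramp_offset_matches_discrete_baseline_mean(self):
        """For x(t) = t the subtracted constant equals the mean of the sampled
        baseline times (~-0.5, within one sample of the continuous value)."""
        ep = epoch(_series(T.copy()), [100.0])
        out = baseline_correct(ep)
        t_epoch = ep.times
        mask = (t_epoch >= -1.0) & (t_epoch < 0.0)
        expected_offset = ep.data[0, 0, mask].mean()
        shift = ep.data[0, 0] - out.data[0, 0]
        assert np.allclose(shift, expected_offset, atol=1e-12)
        onset_time = int(np.floor(100.0 * FS)) / FS
        assert expected_offset - onset_time == pytest.approx(-0.5, abs=1.0 / FS)

    def test_double_correction_rejected(self):
        ep = baseline_correct(epoch(_series(np.zeros(N)), [100.0]))
        with pytest.raises(ValueError, match="already"):
            baseline_correct(ep)


class TestAveraging:
    def _epochs(self, x, onsets=(100.0,)):
        return epoch(_series(x), list(onsets))

    def test_grand_average_identity_single(self, rng):
        ep = self._epochs(rng.standard_normal(N))
        assert np.allclose(grand_average([ep]), ep.data[0])

    def test_grand_average_symmetry(self, rng):
        x = rng.standard_normal(N)
        ep_pos = self._epochs(x)
        ep_neg = self._epochs(-x)
        assert np.allclose(grand_average([ep_pos, ep_neg]), 0.0)

    def test_grand_average_idempotent_for_identical(self, rng):
        ep = self._epochs(rng.standard_normal(N))
        assert np.allclose(grand_average([ep] * 5), grand_average([ep]))

    def test_shape_mismatch_rejected(self, rng):
        ep1 = self._epochs(rng.standard_normal(N))
        ep2 = epoch(_series(rng.standard_normal(N)), [100.0], window_s=(-1.0, 30.0))
        with pytest.raises(ValueError, match="mismatch"):
            grand_average([ep1, ep2])

    def test_trial_then_participant_mean(self, rng):
        eps = [self._epochs(rng.standard_normal(N), onsets=(100.0, 500.0))
               for _ in range(3)]
        manual = np.mean([e.data.mean(axis=0) for e in eps], axis=0)
        assert np.allclose(grand_average(eps), manual)
        assert np.allclose(average_trials(eps[0]), eps[0].data.mean(axis=0))


class TestTemporalMean:
    def test_zero_and_constant(self):
        ep = baseline_correct(epoch(_series(np.zeros(N)), [100.0]))
        assert np.allclose(temporal_mean(ep), 0.0)
        # epoch that is 0 before onset and 1 on the task interval
        onset_sample = int(np.floor(100.0 * FS))
        x = (np.arange(N) >= onset_sample).astype(float)
        ep1 = baseline_correct(epoch(_series(x), [100.0]))
        assert np.allclose(temporal_mean(ep1), 1.0)

    def test_full_period_sine_averages_to_zero(self):
        onset_time = int(np.floor(100.0 * FS)) / FS
        x = np.where(T >= onset_time, np.sin(2 * np.pi * (T - onset_time) / 60.0), 0.0)
        ep = baseline_correct(epoch(_series(x), [100.0]))
        # one full period on [0, 60]: mean vanishes up to quadrature error
        assert np.abs(temporal_mean(ep)).max() < 2.0 / (60.0 * FS)

    def test_requires_baseline_and_valid_interval(self):
        ep = epoch(_series(np.zeros(N)), [100.0])
        with pytest.raises(ValueError, match="baseline"):
            temporal_mean(ep)
        with pytest.raises(ValueError, match="outside"):
            temporal_mean(baseline_correct(ep), interval_s=(0.0, 120.0))
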