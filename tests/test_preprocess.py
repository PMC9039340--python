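"""Filtering, resampling, bad-channel handling, referencing, epoching."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal as sps

from cortrack import (
    BAND_FILTERS,
    FilterSpec,
    SynthConfig,
    average_reference,
    average_repetitions,
    bandpass,
    detect_bad_channels,
    downsample,
    epoch,
    gen_layout,
    gen_session,
    interpolate_channels,
)
from cortrack.preprocess import design_fir

from conftest import multi_channel_recording, single_channel_recording

FS = 100.0


class TestFIRDesign:
    @pytest.mark.parametrize("spec", [BAND_FILTERS["theta"], BAND_FILTERS["alpha"],
                                      BAND_FILTERS["broadband"]])
    def test_minus_6db_at_cutoffs(self, spec):
        fs = 200.0
        taps = design_fir(spec, fs)
        w, h = sps.freqz(taps, worN=16384, fs=fs)
        for f0 in [c for c in (spec.band_lo, spec.band_hi) if 0 < c < fs / 2]:
            mag = abs(h[np.argmin(abs(w - f0))])
            assert abs(mag - 0.5) < 0.05

    def test_passband_ripple_below_1db(self):
        spec = BAND_FILTERS["theta"]
        taps = design_fir(spec, FS)
        w, h = sps.freqz(taps, worN=16384, fs=FS)
        passband = (w > spec.band_lo + spec.transition_width) & (
            w < spec.band_hi - spec.transition_width
        )
        mags = abs(h[passband])
        assert mags.min() > 10 ** (-1 / 20)
        assert mags.max() < 10 ** (1 / 20)

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            FilterSpec(5.0, 3.0)


class TestBandpass:
    def test_out_of_band_sine_suppressed(self):
        t = np.arange(int(60 * FS)) / FS
        x = np.sin(2 * np.pi * 10.0 * t)
        rec = single_channel_recording(x)
        out = bandpass(rec, FilterSpec(0.5, 4.0))
        interior = slice(500, -500)
        ratio = np.std(out.data[0][interior]) / np.std(x[interior])
        assert ratio < 0.05

    def test_zero_signal_stays_zero(self):
        rec = single_channel_recording(np.zeros(4000))
        out = bandpass(rec, BAND_FILTERS["theta"])
        assert np.allclose(out.data, 0.0)

    def test_zero_phase_pulse_correlation_peaks_at_lag_zero(self):
        x = np.zeros(4000)
        x[2000] = 1.0
        rec = single_channel_recording(x)
        out = bandpass(rec, BAND_FILTERS["theta"])
        xc = np.correlate(out.data[0], x, mode="full")
        assert np.argmax(np.abs(xc)) == len(x) - 1  # lag 0

    def test_linearity(self, rng):
        x = rng.standard_normal(3000)
        y = rng.standard_normal(3000)
        a, b = 1.7, -0.4
        spec = BAND_FILTERS["theta"]
        lhs = bandpass(single_channel_recording(a * x + b * y), spec).data
        rhs = a * bandpass(single_channel_recording(x), spec).data + b * bandpass(
            single_channel_recording(y), spec
        ).data
        assert np.allclose(lhs, rhs, atol=1e-9)

    def test_too_short_recording_rejected(self):
        rec = single_channel_recording(np.zeros(100))
        with pytest.raises(ValueError):
            bandpass(rec, BAND_FILTERS["theta"])

    def test_provenance_appended(self):
        rec = single_channel_recording(np.zeros(4000))
        out = bandpass(rec, BAND_FILTERS["delta"])
        assert out.meta[-1]["op"] == "bandpass"


class TestDownsample:
    def test_slow_sine_amplitude_preserved(self):
        fs_hi = 1000.0
        t = np.arange(int(10 * fs_hi)) / fs_hi
        x = np.sin(2 * np.pi * 2.0 * t)
        out = downsample(single_channel_recording(x, fs_hi), 100.0)
        assert out.fs == 100.0
        interior = out.data[0][100:-100]
        amp = (interior.max() - interior.min()) / 2
        assert abs(amp - 1.0) < 0.01

    def test_output_length(self):
        out = downsample(single_channel_recording(np.zeros(10000), 1000.0), 100.0)
        assert out.n_samples == 1000

    def test_upsampling_rejected(self):
        with pytest.raises(ValueError):
            downsample(single_channel_recording(np.zeros(1000), 100.0), 1000.0)


class TestBadChannels:
    def test_spiky_channel_flagged(self, rng):
        data = rng.standard_normal((16, 2000))
        data[5, ::100] = 40.0  # huge-kurtosis spikes
        bad = detect_bad_channels(multi_channel_recording(data))
        assert 5 in bad

    def test_flat_channel_flagged(self, rng):
        data = rng.standard_normal((16, 2000))
        data[3] = 0.0
        bad = detect_bad_channels(multi_channel_recording(data))
        assert 3 in bad

    def test_clean_gaussian_channels_rarely_flagged(self):
        n_flagged = 0
        for seed in range(50):
            data = np.random.default_rng(seed).standard_normal((16, 1000))
            n_flagged += detect_bad_channels(multi_channel_recording(data)).size
        assert n_flagged / (50 * 16) < 0.01

    def test_too_few_channels_rejected(self, rng):
        with pytest.raises(ValueError):
            detect_bad_channels(multi_channel_recording(rng.standard_normal((4, 500))))


class TestInterpolation:
    def test_constant_field_reproduced(self):
        lay = gen_layout(32, seed=0)
        data = np.full((32, 20), 3.7)
        rec = multi_channel_recording(data)
        out = interpolate_channels(rec, np.array([4]))
        assert np.allclose(out.data[4], 3.7, atol=1e-6)

    def test_hold_one_out_on_smooth_topography(self, layout128):
        # smooth spatial field: low-order function of position
        pos = layout128.positions
        field = 1.0 + pos @ np.array([0.3, -0.2, 0.5]) + pos[:, 2] ** 2
        from cortrack.core import EEGRecording

        rec = EEGRecording(np.tile(field[:, None], (1, 5)), FS, layout128)
        out = interpolate_channels(rec, np.array([0]))
        rel_err = abs(out.data[0, 0] - field[0]) / abs(field[0])
        assert rel_err < 0.10

    def test_empty_bad_list_is_identity(self, rng):
        rec = multi_channel_recording(rng.standard_normal((8, 100)))
        out = interpolate_channels(rec, np.array([], dtype=int))
        assert np.array_equal(out.data, rec.data)

    def test_good_channels_unchanged(self, rng):
        rec = multi_channel_recording(rng.standard_normal((16, 50)))
        out = interpolate_channels(rec, np.array([2, 7]))
        keep = [i for i in range(16) if i not in (2, 7)]
        assert np.array_equal(out.data[keep], rec.data[keep])

    def test_too_few_good_channels_rejected(self, rng):
        rec = multi_channel_recording(rng.standard_normal((5, 50)))
        with pytest.raises(ValueError):
            interpolate_channels(rec, np.array([0, 1]))


class TestAverageReference:
    def test_column_means_zero_and_idempotent(self, rng):
        rec = multi_channel_recording(rng.standard_normal((8, 200)) + 5.0)
        once = average_reference(rec)
        assert np.abs(once.data.mean(axis=0)).max() < 1e-9
        twice = average_reference(once)
        assert np.allclose(twice.data, once.data, atol=1e-12)

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            average_reference(single_channel_recording(np.zeros(10)))


class TestEpoching:
    def test_83_phrases_by_3_repetitions_gives_249_epochs_then_83_trials(self):
        cfg = SynthConfig(n_channels=4, fs=FS, n_phrases=83, n_repetitions=3, seed=0)
        rec, _, ann = gen_session(cfg)
        ep = epoch(rec, ann)
        assert len(ep) == 249
        avg = average_repetitions(ep)
        assert len(avg) == 83

    def test_empty_annotations_give_empty_epochset(self, rng):
        rec = multi_channel_recording(rng.standard_normal((8, 1000)))
        ep = epoch(rec, pd.DataFrame(columns=["phrase_id", "repetition", "onset_s", "offset_s"]))
        assert len(ep) == 0

    def test_out_of_bounds_annotation_names_phrase(self, rng):
        rec = multi_channel_recording(rng.standard_normal((8, 1000)))
        ann = pd.DataFrame(
            [{"phrase_id": "P9", "repetition": 1, "onset_s": 5.0, "offset_s": 20.0}]
        )
        with pytest.raises(ValueError, match="P9"):
            epoch(rec, ann)

    def test_noisy_channel_interpolated_in_its_epoch_only(self, rng):
        data = rng.standard_normal((16, 3000))
        data[2, 500:700:10] = 50.0  # spikes confined to the first epoch
        rec = multi_channel_recording(data)
        ann = pd.DataFrame(
            [
                {"phrase_id": "A", "repetition": 1, "onset_s": 5.0, "offset_s": 9.0},
                {"phrase_id": "B", "repetition": 1, "onset_s": 15.0, "offset_s": 19.0},
            ]
        )
        ep = epoch(rec, ann)
        ids_a = ep.interp_log.get(("A", 1), [])
        ids_b = ep.interp_log.get(("B", 1), [])
        assert rec.layout.ids[2] in ids_a
        assert rec.layout.ids[2] not in ids_b


class TestAverageRepetitions:
    def _epochset(self, arrays, fs=FS):
        from cortrack.core import Epoch, EpochSet

        lay = gen_layout(4, seed=0)
        eps = [Epoch(pid, rep, d) for (pid, rep, d) in arrays]
        return EpochSet(epochs=eps, fs=fs, layout=lay)

    def test_identical_repetitions_average_to_themselves(self, rng):
        d = rng.standard_normal((4, 100))
        ep = self._epochset([("P1", r, d.copy()) for r in (1, 2, 3)])
        avg = average_repetitions(ep)
        assert np.allclose(avg.epochs[0].data, d)

    def test_opposite_repetitions_cancel(self, rng):
        d = rng.standard_normal((4, 100))
        ep = self._epochset([("P1", 1, d), ("P1", 2, -d)])
        avg = average_repetitions(ep)
        assert np.allclose(avg.epochs[0].data, 0.0)

    def test_unequal_lengths_truncated_and_logged(self, rng):
        ep = self._epochset(
            [("P1", 1, rng.standard_normal((4, 100))),
             ("P1", 2, rng.standard_normal((4, 90)))]
        )
        avg = average_repetitions(ep)
        assert avg.epochs[0].data.shape[1] == 90
        assert "P1" in avg.meta[-1]["truncated"]
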