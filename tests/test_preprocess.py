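"""Filtering, line-noise removal, epoching, referencing, ocular cleanup."""

import numpy as np
import pytest

from alphagate.containers import ConfigurationError, RawRecording
from alphagate.montage import EEG_CHANNELS_32, EOG_CHANNELS
from alphagate.preprocess import (
    EmptyEpochSetError,
    MinEpochsError,
    bandpass_filter,
    enforce_min_epochs,
    extract_epochs,
    flag_artifacts,
    remove_line_noise,
    remove_ocular_artifacts,
    rereference_linked_mastoids,
)
from alphagate.synthetic import inject_artifacts

FS = 500.0


def make_raw(signal, n_channels=2, events=()):
    sig = np.atleast_2d(signal)
    data = np.repeat(sig, n_channels, axis=0) if sig.shape[0] == 1 else sig
    return RawRecording(
        signal=data,
        channel_names=[f"ch{i}" for i in range(data.shape[0])],
        sampling_rate=FS,
        events=list(events),
    )


def rms(x):
    return float(np.sqrt(np.mean(np.square(x))))


class TestBandpass:
    def test_midband_amplitude_preserved(self):
        t = np.arange(30 * int(FS)) / FS
        raw = make_raw(np.sin(2 * np.pi * 10 * t)[None, :])
        out = bandpass_filter(raw, 0.5, 40.0)
        mid = slice(5000, -5000)
        assert rms(out.signal[0, mid]) == pytest.approx(rms(raw.signal[0, mid]), rel=0.01)

    @pytest.mark.parametrize("freq,min_db", [(50.0, 20.0), (0.25, 20.0)])
    def test_stopband_attenuation(self, freq, min_db):
        t = np.arange(60 * int(FS)) / FS
        raw = make_raw(np.sin(2 * np.pi * freq * t)[None, :])
        out = bandpass_filter(raw, 0.5, 40.0)
        mid = slice(10000, -10000)
        atten = 20 * np.log10(rms(raw.signal[0, mid]) / max(rms(out.signal[0, mid]), 1e-12))
        assert atten >= min_db

    def test_dc_offset_removed(self):
        raw = make_raw(np.full((1, 40 * int(FS)), 100.0))
        out = bandpass_filter(raw, 0.5, 40.0)
        assert abs(out.signal[0, 4000:-4000].mean()) < 1.0

    def test_invalid_band_refused(self):
        raw = make_raw(np.zeros((1, 5000)))
        with pytest.raises(ConfigurationError):
            bandpass_filter(raw, 40.0, 0.5)
        with pytest.raises(ConfigurationError):
            bandpass_filter(raw, 0.5, 300.0)

    def test_linearity(self, rng):
        x = rng.standard_normal((1, 8000))
        y = rng.standard_normal((1, 8000))
        fx = bandpass_filter(make_raw(x), 0.5, 40).signal
        fy = bandpass_filter(make_raw(y), 0.5, 40).signal
        fxy = bandpass_filter(make_raw(2 * x + 3 * y), 0.5, 40).signal
        np.testing.assert_allclose(fxy, 2 * fx + 3 * fy, atol=1e-8)


class TestLineNoise:
    def test_line_component_removed_neighbour_preserved(self):
        t = np.arange(20 * int(FS)) / FS
        sig = 3 * np.sin(2 * np.pi * 10 * t) + 2 * np.sin(2 * np.pi * 60 * t)
        out = remove_line_noise(make_raw(sig[None, :]), 60.0)
        spec = np.fft.rfft(out.signal[0])
        freqs = np.fft.rfftfreq(out.signal.shape[1], 1 / FS)

        def amp_at(f):
            return np.abs(spec[np.argmin(np.abs(freqs - f))]) * 2 / out.signal.shape[1]

        assert amp_at(60.0) < 2 * 10 ** (-20 / 20)  # >= 20 dB down
        assert amp_at(10.0) == pytest.approx(3.0, rel=0.05)

    def test_no_line_component_is_near_identity(self, rng):
        # band-limit the noise below 40 Hz so it truly has no 60 Hz content
        white = rng.standard_normal((2, 10 * int(FS)))
        spec = np.fft.rfft(white, axis=1)
        freqs = np.fft.rfftfreq(white.shape[1], 1 / FS)
        spec[:, freqs > 40.0] = 0.0
        sig = np.fft.irfft(spec, n=white.shape[1], axis=1)
        out = remove_line_noise(make_raw(sig), 60.0)
        assert rms(out.signal - sig) / rms(sig) < 0.01

    def test_pure_line_mostly_removed(self):
        t = np.arange(10 * int(FS)) / FS
        sig = np.sin(2 * np.pi * 60 * t)[None, :]
        out = remove_line_noise(make_raw(sig), 60.0)
        assert rms(out.signal) < 0.1 * rms(sig)

    def test_bad_frequency_refused(self):
        with pytest.raises(ConfigurationError):
            remove_line_noise(make_raw(np.zeros((1, 5000))), 55.0)


class TestExtractEpochs:
    @staticmethod
    def _raw_with_events(hands, n=40000):
        rng = np.random.default_rng(0)
        events = [
            (2000 + 1500 * i, "resp", hand) for i, hand in enumerate(hands)
        ]
        return make_raw(rng.standard_normal((2, n)), events=events)

    def test_contralesional_hand_selection(self):
        raw = self._raw_with_events(["left", "right", "right", "left"])
        es = extract_epochs(raw, "left")  # left lesion -> right hand
        assert es.n_epochs == 2
        es2 = extract_epochs(raw, "right")
        assert es2.n_epochs == 2

    def test_all_matching_events_epoched(self):
        raw = self._raw_with_events(["right"] * 20)
        es = extract_epochs(raw, "left")
        assert es.n_epochs == 20

    def test_edge_event_dropped_with_warning(self, caplog):
        raw = make_raw(
            np.zeros((2, 5000)),
            events=[(100, "resp", "right"), (2000, "resp", "right")],
        )
        with caplog.at_level("WARNING"):
            es = extract_epochs(raw, "left")
        assert es.n_epochs == 1
        assert any("dropping event" in r.message for r in caplog.records)

    def test_no_qualifying_events_is_explicit_error(self):
        raw = self._raw_with_events(["left", "left"])
        with pytest.raises(EmptyEpochSetError):
            extract_epochs(raw, "left")

    def test_epoching_is_pure_slicing(self):
        rng = np.random.default_rng(1)
        raw = make_raw(rng.standard_normal((2, 10000)),
                       events=[(3000, "resp", "right")])
        es = extract_epochs(raw, "left")
        np.testing.assert_array_equal(es.epochs[0], raw.signal[:, 2500:3500])
        assert es.time_axis[es.onset_index] == 0.0
        assert es.time_axis.size == 1000  # half-open [-1, 1) at 500 Hz


class TestRereference:
    @staticmethod
    def _epochs(data):
        from alphagate.containers import EpochSet

        names = list(EEG_CHANNELS_32) + list(EOG_CHANNELS)
        t = (np.arange(data.shape[2]) - data.shape[2] // 2) / FS
        return EpochSet("S", "pre", "left", data, t, names, FS)

    def test_zero_mastoids_is_identity(self, rng):
        data = rng.standard_normal((2, 34, 100))
        names = list(EEG_CHANNELS_32)
        data[:, names.index("TP9")] = 0.0
        data[:, names.index("TP10")] = 0.0
        es = self._epochs(data)
        out = rereference_linked_mastoids(es)
        np.testing.assert_allclose(out.epochs, es.epochs)

    def test_constant_mastoids_shift_all_channels(self, rng):
        data = np.zeros((1, 34, 50))
        names = list(EEG_CHANNELS_32)
        data[:, names.index("TP9")] = 5.0
        data[:, names.index("TP10")] = 5.0
        out = rereference_linked_mastoids(self._epochs(data))
        cz = names.index("Cz")
        np.testing.assert_allclose(out.epochs[0, cz], -5.0)

    def test_idempotent_after_first_application(self, rng):
        data = rng.standard_normal((2, 34, 100))
        once = rereference_linked_mastoids(self._epochs(data))
        twice = rereference_linked_mastoids(once)
        np.testing.assert_allclose(once.epochs, twice.epochs, atol=1e-12)
        assert once.reference_state == "linked_mastoids"

    def test_linearity(self, rng):
        x = rng.standard_normal((1, 34, 60))
        y = rng.standard_normal((1, 34, 60))
        rx = rereference_linked_mastoids(self._epochs(x)).epochs
        ry = rereference_linked_mastoids(self._epochs(y)).epochs
        rxy = rereference_linked_mastoids(self._epochs(2 * x - y)).epochs
        np.testing.assert_allclose(rxy, 2 * rx - ry, atol=1e-10)

    def test_missing_mastoids_refused(self, rng):
        from alphagate.containers import EpochSet

        es = EpochSet("S", "pre", "left", rng.standard_normal((1, 2, 50)),
                      (np.arange(50) - 25) / FS, ["Cz", "Fz"], FS)
        with pytest.raises(ConfigurationError):
            rereference_linked_mastoids(es)


class TestOcularRemoval:
    def test_zero_eog_coupling_near_identity(self, small_epochs):
        """With no planted blinks no component crosses the threshold and
        the full-rank reconstruction error stays below 1% RMS."""
        n_eeg = len(small_epochs.channel_names) - 2
        out, n_removed = remove_ocular_artifacts(
            small_epochs, n_components=n_eeg, seed=0
        )
        assert n_removed == 0
        err = rms(out.epochs - small_epochs.epochs) / rms(small_epochs.epochs)
        assert err < 0.01

    def test_unreachable_threshold_identity(self, small_epochs):
        n_eeg = len(small_epochs.channel_names) - 2
        out, n_removed = remove_ocular_artifacts(
            small_epochs, threshold=1.01, n_components=n_eeg, seed=0
        )
        assert n_removed == 0
        err = rms(out.epochs - small_epochs.epochs) / rms(small_epochs.epochs)
        assert err < 0.01

    def test_planted_blinks_removed_alpha_preserved(self, small_epochs, rng):
        """Ground-truth blinks: frontal peak-to-peak drops by >= 50% on
        contaminated epochs while posterior alpha RMS moves < 10%."""
        dirty, injected = inject_artifacts(small_epochs, 0.6, np.random.default_rng(3))
        assert injected
        names = dirty.channel_names
        n_eeg = len(names) - 2
        clean, n_removed = remove_ocular_artifacts(dirty, n_components=n_eeg, seed=0)
        assert n_removed >= 1
        fp = [names.index(c) for c in ("Fp1", "Fp2")]
        post = [names.index(c) for c in ("O1", "O2", "Pz")]
        for ep in injected:
            ptp_dirty = np.ptp(dirty.epochs[ep][fp], axis=1).max()
            ptp_clean = np.ptp(clean.epochs[ep][fp], axis=1).max()
            assert ptp_clean < 0.5 * ptp_dirty
        rms_before = rms(small_epochs.epochs[:, post, :])
        rms_after = rms(clean.epochs[:, post, :])
        assert abs(rms_after - rms_before) / rms_before < 0.10

    def test_failed_backend_falls_back_to_regression(self, small_epochs, caplog):
        def broken(data, n_components, seed):
            raise RuntimeError("boom")

        with caplog.at_level("WARNING"):
            out, n_removed = remove_ocular_artifacts(small_epochs, backend=broken)
        assert n_removed == 0
        assert any("falling back" in r.message for r in caplog.records)
        assert out.epochs.shape == small_epochs.epochs.shape

    def test_requires_eog_channel(self, rng):
        from alphagate.containers import EpochSet

        es = EpochSet("S", "pre", "left", rng.standard_normal((2, 2, 100)),
                      (np.arange(100) - 50) / FS, ["Cz", "Pz"], FS)
        with pytest.raises(ConfigurationError):
            remove_ocular_artifacts(es)


class TestGate:
    @staticmethod
    def _epochs(n, flags=None):
        from alphagate.containers import EpochSet

        rng = np.random.default_rng(0)
        es = EpochSet("S01", "pre", "left", rng.standard_normal((n, 3, 100)),
                      (np.arange(100) - 50) / FS, ["Cz", "TP9", "TP10"], FS)
        if flags is not None:
            es.artifact_flags[: len(flags)] = flags
        return es

    def test_flagged_epochs_dropped(self):
        es = self._epochs(60, [True] * 5)
        out = enforce_min_epochs(es, minimum=50)
        assert out.n_epochs == 55
        assert not out.artifact_flags.any()

    def test_below_minimum_raises_with_count(self):
        es = self._epochs(60, [True] * 15)
        with pytest.raises(MinEpochsError) as exc:
            enforce_min_epochs(es, minimum=50)
        assert exc.value.n_clean == 45
        assert exc.value.subject_id == "S01"

    def test_exactly_minimum_passes(self):
        es = self._epochs(50)
        assert enforce_min_epochs(es, minimum=50).n_epochs == 50

    def test_amplitude_flagging(self):
        es = self._epochs(10)
        es.epochs[3, 0, 10] = 500.0  # gross excursion on an EEG channel
        out = flag_artifacts(es, ptp_threshold_uv=150.0)
        assert out.artifact_flags[3]
        assert out.artifact_flags.sum() == 1
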