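"""Filtering, re-referencing, channel selection and segmentation contracts."""

import numpy as np
import pytest
from scipy import signal as sps

from iedgan.data import MultichannelRecording
from iedgan.errors import (InvalidInputError, InvalidParameterError,
                           MissingChannelError)
from iedgan.preprocessing import (DEFAULT_SCALP_SELECTION, bandpass,
                                  common_average_reference, extract_segments,
                                  notch, select_scalp_channels)

FS = 200.0


def _sine(freq: float, seconds: float = 20.0, n_ch: int = 2) -> MultichannelRecording:
    t = np.arange(int(seconds * FS)) / FS
    data = np.tile(np.sin(2 * np.pi * freq * t)[:, None], (1, n_ch))
    return MultichannelRecording(data, FS, [f"ch{i}" for i in range(n_ch)])


def _steady_amp(rec: MultichannelRecording) -> float:
    trim = int(2 * FS)                      # discard filter transients
    return np.abs(rec.data[trim:-trim, 0]).max()


class TestBandpass:
    def test_dc_removed(self):
        rec = MultichannelRecording(np.full((4000, 2), 5.0), FS, ["a", "b"])
        out = bandpass(rec)
        assert _steady_amp(out) < 0.05      # <1% of the DC input

    def test_passband_and_stopband_match_designed_response(self):
        sos = sps.butter(4, [1.0, 70.0], btype="bandpass", fs=FS, output="sos")
        for freq, cond in [(10.0, lambda a: abs(a - 1.0) < 0.05),
                           (90.0, lambda a: a < 10 ** (-20 / 20))]:
            out = bandpass(_sine(freq))
            amp = _steady_amp(out)
            # oracle: squared magnitude response of the zero-phase cascade
            _, h = sps.sosfreqz(sos, worN=[freq], fs=FS)
            assert cond(amp)
            assert amp == pytest.approx(np.abs(h[0]) ** 2, abs=0.02)

    def test_shape_and_labels_preserved(self, tiny_subject):
        out = bandpass(tiny_subject.seeg)
        assert out.data.shape == tiny_subject.seeg.data.shape
        assert out.labels == tiny_subject.seeg.labels

    @pytest.mark.parametrize("low,high", [(0.0, 70.0), (70.0, 1.0), (1.0, 100.0)])
    def test_invalid_cutoffs(self, low, high):
        with pytest.raises(InvalidParameterError):
            bandpass(_sine(10.0), low, high)


class TestNotch:
    def test_rejects_mains_passes_signal(self):
        assert _steady_amp(notch(_sine(50.0))) < 10 ** (-30 / 20)
        assert _steady_amp(notch(_sine(10.0))) == pytest.approx(1.0, abs=0.05)

    def test_zero_input_zero_output(self):
        rec = MultichannelRecording(np.zeros((1000, 3)), FS, list("abc"))
        assert not notch(rec).data.any()

    def test_invalid_frequency(self):
        with pytest.raises(InvalidParameterError):
            notch(_sine(10.0), freq=150.0)


class TestCommonAverageReference:
    def test_two_channel_example(self):
        rec = MultichannelRecording(np.array([[1.0, 3.0]]), FS, ["a", "b"])
        np.testing.assert_allclose(common_average_reference(rec).data, [[-1.0, 1.0]])

    def test_zero_mean_at_every_sample(self, tiny_subject):
        out = common_average_reference(tiny_subject.seeg)
        np.testing.assert_allclose(out.data.mean(axis=1), 0.0, atol=1e-10)

    def test_idempotent_on_zero_mean_input(self, rng):
        data = rng.standard_normal((100, 4))
        data -= data.mean(axis=1, keepdims=True)
        rec = MultichannelRecording(data, FS, list("abcd"))
        np.testing.assert_allclose(common_average_reference(rec).data, data)

    def test_single_channel_rejected(self):
        rec = MultichannelRecording(np.ones((10, 1)), FS, ["only"])
        with pytest.raises(InvalidInputError):
            common_average_reference(rec)


class TestChannelSelection:
    def test_default_selection_order(self, tiny_subject):
        out = select_scalp_channels(tiny_subject.seeg)
        assert out.labels == DEFAULT_SCALP_SELECTION
        assert out.data.shape[1] == 12
        i = tiny_subject.seeg.labels.index("T3")
        np.testing.assert_array_equal(out.data[:, 4], tiny_subject.seeg.data[:, i])

    def test_identity_selection(self, tiny_subject):
        out = select_scalp_channels(tiny_subject.seeg, tiny_subject.seeg.labels)
        np.testing.assert_array_equal(out.data, tiny_subject.seeg.data)

    def test_missing_channel_named_in_error(self):
        rec = MultichannelRecording(np.zeros((10, 2)), FS, ["Fp1", "Fp2"])
        with pytest.raises(MissingChannelError, match="Oz"):
            select_scalp_channels(rec, ["Fp1", "Oz"])


class TestFilterComposition:
    def test_order_insensitive_in_passband(self, rng):
        data = rng.standard_normal((4000, 3))
        rec = MultichannelRecording(data, FS, list("abc"))
        ab = notch(bandpass(rec)).data
        ba = bandpass(notch(rec)).data
        trim = int(2 * FS)
        resid = np.abs(ab - ba)[trim:-trim]
        assert resid.max() < 1e-3 * np.abs(ab[trim:-trim]).max()


class TestExtractSegments:
    def test_window_indexing_covers_p_minus_32_to_p_plus_31(self, tiny_preprocessed):
        segs = extract_segments(tiny_preprocessed, seed=0)
        ied = [s for s in segs if s.label == 1]
        s0 = ied[0]
        p = s0.peak_sample
        np.testing.assert_array_equal(
            s0.y_intracranial, tiny_preprocessed.ieeg.data[p - 32: p + 32])
        assert s0.x_scalp.shape == (64, 12) and s0.y_intracranial.shape == (64, 12)

    def test_balanced_counts_one_per_peak(self, tiny_preprocessed):
        segs = extract_segments(tiny_preprocessed, seed=0)
        n_ied, n_non = segs.class_counts
        assert n_ied == n_non == len(tiny_preprocessed.ied_peaks)

    def test_non_ied_windows_respect_guard_interval(self, tiny_preprocessed):
        segs = extract_segments(tiny_preprocessed, seed=0)
        peaks = np.asarray(tiny_preprocessed.ied_peaks)
        data = tiny_preprocessed.ieeg.data
        for s in segs:
            if s.label == 1:
                continue
            # locate the window start by matching its first sample row
            cand = np.flatnonzero((data[:-63] == s.y_intracranial[0]).all(axis=1))
            starts = [t for t in cand if np.array_equal(data[t:t + 64], s.y_intracranial)]
            assert len(starts) == 1
            t = starts[0]
            dists = np.minimum(np.abs(peaks - t), np.abs(peaks - (t + 63)))
            assert (dists > 64).all()

    def test_zero_peaks_zero_segments(self, tiny_preprocessed):
        from iedgan.data import PairedRecording
        empty = PairedRecording(tiny_preprocessed.seeg, tiny_preprocessed.ieeg,
                                np.empty(0, dtype=int), "S0")
        assert len(extract_segments(empty, seed=0)) == 0

    def test_seeded_subsampling_is_deterministic(self, tiny_preprocessed):
        a = extract_segments(tiny_preprocessed, seed=5)
        b = extract_segments(tiny_preprocessed, seed=5)
        np.testing.assert_array_equal(a.stack_x(), b.stack_x())

    def test_requires_12_channel_scalp(self, tiny_subject):
        with pytest.raises(InvalidInputError):
            extract_segments(tiny_subject, seed=0)    # 20 channels, unpreprocessed
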