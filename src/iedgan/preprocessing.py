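"""Filtering, re-referencing, channel selection and peak-centred segmentation.

The clinical pipeline: zero-phase 1–70 Hz band-pass plus 50 Hz notch on both
modalities, common average reference (CAR) on the scalp only, reduction of the
20 scalp electrodes to the 12 fronto-temporal channels matched to the 12
intracranial contacts, then extraction of 64-sample windows (32 samples either
side of each annotated peak) and of an equal number of IED-free windows.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import signal

from .data import SEGMENT_LEN, MultichannelRecording, PairedRecording, Segment, SegmentSet
from .errors import InvalidInputError, InvalidParameterError, MissingChannelError

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_SCALP_SELECTION", "bandpass", "notch", "common_average_reference",
    "select_scalp_channels", "preprocess_paired", "extract_segments",
]

# The 12 fronto-temporal scalp channels retained for translation.
DEFAULT_SCALP_SELECTION = ["Fp1", "F3", "F7", "C3", "T3", "Fp2",
                           "F4", "F8", "C4", "T4", "Fz", "Cz"]

HALF_WIDTH = 32          # samples either side of a peak -> 64-sample window
GUARD = 64               # IED-free guard interval either side of every peak


def bandpass(rec: MultichannelRecording, low: float = 1.0,
             high: float = 70.0) -> MultichannelRecording:
    """Zero-phase 4th-order Butterworth band-pass, per channel."""
    nyq = rec.sampling_rate / 2.0
    if not 0 < low < high < nyq:
        raise InvalidParameterError(
            f"cutoffs must satisfy 0 < {low} < {high} < Nyquist ({nyq})")
    sos = signal.butter(4, [low, high], btype="bandpass", fs=rec.sampling_rate,
                        output="sos")
    return rec.copy_with(signal.sosfiltfilt(sos, rec.data, axis=0))


def notch(rec: MultichannelRecording, freq: float = 50.0,
          quality: float = 30.0) -> MultichannelRecording:
    """Zero-phase IIR notch (quality factor 30 by default)."""
    nyq = rec.sampling_rate / 2.0
    if not 0 < freq < nyq:
        raise InvalidParameterError(f"notch frequency must lie in (0, {nyq})")
    b, a = signal.iirnotch(freq, quality, fs=rec.sampling_rate)
    return rec.copy_with(signal.filtfilt(b, a, rec.data, axis=0))


def common_average_reference(rec: MultichannelRecording) -> MultichannelRecording:
    """Subtract the across-channel mean at every sample (scalp re-referencing)."""
    if rec.n_channels < 2:
        raise InvalidInputError("CAR requires at least 2 channels")
    return rec.copy_with(rec.data - rec.data.mean(axis=1, keepdims=True))


def select_scalp_channels(rec: MultichannelRecording,
                          wanted: list[str] | None = None) -> MultichannelRecording:
    """Reorder/reduce columns to ``wanted`` (default: the 12 fronto-temporal names)."""
    wanted = DEFAULT_SCALP_SELECTION if wanted is None else list(wanted)
    missing = [w for w in wanted if w not in rec.labels]
    if missing:
        raise MissingChannelError(f"channel(s) not present: {', '.join(missing)}")
    idx = [rec.labels.index(w) for w in wanted]
    return rec.copy_with(rec.data[:, idx], labels=wanted)


def preprocess_paired(paired: PairedRecording, low: float = 1.0, high: float = 70.0,
                      notch_freq: float = 50.0,
                      scalp_channels: list[str] | None = None) -> PairedRecording:
    """Full per-subject preprocessing.

    Both modalities are band-passed and notch-filtered; the scalp additionally
    gets CAR (computed on all available electrodes) and is then reduced to the
    12 matched channels.  The intracranial stream is never re-referenced.
    """
    seeg = notch(bandpass(paired.seeg, low, high), notch_freq)
    seeg = select_scalp_channels(common_average_reference(seeg), scalp_channels)
    ieeg = notch(bandpass(paired.ieeg, low, high), notch_freq)
    return PairedRecording(seeg=seeg, ieeg=ieeg, ied_peaks=paired.ied_peaks,
                           subject_id=paired.subject_id)


def _window(data: np.ndarray, p: int) -> np.ndarray:
    return data[p - HALF_WIDTH: p + HALF_WIDTH]


def extract_segments(paired: PairedRecording, half_width: int = HALF_WIDTH,
                     guard: int = GUARD, seed: int = 0) -> SegmentSet:
    """Peak-centred IED windows plus an equal number of IED-free windows.

    IED windows are the half-open ``[p - 32, p + 32)`` around every annotated
    peak (peaks too close to an edge are skipped with a warning).  Non-IED
    windows are drawn, non-overlapping, from stretches farther than ``guard``
    samples from every peak; the majority class is randomly subsampled (seeded)
    so the two class counts are equal.
    """
    if half_width != HALF_WIDTH:
        raise InvalidParameterError("segment windows are fixed at 64 samples (half-width 32)")
    rng = np.random.default_rng(seed)
    n = paired.n_samples
    sid = paired.subject_id
    x_data, y_data = paired.seeg.data, paired.ieeg.data
    if x_data.shape[1] != 12:
        raise InvalidInputError(
            "scalp stream must be preprocessed to 12 channels before segmentation")

    ied = []
    for p in np.asarray(paired.ied_peaks, dtype=int):
        if p - half_width < 0 or p + half_width > n:
            logger.warning("skipping peak %d of %s: too close to an edge", p, sid)
            continue
        ied.append(Segment(_window(x_data, p), _window(y_data, p), 1, sid,
                           peak_sample=int(p)))

    # starts s such that [s, s+64) avoids every guard interval [p-guard, p+guard]
    forbidden = np.zeros(n, dtype=bool)
    for p in np.asarray(paired.ied_peaks, dtype=int):
        forbidden[max(0, p - guard): min(n, p + guard + 1)] = True
    free = ~forbidden
    starts = []
    s = 0
    while s + 2 * half_width <= n:
        if free[s: s + 2 * half_width].all():
            starts.append(s)
            s += 2 * half_width       # keep non-IED windows disjoint
        else:
            s += 1
    starts = np.array(starts, dtype=int)

    n_non = min(len(starts), len(ied)) if ied else 0
    non_ied = []
    if n_non > 0:
        chosen = rng.choice(starts, size=n_non, replace=False)
        non_ied = [Segment(x_data[s: s + 2 * half_width],
                           y_data[s: s + 2 * half_width], 0, sid)
                   for s in np.sort(chosen)]
    if len(ied) > n_non:              # subsample the majority (IED) class
        keep = np.sort(rng.choice(len(ied), size=n_non, replace=False))
        ied = [ied[i] for i in keep]
    return SegmentSet(ied + non_ied)
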