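"""In-memory containers: recordings, paired recordings and segments.

The common currency of the pipeline is the :class:`MultichannelRecording`
(time x channel matrix in microvolts with sampling rate and channel labels).
A :class:`PairedRecording` holds the simultaneous scalp and intracranial
streams of one subject plus the intracranially annotated IED peak samples.
Detection and translation operate on 64-sample, 12-channel :class:`Segment`
windows centred on those peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidInputError, ShapeError

SEGMENT_LEN = 64
N_CHANNELS = 12


@dataclass
class MultichannelRecording:
    """time x channel signal matrix (µV) with sampling rate (Hz) and labels."""

    data: np.ndarray
    sampling_rate: float
    labels: list[str]

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ShapeError("recording data must be 2-D (time x channel)")
        if self.data.shape[1] != len(self.labels):
            raise ShapeError(
                f"{self.data.shape[1]} columns but {len(self.labels)} labels")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def copy_with(self, data: np.ndarray, labels: list[str] | None = None) -> "MultichannelRecording":
        return MultichannelRecording(data, self.sampling_rate,
                                     list(labels) if labels is not None else list(self.labels))


@dataclass
class PairedRecording:
    """Time-aligned scalp (sEEG) and intracranial (iEEG) streams of one subject.

    ``ied_peaks`` are 0-based sample indices of IED peaks on the shared clock,
    annotated from the intracranial ground truth (so scalp-invisible events are
    included).
    """

    seeg: MultichannelRecording
    ieeg: MultichannelRecording
    ied_peaks: np.ndarray
    subject_id: str

    def __post_init__(self):
        self.ied_peaks = np.asarray(self.ied_peaks, dtype=np.int64)
        if self.seeg.n_samples != self.ieeg.n_samples:
            raise ShapeError("scalp and intracranial streams must have equal length")
        if self.seeg.sampling_rate != self.ieeg.sampling_rate:
            raise InvalidInputError("scalp and intracranial sampling rates differ")

    @property
    def sampling_rate(self) -> float:
        return self.seeg.sampling_rate

    @property
    def n_samples(self) -> int:
        return self.seeg.n_samples


@dataclass
class Segment:
    """One 64 x 12 window: scalp matrix X, intracranial matrix Y, binary label."""

    x_scalp: np.ndarray
    y_intracranial: np.ndarray | None
    label: int
    subject_id: str
    peak_sample: int | None = None

    def __post_init__(self):
        self.x_scalp = np.asarray(self.x_scalp, dtype=np.float64)
        if self.x_scalp.shape != (SEGMENT_LEN, N_CHANNELS):
            raise ShapeError(f"x_scalp must be {SEGMENT_LEN}x{N_CHANNELS}, got {self.x_scalp.shape}")
        if self.y_intracranial is not None:
            self.y_intracranial = np.asarray(self.y_intracranial, dtype=np.float64)
            if self.y_intracranial.shape != (SEGMENT_LEN, N_CHANNELS):
                raise ShapeError("y_intracranial must be "
                                 f"{SEGMENT_LEN}x{N_CHANNELS}, got {self.y_intracranial.shape}")
        if self.label not in (0, 1):
            raise InvalidInputError("label must be 0 or 1")


@dataclass
class SegmentSet:
    """Ordered collection of segments with convenience array views."""

    segments: list[Segment] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)

    def __getitem__(self, idx):
        if isinstance(idx, (list, np.ndarray)):
            return SegmentSet([self.segments[i] for i in idx])
        if isinstance(idx, slice):
            return SegmentSet(self.segments[idx])
        return self.segments[idx]

    @property
    def class_counts(self) -> tuple[int, int]:
        labels = self.labels
        return int((labels == 1).sum()), int((labels == 0).sum())

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.segments], dtype=np.int64)

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.segments]

    def stack_x(self) -> np.ndarray:
        """(n, 64, 12) scalp array."""
        return np.stack([s.x_scalp for s in self.segments]) if self.segments \
            else np.empty((0, SEGMENT_LEN, N_CHANNELS))

    def stack_y(self) -> np.ndarray:
        """(n, 64, 12) intracranial array; requires every segment to carry Y."""
        if any(s.y_intracranial is None for s in self.segments):
            raise InvalidInputError("some segments lack intracranial ground truth")
        return np.stack([s.y_intracranial for s in self.segments]) if self.segments \
            else np.empty((0, SEGMENT_LEN, N_CHANNELS))

    def with_features(self, features: np.ndarray) -> "SegmentSet":
        """Copy of the set whose X matrices are replaced (e.g. by translated Ỹ)."""
        if len(features) != len(self.segments):
            raise ShapeError("feature count does not match segment count")
        return SegmentSet([replace(s, x_scalp=f) for s, f in zip(self.segments, features)])

    def extend(self, other: "SegmentSet") -> "SegmentSet":
        return SegmentSet(self.segments + other.segments)
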