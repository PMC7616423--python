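"""File formats: EDF recordings, annotation tables, manifests, checkpoints.

Recordings are exchanged as EDF (one file per subject per modality).  Writing
uses a minimal EDF encoder (16-bit, one-second data records) implemented here;
reading goes through :mod:`mne`'s EDF reader, so files written by this module
round-trip through the standard tool chain.  IED annotations travel as a CSV
table (subject_id, peak_sample, label), cohorts carry a JSON manifest, and
fitted models are persisted as an ``.npz`` of parameter arrays plus a JSON
manifest (config, seed, parameter count).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import MultichannelRecording, PairedRecording, Segment, SegmentSet
from .errors import InvalidInputError, InvalidParameterError

__all__ = [
    "write_edf", "read_edf", "write_annotations", "read_annotations",
    "write_cohort", "read_cohort", "save_segments", "load_segments",
    "save_translator", "load_translator", "save_detector", "load_detector",
    "write_predictions",
]


# ----------------------------------------------------------------------- EDF
def _field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise InvalidInputError(f"EDF header field too long: {s!r}")
    return s.ljust(width).encode("ascii")


def write_edf(rec: MultichannelRecording, path: str | Path,
              patient_id: str = "X", recording_id: str = "synthetic"):
    """Write a recording as 16-bit EDF with one-second data records."""
    fs = rec.sampling_rate
    if fs != int(fs):
        raise InvalidParameterError("EDF export requires an integer sampling rate")
    fs = int(fs)
    nc = rec.n_channels
    n_rec = int(np.ceil(rec.n_samples / fs))
    data = rec.data
    if n_rec * fs > rec.n_samples:                       # zero-pad the last record
        pad = np.zeros((n_rec * fs - rec.n_samples, nc))
        data = np.vstack([data, pad])

    pmax = np.ceil(np.maximum(np.abs(data).max(axis=0), 1.0)).astype(int)
    digital = np.round(data / pmax[None, :] * 32767.0).astype("<i2")

    with open(Path(path), "wb") as f:
        f.write(_field("0", 8))
        f.write(_field(patient_id, 80))
        f.write(_field(recording_id, 80))
        f.write(_field("01.01.00", 8))
        f.write(_field("00.00.00", 8))
        f.write(_field(256 * (nc + 1), 8))
        f.write(_field("", 44))
        f.write(_field(n_rec, 8))
        f.write(_field("1", 8))
        f.write(_field(nc, 4))
        for lab in rec.labels:
            f.write(_field(lab, 16))
        f.write(b" " * 80 * nc)                          # transducer
        for _ in range(nc):
            f.write(_field("uV", 8))
        for p in pmax:
            f.write(_field(-int(p), 8))
        for p in pmax:
            f.write(_field(int(p), 8))
        f.write(_field(-32767, 8) * nc)
        f.write(_field(32767, 8) * nc)
        f.write(b" " * 80 * nc)                          # prefiltering
        f.write(_field(fs, 8) * nc)
        f.write(b" " * 32 * nc)
        for r in range(n_rec):
            block = digital[r * fs:(r + 1) * fs]         # (fs, nc)
            f.write(block.T.tobytes())


def read_edf(path: str | Path) -> MultichannelRecording:
    """Read an EDF file (via mne) into a MultichannelRecording in µV."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data().T * 1e6                        # volts -> µV
    return MultichannelRecording(data, float(raw.info["sfreq"]), list(raw.ch_names))


# --------------------------------------------------------------- annotations
def write_annotations(peaks: np.ndarray, subject_id: str, path: str | Path):
    df = pd.DataFrame({"subject_id": subject_id,
                       "peak_sample": np.asarray(peaks, dtype=int),
                       "label": "IED"})
    df.to_csv(Path(path), index=False)


def read_annotations(path: str | Path) -> np.ndarray:
    df = pd.read_csv(Path(path))
    return df["peak_sample"].to_numpy(dtype=np.int64)


# -------------------------------------------------------------------- cohorts
def write_cohort(cohort: list[PairedRecording], out_dir: str | Path,
                 extra_manifest: dict | None = None) -> Path:
    """One EDF per subject per modality + per-subject annotation CSV + manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for rec in cohort:
        sid = rec.subject_id
        files = {"seeg": f"{sid}_seeg.edf", "ieeg": f"{sid}_ieeg.edf",
                 "annotations": f"{sid}_annotations.csv"}
        write_edf(rec.seeg, out / files["seeg"], patient_id=sid)
        write_edf(rec.ieeg, out / files["ieeg"], patient_id=sid)
        write_annotations(rec.ied_peaks, sid, out / files["annotations"])
        entries.append({"subject_id": sid, "n_ieds": int(len(rec.ied_peaks)),
                        "sampling_rate": rec.sampling_rate,
                        "n_samples": int(rec.n_samples), **files})
    manifest = {"subjects": entries}
    if extra_manifest:
        manifest.update(extra_manifest)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out / "manifest.json"


def read_cohort(in_dir: str | Path) -> list[PairedRecording]:
    in_dir = Path(in_dir)
    manifest = json.loads((in_dir / "manifest.json").read_text())
    cohort = []
    for e in manifest["subjects"]:
        cohort.append(PairedRecording(
            seeg=read_edf(in_dir / e["seeg"]),
            ieeg=read_edf(in_dir / e["ieeg"]),
            ied_peaks=read_annotations(in_dir / e["annotations"]),
            subject_id=e["subject_id"]))
    return cohort


def write_predictions(subject_ids, probabilities, labels, path: str | Path):
    """Per-segment prediction dump: index, subject, probability, hard/true label."""
    probs = np.asarray(probabilities, dtype=float)
    df = pd.DataFrame({"segment_index": np.arange(len(probs)),
                       "subject_id": list(subject_ids),
                       "probability": probs,
                       "predicted_label": (probs >= 0.5).astype(int),
                       "label": np.asarray(labels, dtype=int)})
    df.to_csv(Path(path), index=False)


# ------------------------------------------------------------------- segments
def save_segments(segs: SegmentSet, prefix: str | Path):
    """Persist a segment set as <prefix>.npz plus a <prefix>.json sidecar."""
    prefix = Path(prefix)
    x = segs.stack_x()
    has_y = all(s.y_intracranial is not None for s in segs)
    arrays = {"x": x, "labels": segs.labels}
    if has_y:
        arrays["y"] = segs.stack_y()
    np.savez(prefix.with_suffix(".npz"), **arrays)
    n_ied, n_non = segs.class_counts
    sidecar = {"n_segments": len(segs), "shape": list(x.shape[1:]),
               "class_counts": {"ied": n_ied, "non_ied": n_non},
               "has_intracranial": has_y, "subject_ids": segs.subject_ids,
               "peak_samples": [s.peak_sample for s in segs]}
    prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_segments(prefix: str | Path) -> SegmentSet:
    prefix = Path(prefix)
    arrays = np.load(prefix.with_suffix(".npz"))
    side = json.loads(prefix.with_suffix(".json").read_text())
    y = arrays["y"] if side["has_intracranial"] else None
    segs = []
    for i in range(side["n_segments"]):
        segs.append(Segment(arrays["x"][i], None if y is None else y[i],
                            int(arrays["labels"][i]), side["subject_ids"][i],
                            peak_sample=side["peak_samples"][i]))
    return SegmentSet(segs)


# ---------------------------------------------------------------- checkpoints
def _save_modules(prefix: Path, manifest: dict, arrays: list[np.ndarray]):
    np.savez(prefix.with_suffix(".npz"), **{f"p{i}": a for i, a in enumerate(arrays)})
    prefix.with_suffix(".json").write_text(json.dumps(manifest, indent=2))


def _load_arrays(prefix: Path) -> list[np.ndarray]:
    z = np.load(prefix.with_suffix(".npz"))
    return [z[f"p{i}"] for i in range(len(z.files))]


def save_translator(tt, prefix: str | Path):
    from .translator import count_parameters

    prefix = Path(prefix)
    arrays = tt.generator.state() + tt.discriminator.state() + \
        [tt.x_scaler.mean, tt.x_scaler.std, tt.y_scaler.mean, tt.y_scaler.std]
    manifest = {"kind": "translator", "config": dataclasses.asdict(tt.config),
                "n_generator_params": len(tt.generator.state()),
                "parameter_count": count_parameters(tt),
                "n_epochs_trained": len(tt.loss_history),
                "loss_history": tt.loss_history}
    _save_modules(prefix, manifest, arrays)


def load_translator(prefix: str | Path):
    from .translator import (ChannelScaler, TrainedTranslator, TranslatorConfig,
                             build_discriminator, build_generator)

    prefix = Path(prefix)
    manifest = json.loads(prefix.with_suffix(".json").read_text())
    cfg = TranslatorConfig(**manifest["config"])
    gen, disc = build_generator(cfg), build_discriminator(cfg)
    arrays = _load_arrays(prefix)
    ng = manifest["n_generator_params"]
    gen.load_state(arrays[:ng])
    disc.load_state(arrays[ng:-4])
    xs, ys = ChannelScaler(), ChannelScaler()
    xs.mean, xs.std, ys.mean, ys.std = arrays[-4:]
    gen.eval()
    disc.eval()
    return TrainedTranslator(gen, disc, cfg, xs, ys, manifest["loss_history"])


def save_detector(det, prefix: str | Path):
    prefix = Path(prefix)
    arrays = det.model.state() + [det.scaler.mean, det.scaler.std]
    manifest = {"kind": "detector", "config": dataclasses.asdict(det.config),
                "parameter_count": det.model.n_parameters(),
                "training_history": det.training_history}
    _save_modules(prefix, manifest, arrays)


def load_detector(prefix: str | Path):
    from .detector import DetectorConfig, TrainedDetector, build_detector
    from .translator import ChannelScaler

    prefix = Path(prefix)
    manifest = json.loads(prefix.with_suffix(".json").read_text())
    cfg = DetectorConfig(**manifest["config"])
    model = build_detector(cfg)
    arrays = _load_arrays(prefix)
    model.load_state(arrays[:-2])
    scaler = ChannelScaler()
    scaler.mean, scaler.std = arrays[-2:]
    model.eval()
    return TrainedDetector(model, cfg, scaler, manifest["training_history"])
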