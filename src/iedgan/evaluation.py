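"""Evaluation protocols: metrics, stratified splits, intra- and inter-subject runs.

Intra-subject: a subject's balanced segments are split 70/10/20 into
train/validation/test; one translator is trained on the training part, all
parts are mapped through it, one detector is trained on the translated
train/validation parts and scored on the translated test part.

Inter-subject: leave-one-subject-out.  For each held-out subject, the N
training subjects are those whose intra-subject accuracy met the selection
threshold (computed without the held-out subject); one translator G_n is
trained per training subject, every subject's scalp segments are mapped
through each G_n, one detector is trained per G_n on its translated training
pool, and the N detectors' probabilities on the held-out subject are averaged
(average voting) before thresholding at 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .data import PairedRecording, SegmentSet
from .detector import DetectorConfig, predict_proba, train_detector
from .errors import EmptySelectionError, InvalidInputError, ShapeError
from .preprocessing import extract_segments
from .translator import TranslatorConfig, train_translator, translate

__all__ = [
    "MetricsReport", "compute_metrics", "mean_report", "split_intra",
    "run_intra_subject", "select_training_subjects", "average_vote",
    "run_inter_subject", "segment_correlation",
]


@dataclass
class MetricsReport:
    subject_id: str
    tp: int
    tn: int
    fp: int
    fn: int
    acc: float
    sen: float
    spc: float


def compute_metrics(labels, predictions, subject_id: str = "") -> MetricsReport:
    """Confusion counts and ACC/SEN/SPC from binary labels and hard predictions."""
    labels = np.asarray(labels, dtype=int).ravel()
    predictions = np.asarray(predictions, dtype=int).ravel()
    if labels.size == 0:
        raise InvalidInputError("empty label vector")
    if labels.shape != predictions.shape:
        raise InvalidInputError("labels and predictions differ in length")
    tp = int(((labels == 1) & (predictions == 1)).sum())
    tn = int(((labels == 0) & (predictions == 0)).sum())
    fp = int(((labels == 0) & (predictions == 1)).sum())
    fn = int(((labels == 1) & (predictions == 0)).sum())
    acc = (tp + tn) / (tp + tn + fp + fn)
    sen = tp / (tp + fn) if tp + fn else float("nan")
    spc = tn / (tn + fp) if tn + fp else float("nan")
    return MetricsReport(subject_id, tp, tn, fp, fn, acc, sen, spc)


def mean_report(reports: list[MetricsReport]) -> MetricsReport:
    """Unweighted mean of per-subject proportions (counts are summed)."""
    if not reports:
        raise InvalidInputError("no reports to average")
    return MetricsReport(
        "Mean",
        tp=sum(r.tp for r in reports), tn=sum(r.tn for r in reports),
        fp=sum(r.fp for r in reports), fn=sum(r.fn for r in reports),
        acc=float(np.mean([r.acc for r in reports])),
        sen=float(np.mean([r.sen for r in reports])),
        spc=float(np.mean([r.spc for r in reports])),
    )


def _derive_seed(seed: int, tag: int) -> int:
    return int(np.random.SeedSequence([seed, tag]).generate_state(1)[0] % (2 ** 31))


def split_intra(segs: SegmentSet, fractions: tuple[float, float, float] = (0.7, 0.1, 0.2),
                seed: int = 0) -> tuple[SegmentSet, SegmentSet, SegmentSet]:
    """Stratified, seeded, exhaustive train/validation/test split."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise InvalidInputError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    labels = segs.labels
    parts: list[list[int]] = [[], [], []]
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        n = len(idx)
        # largest-remainder apportionment keeps the split exhaustive
        raw = np.array(fractions) * n
        counts = np.floor(raw).astype(int)
        for _ in range(n - counts.sum()):
            counts[int(np.argmax(raw - counts))] += 1
        stops = np.cumsum(counts)
        parts[0].extend(idx[:stops[0]])
        parts[1].extend(idx[stops[0]:stops[1]])
        parts[2].extend(idx[stops[1]:stops[2]])
    for frac, part, name in zip(fractions, parts, ("train", "validation", "test")):
        if frac > 0 and not part:
            raise InvalidInputError(f"too few segments for a non-empty {name} part")
    return tuple(segs[sorted(p)] for p in parts)


def segment_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Mean per-segment, per-channel Pearson correlation of (n, 64, 12) arrays."""
    if a.shape != b.shape:
        raise ShapeError("arrays must have identical shapes")
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    num = (ac * bc).sum(axis=1)
    den = np.sqrt((ac ** 2).sum(axis=1) * (bc ** 2).sum(axis=1))
    valid = den > 0
    return float((num[valid] / den[valid]).mean())


def run_intra_subject(paired: PairedRecording, tcfg: TranslatorConfig,
                      dcfg: DetectorConfig, seed: int = 0,
                      fractions: tuple[float, float, float] = (0.7, 0.1, 0.2),
                      use_translation: bool = True, return_details: bool = False):
    """Intra-subject protocol on one preprocessed subject -> MetricsReport.

    With ``use_translation=False`` the detector is trained and scored on the
    raw scalp segments instead of the translated ones (same segments, same
    split, same detector seed), giving the paired scalp baseline.
    """
    segs = extract_segments(paired, seed=_derive_seed(seed, 10))
    train, val, test = split_intra(segs, fractions=fractions, seed=_derive_seed(seed, 11))

    details: dict = {"segments": segs, "split": (train, val, test)}
    if use_translation:
        tt = train_translator(train, replace(tcfg, seed=_derive_seed(seed, 12)))
        feats = {name: translate(tt, part.stack_x())
                 for name, part in (("train", train), ("val", val), ("test", test))}
        details["translator"] = tt
        details["translated_test"] = feats["test"]
    else:
        feats = {"train": train.stack_x(), "val": val.stack_x(), "test": test.stack_x()}

    det = train_detector(train.with_features(feats["train"]),
                         val.with_features(feats["val"]),
                         replace(dcfg, seed=_derive_seed(seed, 13)))
    probs = predict_proba(det, test.with_features(feats["test"]))
    report = compute_metrics(test.labels, (probs >= 0.5).astype(int),
                             subject_id=paired.subject_id)
    if return_details:
        details.update(detector=det, test_probs=probs)
        return report, details
    return report


def select_training_subjects(intra_reports: list[MetricsReport],
                             threshold: float = 0.70) -> list[str]:
    """Ids of subjects whose intra-subject accuracy reached the threshold."""
    ids = [r.subject_id for r in intra_reports if r.acc >= threshold]
    if not ids:
        raise EmptySelectionError(
            f"no subject reached intra-subject accuracy {threshold}; lower the threshold")
    return ids


def average_vote(probability_rows) -> np.ndarray:
    """Column-wise arithmetic mean of an N x m matrix of probabilities."""
    rows = [np.asarray(r, dtype=float).ravel() for r in probability_rows]
    if not rows:
        raise InvalidInputError("average_vote requires at least one row")
    m = rows[0].size
    if any(r.size != m for r in rows):
        raise ShapeError("ragged probability rows")
    return np.mean(np.stack(rows), axis=0)


def run_inter_subject(cohort: list[PairedRecording], tcfg: TranslatorConfig,
                      dcfg: DetectorConfig, threshold: float = 0.70,
                      seed: int = 0, return_details: bool = False):
    """Leave-one-subject-out protocol on a preprocessed cohort.

    Returns one MetricsReport per held-out subject (in cohort order); details
    additionally expose the per-fold ensembles and the intra-subject reports
    used for training-subject selection.
    """
    if len(cohort) < 3:
        raise InvalidInputError("inter-subject evaluation needs a cohort of >= 3")
    ids = [p.subject_id for p in cohort]
    by_id = dict(zip(ids, cohort))

    intra_reports = [run_intra_subject(p, tcfg, dcfg, seed=_derive_seed(seed, 20 + i))
                     for i, p in enumerate(cohort)]
    qualifying = set(select_training_subjects(intra_reports, threshold))

    # per-subject balanced segments, one fixed extraction per subject
    segsets = {sid: extract_segments(by_id[sid], seed=_derive_seed(seed, 40 + i))
               for i, sid in enumerate(ids)}

    # one translator per qualifying subject, trained once on that subject's segments
    translators = {sid: train_translator(segsets[sid],
                                         replace(tcfg, seed=_derive_seed(seed, 60 + i)))
                   for i, sid in enumerate(ids) if sid in qualifying}
    translation_cache: dict[tuple[str, str], np.ndarray] = {}

    def translated(gn_id: str, subj_id: str) -> np.ndarray:
        key = (gn_id, subj_id)
        if key not in translation_cache:
            translation_cache[key] = translate(translators[gn_id],
                                               segsets[subj_id].stack_x())
        return translation_cache[key]

    reports, folds = [], []
    for i, test_id in enumerate(ids):
        pool = [sid for sid in ids if sid in qualifying and sid != test_id]
        if not pool:
            raise EmptySelectionError(
                f"no training subject for held-out {test_id}; lower the threshold")
        prob_rows = []
        detectors = {}
        for j, gn_id in enumerate(pool):
            train_set = SegmentSet([])
            for sid in pool:
                train_set = train_set.extend(
                    segsets[sid].with_features(translated(gn_id, sid)))
            tr, va, _ = split_intra(train_set, fractions=(0.9, 0.1, 0.0),
                                    seed=_derive_seed(seed, 80 + 10 * i + j))
            det = train_detector(tr, va, replace(dcfg, seed=_derive_seed(seed, 90 + 10 * i + j)))
            detectors[gn_id] = det
            prob_rows.append(predict_proba(
                det, segsets[test_id].with_features(translated(gn_id, test_id))))
        probs = average_vote(prob_rows)
        reports.append(compute_metrics(segsets[test_id].labels,
                                       (probs >= 0.5).astype(int), subject_id=test_id))
        folds.append({"test_subject": test_id, "n_models": len(pool),
                      "training_subjects": pool, "detectors": detectors,
                      "probability_rows": prob_rows,
                      "test_labels": segsets[test_id].labels})
    if return_details:
        return reports, {"intra_reports": intra_reports, "folds": folds,
                         "translators": translators}
    return reports
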