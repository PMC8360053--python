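"""Pixel-, lesion-, and patient-level evaluation, plus the radiologist
comparison and the combined (model + radiologist) score.

Pixel level: one-vs-all ROC AUC over the pooled in-gland pixels of the
evaluated slices (cancer-annotated slices for cancer cases, all prostate
slices for normal cases); ungraded pixels are excluded when evaluating the
indolent and aggressive classes. Lesion level: a ground-truth lesion counts
as detected when the 90th percentile of the model probability inside its
outline exceeds a threshold; negatives are gland sextants with >= 95% benign
pixels, scored by the same 90th-percentile statistic. Patient level: a
patient with clinically significant (CS) lesions is a true positive when at
least one CS lesion is detected; a normal patient is a false positive when
thresholding + morphology of the aggressive channel yields any predicted
lesion. Sensitivity = TP/(TP+FN) and specificity = TN/(TN+FP) throughout;
an undefined ratio is reported as None, never as 0/0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from sklearn.metrics import roc_auc_score, roc_curve

from .labels import CLASS_AGGRESSIVE, CLASS_INDOLENT, CLASS_NORMAL
from .lesions import (
    DEFAULT_CLOSING_RADII_MM,
    MIN_LESION_VOLUME_MM3,
    Lesion,
    benign_sextants,
    build_sextants,
    close_labels_3d,
    extract_lesions,
    extract_predicted_lesions,
)
from .model import ProbabilityVolume
from .training import PreparedCase
from .volume import ImageVolume, VolumeError

__all__ = [
    "DetectionOutcome",
    "EvalReport",
    "evaluated_slices",
    "per_pixel_eval",
    "lesion_detected",
    "case_ground_truth_lesions",
    "per_lesion_eval",
    "per_patient_eval",
    "radiologist_as_prediction",
    "combine_predictions",
    "pick_thresholds",
    "CLASS_NAMES",
]

CLASS_NAMES = ("normal", "indolent", "aggressive")
DETECTION_PERCENTILE = 90.0


@dataclass(frozen=True)
class DetectionOutcome:
    """Confusion counts with sensitivity/specificity per their defining
    ratios; a ratio with zero denominator is None."""

    true_positives: int
    false_negatives: int
    true_negatives: int
    false_positives: int

    @property
    def sensitivity(self) -> float | None:
        denom = self.true_positives + self.false_negatives
        return self.true_positives / denom if denom else None

    @property
    def specificity(self) -> float | None:
        denom = self.true_negatives + self.false_positives
        return self.true_negatives / denom if denom else None

    def as_dict(self) -> dict:
        return {
            "tp": self.true_positives,
            "fn": self.false_negatives,
            "tn": self.true_negatives,
            "fp": self.false_positives,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


@dataclass
class EvalReport:
    """One evaluation table: per-entry AUC / Se / Sp plus the thresholds and
    counts they were computed at."""

    level: str  # {"pixel", "lesion", "patient"}
    cohort_tag: str
    entries: dict[str, dict] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {"level": self.level, "cohort": self.cohort_tag, "entries": self.entries}


def evaluated_slices(case: PreparedCase) -> np.ndarray:
    """Slice indices entering evaluation: cancer-annotated slices for
    cancer-bearing cases, all prostate slices for normal cases."""
    cancer = case.labels.cancer_mask()
    if case.cohort_tag == "normal" or not cancer.any():
        return np.flatnonzero(case.gland.any(axis=(1, 2)))
    return np.flatnonzero(cancer.any(axis=(1, 2)))


def _pool_pixels(
    cases: list[PreparedCase], predictions: list[ProbabilityVolume]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pooled (hard labels, ungraded flags, class scores (n, 3)) over the
    in-gland pixels of every case's evaluated slices."""
    labels, ungraded, scores = [], [], []
    for case, prob in zip(cases, predictions):
        if prob.shape != case.t2w.shape:
            raise VolumeError(f"prediction grid mismatch for {case.case_id}")
        sl = evaluated_slices(case)
        gland = case.gland[sl]
        labels.append(case.labels.hard_labels()[sl][gland])
        ungraded.append(case.labels.ungraded[sl][gland])
        scores.append(prob.probs[:, sl][:, gland].T)
    return (
        np.concatenate(labels),
        np.concatenate(ungraded),
        np.concatenate(scores, axis=0),
    )


def _auc_or_none(y: np.ndarray, s: np.ndarray, what: str) -> float | None:
    if y.size == 0 or len(np.unique(y)) < 2:
        warnings.warn(f"AUC undefined for {what}: one class absent", stacklevel=3)
        return None
    return float(roc_auc_score(y, s))


def per_pixel_eval(
    cases: list[PreparedCase],
    predictions: list[ProbabilityVolume],
    thresholds: dict[str, float],
    cohort_tag: str = "",
    strict: bool = True,
) -> EvalReport:
    """One-vs-all per-pixel ROC AUC, sensitivity, and specificity for each
    class over the pooled evaluated in-gland pixels."""
    hard, ungraded, scores = _pool_pixels(cases, predictions)
    report = EvalReport(level="pixel", cohort_tag=cohort_tag)
    for c, name in enumerate(CLASS_NAMES):
        keep = (
            np.ones_like(ungraded)
            if c == CLASS_NORMAL
            else ~ungraded  # graded-cancer rule: drop ungraded pixels entirely
        )
        y = (hard[keep] == c).astype(int)
        s = scores[keep, c]
        auc = _auc_or_none(y, s, f"class {name}")
        thr = thresholds[name]
        pred_pos = s > thr if strict else s >= thr
        outcome = DetectionOutcome(
            true_positives=int((pred_pos & (y == 1)).sum()),
            false_negatives=int((~pred_pos & (y == 1)).sum()),
            true_negatives=int((~pred_pos & (y == 0)).sum()),
            false_positives=int((pred_pos & (y == 0)).sum()),
        )
        report.entries[name] = {
            "auc": auc,
            "threshold": thr,
            "n_pixels": int(y.size),
            **outcome.as_dict(),
        }
    return report


def _percentile_score(values: np.ndarray) -> float:
    """The detection statistic: 90th percentile with linear interpolation
    between order statistics."""
    return float(np.percentile(values, DETECTION_PERCENTILE))


def lesion_detected(
    lesion: Lesion,
    score_volume: np.ndarray,
    threshold: float,
    strict: bool = True,
) -> bool:
    """Detected iff the 90th percentile of the score inside the lesion
    outline exceeds the threshold (strict > by default)."""
    vals = score_volume[tuple(lesion.voxels.T)]
    stat = _percentile_score(vals)
    return stat > threshold if strict else stat >= threshold


def case_ground_truth_lesions(
    case: PreparedCase,
    closing_radii_mm: tuple[float, float] = DEFAULT_CLOSING_RADII_MM,
    min_volume_mm3: float = MIN_LESION_VOLUME_MM3,
) -> list[Lesion]:
    """Ground-truth lesion outlines for a case: close the label cancer mask,
    extract 26-connected components, apply the minimum-volume rule."""
    mask = ImageVolume(
        case.labels.cancer_mask().astype(np.uint8),
        case.labels.in_plane_spacing_mm,
        case.labels.slice_spacing_mm,
        is_mask=True,
    )
    closed = close_labels_3d(mask, closing_radii_mm)
    return extract_lesions(closed, case.labels, min_volume_mm3)


def _case_score(prob: ProbabilityVolume, mode: str) -> np.ndarray:
    if mode == "all":
        return prob.cancer_probability()
    if mode == "cs":
        return prob.probs[CLASS_AGGRESSIVE]
    raise ValueError(f"unknown lesion-eval mode {mode!r}")


def per_lesion_eval(
    cases: list[PreparedCase],
    score_volumes: list[np.ndarray],
    threshold: float,
    mode: str = "all",
    significance_rule: str = "1pct",
    benign_threshold: float = 0.95,
    closing_radii_mm: tuple[float, float] = DEFAULT_CLOSING_RADII_MM,
    min_volume_mm3: float = MIN_LESION_VOLUME_MM3,
    cohort_tag: str = "",
    strict: bool = True,
) -> EvalReport:
    """Lesion-level ROC over pooled lesion/sextant 90th-percentile scores.

    Positives are the ground-truth lesions (mode "all": every lesion, scored
    on the any-cancer channel; mode "cs": clinically significant lesions at
    ``significance_rule``, scored on the aggressive channel — pass the
    matching ``score_volumes``). Negatives are >= 95%-benign sextants of all
    cases, scored by the same statistic over their in-gland voxels."""
    if significance_rule not in ("1pct", "5pct"):
        raise ValueError(f"unknown significance rule {significance_rule!r}")
    pos_scores: list[float] = []
    neg_scores: list[float] = []
    n_detected = 0
    for case, score in zip(cases, score_volumes):
        if score.shape != case.t2w.shape:
            raise VolumeError(f"score grid mismatch for {case.case_id}")
        lesions = case_ground_truth_lesions(case, closing_radii_mm, min_volume_mm3)
        if mode == "cs":
            key = (
                "significant_at_1pct"
                if significance_rule == "1pct"
                else "significant_at_5pct"
            )
            lesions = [l for l in lesions if getattr(l, key)]
        for lesion in lesions:
            s = _percentile_score(score[tuple(lesion.voxels.T)])
            pos_scores.append(s)
            if (s > threshold) if strict else (s >= threshold):
                n_detected += 1
        partition = build_sextants(
            ImageVolume(
                case.gland.astype(np.uint8),
                case.labels.in_plane_spacing_mm,
                case.labels.slice_spacing_mm,
                is_mask=True,
            )
        )
        for sid in benign_sextants(partition, case.labels, benign_threshold):
            neg_scores.append(_percentile_score(score[partition.mask(sid)]))

    n_pos, n_neg = len(pos_scores), len(neg_scores)
    if n_neg == 0:
        warnings.warn("no benign sextants available; specificity absent", stacklevel=2)
    neg_above = sum(
        1 for s in neg_scores if ((s > threshold) if strict else (s >= threshold))
    )
    outcome = DetectionOutcome(
        true_positives=n_detected,
        false_negatives=n_pos - n_detected,
        true_negatives=n_neg - neg_above,
        false_positives=neg_above,
    )
    y = np.concatenate([np.ones(n_pos), np.zeros(n_neg)])
    s = np.asarray(pos_scores + neg_scores)
    auc = _auc_or_none(y, s, f"lesion-level mode={mode}")
    report = EvalReport(level="lesion", cohort_tag=cohort_tag)
    report.entries[mode if mode == "all" else f"cs_{significance_rule}"] = {
        "auc": auc,
        "threshold": threshold,
        "n_lesions": n_pos,
        "n_sextants": n_neg,
        **outcome.as_dict(),
    }
    return report


def per_patient_eval(
    cases: list[PreparedCase],
    predictions: list[ProbabilityVolume],
    threshold: float,
    significance_rule: str = "1pct",
    closing_radii_mm: tuple[float, float] = DEFAULT_CLOSING_RADII_MM,
    min_volume_mm3: float = MIN_LESION_VOLUME_MM3,
    strict: bool = True,
) -> DetectionOutcome:
    """Patient-level detection of clinically significant cancer.

    A patient with CS lesions is a TP when at least one CS lesion is detected
    on the aggressive channel, else FN. A normal patient is an FP when the
    thresholded + morphologically processed aggressive channel contains any
    predicted lesion, else TN. Patients with lesions but none CS do not enter
    the tally. Only sensitivity and specificity are meaningful here (the
    procedure is a hard decision, not a score)."""
    key = (
        "significant_at_1pct" if significance_rule == "1pct" else "significant_at_5pct"
    )
    tp = fn = tn = fp = 0
    for case, prob in zip(cases, predictions):
        lesions = case_ground_truth_lesions(case, closing_radii_mm, min_volume_mm3)
        cs = [l for l in lesions if getattr(l, key)]
        agg_score = prob.probs[CLASS_AGGRESSIVE]
        if cs:
            if any(lesion_detected(l, agg_score, threshold, strict) for l in cs):
                tp += 1
            else:
                fn += 1
        elif not lesions:
            predicted = extract_predicted_lesions(
                prob,
                CLASS_AGGRESSIVE,
                threshold,
                closing_radii_mm,
                min_volume_mm3,
                strict,
            )
            if predicted:
                fp += 1
            else:
                tn += 1
    return DetectionOutcome(tp, fn, tn, fp)


def radiologist_as_prediction(outline: ImageVolume) -> ProbabilityVolume:
    """Treat a radiologist outline as a prediction: every pixel inside the
    outline is aggressive cancer with probability 1.00, everything else
    normal."""
    agg = outline.data.astype(np.float64)
    probs = np.stack([1.0 - agg, np.zeros_like(agg), agg])
    return ProbabilityVolume(
        probs, outline.in_plane_spacing_mm, outline.slice_spacing_mm
    )


def combine_predictions(
    model_prob: ProbabilityVolume, radiologist_prob: ProbabilityVolume
) -> np.ndarray:
    """Sum of model and radiologist per-channel outputs, shape (3, S, H, W).

    The sums are detection scores in [0, 2], not probabilities; downstream
    detection applies the same 90th-percentile rule and threshold to the
    summed aggressive channel."""
    if model_prob.shape != radiologist_prob.shape:
        raise VolumeError("model and radiologist predictions on different grids")
    return model_prob.probs + radiologist_prob.probs


def pick_thresholds(
    cases: list[PreparedCase],
    predictions: list[ProbabilityVolume],
) -> dict[str, float]:
    """Per-class operating thresholds maximizing Youden's J (Se + Sp - 1) on
    the pooled validation pixels; also a threshold for the any-cancer score
    used by the all-lesion evaluation. Freeze the result (YAML) before
    touching any test set."""
    hard, ungraded, scores = _pool_pixels(cases, predictions)
    out: dict[str, float] = {}
    for c, name in enumerate(CLASS_NAMES):
        keep = np.ones_like(ungraded) if c == CLASS_NORMAL else ~ungraded
        y = (hard[keep] == c).astype(int)
        s = scores[keep, c]
        out[name] = _youden_threshold(y, s, name)
    y_cancer = (hard != CLASS_NORMAL).astype(int)
    s_cancer = scores[:, CLASS_INDOLENT] + scores[:, CLASS_AGGRESSIVE]
    out["cancer"] = _youden_threshold(y_cancer, s_cancer, "cancer")
    return out


def _youden_threshold(y: np.ndarray, s: np.ndarray, what: str) -> float:
    if len(np.unique(y)) < 2:
        raise VolumeError(f"cannot pick a threshold for {what}: one class absent")
    fpr, tpr, thr = roc_curve(y, s)
    j = tpr - fpr
    best = int(np.argmax(j))
    t = float(thr[best])
    # roc_curve's first threshold is max(score)+1; clamp into the score range
    return min(t, float(s.max()))


def save_thresholds(thresholds: dict[str, float], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump({k: float(v) for k, v in thresholds.items()}))
    return path


def load_thresholds(path: str | Path) -> dict[str, float]:
    return {k: float(v) for k, v in yaml.safe_load(Path(path).read_text()).items()}
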