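"""Training: class-weighted categorical cross-entropy, cancer-slice
selection, rotation/flip augmentation, patient-level cross-validation folds,
and the Adam optimization loop.

The loss is a weighted categorical cross-entropy

    L = -(1/N) sum_n sum_i w_i y_i(n) ln yhat_i(n)

over the N in-scope pixels of a batch, where the class weights are the
inverse class proportions over the entire training set,

    w_i = M / sum_m y_i(m),

with M the number of in-scope training pixels. Soft labels (the 0.5/0.5
ungraded-cancer voxels) contribute fractional mass to both the loss and the
class counts. By default the in-scope pixels are the prostate pixels of the
selected slices, matching the gland-restricted normalization and evaluation;
``loss_mask="full_frame"`` uses every pixel instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .labels import SoftLabelVolume
from .model import ModelConfig, SPCNet, assemble_25d_input, build_model
from .nn import Adam, softmax
from .volume import VolumeError

__all__ = [
    "ClassWeights",
    "TrainConfig",
    "PreparedCase",
    "select_training_slices",
    "compute_class_weights",
    "weighted_cce",
    "make_folds",
    "augment_sample",
    "train_fold",
]

_EPS = 1e-7
_CLASS_NAMES = ("normal", "indolent", "aggressive")


@dataclass(frozen=True)
class ClassWeights:
    """Inverse-proportion class weights over the training pixels."""

    w: tuple[float, float, float]
    M_total: int

    def __post_init__(self) -> None:
        if any(wi <= 0 for wi in self.w):
            raise ValueError("class weights must be positive")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.w, dtype=np.float64)


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 25
    batch_size: int = 32
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    rotation_range_deg: tuple[float, float] = (-15.0, 15.0)
    lr_flip: bool = True
    n_folds: int = 5
    seed: int = 0
    loss_mask: str = "prostate_only"  # or "full_frame"
    augment: bool = True

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.loss_mask not in ("prostate_only", "full_frame"):
            raise ValueError(f"unknown loss_mask {self.loss_mask!r}")


@dataclass
class PreparedCase:
    """A preprocessed case ready for training/prediction: model-grid arrays
    plus fused soft labels."""

    case_id: str
    t2w: np.ndarray  # (S, H, W), standardized + z-scored
    adc: np.ndarray
    gland: np.ndarray  # (S, H, W) bool
    labels: SoftLabelVolume
    cohort_tag: str = "prostatectomy-like"

    def __post_init__(self) -> None:
        if not (self.t2w.shape == self.adc.shape == self.gland.shape):
            raise VolumeError("case arrays must share one grid")
        if self.labels.shape != self.t2w.shape:
            raise VolumeError("label grid mismatch")
        self.gland = self.gland.astype(bool)


def select_training_slices(
    cases: list[PreparedCase],
) -> list[tuple[str, int]]:
    """Training slices: for cancer-bearing cases only the slices containing
    at least one cancer-labeled voxel; for normal cases every slice that
    intersects the prostate."""
    out: list[tuple[str, int]] = []
    for case in cases:
        if case.gland.sum() == 0:
            raise VolumeError(f"case {case.case_id} has no prostate voxels")
        cancer = case.labels.cancer_mask()
        if case.cohort_tag == "normal" or not cancer.any():
            slices = np.flatnonzero(case.gland.any(axis=(1, 2)))
        else:
            slices = np.flatnonzero(cancer.any(axis=(1, 2)))
        out.extend((case.case_id, int(s)) for s in slices)
    return out


def _scope_mask(case: PreparedCase, slice_idx: int, loss_mask: str) -> np.ndarray:
    if loss_mask == "prostate_only":
        return case.gland[slice_idx]
    return np.ones_like(case.gland[slice_idx], dtype=bool)


def compute_class_weights(
    cases: list[PreparedCase],
    slices: list[tuple[str, int]],
    loss_mask: str = "prostate_only",
) -> ClassWeights:
    """w_i = M / (total class-i probability mass) over the in-scope pixels of
    the selected slices; soft labels count fractionally."""
    by_id = {c.case_id: c for c in cases}
    mass = np.zeros(3)
    m_total = 0
    for case_id, s in slices:
        case = by_id[case_id]
        scope = _scope_mask(case, s, loss_mask)
        mass += case.labels.probs[:, s][:, scope].sum(axis=1)
        m_total += int(scope.sum())
    if m_total == 0:
        raise VolumeError("no in-scope pixels in the selected slices")
    for i, m in enumerate(mass):
        if m <= 0:
            raise VolumeError(f"class '{_CLASS_NAMES[i]}' has zero total mass")
    return ClassWeights(tuple(float(m_total / m) for m in mass), m_total)


def weighted_cce(
    pred: np.ndarray,
    label: np.ndarray,
    weights: ClassWeights,
    mask: np.ndarray | None = None,
) -> float:
    """Weighted categorical cross-entropy over a batch of pixels.

    ``pred``/``label`` are (..., 3, H, W) or (N, 3) probability arrays;
    predictions are epsilon-clipped before the log. ``mask`` selects the
    in-scope pixels (all pixels if None)."""
    pred = np.asarray(pred, dtype=np.float64)
    label = np.asarray(label, dtype=np.float64)
    if pred.shape != label.shape:
        raise VolumeError(f"shape mismatch: pred {pred.shape} vs label {label.shape}")
    if pred.ndim == 2:
        p, y = pred, label
        msk = np.ones(p.shape[0], dtype=bool) if mask is None else mask
    else:
        ax_cls = pred.ndim - 3
        p = np.moveaxis(pred, ax_cls, -1).reshape(-1, 3)
        y = np.moveaxis(label, ax_cls, -1).reshape(-1, 3)
        msk = (
            np.ones(p.shape[0], dtype=bool)
            if mask is None
            else np.asarray(mask, dtype=bool).reshape(-1)
        )
    p, y = p[msk], y[msk]
    n = p.shape[0]
    if n == 0:
        raise VolumeError("empty pixel batch")
    w = weights.as_array()
    return float(-(y * np.log(np.clip(p, _EPS, 1.0)) * w).sum() / n)


def make_folds(
    case_ids: list[str], n_folds: int, seed: int
) -> dict[str, int]:
    """Seeded near-equal partition of patients into folds (never slices)."""
    if len(case_ids) < n_folds:
        raise VolumeError(
            f"cannot split {len(case_ids)} cases into {n_folds} folds"
        )
    ids = sorted(case_ids)
    rng = np.random.default_rng(seed)
    rng.shuffle(ids)
    assignment: dict[str, int] = {}
    for fold, chunk in enumerate(np.array_split(ids, n_folds)):
        for cid in chunk:
            assignment[str(cid)] = fold
    return assignment


def _rotate(arr: np.ndarray, angle: float, order: int, cval: float) -> np.ndarray:
    return ndimage.rotate(
        arr, angle, axes=(-2, -1), reshape=False, order=order, mode="constant",
        cval=cval,
    )


def augment_sample(
    inputs: list[np.ndarray],
    label_probs: np.ndarray,
    masks: list[np.ndarray],
    rng: np.random.Generator,
    cfg: TrainConfig,
) -> tuple[list[np.ndarray], np.ndarray, list[np.ndarray]]:
    """Identical random rotation + left-right flip applied to the input
    stacks, the (3, H, W) soft-label slice, and any boolean masks.

    Images are interpolated bilinearly; labels and masks nearest-neighbour.
    Out-of-frame regions become background: 0 for images and masks, the
    normal class for labels."""
    lo, hi = cfg.rotation_range_deg
    angle = float(rng.uniform(lo, hi))
    flip = bool(cfg.lr_flip and rng.random() < 0.5)

    def tf_image(a: np.ndarray) -> np.ndarray:
        out = _rotate(a, angle, order=1, cval=0.0) if angle else a
        return out[..., ::-1].copy() if flip else out

    def tf_mask(a: np.ndarray) -> np.ndarray:
        out = (
            _rotate(a.astype(np.float64), angle, order=0, cval=0.0) > 0.5
            if angle
            else a.astype(bool)
        )
        return out[..., ::-1].copy() if flip else out

    out_inputs = [tf_image(a) for a in inputs]
    if angle:
        chans = [
            _rotate(label_probs[i], angle, order=0, cval=1.0 if i == 0 else 0.0)
            for i in range(3)
        ]
        out_labels = np.stack(chans)
    else:
        out_labels = label_probs.copy()
    if flip:
        out_labels = out_labels[..., ::-1].copy()
    out_masks = [tf_mask(a) for a in masks]
    return out_inputs, out_labels, out_masks


def _loss_gradient(
    probs: np.ndarray, y: np.ndarray, w: np.ndarray, mask: np.ndarray, n: int
) -> np.ndarray:
    """d(weighted CCE)/d(logits) for a softmax head, masked pixels only."""
    s = (w[None, :, None, None] * y).sum(axis=1, keepdims=True)
    g = (s * probs - w[None, :, None, None] * y) / n
    return g * mask[:, None]


def train_fold(
    train_cases: list[PreparedCase],
    val_cases: list[PreparedCase],
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
) -> tuple[SPCNet, dict]:
    """Run the optimization loop on one fold.

    Returns the trained network and a history dict with per-epoch mean
    training loss (and validation loss when ``val_cases`` is nonempty).
    Training is seeded end-to-end; NaN loss aborts with a diagnostic.
    """
    if not train_cases:
        raise VolumeError("empty training set")
    slices = select_training_slices(train_cases)
    if not slices:
        raise VolumeError("no training slices selected")
    weights = compute_class_weights(train_cases, slices, train_cfg.loss_mask)
    w = weights.as_array()
    by_id = {c.case_id: c for c in train_cases}

    model = build_model(model_cfg)
    opt = Adam(model.params(), lr=train_cfg.learning_rate)
    rng = np.random.default_rng(train_cfg.seed)
    history: dict = {"train_loss": [], "val_loss": [], "class_weights": weights.w}

    n_heads = 1 + (model_cfg.n_side_outputs if model_cfg.deep_supervision else 0)
    order = np.arange(len(slices))
    for epoch in range(train_cfg.epochs):
        rng.shuffle(order)
        epoch_losses = []
        for start in range(0, len(order), train_cfg.batch_size):
            batch = [slices[i] for i in order[start : start + train_cfg.batch_size]]
            xs_t2, xs_adc, ys, ms = [], [], [], []
            for case_id, s in batch:
                case = by_id[case_id]
                x_t2 = assemble_25d_input(case.t2w, s)
                x_adc = assemble_25d_input(case.adc, s)
                y = case.labels.probs[:, s]
                m = _scope_mask(case, s, train_cfg.loss_mask)
                if train_cfg.augment:
                    (x_t2, x_adc), y, (m,) = augment_sample(
                        [x_t2, x_adc], y, [m], rng, train_cfg
                    )
                xs_t2.append(x_t2)
                xs_adc.append(x_adc)
                ys.append(y)
                ms.append(m)
            xb_t2, xb_adc = np.stack(xs_t2), np.stack(xs_adc)
            yb, mb = np.stack(ys), np.stack(ms)
            n_pix = int(mb.sum())
            if n_pix == 0:
                continue
            model.zero_grads()
            fused, sides = model.forward(xb_t2, xb_adc, train=True)
            heads = [fused] + (sides if model_cfg.deep_supervision else [])
            batch_loss = 0.0
            d_fused, d_sides = None, None
            for hi, h in enumerate(heads):
                p = softmax(h, axis=1)
                batch_loss += weighted_cce(p, yb, weights, mb)
                g = _loss_gradient(p, yb, w, mb, n_pix) / n_heads
                if hi == 0:
                    d_fused = g
                else:
                    if d_sides is None:
                        d_sides = [np.zeros_like(g) for _ in sides]
                    d_sides[hi - 1] = g
            batch_loss /= n_heads
            if not math.isfinite(batch_loss):
                raise RuntimeError(
                    f"training diverged (non-finite loss) at epoch {epoch}, "
                    f"batch starting {start}"
                )
            model.backward(d_fused, d_sides)
            opt.step(model.grads())
            epoch_losses.append(batch_loss)
        history["train_loss"].append(float(np.mean(epoch_losses)))
        if val_cases:
            history["val_loss"].append(
                _validation_loss(model, val_cases, weights, train_cfg)
            )
    return model, history


def _validation_loss(
    model: SPCNet,
    cases: list[PreparedCase],
    weights: ClassWeights,
    cfg: TrainConfig,
) -> float:
    losses = []
    by_id = {c.case_id: c for c in cases}
    for case_id, s in select_training_slices(cases):
        case = by_id[case_id]
        x_t2 = assemble_25d_input(case.t2w, s)[None]
        x_adc = assemble_25d_input(case.adc, s)[None]
        p = model.predict_proba(x_t2, x_adc)
        m = _scope_mask(case, s, cfg.loss_mask)[None]
        if m.sum():
            losses.append(weighted_cce(p, case.labels.probs[:, s][None], weights, m))
    return float(np.mean(losses)) if losses else float("nan")
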