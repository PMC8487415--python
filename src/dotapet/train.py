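"""Training: combined BCE + Dice loss, augmentation, SGD, early stopping.

The loss is a 6:1 linear combination of pixel-mean binary cross-entropy and
soft Dice loss, minimized with momentum SGD under a polynomial
learning-rate decay.  Training runs for a fixed iteration budget
(mini-batches of augmented liver-masked slices) and stops early when the
validation metric — lesion-level F1 at the default detection settings —
fails to improve for a patience window; the best-validation weights are
restored at the end.  The replicate protocol retrains the model several
times from distinct derived seeds so metrics can be reported as mean ± SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage

from . import nn
from .detect import DetectionConfig, detect_stack
from .evaluate import IOU_MIN_DEFAULT, gold_components, match_lesions, pooled_metrics
from .phantom import Study
from .unet import ModelConfig, ResUNet, build_model, normalize_masked, predict_study

DICE_EPS = 1e-6
BCE_CLIP = 1e-7


# --------------------------------------------------------------------------
# losses
# --------------------------------------------------------------------------

def dice_loss(pred: np.ndarray, target: np.ndarray,
              eps: float = DICE_EPS) -> float:
    """Soft Dice loss 1 − (2Σpt + ε)/(Σp + Σt + ε); 0 for empty–empty."""
    pred = np.asarray(pred, np.float64)
    target = np.asarray(target, np.float64)
    num = 2.0 * float((pred * target).sum()) + eps
    den = float(pred.sum() + target.sum()) + eps
    return 1.0 - num / den


def dice_loss_grad(pred: np.ndarray, target: np.ndarray,
                   eps: float = DICE_EPS) -> np.ndarray:
    pred = np.asarray(pred, np.float64)
    target = np.asarray(target, np.float64)
    num = 2.0 * float((pred * target).sum()) + eps
    den = float(pred.sum() + target.sum()) + eps
    return -(2.0 * target * den - num) / den ** 2


def bce_loss(pred: np.ndarray, target: np.ndarray,
             clip: float = BCE_CLIP) -> float:
    """Pixel-mean binary cross-entropy with probability clipping."""
    p = np.clip(np.asarray(pred, np.float64), clip, 1.0 - clip)
    t = np.asarray(target, np.float64)
    return float(-(t * np.log(p) + (1.0 - t) * np.log1p(-p)).mean())


def bce_loss_grad(pred: np.ndarray, target: np.ndarray,
                  clip: float = BCE_CLIP) -> np.ndarray:
    p = np.clip(np.asarray(pred, np.float64), clip, 1.0 - clip)
    t = np.asarray(target, np.float64)
    return (p - t) / (p * (1.0 - p)) / p.size


def combined_loss(pred: np.ndarray, target: np.ndarray,
                  w_bce: float = 6.0, w_dice: float = 1.0) -> float:
    """w_bce · BCE + w_dice · Dice (6:1 by default)."""
    return w_bce * bce_loss(pred, target) + w_dice * dice_loss(pred, target)


def combined_loss_grad(pred: np.ndarray, target: np.ndarray,
                       w_bce: float = 6.0, w_dice: float = 1.0) -> np.ndarray:
    return (w_bce * bce_loss_grad(pred, target)
            + w_dice * dice_loss_grad(pred, target))


# --------------------------------------------------------------------------
# augmentation
# --------------------------------------------------------------------------

def augment(image: np.ndarray, label: np.ndarray, rng: np.random.Generator,
            flip_prob: float = 0.5, max_rotate_deg: float = 10.0,
            max_translate_frac: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Apply one shared random transform to an (image, label) slice pair.

    Horizontal flip with probability ``flip_prob``, rotation uniform in
    ±max_rotate_deg, translation uniform in ±max_translate_frac of the grid.
    The image is resampled bilinearly; the label with nearest neighbor so it
    stays binary.
    """
    if image.shape != label.shape:
        raise ValueError("image and label must be aligned")
    img, lab = image, label
    if rng.random() < flip_prob:
        img, lab = img[:, ::-1], lab[:, ::-1]
    angle = np.deg2rad(rng.uniform(-max_rotate_deg, max_rotate_deg))
    shift = rng.uniform(-max_translate_frac, max_translate_frac, 2) \
        * np.array(image.shape)
    if angle == 0.0 and not shift.any():
        return img.copy(), lab.copy()
    c = (np.array(image.shape) - 1) / 2.0
    rot = np.array([[np.cos(angle), -np.sin(angle)],
                    [np.sin(angle), np.cos(angle)]])
    matrix = rot.T  # inverse rotation
    offset = c - matrix @ (c + shift)
    img = ndimage.affine_transform(img, matrix, offset=offset, order=1,
                                   mode="constant", cval=0.0)
    lab = ndimage.affine_transform(lab.astype(np.float64), matrix,
                                   offset=offset, order=0,
                                   mode="constant", cval=0.0)
    return img, (lab > 0.5).astype(label.dtype)


# --------------------------------------------------------------------------
# configuration / history
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    w_bce: float = 6.0
    w_dice: float = 1.0
    lr: float = 0.01
    momentum: float = 0.9
    lr_decay_power: float = 0.9
    max_iterations: int = 100_000
    patience_iterations: int = 20_000
    validation_interval: int = 1_000
    batch_size: int = 8
    n_replicates: int = 5
    augment_enabled: bool = True
    flip_prob: float = 0.5
    max_rotate_deg: float = 10.0
    max_translate_frac: float = 0.05
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    iou_min: float = IOU_MIN_DEFAULT
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patience_iterations >= self.max_iterations:
            raise ValueError("patience must be smaller than max_iterations")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.validation_interval < 1 or self.batch_size < 1:
            raise ValueError("validation_interval and batch_size must be >= 1")


@dataclass
class TrainHistory:
    iterations: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    val_iterations: list[int] = field(default_factory=list)
    val_metric: list[float] = field(default_factory=list)
    best_iteration: int = 0
    best_metric: float = float("-inf")
    stop_iteration: int = 0
    stop_reason: str = ""


class SGD:
    """Momentum SGD with polynomial learning-rate decay."""

    def __init__(self, params: Sequence[nn.Parameter], lr: float,
                 momentum: float, max_iterations: int, power: float):
        self.params = list(params)
        self.lr0, self.momentum = lr, momentum
        self.max_iterations, self.power = max_iterations, power
        self.velocity = [np.zeros_like(p.value) for p in self.params]

    def step(self, iteration: int) -> None:
        lr = self.lr0 * (1.0 - iteration / self.max_iterations) ** self.power
        for p, v in zip(self.params, self.velocity):
            v *= self.momentum
            v -= lr * p.grad
            p.value += v


# --------------------------------------------------------------------------
# training loop
# --------------------------------------------------------------------------

def _slice_pool(studies: Sequence[Study]) -> tuple[np.ndarray, np.ndarray]:
    imgs, labs = [], []
    for st in studies:
        norm = normalize_masked(st.stack.voxels, st.liver.mask)
        for z in range(st.stack.n_slices):
            imgs.append(norm[z])
            labs.append(st.lesions.mask[z].astype(np.float64))
    return np.array(imgs), np.array(labs)


def make_f1_validator(val_studies: Sequence[Study],
                      detection: DetectionConfig,
                      iou_min: float = IOU_MIN_DEFAULT,
                      ) -> Callable[[ResUNet], float]:
    """Validation metric: pooled lesion-level F1 at fixed detection settings."""
    golds = [gold_components(st.lesions.labels) for st in val_studies]

    def metric(model: ResUNet) -> float:
        matches = []
        for st, gold in zip(val_studies, golds):
            scores = predict_study(model, st.stack, st.liver)
            comps = detect_stack(scores, detection)
            matches.append(match_lesions(comps, gold, iou_min))
        return pooled_metrics(matches)[2]

    return metric


def train_model(train_studies: Sequence[Study], val_studies: Sequence[Study],
                model_config: ModelConfig, train_config: TrainConfig,
                val_metric_fn: Callable[[ResUNet], float] | None = None,
                ) -> tuple[ResUNet, TrainHistory]:
    """Train one model; deterministic for a fixed (configs, data) triple.

    ``val_metric_fn`` may override the default lesion-F1 validator (used by
    tests to probe the early-stopping contract).  Training halts at the
    iteration budget or once the validation metric has not strictly
    improved for ``patience_iterations``; the best checkpoint is restored.
    """
    if not train_studies or (val_metric_fn is None and not val_studies):
        raise ValueError("train and validation splits must be non-empty")
    cfg = train_config
    imgs, labs = _slice_pool(train_studies)
    if val_metric_fn is None:
        val_metric_fn = make_f1_validator(val_studies, cfg.detection,
                                          cfg.iou_min)
    model = build_model(model_config)
    opt = SGD(model.parameters(), cfg.lr, cfg.momentum,
              cfg.max_iterations, cfg.lr_decay_power)
    rng = np.random.default_rng(cfg.seed)
    hist = TrainHistory()
    best_state = nn.get_state(model)

    n_slices = len(imgs)
    for it in range(1, cfg.max_iterations + 1):
        idx = rng.integers(0, n_slices, cfg.batch_size)
        batch_x = np.empty((cfg.batch_size, 1) + imgs.shape[1:], nn.DTYPE)
        batch_y = np.empty((cfg.batch_size, 1) + labs.shape[1:], np.float64)
        for j, i in enumerate(idx):
            if cfg.augment_enabled:
                xi, yi = augment(imgs[i], labs[i], rng, cfg.flip_prob,
                                 cfg.max_rotate_deg, cfg.max_translate_frac)
            else:
                xi, yi = imgs[i], labs[i]
            batch_x[j, 0] = xi
            batch_y[j, 0] = yi

        model.set_training(True)
        pred = model.forward(batch_x)
        loss = combined_loss(pred, batch_y, cfg.w_bce, cfg.w_dice)
        if not np.isfinite(loss):
            raise RuntimeError(f"non-finite loss {loss} at iteration {it}")
        hist.iterations.append(it)
        hist.train_loss.append(float(loss))
        grad = combined_loss_grad(pred, batch_y, cfg.w_bce, cfg.w_dice)
        model.zero_grad()
        model.backward(grad.astype(nn.DTYPE))
        opt.step(it - 1)

        if it % cfg.validation_interval == 0:
            metric = float(val_metric_fn(model))
            hist.val_iterations.append(it)
            hist.val_metric.append(metric)
            if metric > hist.best_metric:
                hist.best_metric = metric
                hist.best_iteration = it
                best_state = nn.get_state(model)
            if it - hist.best_iteration >= cfg.patience_iterations:
                hist.stop_iteration = it
                hist.stop_reason = "patience"
                break
    else:
        hist.stop_iteration = cfg.max_iterations
        hist.stop_reason = "budget"

    nn.set_state(model, best_state)
    model.set_training(False)
    return model, hist


def derive_replicate_seeds(master_seed: int, n: int) -> list[int]:
    seq = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in seq.spawn(n)]


def train_replicates(train_studies: Sequence[Study],
                     val_studies: Sequence[Study],
                     model_config: ModelConfig, train_config: TrainConfig,
                     ) -> list[tuple[ResUNet, TrainHistory]]:
    """Run the full training n_replicates times from distinct derived seeds."""
    seeds = derive_replicate_seeds(train_config.seed,
                                   train_config.n_replicates)
    out = []
    for rep_seed in seeds:
        mc = replace(model_config, seed=rep_seed)
        tc = replace(train_config, seed=rep_seed)
        out.append(train_model(train_studies, val_studies, mc, tc))
    return out
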