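"""Feature distance, multi-level distillation loss, and student training.

The disparity between a teacher feature vector f_t and the student's f_s at
the same pyramid position is

    D(f_t, f_s) = lambda * (1 - f_t.f_s / max(||f_t|| ||f_s||, eps))
                  + ||f_t - f_s||_2

a weighted sum of the cosine distance and the Euclidean distance (lambda
weights the cosine term; default lambda = 1, eps = 1e-8). The training loss
sums, over the N pyramid levels, the spatial mean of D:

    L = sum_n (1/I_n) sum_i D(F_{n,i}^T, F_{n,i}^S),   I_n = H_n * W_n.

Only the student and bottleneck receive gradients; the teacher is frozen
structurally (its arrays are not Parameters).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .autograd import Adam, Tensor
from .backbone import FeaturePyramid, ModelBundle, preprocess_image

__all__ = [
    "DistanceConfig",
    "TrainConfig",
    "feature_distance",
    "distance_map",
    "distillation_loss",
    "train_student",
]


@dataclass(frozen=True)
class DistanceConfig:
    lambda_weight: float = 1.0
    epsilon: float = 1e-8

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.lambda_weight < 0:
            raise ValueError("lambda_weight must be nonnegative")


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 15
    batch_size: int = 16
    learning_rate: float = 5e-3
    optimizer_name: str = "adam"
    seed: int = 0
    checkpoint_dir: Optional[str] = None

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be nonnegative")
        if self.optimizer_name != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer_name!r}")


# ----------------------------------------------------------------- distances
def feature_distance(f_t: np.ndarray, f_s: np.ndarray, cfg: DistanceConfig = DistanceConfig()) -> float:
    """Distance D between two channel vectors (cosine + Euclidean terms)."""
    f_t = np.asarray(f_t, dtype=np.float64)
    f_s = np.asarray(f_s, dtype=np.float64)
    if f_t.shape != f_s.shape or f_t.ndim != 1:
        raise ValueError(f"expected equal-length vectors, got {f_t.shape} and {f_s.shape}")
    denom = max(np.linalg.norm(f_t) * np.linalg.norm(f_s), cfg.epsilon)
    cos_dist = 1.0 - float(f_t @ f_s) / denom
    return cfg.lambda_weight * cos_dist + float(np.linalg.norm(f_t - f_s))


def distance_map(level_t: np.ndarray, level_s: np.ndarray, cfg: DistanceConfig = DistanceConfig()) -> np.ndarray:
    """Per-position distance over one pyramid level.

    Inputs are (C, H_n, W_n); the output M_n is (H_n, W_n), nonnegative.
    """
    level_t = np.asarray(level_t, dtype=np.float64)
    level_s = np.asarray(level_s, dtype=np.float64)
    if level_t.shape != level_s.shape or level_t.ndim != 3:
        raise ValueError(f"shape-paired (C, H, W) maps required, got {level_t.shape} and {level_s.shape}")
    dot = np.einsum("chw,chw->hw", level_t, level_s)
    nt = np.sqrt(np.einsum("chw,chw->hw", level_t, level_t))
    ns = np.sqrt(np.einsum("chw,chw->hw", level_s, level_s))
    denom = np.maximum(nt * ns, cfg.epsilon)
    cos_dist = 1.0 - dot / denom
    l2 = np.sqrt(np.einsum("chw,chw->hw", level_t - level_s, level_t - level_s))
    return cfg.lambda_weight * cos_dist + l2


def distillation_loss(pyr_t: FeaturePyramid, pyr_s: FeaturePyramid,
                      cfg: DistanceConfig = DistanceConfig()) -> float:
    """Multi-level loss: per-level spatial mean of D, summed over levels."""
    if len(pyr_t.levels) != len(pyr_s.levels):
        raise ValueError("pyramids have different level counts")
    total = 0.0
    for lt, ls in zip(pyr_t.levels, pyr_s.levels):
        total += float(distance_map(lt, ls, cfg).mean())
    return total


def _loss_tensors(t_levels: List[Tensor], s_levels: List[Tensor], cfg: DistanceConfig) -> Tensor:
    """Autograd version of the loss over batched levels (N, C, H, W).

    Returns the batch mean of the per-image multi-level loss.
    """
    total = None
    for lt, ls in zip(t_levels, s_levels):
        dot = (lt * ls).sum(axis=1)                       # (N, H, W)
        nt = (lt * lt).sum(axis=1).sqrt()
        ns = (ls * ls).sum(axis=1).sqrt()
        denom = (nt * ns).clamp_min(cfg.epsilon)
        cos_dist = 1.0 - dot / denom
        diff = lt - ls
        l2 = (diff * diff).sum(axis=1).sqrt()
        d = cfg.lambda_weight * cos_dist + l2
        per_image = d.mean(axis=2).mean(axis=1)           # spatial mean, (N,)
        level_term = per_image.mean()
        total = level_term if total is None else total + level_term
    return total


# ------------------------------------------------------------------ training
def train_student(bundle: ModelBundle, normal_images: Sequence[np.ndarray],
                  tcfg: TrainConfig = TrainConfig(), dcfg: DistanceConfig = DistanceConfig(),
                  labels: Optional[Sequence[int]] = None, verbose: bool = False):
    """Fit the student and bottleneck to replicate the frozen teacher.

    ``normal_images`` must contain only normal B-scans; if ``labels`` is
    given, any nonzero (anomalous) entry raises. Returns ``(bundle,
    loss_history)`` with one mean loss per epoch. The teacher is untouched
    (checksum-verified).
    """
    images = [np.asarray(im, dtype=np.float64) for im in normal_images]
    if not images:
        raise ValueError("training set is empty")
    if labels is not None:
        labels = np.asarray(labels)
        if len(labels) != len(images):
            raise ValueError("labels length does not match images")
        if np.any(labels != 0):
            raise ValueError("training set must contain only normal (label 0) images")

    checksum_before = bundle.teacher_checksum()
    params = bundle.trainable_parameters()
    opt = Adam(params, lr=tcfg.learning_rate)
    rng = np.random.default_rng(tcfg.seed)
    batch = np.stack([preprocess_image(im, bundle.spec) for im in images])[:, None]  # (M, 1, H, W)
    m = len(images)
    history = []
    for epoch in range(tcfg.epochs):
        order = rng.permutation(m)
        epoch_losses = []
        for start in range(0, m, tcfg.batch_size):
            idx = order[start:start + tcfg.batch_size]
            x = Tensor(batch[idx])
            t_levels = bundle.teacher.forward(x)
            code = bundle.bottleneck.forward(t_levels)
            s_levels = bundle.student.forward(code)
            loss = _loss_tensors(t_levels, s_levels, dcfg)
            epoch_losses.append(float(loss.data))
            if tcfg.learning_rate > 0:
                opt.zero_grad()
                loss.backward()
                opt.step()
        history.append(float(np.mean(epoch_losses)))
        if verbose:
            print(f"epoch {epoch + 1}/{tcfg.epochs}  mean_loss={history[-1]:.6f}")
    if bundle.teacher_checksum() != checksum_before:
        raise RuntimeError("teacher parameters changed during training (frozen contract violated)")
    return bundle, history
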