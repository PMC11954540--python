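"""Teacher encoder, bottleneck aggregator and student decoder.

The reverse-distillation layout: a frozen convolutional *teacher* encoder
produces an N-level feature pyramid from a B-scan; a trainable *bottleneck*
fuses all pyramid levels into a single compact code at the deepest spatial
resolution; a trainable *student* decoder runs deepest-to-shallowest and must
emit feature maps with exactly the teacher's shapes at every level.

The teacher is never updated. With ``pretrained_source='none'`` it is a
frozen randomly-initialised encoder — a recognised variant of
distillation-based anomaly detection, and the default at desk scale. A saved
encoder checkpoint can be plugged in via a file path.

Networks are built on :mod:`octad.autograd`; all arrays are float64 NumPy.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import List

import numpy as np
from scipy.ndimage import gaussian_filter

from .autograd import Parameter, Tensor, avg_pool, concat, conv2d, leaky_relu, upsample_nearest

__all__ = [
    "EncoderSpec",
    "FeaturePyramid",
    "ModelBundle",
    "build_bundle",
    "teacher_forward",
    "bottleneck_forward",
    "student_forward",
    "normalize_image",
    "save_bundle",
    "load_bundle",
]


@dataclass(frozen=True)
class EncoderSpec:
    """Architecture contract shared by teacher and student.

    channels[n] and strides[n] fix the shape (C_n, H/stride_n, W/stride_n) of
    pyramid level n. Strides must be strictly increasing powers-of-two
    multiples of each other.
    """

    n_levels: int = 3
    channels: tuple = (16, 32, 64)
    strides: tuple = (4, 8, 16)
    pretrained_source: str = "none"
    kernel_size: int = 5
    input_smoothing_sigma: float = 1.0
    code_channels: int = 0  # 0 -> channels[-1] // 4

    def __post_init__(self):
        if self.n_levels < 1:
            raise ValueError("n_levels must be >= 1")
        if self.kernel_size < 1 or self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be a positive odd integer")
        if self.input_smoothing_sigma < 0:
            raise ValueError("input_smoothing_sigma must be >= 0")
        if self.code_channels < 0:
            raise ValueError("code_channels must be >= 0")
        if len(self.channels) != self.n_levels or len(self.strides) != self.n_levels:
            raise ValueError("channels and strides must have n_levels entries")
        if any(c <= 0 for c in self.channels):
            raise ValueError("channels must be positive")
        if any(s2 <= s1 for s1, s2 in zip(self.strides, self.strides[1:])):
            raise ValueError("strides must be strictly increasing")
        for prev, cur in zip((1,) + tuple(self.strides), self.strides):
            ratio = cur // prev
            if cur % prev or ratio & (ratio - 1):
                raise ValueError("each stride must be a power-of-two multiple of the previous")

    @property
    def effective_code_channels(self) -> int:
        return self.code_channels or max(self.channels[-1] // 4, 4)


@dataclass
class FeaturePyramid:
    """Ordered multi-level feature maps, each of shape (C_n, H_n, W_n)."""

    levels: List[np.ndarray]
    origin: str  # "teacher" | "student"

    def __post_init__(self):
        if self.origin not in ("teacher", "student"):
            raise ValueError("origin must be 'teacher' or 'student'")

    def shapes(self):
        return [lv.shape for lv in self.levels]


def _n_halvings(ratio: int) -> int:
    return int(ratio).bit_length() - 1


def _he_conv(rng: np.random.Generator, oc: int, ic: int, k: int, trainable: bool):
    fan_in = ic * k * k
    w = rng.standard_normal((oc, ic, k, k)) * np.sqrt(2.0 / fan_in)
    b = np.zeros(oc)
    cls = Parameter if trainable else Tensor
    return cls(w), cls(b)


class _ConvNet:
    """Flat container of conv layers with a parameter list."""

    def __init__(self):
        self.layers: list = []  # (name, w, b, stride, pad, activate)

    def add(self, rng, oc, ic, k, stride, pad, activate, trainable, name):
        w, b = _he_conv(rng, oc, ic, k, trainable)
        self.layers.append((name, w, b, stride, pad, activate))

    def parameters(self):
        out = []
        for _, w, b, *_ in self.layers:
            out.extend([w, b])
        return out

    def n_params(self) -> int:
        return sum(p.data.size for p in self.parameters())


class TeacherEncoder(_ConvNet):
    """Strided conv encoder emitting an N-level pyramid (frozen by default)."""

    def __init__(self, spec: EncoderSpec, rng: np.random.Generator, trainable: bool = False):
        super().__init__()
        self.spec = spec
        self.stage_slices = []  # layer index at which each level is emitted
        k = spec.kernel_size
        ic = 1
        prev_stride = 1
        for n in range(spec.n_levels):
            halvings = _n_halvings(spec.strides[n] // prev_stride)
            for h in range(halvings):
                last = h == halvings - 1
                oc = spec.channels[n] if last else max(spec.channels[n] // 2, 4)
                self.add(rng, oc, ic, k, 2, k // 2, True, trainable, f"t{n}_{h}")
                ic = oc
            self.stage_slices.append(len(self.layers) - 1)
            prev_stride = spec.strides[n]

    def forward(self, x: Tensor) -> List[Tensor]:
        h, w = x.data.shape[2], x.data.shape[3]
        if h < self.spec.strides[-1] or w < self.spec.strides[-1]:
            raise ValueError(f"input {h}x{w} smaller than total downsampling {self.spec.strides[-1]}")
        levels = []
        for i, (_, wgt, b, stride, pad, act) in enumerate(self.layers):
            x = conv2d(x, wgt, b, stride=stride, pad=pad)
            if act:
                x = leaky_relu(x)
            if i in self.stage_slices:
                levels.append(x)
        return levels


class Bottleneck(_ConvNet):
    """Fuses all teacher levels into one code at the deepest resolution."""

    def __init__(self, spec: EncoderSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        proj_ch = max(spec.channels[-1] // 4, 4)
        self.proj_ch = proj_ch
        for n in range(spec.n_levels):
            self.add(rng, proj_ch, spec.channels[n], 1, 1, 0, False, True, f"b_proj{n}")
        # a deliberately narrow code: compression is what prevents the student
        # from reconstructing anomalous features
        self.add(rng, spec.effective_code_channels, proj_ch * spec.n_levels, 1, 1, 0, True, True, "b_fuse")

    def forward(self, levels: List[Tensor]) -> Tensor:
        spec = self.spec
        pooled = []
        for n, lv in enumerate(levels):
            factor = spec.strides[-1] // spec.strides[n]
            x = avg_pool(lv, factor)
            name, w, b, stride, pad, act = self.layers[n]
            x = conv2d(x, w, b, stride=stride, pad=pad)
            pooled.append(x)
        x = concat(pooled, axis=1)
        name, w, b, stride, pad, act = self.layers[-1]
        x = conv2d(x, w, b, stride=stride, pad=pad)
        return leaky_relu(x)


class StudentDecoder(_ConvNet):
    """Mirror decoder at half width; emits levels deepest-to-shallowest."""

    def __init__(self, spec: EncoderSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        # 0.75 width: narrow enough to keep the capacity ordering vs the
        # teacher, wide enough to replicate normal variation with a low
        # noise floor (the anomaly gap then comes from the narrow code)
        hidden = [max(int(0.75 * c), 4) for c in spec.channels]
        self.add(rng, hidden[-1], spec.effective_code_channels, 1, 1, 0, True, True, "s_reduce")
        stages = []
        for n in range(spec.n_levels - 1, -1, -1):
            stages.append(n)
        self.stage_plan = stages
        ic = hidden[-1]
        for n in stages:
            self.add(rng, hidden[n], ic, 3, 1, 1, True, True, f"s_conv{n}")
            self.add(rng, spec.channels[n], hidden[n], 1, 1, 0, False, True, f"s_head{n}")
            ic = hidden[n]

    def forward(self, code: Tensor) -> List[Tensor]:
        spec = self.spec
        name, w, b, stride, pad, act = self.layers[0]
        x = conv2d(code, w, b, stride=stride, pad=pad)
        x = leaky_relu(x)
        outs: list = []
        li = 1
        for idx, n in enumerate(self.stage_plan):
            if idx > 0:
                factor = spec.strides[self.stage_plan[idx - 1]] // spec.strides[n]
                x = upsample_nearest(x, factor)
            _, w, b, stride, pad, act = self.layers[li]
            x = conv2d(x, w, b, stride=stride, pad=pad)
            x = leaky_relu(x)
            li += 1
            _, wh, bh, sh, ph, _ = self.layers[li]
            outs.append(conv2d(x, wh, bh, stride=sh, pad=ph))
            li += 1
        outs.reverse()  # shallow-to-deep, matching the teacher pyramid order
        return outs


@dataclass
class ModelBundle:
    """Frozen teacher + trainable bottleneck and student, plus their spec."""

    teacher: TeacherEncoder
    bottleneck: Bottleneck
    student: StudentDecoder
    spec: EncoderSpec

    def __post_init__(self):
        t, s = self.teacher.n_params(), self.student.n_params()
        if s >= t:
            raise ValueError(f"student must have fewer parameters than the teacher ({s} >= {t})")
        for p in self.teacher.parameters():
            if p.requires_grad:
                raise ValueError("teacher parameters must be frozen")

    def trainable_parameters(self):
        return self.bottleneck.parameters() + self.student.parameters()

    def teacher_checksum(self) -> str:
        h = hashlib.sha256()
        for p in self.teacher.parameters():
            h.update(np.ascontiguousarray(p.data).tobytes())
        return h.hexdigest()


def build_bundle(spec: EncoderSpec = EncoderSpec(), seed: int = 0) -> ModelBundle:
    """Construct a bundle with a frozen teacher and fresh trainable S and B."""
    if spec.pretrained_source == "imagenet":
        raise ValueError(
            "no ImageNet-pretrained backbone is bundled; use pretrained_source='none' "
            "or a path to a saved encoder checkpoint")
    rng = np.random.default_rng(seed)
    teacher = TeacherEncoder(spec, rng, trainable=False)
    if spec.pretrained_source not in ("none", ""):
        _load_teacher_weights(teacher, spec.pretrained_source)
    bottleneck = Bottleneck(spec, rng)
    student = StudentDecoder(spec, rng)
    return ModelBundle(teacher=teacher, bottleneck=bottleneck, student=student, spec=spec)


def normalize_image(image: np.ndarray) -> np.ndarray:
    """Per-image min-max normalization to [0, 1] (flat images map to 0)."""
    image = np.asarray(image, dtype=np.float64)
    lo, hi = image.min(), image.max()
    if hi > lo:
        return (image - lo) / (hi - lo)
    return np.zeros_like(image)


def preprocess_image(image: np.ndarray, spec: EncoderSpec) -> np.ndarray:
    """Network input pipeline: light Gaussian despeckling, then min-max.

    The smoothing (sigma = ``spec.input_smoothing_sigma`` px, 0 disables)
    suppresses speckle so teacher features respond to structure rather than
    coherent noise; it is part of the model contract and is applied
    identically at training and inference time.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D B-scan, got shape {image.shape}")
    if spec.input_smoothing_sigma > 0:
        image = gaussian_filter(image, spec.input_smoothing_sigma)
    return normalize_image(image)


def _as_batch(image: np.ndarray, spec: EncoderSpec) -> Tensor:
    return Tensor(preprocess_image(image, spec)[None, None])


def teacher_forward(bundle: ModelBundle, image: np.ndarray) -> FeaturePyramid:
    """Run the frozen teacher on one B-scan; deterministic for fixed weights."""
    levels = bundle.teacher.forward(_as_batch(image, bundle.spec))
    return FeaturePyramid(levels=[lv.data[0] for lv in levels], origin="teacher")


def bottleneck_forward(bundle: ModelBundle, pyramid: FeaturePyramid) -> np.ndarray:
    """Fuse a teacher pyramid into the compact code F^B (C, H_N, W_N)."""
    for n, lv in enumerate(pyramid.levels):
        if lv.shape[0] != bundle.spec.channels[n]:
            raise ValueError(f"level {n} has {lv.shape[0]} channels, spec says {bundle.spec.channels[n]}")
    tensors = [Tensor(lv[None]) for lv in pyramid.levels]
    return bundle.bottleneck.forward(tensors).data[0]


def student_forward(bundle: ModelBundle, code: np.ndarray) -> FeaturePyramid:
    """Decode the bottleneck code into a student pyramid (teacher shapes)."""
    if code.ndim != 3 or code.shape[0] != bundle.spec.effective_code_channels:
        raise ValueError(f"code shape {code.shape} does not match spec")
    levels = bundle.student.forward(Tensor(code[None]))
    return FeaturePyramid(levels=[lv.data[0] for lv in levels], origin="student")


def forward_pyramids(bundle: ModelBundle, image: np.ndarray):
    """Teacher and student pyramids for one B-scan (inference path)."""
    t_levels = bundle.teacher.forward(_as_batch(image, bundle.spec))
    code = bundle.bottleneck.forward(t_levels)
    s_levels = bundle.student.forward(code)
    return (FeaturePyramid([lv.data[0] for lv in t_levels], "teacher"),
            FeaturePyramid([lv.data[0] for lv in s_levels], "student"))


def forward_pyramids_batch(bundle: ModelBundle, images: np.ndarray):
    """Batched inference: images (M, H, W) -> (teacher levels, student levels),
    each a list of arrays (M, C_n, H_n, W_n)."""
    batch = np.stack([preprocess_image(im, bundle.spec) for im in images])[:, None]
    t_levels = bundle.teacher.forward(Tensor(batch))
    code = bundle.bottleneck.forward(t_levels)
    s_levels = bundle.student.forward(code)
    return [lv.data for lv in t_levels], [lv.data for lv in s_levels]


# -------------------------------------------------------------- persistence
def _collect_arrays(net: _ConvNet, prefix: str) -> dict:
    out = {}
    for name, w, b, *_ in net.layers:
        out[f"{prefix}.{name}.w"] = w.data
        out[f"{prefix}.{name}.b"] = b.data
    return out


def _restore_arrays(net: _ConvNet, prefix: str, arrays: dict):
    for name, w, b, *_ in net.layers:
        w.data = np.asarray(arrays[f"{prefix}.{name}.w"], dtype=np.float64)
        b.data = np.asarray(arrays[f"{prefix}.{name}.b"], dtype=np.float64)


def save_bundle(bundle: ModelBundle, path):
    """Save spec + all weights to a single .npz archive."""
    arrays = {}
    arrays.update(_collect_arrays(bundle.teacher, "teacher"))
    arrays.update(_collect_arrays(bundle.bottleneck, "bottleneck"))
    arrays.update(_collect_arrays(bundle.student, "student"))
    spec_json = json.dumps({
        "n_levels": bundle.spec.n_levels,
        "channels": list(bundle.spec.channels),
        "strides": list(bundle.spec.strides),
        "pretrained_source": "none",
        "kernel_size": bundle.spec.kernel_size,
        "input_smoothing_sigma": bundle.spec.input_smoothing_sigma,
        "code_channels": bundle.spec.code_channels,
    })
    np.savez(path, __spec__=np.frombuffer(spec_json.encode(), dtype=np.uint8), **arrays)


def load_bundle(path) -> ModelBundle:
    with np.load(path) as data:
        spec_dict = json.loads(bytes(data["__spec__"]).decode())
        spec = EncoderSpec(
            n_levels=spec_dict["n_levels"],
            channels=tuple(spec_dict["channels"]),
            strides=tuple(spec_dict["strides"]),
            pretrained_source=spec_dict.get("pretrained_source", "none"),
            kernel_size=spec_dict.get("kernel_size", 5),
            input_smoothing_sigma=spec_dict.get("input_smoothing_sigma", 1.0),
            code_channels=spec_dict.get("code_channels", 0),
        )
        bundle = build_bundle(spec, seed=0)
        _restore_arrays(bundle.teacher, "teacher", data)
        _restore_arrays(bundle.bottleneck, "bottleneck", data)
        _restore_arrays(bundle.student, "student", data)
    return bundle


def _load_teacher_weights(teacher: TeacherEncoder, path: str):
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"pretrained teacher checkpoint not found: {p}")
    with np.load(p) as data:
        _restore_arrays(teacher, "teacher", data)
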