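"""Anomaly explanation maps and scalar anomaly scores.

Per B-scan, each pyramid level yields a distance map M_n. The explanation map
is the sum of all M_n bilinearly resized (corner-aligned) to the input size,
then Gaussian-smoothed. The scalar B-scan score is sum_n P(M_n) with P = max
by default, computed on the raw per-level maps; a volume's score is the
maximum of its B-scan scores, and its explanation map is the slice-wise
concatenation of the per-B-scan maps (each slice processed independently).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.ndimage import gaussian_filter

from .backbone import ModelBundle, forward_pyramids_batch
from .distill import DistanceConfig, distance_map

__all__ = [
    "ScoreConfig",
    "ScoreRecord",
    "compose_anomaly_map",
    "bscan_score",
    "volume_score",
    "volume_anomaly_map",
    "score_volume",
]

_AGGREGATIONS = {"max": np.max, "mean": np.mean}


@dataclass(frozen=True)
class ScoreConfig:
    """Aggregation rule P, Gaussian smoothing width, and score source."""

    aggregation_rule: str = "max"
    gaussian_sigma: float = 4.0
    score_source: str = "per_level_raw"  # or "composed_map"

    def __post_init__(self):
        if self.aggregation_rule not in _AGGREGATIONS:
            raise ValueError(f"aggregation_rule must be one of {sorted(_AGGREGATIONS)}")
        if self.gaussian_sigma < 0:
            raise ValueError("gaussian_sigma must be >= 0 (0 disables smoothing)")
        if self.score_source not in ("per_level_raw", "composed_map"):
            raise ValueError("score_source must be 'per_level_raw' or 'composed_map'")


@dataclass(frozen=True)
class ScoreRecord:
    """Scalar anomaly score with provenance; slice_index None at volume level."""

    volume_id: str
    slice_index: Optional[int]
    score: float


def resize_bilinear(m: np.ndarray, out_shape: tuple) -> np.ndarray:
    """Corner-aligned bilinear resize of a 2-D map.

    Output pixel (i, j) samples the input at
    (i * (H-1) / (OH-1), j * (W-1) / (OW-1)), so the four corners map
    exactly onto the input corners.
    """
    h, w = m.shape
    oh, ow = out_shape
    if (h, w) == (oh, ow):
        return np.array(m, dtype=np.float64)
    if h == 1 or w == 1:
        # degenerate axis: constant along it
        m = np.broadcast_to(m, (max(h, 2), max(w, 2)))
        h, w = m.shape
    interp = RegularGridInterpolator((np.arange(h), np.arange(w)), np.asarray(m, dtype=np.float64),
                                     method="linear")
    rows = np.linspace(0.0, h - 1.0, oh)
    cols = np.linspace(0.0, w - 1.0, ow)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    return interp(np.stack([rr, cc], axis=-1))


def compose_anomaly_map(level_maps: Sequence[np.ndarray], input_shape: tuple,
                        cfg: ScoreConfig = ScoreConfig()) -> np.ndarray:
    """Resize each level map to the input size, sum, and smooth."""
    if len(level_maps) == 0:
        raise ValueError("level_maps is empty")
    acc = np.zeros(input_shape, dtype=np.float64)
    for m in level_maps:
        if np.any(np.asarray(m) < 0):
            raise ValueError("level maps must be nonnegative")
        acc += resize_bilinear(np.asarray(m, dtype=np.float64), input_shape)
    if cfg.gaussian_sigma > 0:
        acc = gaussian_filter(acc, sigma=cfg.gaussian_sigma)
    return np.maximum(acc, 0.0)


def bscan_score(level_maps: Sequence[np.ndarray], cfg: ScoreConfig = ScoreConfig(),
                input_shape: Optional[tuple] = None) -> float:
    """Scalar anomaly score for one B-scan.

    With ``score_source='per_level_raw'`` (default): sum over levels of the
    aggregation P applied to each raw level map. With ``'composed_map'``: P
    applied to the composed (resized + smoothed) map; requires input_shape.
    """
    if len(level_maps) == 0:
        raise ValueError("level_maps is empty")
    agg = _AGGREGATIONS[cfg.aggregation_rule]
    if cfg.score_source == "per_level_raw":
        return float(sum(agg(np.asarray(m, dtype=np.float64)) for m in level_maps))
    if input_shape is None:
        raise ValueError("input_shape is required for score_source='composed_map'")
    return float(agg(compose_anomaly_map(level_maps, input_shape, cfg)))


def volume_score(slice_scores: Sequence[float]) -> float:
    """Volume-level score: maximum of the B-scan scores."""
    if len(slice_scores) == 0:
        raise ValueError("slice_scores is empty")
    return float(np.max(slice_scores))


def volume_anomaly_map(bscan_maps: Sequence[np.ndarray]) -> np.ndarray:
    """Stack per-B-scan maps along the slice axis (order preserved)."""
    if len(bscan_maps) == 0:
        raise ValueError("bscan_maps is empty")
    shapes = {m.shape for m in bscan_maps}
    if len(shapes) != 1:
        raise ValueError(f"heterogeneous map shapes: {sorted(shapes)}")
    return np.stack([np.asarray(m, dtype=np.float64) for m in bscan_maps], axis=0)


def score_volume(bundle: ModelBundle, images: Sequence[np.ndarray],
                 dcfg: DistanceConfig = DistanceConfig(), scfg: ScoreConfig = ScoreConfig(),
                 volume_id: str = "vol"):
    """Score every B-scan of a volume and compose the volumetric map.

    Returns ``(volume_record, slice_records, volumetric_map)``.
    """
    if len(images) == 0:
        raise ValueError("volume has no slices")
    images = np.stack([np.asarray(im, dtype=np.float64) for im in images])
    t_levels, s_levels = forward_pyramids_batch(bundle, images)
    slice_records: List[ScoreRecord] = []
    maps: List[np.ndarray] = []
    h, w = images.shape[1], images.shape[2]
    for k in range(images.shape[0]):
        level_maps = [distance_map(t[k], s[k], dcfg) for t, s in zip(t_levels, s_levels)]
        score = bscan_score(level_maps, scfg, input_shape=(h, w))
        slice_records.append(ScoreRecord(volume_id=volume_id, slice_index=k, score=score))
        maps.append(compose_anomaly_map(level_maps, (h, w), scfg))
    vol_record = ScoreRecord(volume_id=volume_id, slice_index=None,
                             score=volume_score([r.score for r in slice_records]))
    return vol_record, slice_records, volume_anomaly_map(maps)
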