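"""Synthetic layered-retina OCT phantom generator.

Produces B-scans built from horizontal reflectivity bands separated by
smooth random boundaries, with multiplicative gamma speckle — a standard
surrogate for the coherent noise of OCT. Volumes are stacks of B-scans whose
boundary geometry varies smoothly along the slice axis. Lesions (drusen-like
bumps, hypo-reflective fluid pockets, smooth deformations) can be injected
with pixel-accurate masks, emulating IRF/SRF/PED-style area annotations.

Everything is a pure function of (config, specs, seed): identical inputs give
bit-identical outputs.

Coordinate convention: row 0 is the top of the B-scan; positions are
(row, col), 0-based; crops are half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

__all__ = [
    "PhantomConfig",
    "LesionSpec",
    "PhantomVolume",
    "PhantomConfigError",
    "LesionPlacementError",
    "generate_normal_bscan",
    "inject_lesion",
    "generate_volume",
    "random_lesion_specs",
    "write_dataset",
    "read_dataset",
]

# Default band reflectivities loosely follow the bright/dark alternation of
# retinal layers (NFL, plexiform, nuclear, photoreceptor, RPE).
_DEFAULT_REFLECTIVITIES = (0.35, 0.15, 0.45, 0.25, 0.65)
_BACKGROUND_LEVEL = 0.05


class PhantomConfigError(ValueError):
    """Invalid phantom configuration."""


class LesionPlacementError(ValueError):
    """Lesion cannot be placed at the requested location."""


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, optics and noise settings for one synthetic volume.

    Parameters
    ----------
    height, width : int
        B-scan size in pixels. 64×64 is the desk-scale default; 496×512
        mirrors common Spectralis acquisitions.
    n_layers : int
        Number of reflectivity bands in the retina stack.
    layer_reflectivities : tuple of float
        Mean intensity of each band, in [0, 1], top to bottom.
    boundary_smoothness : float
        Spatial correlation length (pixels) of the random boundary
        perturbations; larger values give flatter, smoother layers.
    speckle_shape : float
        Shape parameter of the unit-mean multiplicative gamma speckle.
        Larger is less noisy; ``inf`` disables speckle entirely.
    n_bscans : int
        Slices per volume.
    seed : int
        Seed for all randomness in this volume.
    """

    height: int = 64
    width: int = 64
    n_layers: int = 5
    layer_reflectivities: tuple = _DEFAULT_REFLECTIVITIES
    boundary_smoothness: float = 12.0
    speckle_shape: float = 10.0
    n_bscans: int = 8
    seed: int = 0

    def __post_init__(self):
        if min(self.height, self.width, self.n_layers, self.n_bscans) <= 0:
            raise PhantomConfigError("height, width, n_layers and n_bscans must be positive")
        refl = tuple(float(r) for r in self.layer_reflectivities)
        if len(refl) != self.n_layers:
            raise PhantomConfigError(
                f"layer_reflectivities has {len(refl)} entries, expected n_layers={self.n_layers}")
        if any(r < 0 or r > 1 for r in refl):
            raise PhantomConfigError("layer_reflectivities must lie in [0, 1]")
        if self.boundary_smoothness <= 0:
            raise PhantomConfigError("boundary_smoothness must be positive")
        if not (self.speckle_shape > 0):
            raise PhantomConfigError("speckle_shape must be positive (inf disables speckle)")
        object.__setattr__(self, "layer_reflectivities", refl)


@dataclass(frozen=True)
class LesionSpec:
    """One injected lesion.

    kind : 'bump' (drusen/PED-like boundary elevation with bright fill),
    'fluid_pocket' (hypo-reflective ellipse, IRF/SRF-like) or 'deformation'
    (smooth vertical warp of the whole band stack).
    center : (row, col) pixel position.
    target_area : requested lesion area in px²; the realised mask area is
    within ±20% of it (discretised shapes cannot hit it exactly).
    intensity_shift : additive intensity change applied inside the lesion,
    in [-1, 1]; negative for fluid.
    """

    kind: str
    center: tuple
    target_area: float
    intensity_shift: float = 0.0

    def __post_init__(self):
        if self.kind not in ("bump", "fluid_pocket", "deformation"):
            raise ValueError(f"unknown lesion kind {self.kind!r}")
        if not (self.target_area > 0):
            raise ValueError("target_area must be positive")
        if not (-1.0 <= self.intensity_shift <= 1.0):
            raise ValueError("intensity_shift must lie in [-1, 1]")


@dataclass
class PhantomVolume:
    """A labelled synthetic volume: images, per-slice masks, area table."""

    volume_id: str
    images: list  # of (H, W) float arrays in [0, 1]
    masks: list   # of (H, W) uint8 binary arrays
    lesion_areas: list  # of int, per slice
    label: str = field(init=False)

    def __post_init__(self):
        if not (len(self.images) == len(self.masks) == len(self.lesion_areas)):
            raise ValueError("images, masks and lesion_areas must have equal length")
        for k, (m, a) in enumerate(zip(self.masks, self.lesion_areas)):
            if int(m.sum()) != int(a):
                raise ValueError(f"lesion_areas[{k}] does not match mask pixel count")
        self.label = "anomalous" if any(a > 0 for a in self.lesion_areas) else "normal"

    @property
    def n_bscans(self) -> int:
        return len(self.images)


# ----------------------------------------------------------------- geometry
def _boundary_field(config: PhantomConfig) -> np.ndarray:
    """Smooth boundary surfaces for the whole volume.

    Returns an array of shape (n_layers + 1, n_bscans, width) of float row
    positions, strictly increasing along the first axis at every (slice, col).
    """
    rng = np.random.default_rng(config.seed)
    h, w, s, nl = config.height, config.width, config.n_bscans, config.n_layers
    top_base = 0.22 * h
    stack_height = 0.55 * h
    thickness = stack_height / nl

    sig_col = config.boundary_smoothness
    sig_slice = max(1.0, config.n_bscans / 6.0)

    def smooth_noise(amplitude: float) -> np.ndarray:
        noise = rng.standard_normal((s, w))
        noise = gaussian_filter(noise, sigma=(sig_slice, sig_col), mode="nearest")
        peak = np.abs(noise).max()
        if peak > 0:
            noise *= amplitude / peak
        return noise

    top = top_base + smooth_noise(0.08 * h)
    boundaries = [top]
    for _ in range(nl):
        # positive thickness everywhere keeps boundaries strictly increasing
        t = thickness + smooth_noise(0.35 * thickness)
        t = np.maximum(t, 0.3 * thickness)
        boundaries.append(boundaries[-1] + t)
    field3 = np.stack(boundaries, axis=0)
    return np.clip(field3, 1.0, h - 2.0)


def _render_bands(config: PhantomConfig, boundaries: np.ndarray) -> np.ndarray:
    """Paint the reflectivity bands defined by per-column boundaries (no noise)."""
    h, w = config.height, config.width
    rows = np.arange(h)[:, None]
    img = np.full((h, w), _BACKGROUND_LEVEL)
    for k, refl in enumerate(config.layer_reflectivities):
        inside = (rows >= boundaries[k][None, :]) & (rows < boundaries[k + 1][None, :])
        img[inside] = refl
    return img


def _apply_speckle(img: np.ndarray, shape: float, rng: np.random.Generator) -> np.ndarray:
    if np.isinf(shape):
        return img
    speckle = rng.gamma(shape, 1.0 / shape, size=img.shape)
    return np.clip(img * speckle, 0.0, 1.0)


def generate_normal_bscan(config: PhantomConfig, slice_index: int = 0):
    """Generate one lesion-free B-scan.

    Returns ``(image, boundaries)`` where image is (H, W) float in [0, 1] and
    boundaries is (n_layers + 1, W) float row positions, strictly increasing
    top-to-bottom in every column.
    """
    if not (0 <= slice_index < config.n_bscans):
        raise PhantomConfigError(f"slice_index {slice_index} outside [0, {config.n_bscans})")
    field3 = _boundary_field(config)
    boundaries = field3[:, slice_index, :]
    img = _render_bands(config, boundaries)
    rng = np.random.default_rng((config.seed, 1, slice_index))
    img = _apply_speckle(img, config.speckle_shape, rng)
    return img, boundaries


# ------------------------------------------------------------------- lesions
def _check_center(image: np.ndarray, spec: LesionSpec):
    r, c = spec.center
    h, w = image.shape
    if not (0 <= r < h and 0 <= c < w):
        raise LesionPlacementError(f"lesion center {spec.center} outside image {image.shape}")


def _inject_bump(image, boundaries, spec, rng):
    h, w = image.shape
    r0, c0 = spec.center
    # choose the boundary nearest the requested row
    b_idx = int(np.argmin(np.abs(boundaries[:, int(round(c0))] - r0)))
    b_idx = max(b_idx, 1)  # never elevate the top-of-retina boundary itself
    base = boundaries[b_idx]
    # semi-ellipse elevation: area = pi * a * hgt / 2
    hgt = np.sqrt(spec.target_area / np.pi)
    a = 2.0 * hgt
    max_a = 0.95 * min(c0, w - 1 - c0)
    if max_a < 1.0:
        raise LesionPlacementError("bump center too close to the lateral image edge")
    if a > max_a:
        a = max_a
        hgt = 2.0 * spec.target_area / (np.pi * a)
    cols = np.arange(w)
    u = (cols - c0) / a
    lift = np.where(np.abs(u) < 1.0, hgt * np.sqrt(np.clip(1 - u ** 2, 0, 1)), 0.0)
    new_boundary = base - lift
    if np.all(new_boundary <= 0):
        raise LesionPlacementError("bump extends fully above the image")
    rows = np.arange(h)[:, None]
    region = (rows >= new_boundary[None, :]) & (rows < base[None, :])
    # bright drusen-like fill, brighter for larger intensity_shift
    fill = float(np.clip(0.55 + abs(spec.intensity_shift) * 0.4, 0.0, 1.0))
    out = image.copy()
    out[region] = np.clip(fill * (1 + 0.05 * rng.standard_normal(int(region.sum()))), 0.0, 1.0)
    return out, region.astype(np.uint8)


def _inject_fluid(image, boundaries, spec, rng):
    h, w = image.shape
    r0, c0 = spec.center
    top, bottom = boundaries[0], boundaries[-1]
    cint = int(round(c0))
    if r0 < top[cint] - 2 or r0 > bottom[cint] + 2:
        raise LesionPlacementError("fluid pocket center outside the band stack")
    # ellipse with 2:1 aspect: area = pi * a * b, b = a / 2
    a = np.sqrt(2.0 * spec.target_area / np.pi)
    b = a / 2.0
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    region = ((rows - r0) / b) ** 2 + ((cols - c0) / a) ** 2 <= 1.0
    if not region.any():
        raise LesionPlacementError("fluid pocket degenerate (empty region)")
    shift = spec.intensity_shift if spec.intensity_shift != 0 else -0.3
    out = image.copy()
    old = image[region]
    new_vals = np.clip(old + shift, 0.0, 1.0)
    # where clipping saturated the change (old already at 0 or 1), still modify
    stuck = new_vals == old
    new_vals[stuck] = np.where(old[stuck] < 0.5, old[stuck] + 0.05, old[stuck] - 0.05)
    out[region] = new_vals
    return out, region.astype(np.uint8)


def _inject_deformation(image, boundaries, spec, rng):
    h, w = image.shape
    r0, c0 = spec.center
    # peak displacement must exceed the normal boundary-perturbation envelope
    # (~0.08*H) or the warp is within the normal distribution, not a lesion
    amp = max(10.0, 0.16 * h)
    thresh = 0.5  # displacement above which a pixel counts as lesioned
    # super-level set {disp > thresh} is an ellipse of area 2*pi*sc*sr*ln(amp/thresh)
    prod = spec.target_area / (2.0 * np.pi * np.log(amp / thresh))
    sc = np.sqrt(2.0 * prod)
    sr = prod / sc
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    disp = amp * np.exp(-(((cols - c0) ** 2) / (2 * sc ** 2) + ((rows - r0) ** 2) / (2 * sr ** 2)))
    top, bottom = boundaries[0], boundaries[-1]
    cint = int(round(c0))
    if r0 < top[cint] - 4 or r0 > bottom[cint] + 4:
        raise LesionPlacementError("deformation center outside the band stack")
    out = np.empty_like(image)
    grid = np.arange(h, dtype=float)
    for c in range(w):
        # sample the column at vertically shifted positions
        src = np.clip(grid + disp[:, c], 0, h - 1)
        out[:, c] = np.interp(src, grid, image[:, c])
    region = disp > thresh
    return out, region.astype(np.uint8)


_INJECTORS = {"bump": _inject_bump, "fluid_pocket": _inject_fluid, "deformation": _inject_deformation}


def inject_lesion(image: np.ndarray, boundaries: np.ndarray, spec: LesionSpec, seed: int = 0):
    """Inject one lesion into a B-scan.

    Returns ``(modified image, binary mask)``; the mask marks the modified
    pixels and its area is within ±20% of ``spec.target_area`` whenever the
    lesion fits inside the image.
    """
    _check_center(image, spec)
    rng = np.random.default_rng(seed)
    out, mask = _INJECTORS[spec.kind](image, boundaries, spec, rng)
    if mask.sum() < 1:
        raise LesionPlacementError("lesion produced an empty mask")
    return out, mask


# ------------------------------------------------------------------- volumes
def generate_volume(config: PhantomConfig, lesion_specs: Optional[Sequence[Sequence[LesionSpec]]] = None,
                    volume_id: str = "vol") -> PhantomVolume:
    """Generate a coherent volume with optional per-slice lesion lists.

    ``lesion_specs`` must have one (possibly empty) list per B-scan, or be
    None for an all-normal volume.
    """
    if lesion_specs is None:
        lesion_specs = [[] for _ in range(config.n_bscans)]
    if len(lesion_specs) != config.n_bscans:
        raise PhantomConfigError(
            f"lesion_specs has {len(lesion_specs)} entries, expected n_bscans={config.n_bscans}")
    field3 = _boundary_field(config)
    images, masks, areas = [], [], []
    for k in range(config.n_bscans):
        boundaries = field3[:, k, :]
        img = _render_bands(config, boundaries)
        rng = np.random.default_rng((config.seed, 1, k))
        img = _apply_speckle(img, config.speckle_shape, rng)
        mask = np.zeros(img.shape, dtype=np.uint8)
        for j, spec in enumerate(lesion_specs[k]):
            img, m = inject_lesion(img, boundaries, spec,
                                   seed=(config.seed * 1000003 + k * 131 + j) % (2 ** 31))
            mask |= m
        images.append(img)
        masks.append(mask)
        areas.append(int(mask.sum()))
    return PhantomVolume(volume_id=volume_id, images=images, masks=masks, lesion_areas=areas)


def random_lesion_specs(config: PhantomConfig, rng: np.random.Generator,
                        slice_fraction: float = 0.5,
                        area_range: tuple = (100.0, 1600.0),
                        kinds: Sequence[str] = ("bump", "fluid_pocket", "deformation")):
    """Draw per-slice lesion lists for one anomalous volume.

    A contiguous central block of ``slice_fraction`` of the slices receives
    one lesion each (disease concentrated near the volume centre, as in
    fovea-centred scans); kinds cycle, areas are log-uniform in
    ``area_range``, centred in the middle of the band stack with lateral
    jitter.
    """
    n = config.n_bscans
    n_lesioned = max(1, int(round(slice_fraction * n)))
    start = (n - n_lesioned) // 2
    specs: list = [[] for _ in range(n)]
    lo, hi = np.log(area_range[0]), np.log(area_range[1])
    for i, k in enumerate(range(start, start + n_lesioned)):
        area = float(np.exp(rng.uniform(lo, hi)))
        kind = kinds[i % len(kinds)]
        row = config.height * rng.uniform(0.4, 0.6)
        col = config.width * rng.uniform(0.35, 0.65)
        shift = -0.45 if kind == "fluid_pocket" else 0.3
        specs[k] = [LesionSpec(kind=kind, center=(row, col), target_area=area, intensity_shift=shift)]
    return specs


# ----------------------------------------------------------------------- I/O
def _to_png(img: np.ndarray, bits: int) -> np.ndarray:
    if bits == 8:
        return np.round(img * 255).astype(np.uint8)
    if bits == 16:
        return np.round(img * 65535).astype(np.uint16)
    raise ValueError("bits must be 8 or 16")


def _from_png(arr: np.ndarray) -> np.ndarray:
    scale = 255.0 if arr.dtype == np.uint8 else 65535.0
    return arr.astype(np.float64) / scale


def write_dataset(volumes: Sequence[PhantomVolume], out_dir, bits: int = 16) -> pd.DataFrame:
    """Write volumes as per-slice PNGs plus a CSV manifest.

    Layout: ``<out_dir>/<volume_id>/images/<k>.png`` and ``.../masks/<k>.png``;
    manifest columns: volume_id, slice_index, label, lesion_area_px,
    relative_lesion_area. Returns the manifest frame (also saved as
    ``manifest.csv``).
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create dataset directory {out_dir}: {exc}") from exc
    rows = []
    for vol in volumes:
        vdir = out_dir / vol.volume_id
        (vdir / "images").mkdir(parents=True, exist_ok=True)
        (vdir / "masks").mkdir(parents=True, exist_ok=True)
        for k, (img, mask) in enumerate(zip(vol.images, vol.masks)):
            iio.imwrite(vdir / "images" / f"{k:04d}.png", _to_png(img, bits))
            iio.imwrite(vdir / "masks" / f"{k:04d}.png", (mask * 255).astype(np.uint8))
            rows.append({
                "volume_id": vol.volume_id,
                "slice_index": k,
                "label": vol.label,
                "lesion_area_px": int(vol.lesion_areas[k]),
                "relative_lesion_area": vol.lesion_areas[k] / img.size,
            })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def read_dataset(out_dir):
    """Read back a dataset written by :func:`write_dataset`.

    Returns ``(volumes, manifest)`` with images as float arrays in [0, 1]
    and masks binary uint8.
    """
    out_dir = Path(out_dir)
    manifest = pd.read_csv(out_dir / "manifest.csv")
    volumes = []
    for vid, grp in manifest.groupby("volume_id", sort=False):
        grp = grp.sort_values("slice_index")
        images, masks, areas = [], [], []
        for _, row in grp.iterrows():
            k = int(row.slice_index)
            img = _from_png(iio.imread(out_dir / str(vid) / "images" / f"{k:04d}.png"))
            mask = (iio.imread(out_dir / str(vid) / "masks" / f"{k:04d}.png") > 127).astype(np.uint8)
            images.append(img)
            masks.append(mask)
            areas.append(int(mask.sum()))
        volumes.append(PhantomVolume(volume_id=str(vid), images=images, masks=masks, lesion_areas=areas))
    return volumes, manifest
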