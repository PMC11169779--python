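"""CTA-style preprocessing and augmentation.

The chain mirrors standard volumetric-segmentation preprocessing:
resample to isotropic spacing (trilinear for images, nearest for
labels), clip the HU range to [0, 1200] and min-max normalize to
[0, 1], crop away non-body regions, extract cubic patches, and apply
seeded rigid-rotation / isotropic-zoom / noise / artifact augmentation.

Grid convention: voxel ``i`` is centred at ``origin + i * spacing``, so
resampling maps output index ``j`` to input index ``j * target / source``
with no half-voxel shift.  All operations are pure functions; stochastic
ones are fully determined by their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import EmptyStructureError, ValidationError
from .phantom import _artifact_field
from .volume import ImageVolume, LabelVolume, check_congruent


@dataclass(frozen=True)
class PreprocessConfig:
    target_spacing_mm: float = 0.5
    clip_low: float = 0.0
    clip_high: float = 1200.0
    patch_edge: int = 256
    body_threshold: float = 0.0

    def __post_init__(self) -> None:
        if self.clip_low >= self.clip_high:
            raise ValidationError(
                f"clip_low must be < clip_high, got [{self.clip_low}, {self.clip_high}]"
            )
        if self.target_spacing_mm <= 0:
            raise ValidationError(f"target_spacing_mm must be > 0, got {self.target_spacing_mm}")
        if self.patch_edge < 16:
            raise ValidationError(f"patch_edge must be >= 16, got {self.patch_edge}")


@dataclass(frozen=True)
class AugmentParams:
    """Rigid rotation (deg, about x/y/z), isotropic zoom, noise, artifacts."""

    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    zoom: float = 1.0
    noise_sigma: float = 0.0
    artifact_strength: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        rot = tuple(float(a) for a in self.rotation_deg)
        object.__setattr__(self, "rotation_deg", rot)
        if len(rot) != 3 or any(abs(a) > 20.0 for a in rot):
            raise ValidationError(f"rotation angles must each be within +-20 deg, got {rot}")
        if not 0.85 <= self.zoom <= 1.15:
            raise ValidationError(f"zoom must be within [0.85, 1.15], got {self.zoom}")
        if self.noise_sigma < 0 or self.artifact_strength < 0:
            raise ValidationError("noise_sigma and artifact_strength must be >= 0")


def _target_shape(shape, spacing, target):
    extent = np.asarray(shape) * np.asarray(spacing)
    return tuple(max(1, int(round(e / target))) for e in extent)


def _resample_coords(out_shape, scale):
    grids = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in out_shape], indexing="ij")
    return [g * s for g, s in zip(grids, scale)]


def resample_image(image: ImageVolume, target_spacing_mm: float) -> ImageVolume:
    """Trilinear resampling onto an isotropic grid at the target spacing."""
    if target_spacing_mm <= 0:
        raise ValidationError(f"target_spacing_mm must be > 0, got {target_spacing_mm}")
    out_shape = _target_shape(image.shape, image.spacing, target_spacing_mm)
    scale = [target_spacing_mm / s for s in image.spacing]
    coords = _resample_coords(out_shape, scale)
    out = ndimage.map_coordinates(
        image.data.astype(np.float64), coords, order=1, mode="nearest"
    )
    return ImageVolume(
        out.astype(image.data.dtype if np.issubdtype(image.data.dtype, np.floating) else np.float64),
        (target_spacing_mm,) * 3,
        image.origin,
        image.orientation,
    )


def resample_labels(labels: LabelVolume, target_spacing_mm: float) -> LabelVolume:
    """Nearest-neighbour resampling; never invents labels."""
    if target_spacing_mm <= 0:
        raise ValidationError(f"target_spacing_mm must be > 0, got {target_spacing_mm}")
    out_shape = _target_shape(labels.shape, labels.spacing, target_spacing_mm)
    scale = [target_spacing_mm / s for s in labels.spacing]
    coords = _resample_coords(out_shape, scale)
    out = ndimage.map_coordinates(labels.data, coords, order=0, mode="nearest")
    return LabelVolume(
        out.astype(labels.data.dtype),
        (target_spacing_mm,) * 3,
        labels.origin,
        labels.orientation,
        labels.vocabulary,
    )


def clip_and_normalize(
    image: ImageVolume, clip_low: float = 0.0, clip_high: float = 1200.0
) -> ImageVolume:
    """Clip to [clip_low, clip_high] then affinely map that window to [0, 1]."""
    if clip_low >= clip_high:
        raise ValidationError(f"clip window degenerate: [{clip_low}, {clip_high}]")
    data = np.clip(image.data.astype(np.float64), clip_low, clip_high)
    data = (data - clip_low) / (clip_high - clip_low)
    return ImageVolume(data.astype(np.float32), image.spacing, image.origin, image.orientation)


def crop_to_body(
    image: ImageVolume, body_threshold: float = 0.0, margin: int = 2
) -> tuple[ImageVolume, tuple[int, int, int]]:
    """Tight bounding box (plus a fixed margin) of voxels above threshold.

    Returns the cropped volume and the crop offset (min corner, in voxels
    of the input grid) so congruent label volumes can be cropped with
    :func:`crop_with_offset`.
    """
    fg = image.data > body_threshold
    if not fg.any():
        raise EmptyStructureError("empty body region: no voxel above threshold")
    idx = np.argwhere(fg)
    lo = np.maximum(idx.min(axis=0) - margin, 0)
    hi = np.minimum(idx.max(axis=0) + 1 + margin, image.shape)
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    origin = tuple(o + int(l) * s for o, l, s in zip(image.origin, lo, image.spacing))
    out = ImageVolume(image.data[sl].copy(), image.spacing, origin, image.orientation)
    return out, (int(lo[0]), int(lo[1]), int(lo[2]))


def crop_with_offset(volume, offset, shape):
    """Crop a congruent volume with the offset/shape from :func:`crop_to_body`."""
    sl = tuple(slice(int(o), int(o) + int(n)) for o, n in zip(offset, shape))
    origin = tuple(
        org + int(o) * s for org, o, s in zip(volume.origin, offset, volume.spacing)
    )
    out = volume.with_data(volume.data[sl].copy())
    out.origin = origin
    return out


def extract_patch(
    image: ImageVolume, patch_edge: int, center: tuple[int, int, int]
) -> ImageVolume:
    """Cubic patch centred at a voxel, zero-padded past the volume edge."""
    if patch_edge < 16:
        raise ValidationError(f"patch_edge must be >= 16, got {patch_edge}")
    center = tuple(int(c) for c in center)
    if any(c < 0 or c >= n for c, n in zip(center, image.shape)):
        raise ValidationError(f"center {center} outside volume of shape {image.shape}")
    out = np.zeros((patch_edge,) * 3, dtype=image.data.dtype)
    start = [c - patch_edge // 2 for c in center]
    src_lo = [max(0, s) for s in start]
    src_hi = [min(n, s + patch_edge) for s, n in zip(start, image.shape)]
    dst_lo = [sl - s for sl, s in zip(src_lo, start)]
    dst_hi = [dl + (sh - sl) for dl, sl, sh in zip(dst_lo, src_lo, src_hi)]
    out[tuple(slice(a, b) for a, b in zip(dst_lo, dst_hi))] = image.data[
        tuple(slice(a, b) for a, b in zip(src_lo, src_hi))
    ]
    origin = tuple(o + s * sp for o, s, sp in zip(image.origin, start, image.spacing))
    return ImageVolume(out, image.spacing, origin, image.orientation)


def _rotation_matrix(angles_deg):
    ax, ay, az = np.radians(angles_deg)
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def augment(
    image: ImageVolume,
    labels: LabelVolume,
    params: AugmentParams,
    *,
    fill_value: float = 0.0,
) -> tuple[ImageVolume, LabelVolume]:
    """Apply the same rigid rotation + isotropic zoom to both volumes.

    The image is interpolated trilinearly (out-of-field filled with
    ``fill_value``, i.e. the post-normalization background), labels with
    nearest neighbour; seeded noise and artifacts are then added to the
    image only.  ``noise_sigma`` is on the image's own intensity scale
    (use normalized images).
    """
    check_congruent(image, labels, names=("image", "labels"))
    R = _rotation_matrix(params.rotation_deg)
    S = np.diag(image.spacing)
    Sinv = np.diag([1.0 / s for s in image.spacing])
    # affine_transform maps output voxel o to input voxel M @ o + off;
    # objects in the output appear rotated by R and magnified by zoom
    M = Sinv @ (R.T / params.zoom) @ S
    c = (np.asarray(image.shape) - 1) / 2.0
    off = c - M @ c
    img = ndimage.affine_transform(
        image.data.astype(np.float64), M, offset=off, order=1, mode="constant",
        cval=fill_value,
    )
    lab = ndimage.affine_transform(
        labels.data, M, offset=off, order=0, mode="constant", cval=0
    )
    rng = np.random.default_rng(params.seed)
    if params.noise_sigma > 0:
        img = img + rng.standard_normal(img.shape) * params.noise_sigma
    if params.artifact_strength > 0:
        img = img + _artifact_field(
            img.shape, image.spacing, params.artifact_strength, rng, 1.0
        )
    out_img = ImageVolume(img.astype(np.float32), image.spacing, image.origin, image.orientation)
    out_lab = LabelVolume(
        lab.astype(labels.data.dtype), labels.spacing, labels.origin,
        labels.orientation, labels.vocabulary,
    )
    return out_img, out_lab
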