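"""In-memory containers for 3-D image and label volumes.

Both containers carry the grid geometry (per-axis voxel spacing in mm,
world origin, axis-orientation tag) next to the dense data array.  The
convention throughout the package is voxel-centred: voxel index ``i``
sits at world position ``origin + i * spacing`` along each axis, which
matches a diagonal NIfTI affine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError, ValidationError

# Label vocabulary: fixed integer codes for the four aortic-root
# structures segmented from contrast CTA.
LABEL_BACKGROUND = 0
LABEL_AA = 1  # ascending aorta (blood pool)
LABEL_LV = 2  # left ventricle (blood pool)
LABEL_LEAFLET = 3  # aortic-valve leaflets
LABEL_CALCIFICATION = 4

LABEL_VOCABULARY = (
    LABEL_BACKGROUND,
    LABEL_AA,
    LABEL_LV,
    LABEL_LEAFLET,
    LABEL_CALCIFICATION,
)

#: structure name -> label code, in reporting order
STRUCTURE_LABELS = {
    "AA": LABEL_AA,
    "LV": LABEL_LV,
    "leaflet": LABEL_LEAFLET,
    "calcification": LABEL_CALCIFICATION,
}


def _as_triple(value, name: str) -> tuple[float, float, float]:
    arr = np.asarray(value, dtype=float).ravel()
    if arr.size != 3:
        raise ValidationError(f"{name} must have exactly 3 components, got {arr.size}")
    return (float(arr[0]), float(arr[1]), float(arr[2]))


@dataclass
class ImageVolume:
    """Dense 3-D scalar field (HU-like or normalized intensity)."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    orientation: str = "RAS"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValidationError(f"data must be 3-D, got ndim={self.data.ndim}")
        self.spacing = _as_triple(self.spacing, "spacing")
        if any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be strictly positive, got {self.spacing}")
        self.origin = _as_triple(self.origin, "origin")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def with_data(self, data: np.ndarray) -> "ImageVolume":
        """Same geometry, new array (shape may differ, e.g. after cropping)."""
        return ImageVolume(data, self.spacing, self.origin, self.orientation)

    def copy(self) -> "ImageVolume":
        return ImageVolume(self.data.copy(), self.spacing, self.origin, self.orientation)


@dataclass
class LabelVolume:
    """Dense 3-D integer label field on the same geometry as its image.

    Every voxel must belong to the fixed vocabulary
    {0 background, 1 AA, 2 LV, 3 leaflet, 4 calcification}.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    orientation: str = "RAS"
    vocabulary: tuple[int, ...] = field(default=LABEL_VOCABULARY)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValidationError(f"data must be 3-D, got ndim={self.data.ndim}")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValidationError(f"label data must be integer-typed, got {self.data.dtype}")
        self.spacing = _as_triple(self.spacing, "spacing")
        if any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be strictly positive, got {self.spacing}")
        self.origin = _as_triple(self.origin, "origin")
        present = np.unique(self.data)
        unknown = set(present.tolist()) - set(self.vocabulary)
        if unknown:
            raise ValidationError(f"labels outside vocabulary {self.vocabulary}: {sorted(unknown)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def mask(self, label: int) -> np.ndarray:
        return self.data == label

    def with_data(self, data: np.ndarray) -> "LabelVolume":
        return LabelVolume(data, self.spacing, self.origin, self.orientation, self.vocabulary)

    def copy(self) -> "LabelVolume":
        return LabelVolume(
            self.data.copy(), self.spacing, self.origin, self.orientation, self.vocabulary
        )


def check_congruent(a, b, *, names=("first", "second")) -> None:
    """Raise :class:`GeometryError` unless the two volumes share shape and spacing."""
    if a.data.shape != b.data.shape:
        raise GeometryError(
            f"{names[0]} shape {a.data.shape} != {names[1]} shape {b.data.shape}"
        )
    if not np.allclose(a.spacing, b.spacing):
        raise GeometryError(
            f"{names[0]} spacing {a.spacing} != {names[1]} spacing {b.spacing}"
        )
    if not np.allclose(a.origin, b.origin):
        raise GeometryError(f"{names[0]} origin {a.origin} != {names[1]} origin {b.origin}")
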