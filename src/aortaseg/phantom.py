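"""Synthetic aortic-root phantom generator.

Emits paired image/label volumes that mimic a contrast-CTA aortic root:
a bright tubular ascending aorta (AA), a left-ventricle (LV) blood-pool
ellipsoid capping the tube, two or three thin leaflet sheets spanning
the annulus and separated at the commissures, bright calcification
specks sitting on the leaflet surfaces, and optional Gaussian noise and
low-frequency artifacts.  Valve morphology follows the Sievers
vocabulary: TAV (three cusps), BAV type 0 (two cusps, no raphe) and BAV
type 1 (two cusps, one raphe modelled as a thin leaflet-labelled ridge
rising from the conjoined cusp at the fusion line of the two embryonic
cusp positions).

The geometry is deliberately idealised (a cylinder, an ellipsoid and
flat wedge-shaped sheets) — it preserves the *topological* facts the
post-processing pipeline exploits (k separated thin sheets, two large
blood-pool bodies, high-contrast calcium) rather than patient anatomy.

All randomness flows from ``PhantomSpec.seed``; the generator is a pure
function of its spec.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .volume import (
    LABEL_AA,
    LABEL_CALCIFICATION,
    LABEL_LEAFLET,
    LABEL_LV,
    ImageVolume,
    LabelVolume,
)

VALVE_TYPES = ("TAV", "BAV0", "BAV1")

# Canonical angular placement of the cusps in the annular (x, y) plane,
# degrees counter-clockwise from +x.  With a RAS-like frame (+y anterior)
# the tricuspid non-coronary cusp faces anterior-right in patients; here
# we fix a documented convention and the naming stage mirrors it.
TAV_CUSP_ANGLES = {
    "non-coronary": 90.0,
    "left-coronary": 210.0,
    "right-coronary": 330.0,
}
BAV_CUSP_ANGLES = {"anterior": 90.0, "posterior": 270.0}

# HU palette, chosen inside the CTA clipping window [0, 1200] so that the
# leaflets are the lowest-contrast class (hardest to segment) and calcium
# the brightest, as in real contrast scans.
HU_BACKGROUND = -50.0
HU_BLOOD = 400.0
HU_LEAFLET = 150.0
HU_CALCIFICATION = 1000.0
HU_SCALE = 1200.0  # width of the clipping window; noise sigma is relative to it


@dataclass(frozen=True)
class PhantomSpec:
    """Generative parameters for one synthetic aortic-root case."""

    valve_type: str = "TAV"
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    annulus_radius_mm: float = 12.0
    aorta_length_mm: float = 30.0
    leaflet_thickness_mm: float = 2.0
    cusp_gap_deg: float = 16.0
    raphe: bool | None = None  # None -> derived from valve_type
    n_calcifications: int = 4
    calcification_radius_mm: float = 1.5
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.valve_type not in VALVE_TYPES:
            raise ValidationError(f"valve_type must be one of {VALVE_TYPES}, got {self.valve_type!r}")
        shape = tuple(int(n) for n in self.grid_shape)
        object.__setattr__(self, "grid_shape", shape)
        if len(shape) != 3 or any(n < 32 for n in shape):
            raise ValidationError(f"grid_shape axes must each be >= 32, got {shape}")
        spacing = tuple(float(s) for s in self.spacing_mm)
        object.__setattr__(self, "spacing_mm", spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValidationError(f"spacing_mm must be 3 positive lengths, got {spacing}")
        for name in ("annulus_radius_mm", "aorta_length_mm", "leaflet_thickness_mm",
                     "calcification_radius_mm"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive, got {getattr(self, name)}")
        if self.leaflet_thickness_mm >= self.annulus_radius_mm:
            raise ValidationError(
                "leaflet_thickness_mm must be smaller than annulus_radius_mm "
                f"({self.leaflet_thickness_mm} >= {self.annulus_radius_mm})"
            )
        if not 0.0 < self.cusp_gap_deg < 60.0:
            raise ValidationError(f"cusp_gap_deg must be in (0, 60), got {self.cusp_gap_deg}")
        if self.n_calcifications < 0:
            raise ValidationError(f"n_calcifications must be >= 0, got {self.n_calcifications}")
        if self.noise_sigma < 0:
            raise ValidationError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        expected_raphe = self.valve_type == "BAV1"
        if self.raphe is None:
            object.__setattr__(self, "raphe", expected_raphe)
        elif bool(self.raphe) != expected_raphe:
            raise ValidationError(
                f"raphe must be {expected_raphe} for valve_type {self.valve_type}, got {self.raphe}"
            )

    @property
    def n_cusps(self) -> int:
        return 3 if self.valve_type == "TAV" else 2

    def cusp_layout(self) -> dict[str, float]:
        """Name -> angular centre (deg) of each cusp in this morphology."""
        return dict(TAV_CUSP_ANGLES if self.valve_type == "TAV" else BAV_CUSP_ANGLES)


def _world_grids(shape, spacing):
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def generate_phantom(spec: PhantomSpec) -> tuple[ImageVolume, LabelVolume]:
    """Build one synthetic case from its spec.

    Returns an HU-valued image and the exact label volume it was painted
    from.  Leaflets are flat sheets one ``leaflet_thickness_mm`` thick,
    carved into k angular wedges by slits of constant width at the
    commissure half-planes (so the wedges are genuinely disconnected
    regardless of radius); a BAV1 raphe is an extra ridge of leaflet
    voxels rising ~4 mm above the sheet along the conjoined cusp's
    fusion line.
    """
    shape = spec.grid_shape
    spacing = np.asarray(spec.spacing_mm)
    X, Y, Z = _world_grids(shape, spacing)
    extent = (np.asarray(shape) - 1) * spacing

    cx, cy = extent[0] / 2.0, extent[1] / 2.0
    R = spec.annulus_radius_mm
    # annulus plane height: leave room for the LV below and the tube above
    z0 = min(0.38 * extent[2], extent[2] - spec.aorta_length_mm - 2 * spacing[2])
    z0 = max(z0, 0.25 * extent[2])

    dx, dy = X - cx, Y - cy
    r2 = dx * dx + dy * dy
    in_tube = r2 <= R * R

    labels = np.zeros(shape, dtype=np.uint8)

    # ascending aorta: bright lumen cylinder along +z
    aa = in_tube & (Z >= z0) & (Z < z0 + spec.aorta_length_mm)
    labels[aa] = LABEL_AA

    # left ventricle: ellipsoid capping the tube from below, cut at z0
    lv_a = 0.75 * R
    lv_c = 0.9 * R
    lv_cz = z0 - 0.8 * lv_c
    lv = ((dx / lv_a) ** 2 + (dy / lv_a) ** 2 + ((Z - lv_cz) / lv_c) ** 2 <= 1.0) & (Z < z0)
    labels[lv] = LABEL_LV

    # leaflet sheets: flat slab 1 mm above the annulus plane, split into
    # cusps by slits of half-width g at the commissure half-planes
    theta = np.degrees(np.arctan2(dy, dx)) % 360.0
    t = spec.leaflet_thickness_mm
    sheet_lo = z0 + 1.0
    slab = in_tube & (Z >= sheet_lo) & (Z < sheet_lo + t)
    g = max(1.1 * float(spacing.max()), R * np.sin(np.radians(spec.cusp_gap_deg) / 2.0))

    centers = sorted(spec.cusp_layout().values())
    half = 360.0 / spec.n_cusps / 2.0
    r = np.sqrt(r2)
    leaflet = np.zeros(shape, dtype=bool)
    for c in centers:
        ang = (theta - c + 180.0) % 360.0 - 180.0  # signed offset from cusp centre
        in_sector = np.abs(ang) <= half
        # perpendicular distance to the two bounding commissure half-planes
        d_edge = r * np.abs(np.sin(np.radians(half - np.abs(ang))))
        leaflet |= slab & in_sector & (d_edge >= g)
    labels[leaflet] = LABEL_LEAFLET

    # BAV1 raphe: thin ridge along the conjoined (anterior) cusp midline
    if spec.raphe:
        raphe_angle = BAV_CUSP_ANGLES["anterior"]
        ang = (theta - raphe_angle + 180.0) % 360.0 - 180.0
        ridge = (
            (np.abs(ang) <= 90.0)
            & (r * np.abs(np.sin(np.radians(ang))) <= 1.5)
            & (r >= 0.25 * R)
            & (r <= 0.95 * R)
            & (Z >= sheet_lo)
            & (Z < sheet_lo + t + 4.0)
        )
        labels[ridge] = LABEL_LEAFLET

    # calcification specks on the leaflet top surface, non-overlapping
    rng = np.random.default_rng(spec.seed)
    if spec.n_calcifications > 0:
        rc = spec.calcification_radius_mm
        leaf_idx = np.argwhere(labels == LABEL_LEAFLET)
        top_z = sheet_lo + t
        placed: list[np.ndarray] = []
        attempts = 0
        while len(placed) < spec.n_calcifications and attempts < 2000 and len(leaf_idx):
            attempts += 1
            i = int(rng.integers(len(leaf_idx)))
            pos = leaf_idx[i] * spacing
            center = np.array([pos[0], pos[1], top_z + 1.0])
            if all(np.linalg.norm(center - p) >= 2 * rc + 2.0 for p in placed):
                placed.append(center)
        for center in placed:
            speck = (X - center[0]) ** 2 + (Y - center[1]) ** 2 + (Z - center[2]) ** 2 <= rc * rc
            labels[speck] = LABEL_CALCIFICATION

    image = np.full(shape, HU_BACKGROUND, dtype=np.float32)
    image[(labels == LABEL_AA) | (labels == LABEL_LV)] = HU_BLOOD
    image[labels == LABEL_LEAFLET] = HU_LEAFLET
    image[labels == LABEL_CALCIFICATION] = HU_CALCIFICATION

    img_vol = ImageVolume(image, tuple(spacing), (0.0, 0.0, 0.0))
    if spec.noise_sigma > 0:
        img_vol = degrade_image(img_vol, spec.noise_sigma, 0.0, seed=spec.seed)
    lab_vol = LabelVolume(labels, tuple(spacing), (0.0, 0.0, 0.0))
    return img_vol, lab_vol


def _artifact_field(shape, spacing, strength, rng, scale):
    """Additive low-frequency bias + a few Gaussian streak planes.

    ``scale`` converts the dimensionless strength to intensity units
    (1200 for HU images, 1 for normalized images).
    """
    X, Y, Z = _world_grids(shape, spacing)
    extent = (np.asarray(shape) - 1) * np.asarray(spacing)
    field = np.zeros(shape, dtype=np.float64)
    # smooth bias: three random 3-D sinusoids, <= 2 cycles per volume
    for _ in range(3):
        freq = rng.uniform(0.5, 2.0, size=3) / np.maximum(extent, 1e-9)
        phase = rng.uniform(0, 2 * np.pi)
        amp = strength * scale * 0.05
        field += amp * np.sin(2 * np.pi * (freq[0] * X + freq[1] * Y + freq[2] * Z) + phase)
    # streaks: bright/dark Gaussian slabs along random orientations
    for _ in range(3):
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        offset = rng.uniform(0, np.linalg.norm(extent))
        width = rng.uniform(1.0, 3.0)
        sign = rng.choice([-1.0, 1.0])
        proj = u[0] * X + u[1] * Y + u[2] * Z
        field += sign * strength * scale * 0.1 * np.exp(-0.5 * ((proj - offset) / width) ** 2)
    return field


def degrade_image(
    image: ImageVolume,
    noise_sigma: float,
    artifact_strength: float = 0.0,
    *,
    seed: int = 0,
) -> ImageVolume:
    """Add seeded Gaussian noise and optional low-frequency artifacts.

    ``noise_sigma`` is expressed on the normalized [0, 1] intensity scale
    and rescaled by the 1200-HU clipping window, so sigma=0.05 means a
    60-HU noise floor.  Geometry is unchanged; sigma = strength = 0
    returns an exact copy.
    """
    if noise_sigma < 0:
        raise ValidationError(f"noise_sigma must be >= 0, got {noise_sigma}")
    if artifact_strength < 0:
        raise ValidationError(f"artifact_strength must be >= 0, got {artifact_strength}")
    data = image.data.astype(np.float32, copy=True)
    rng = np.random.default_rng(seed)
    if noise_sigma > 0:
        data = data + rng.standard_normal(data.shape).astype(np.float32) * (
            noise_sigma * HU_SCALE
        )
    if artifact_strength > 0:
        data = data + _artifact_field(
            data.shape, image.spacing, artifact_strength, rng, HU_SCALE
        ).astype(np.float32)
    return ImageVolume(data, image.spacing, image.origin, image.orientation)


def generate_cohort(
    n_per_class: int,
    base_spec: PhantomSpec | None = None,
    seed: int = 0,
) -> list[tuple[ImageVolume, LabelVolume, PhantomSpec]]:
    """Generate a balanced cohort: ``n_per_class`` cases of each valve type.

    Each case gets a distinct derived seed and geometric parameters
    jittered by +-10% of the base lengths, all drawn from one seeded
    stream so the cohort is reproducible end to end.
    """
    if n_per_class < 1:
        raise ValidationError(f"n_per_class must be >= 1, got {n_per_class}")
    if base_spec is None:
        base_spec = PhantomSpec()
    rng = np.random.default_rng(seed)
    cases = []
    for valve_type in VALVE_TYPES:
        for _ in range(n_per_class):
            case_seed = int(rng.integers(0, 2**31 - 1))
            jitter = {
                name: float(getattr(base_spec, name) * rng.uniform(0.9, 1.1))
                for name in (
                    "annulus_radius_mm",
                    "aorta_length_mm",
                    "leaflet_thickness_mm",
                    "calcification_radius_mm",
                )
            }
            spec = dataclasses.replace(
                base_spec, valve_type=valve_type, raphe=None, seed=case_seed, **jitter
            )
            img, lab = generate_phantom(spec)
            cases.append((img, lab, spec))
    return cases


def cohort_manifest(cases) -> "list[dict]":
    """Flat per-case records (for a CSV manifest) from generate_cohort output."""
    rows = []
    for i, (_, _, spec) in enumerate(cases):
        row = {"case_id": f"case_{i:04d}", "valve_type": spec.valve_type}
        row.update({f.name: getattr(spec, f.name) for f in dataclasses.fields(spec)
                    if f.name != "valve_type"})
        rows.append(row)
    return rows
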