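"""Cuspid-number determination and leaflet re-segmentation.

After a segmentation stage produces a leaflet mask, this module
(1) removes scattered pieces by largest-connected-component filtering,
(2) decides between two and three cusps by running seeded mini-batch
K-means on the leaflet voxels' world coordinates at k = 2 and k = 3 and
picking the k with the higher mean silhouette coefficient,
(3) sharpens the inter-leaflet boundary with a K-nearest-neighbour
majority vote, (4) names the leaflets from their angular positions
around the aortic long axis, and (5) classifies the valve as tricuspid
(TAV) or bicuspid Sievers type 0 / type 1, the latter via a raphe-ridge
detector, and summarizes cohort agreement in a confusion matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
from scipy import ndimage
from sklearn.cluster import MiniBatchKMeans
from sklearn.metrics import silhouette_score
from sklearn.neighbors import NearestNeighbors

from .errors import EmptyStructureError, GeometryError, ValidationError
from .volume import LABEL_AA, LABEL_LV, ImageVolume, LabelVolume

TAV_CANONICAL_ANGLES = {"non-coronary": 90.0, "left-coronary": 210.0, "right-coronary": 330.0}


@dataclass
class CuspidResult:
    """Outcome of cuspid-number determination for one case."""

    k: int
    assignment: np.ndarray  # cluster index per leaflet voxel (argwhere order)
    silhouette: float  # mean silhouette of the chosen k
    silhouettes: tuple[float, float]  # (k=2, k=3)
    leaflet_names: list[str] = field(default_factory=list)
    valve_class: str = ""
    raphe_detected: bool = False

    def __post_init__(self) -> None:
        if self.k not in (2, 3):
            raise ValidationError(f"k must be 2 or 3, got {self.k}")
        if self.valve_class:
            if (self.k == 3) != (self.valve_class == "TAV"):
                raise ValidationError(
                    f"k={self.k} inconsistent with valve_class={self.valve_class}"
                )
            if self.raphe_detected != (self.valve_class == "BAV1"):
                raise ValidationError(
                    f"raphe_detected={self.raphe_detected} inconsistent with "
                    f"valve_class={self.valve_class}"
                )
        a = np.asarray(self.assignment)
        if a.size and (a.min() < 0 or a.max() >= self.k):
            raise ValidationError("assignment contains cluster indices outside [0, k)")


@dataclass
class ConfusionMatrix:
    classes: tuple[str, ...]
    counts: np.ndarray  # rows = expert label, columns = predicted

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts)) / self.total

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "counts": self.counts.tolist(),
            "accuracy": self.accuracy,
        }


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    raise ValidationError(f"connectivity must be 6 or 26, got {connectivity}")


def keep_largest_component(mask: np.ndarray, connectivity: int = 26) -> np.ndarray:
    """Keep only the maximum-cardinality connected component.

    Ties are broken toward the component containing the lexicographically
    smallest voxel index (row-major order).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyStructureError("empty structure: mask has no foreground voxels")
    lab, n = ndimage.label(mask, structure=_structure(connectivity))
    if n == 1:
        return mask.copy()
    counts = np.bincount(lab.ravel())[1:]  # skip background
    best = counts.max()
    tied = np.flatnonzero(counts == best) + 1
    if len(tied) == 1:
        keep = tied[0]
    else:
        flat = lab.ravel()
        first = {int(l): np.argmax(flat == l) for l in tied}
        keep = min(first, key=first.get)
    return lab == keep


def remove_small_components(
    mask: np.ndarray, min_voxels: int, connectivity: int = 26
) -> np.ndarray:
    """Drop connected components below a voxel-count threshold.

    Used for multi-component structures (leaflets, calcification) where
    keeping only the largest piece would destroy real anatomy.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return mask.copy()
    lab, n = ndimage.label(mask, structure=_structure(connectivity))
    counts = np.bincount(lab.ravel())
    keep = counts >= min_voxels
    keep[0] = False
    return keep[lab]


def determine_cuspid_number(
    leaflet_mask: np.ndarray,
    spacing_mm,
    seed: int = 0,
    *,
    min_voxels: int = 200,
    tie_tol: float = 0.02,
    batch_size: int = 1024,
    n_init: int = 10,
):
    """Choose between 2 and 3 cusps by silhouette comparison.

    Mini-batch K-means is run on the leaflet voxels' world coordinates
    (mm) at k = 2 and k = 3; the k with the higher mean silhouette
    coefficient wins, with near-ties (|difference| < ``tie_tol``)
    resolved toward k = 3, the prevalent tricuspid morphology.

    Returns ``(k, assignment, (silhouette_k2, silhouette_k3))`` where the
    assignment indexes leaflet voxels in ``np.argwhere`` order.
    """
    mask = np.asarray(leaflet_mask, dtype=bool)
    idx = np.argwhere(mask)
    if len(idx) < min_voxels:
        raise ValidationError(
            f"insufficient leaflet volume: {len(idx)} voxels < minimum {min_voxels}"
        )
    coords = idx * np.asarray(spacing_mm, dtype=np.float64)
    results = {}
    sils = {}
    rng = np.random.default_rng(seed)
    if len(coords) > 4000:
        sub = rng.choice(len(coords), 4000, replace=False)
    else:
        sub = slice(None)
    for k in (2, 3):
        km = MiniBatchKMeans(
            n_clusters=k,
            random_state=seed + k,
            n_init=n_init,
            batch_size=batch_size,
            max_iter=300,
        ).fit(coords)
        labels = km.labels_.astype(np.int32)
        results[k] = labels
        sils[k] = float(silhouette_score(coords[sub], labels[sub]))
    k = 3 if sils[3] > sils[2] - tie_tol else 2
    return k, results[k], (sils[2], sils[3])


def _neighbor_offsets_26():
    offs = [
        (i, j, k)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0)
    ]
    return offs


def refine_leaflet_boundary(
    leaflet_mask: np.ndarray,
    initial_assignment: np.ndarray,
    n_neighbors: int = 15,
    spacing_mm=(1.0, 1.0, 1.0),
) -> np.ndarray:
    """KNN majority-vote relabelling of the inter-leaflet boundary band.

    The band consists of mask voxels with at least one 26-neighbour in a
    different cluster, dilated by one voxel (within the mask).  Band
    voxels are re-labelled by the majority of their ``n_neighbors``
    nearest leaflet voxels *outside* the band, measured in world
    coordinates; tied votes go to the lower cluster index.  Interior
    voxels are untouched, so the voxel set is preserved exactly.
    """
    if n_neighbors % 2 == 0:
        raise ValidationError(f"n_neighbors must be odd, got {n_neighbors}")
    mask = np.asarray(leaflet_mask, dtype=bool)
    idx = np.argwhere(mask)
    assignment = np.asarray(initial_assignment, dtype=np.int32)
    if len(assignment) != len(idx):
        raise ValidationError(
            f"assignment length {len(assignment)} != leaflet voxel count {len(idx)}"
        )
    # paint assignment into a volume for neighbourhood comparisons
    vol = np.full(mask.shape, -1, dtype=np.int32)
    vol[tuple(idx.T)] = assignment

    disagree = np.zeros(mask.shape, dtype=bool)
    padded = np.pad(vol, 1, constant_values=-1)
    core = padded[1:-1, 1:-1, 1:-1]
    for di, dj, dk in _neighbor_offsets_26():
        nb = padded[1 + di : 1 + di + mask.shape[0],
                    1 + dj : 1 + dj + mask.shape[1],
                    1 + dk : 1 + dk + mask.shape[2]]
        disagree |= mask & (nb >= 0) & (nb != core)
    band = ndimage.binary_dilation(
        disagree, structure=ndimage.generate_binary_structure(3, 3)
    ) & mask
    if not band.any():
        return assignment.copy()
    band_flat = band[tuple(idx.T)]
    ref_flat = ~band_flat
    n_ref = int(ref_flat.sum())
    if n_ref < n_neighbors:
        raise ValidationError(
            f"n_neighbors={n_neighbors} exceeds available reference voxels ({n_ref})"
        )
    spacing = np.asarray(spacing_mm, dtype=np.float64)
    coords = idx * spacing
    nn = NearestNeighbors(n_neighbors=n_neighbors).fit(coords[ref_flat])
    _, nbr = nn.kneighbors(coords[band_flat])
    ref_labels = assignment[ref_flat]
    votes = ref_labels[nbr]  # (n_band, n_neighbors)
    k = int(assignment.max()) + 1
    tallies = np.zeros((votes.shape[0], k), dtype=np.int64)
    for c in range(k):
        tallies[:, c] = (votes == c).sum(axis=1)
    new_labels = tallies.argmax(axis=1).astype(np.int32)  # argmax -> lowest index on ties
    out = assignment.copy()
    out[band_flat] = new_labels
    return out


def _long_axis_frame(labels: LabelVolume):
    """Unit long axis (LV -> AA) and in-plane basis (e1, e2) in world mm."""
    spacing = np.asarray(labels.spacing)
    aa = np.argwhere(labels.data == LABEL_AA)
    lv = np.argwhere(labels.data == LABEL_LV)
    if not len(aa) or not len(lv):
        raise GeometryError("degenerate geometry: AA or LV structure missing")
    axis = (aa.mean(axis=0) - lv.mean(axis=0)) * spacing
    norm = np.linalg.norm(axis)
    if norm < 1e-6:
        raise GeometryError("degenerate geometry: AA and LV centroids coincide")
    n = axis / norm
    e1 = np.array([1.0, 0.0, 0.0])
    e1 = e1 - (e1 @ n) * n
    if np.linalg.norm(e1) < 1e-6:
        e1 = np.array([0.0, 1.0, 0.0])
        e1 = e1 - (e1 @ n) * n
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    return n, e1, e2


def _circular_distance(a: float, b: float) -> float:
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def name_leaflets(
    assignment: np.ndarray, leaflet_mask: np.ndarray, labels: LabelVolume
) -> list[str]:
    """Name cusps from their angular position about the aortic long axis.

    The long axis runs from the LV centroid to the AA centroid; cluster
    centroids are projected onto the orthogonal (annular) plane.  For
    three cusps, names {non-coronary, left-coronary, right-coronary} are
    assigned as the permutation minimizing total circular distance to
    the canonical angles (90/210/330 deg from +x), which makes the
    naming stable under moderate (well beyond +-30 deg) rotations of the
    whole case.  For two cusps, the cusp whose centroid lies further
    along the anteroposterior (+y) axis is "anterior", the other
    "posterior".  Returns one name per cluster index.
    """
    mask = np.asarray(leaflet_mask, dtype=bool)
    idx = np.argwhere(mask)
    assignment = np.asarray(assignment)
    if len(assignment) != len(idx):
        raise ValidationError("assignment does not cover the leaflet voxel set")
    k = int(assignment.max()) + 1
    if k not in (2, 3):
        raise ValidationError(f"k must be 2 or 3, got {k}")
    n, e1, e2 = _long_axis_frame(labels)
    spacing = np.asarray(labels.spacing)
    coords = idx * spacing
    center = coords.mean(axis=0)
    centroids = np.stack([coords[assignment == c].mean(axis=0) for c in range(k)])
    rel = centroids - center
    if k == 2:
        names = ["", ""]
        anterior = int(np.argmax(rel @ e2))
        names[anterior] = "anterior"
        names[1 - anterior] = "posterior"
        return names
    angles = np.degrees(np.arctan2(rel @ e2, rel @ e1)) % 360.0
    best_perm, best_cost = None, np.inf
    for perm in permutations(TAV_CANONICAL_ANGLES):
        cost = sum(
            _circular_distance(angles[c], TAV_CANONICAL_ANGLES[name])
            for c, name in enumerate(perm)
        )
        if cost < best_cost:
            best_perm, best_cost = perm, cost
    return list(best_perm)


def detect_raphe(
    leaflet_mask: np.ndarray,
    spacing_mm,
    *,
    min_ridge_voxels: int = 15,
    min_radial_span_frac: float = 0.3,
    height_threshold_mm: float = 1.6,
) -> bool:
    """Detect a raphe ridge protruding from the leaflet sheet plane.

    Fits the sheet plane by PCA of the leaflet voxels' world coordinates
    (normal = least-variance direction) and flags voxels whose offset
    from the median plane exceeds a robust thickness threshold.  A raphe
    is declared when the largest connected clump of such voxels is big
    enough and spans a sufficient radial range (free-edge region out
    toward the wall).
    """
    mask = np.asarray(leaflet_mask, dtype=bool)
    idx = np.argwhere(mask)
    if len(idx) < 10:
        return False
    spacing = np.asarray(spacing_mm, dtype=np.float64)
    coords = idx * spacing
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    normal = vt[-1]
    d = centered @ normal
    med = np.median(d)
    q25, q75 = np.percentile(d, [25, 75])
    thr = max(height_threshold_mm, 1.3 * (q75 - q25))
    pos = d - med > thr
    neg = med - d > thr
    cand = pos if pos.sum() >= neg.sum() else neg
    if cand.sum() < min_ridge_voxels:
        return False
    cand_vol = np.zeros(mask.shape, dtype=bool)
    cand_vol[tuple(idx[cand].T)] = True
    lab, n = ndimage.label(cand_vol, structure=ndimage.generate_binary_structure(3, 3))
    if n == 0:
        return False
    counts = np.bincount(lab.ravel())[1:]
    biggest = int(counts.argmax()) + 1
    if counts.max() < min_ridge_voxels:
        return False
    ridge_idx = np.argwhere(lab == biggest)
    ridge_coords = ridge_idx * spacing - coords.mean(axis=0)
    inplane = centered - np.outer(d, normal)
    r_all = np.linalg.norm(inplane, axis=1)
    ridge_d = ridge_coords @ normal
    ridge_inplane = ridge_coords - np.outer(ridge_d, normal)
    r_ridge = np.linalg.norm(ridge_inplane, axis=1)
    r95 = np.percentile(r_all, 95)
    span = r_ridge.max() - r_ridge.min()
    return bool(span >= min_radial_span_frac * r95)


def classify_valve(
    k: int,
    leaflet_mask: np.ndarray,
    image: ImageVolume,
    assignment: np.ndarray | None = None,
) -> tuple[str, bool]:
    """Map the cusp count to the Sievers valve class.

    k = 3 is tricuspid by definition.  k = 2 is bicuspid, subtyped by the
    raphe detector: a ridge of leaflet voxels protruding from the sheet
    plane marks type 1 (one raphe), otherwise type 0.
    """
    if k == 3:
        return "TAV", False
    if k != 2:
        raise ValidationError(f"k must be 2 or 3, got {k}")
    raphe = detect_raphe(leaflet_mask, image.spacing)
    return ("BAV1", True) if raphe else ("BAV0", False)


def confusion_and_accuracy(
    predicted, expert, classes: tuple[str, ...] = ("TAV", "BAV0", "BAV1")
) -> ConfusionMatrix:
    """Confusion matrix (rows = expert, columns = predicted) and accuracy."""
    predicted = list(predicted)
    expert = list(expert)
    if not predicted or not expert:
        raise ValidationError("class lists must be non-empty")
    if len(predicted) != len(expert):
        raise ValidationError(
            f"length mismatch: {len(predicted)} predicted vs {len(expert)} expert"
        )
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for p, e in zip(predicted, expert):
        if p not in index or e not in index:
            raise ValidationError(f"unknown class in inputs: {p!r} / {e!r}")
        counts[index[e], index[p]] += 1
    return ConfusionMatrix(tuple(classes), counts)
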