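"""Independent brute-force oracles used to cross-check the implementation.

Deliberately naive (flood fill, all-pairs distances, exhaustive
formulas) and kept free of any code path they validate.
"""

from collections import deque

import numpy as np
from scipy.spatial.distance import cdist


def flood_fill_components(mask: np.ndarray, connectivity: int = 26):
    """Label connected components by explicit BFS flood fill."""
    mask = np.asarray(mask, dtype=bool)
    if connectivity == 6:
        offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    else:
        offsets = [
            (i, j, k)
            for i in (-1, 0, 1)
            for j in (-1, 0, 1)
            for k in (-1, 0, 1)
            if (i, j, k) != (0, 0, 0)
        ]
    labels = np.zeros(mask.shape, dtype=np.int32)
    current = 0
    for start in map(tuple, np.argwhere(mask)):
        if labels[start]:
            continue
        current += 1
        queue = deque([start])
        labels[start] = current
        while queue:
            x, y, z = queue.popleft()
            for dx, dy, dz in offsets:
                nb = (x + dx, y + dy, z + dz)
                if all(0 <= c < s for c, s in zip(nb, mask.shape)) and mask[nb] and not labels[nb]:
                    labels[nb] = current
                    queue.append(nb)
    return labels, current


def surface_voxels(mask: np.ndarray) -> np.ndarray:
    """6-neighbourhood surface voxels by direct per-voxel inspection."""
    mask = np.asarray(mask, dtype=bool)
    out = np.zeros_like(mask)
    for idx in map(tuple, np.argwhere(mask)):
        for axis in range(3):
            for step in (-1, 1):
                nb = list(idx)
                nb[axis] += step
                if not (0 <= nb[axis] < mask.shape[axis]) or not mask[tuple(nb)]:
                    out[idx] = True
    return out


def pooled_surface_distances(pred, gt, spacing):
    """All-pairs O(n^2) symmetric surface-distance set in mm."""
    spacing = np.asarray(spacing, dtype=np.float64)
    ps = np.argwhere(surface_voxels(pred)) * spacing
    gs = np.argwhere(surface_voxels(gt)) * spacing
    dmat = cdist(ps, gs)
    return np.concatenate([dmat.min(axis=1), dmat.min(axis=0)])


def mean_silhouette(points: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette coefficient from the textbook pairwise formula."""
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    dmat = cdist(points, points)
    values = []
    for i in range(len(points)):
        same = (labels == labels[i]) & (np.arange(len(points)) != i)
        if not same.any():
            values.append(0.0)
            continue
        a = dmat[i, same].mean()
        b = min(
            dmat[i, labels == other].mean()
            for other in np.unique(labels)
            if other != labels[i]
        )
        values.append((b - a) / max(a, b))
    return float(np.mean(values))


def nearest_resample(data: np.ndarray, source_spacing, target: float) -> np.ndarray:
    """Brute-force nearest-neighbour resample under the voxel-centre
    convention (voxel i at i * spacing; nearest = floor(x + 0.5))."""
    shape = data.shape
    spacing = np.asarray(source_spacing, dtype=float)
    out_shape = tuple(max(1, int(round(n * s / target))) for n, s in zip(shape, spacing))
    out = np.zeros(out_shape, dtype=data.dtype)
    for i in range(out_shape[0]):
        for j in range(out_shape[1]):
            for k in range(out_shape[2]):
                src = [
                    min(shape[ax] - 1, max(0, int(np.floor(idx * target / spacing[ax] + 0.5))))
                    for ax, idx in enumerate((i, j, k))
                ]
                out[i, j, k] = data[tuple(src)]
    return out
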