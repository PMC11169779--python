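"""Segmentation-quality metrics and the composite Dice + focal loss.

Overlap metrics (Dice, precision, recall) are direct voxel counts.
Surface-distance metrics (HD95, ASSD) use the standard convention:
surface voxels are mask voxels with at least one face-adjacent
(6-neighbourhood) voxel outside the mask (the grid edge counts as
outside), distances are voxel-centre to voxel-centre in mm, and the two
directed distance sets are pooled before taking the percentile / mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import EmptyStructureError, ValidationError
from .volume import STRUCTURE_LABELS, LabelVolume, check_congruent


@dataclass
class StructureMetrics:
    dsc: float
    precision: float
    recall: float
    hd95_mm: float
    assd_mm: float
    flags: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return {
            "dsc": self.dsc,
            "precision": self.precision,
            "recall": self.recall,
            "hd95_mm": self.hd95_mm,
            "assd_mm": self.assd_mm,
        }


@dataclass
class CaseReport:
    """Per-structure metric bundle for one case; None marks an absent structure."""

    case_id: str
    structures: dict[str, StructureMetrics | None]
    provenance: dict = field(default_factory=dict)


def overlap_metrics(pred: np.ndarray, gt: np.ndarray) -> tuple[float, float, float]:
    """(dsc, precision, recall) by direct voxel counting.

    Conventions for degenerate inputs (with a warning): both masks empty
    -> dsc 1.0 and both ratios 1.0; exactly one empty -> the undefined
    ratio(s) and dsc reported as 0.0.
    """
    pred = np.asarray(pred, dtype=bool)
    gt = np.asarray(gt, dtype=bool)
    if pred.shape != gt.shape:
        raise ValidationError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    np_, ng = int(pred.sum()), int(gt.sum())
    if np_ == 0 and ng == 0:
        warnings.warn("both masks empty; dsc defined as 1.0", stacklevel=2)
        return 1.0, 1.0, 1.0
    inter = int((pred & gt).sum())
    dsc = 2.0 * inter / (np_ + ng)
    if np_ == 0 or ng == 0:
        warnings.warn("one mask empty; undefined ratio reported as 0.0", stacklevel=2)
    precision = inter / np_ if np_ else 0.0
    recall = inter / ng if ng else 0.0
    return dsc, precision, recall


def surface_extract(mask: np.ndarray) -> np.ndarray:
    """Boolean grid of surface voxels (6-neighbourhood convention).

    A voxel is surface if any of its 6 face neighbours is outside the
    mask; voxels on the grid boundary count as surface.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyStructureError("cannot extract surface of an empty mask")
    eroded = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(3, 1), border_value=0
    )
    return mask & ~eroded


def _pooled_surface_distances(pred: np.ndarray, gt: np.ndarray, spacing_mm) -> np.ndarray:
    spacing = np.asarray(spacing_mm, dtype=np.float64)
    ps = np.argwhere(surface_extract(pred)) * spacing
    gs = np.argwhere(surface_extract(gt)) * spacing
    d_pg, _ = cKDTree(gs).query(ps)
    d_gp, _ = cKDTree(ps).query(gs)
    return np.concatenate([d_pg, d_gp])


def hd95(pred: np.ndarray, gt: np.ndarray, spacing_mm, percentile: float = 95.0) -> float:
    """Percentile (default 95th) of pooled symmetric surface distances, mm.

    ``percentile=100`` gives the exact (maximum) Hausdorff distance.
    """
    return float(np.percentile(_pooled_surface_distances(pred, gt, spacing_mm), percentile))


def assd(pred: np.ndarray, gt: np.ndarray, spacing_mm) -> float:
    """Average symmetric surface distance in mm (pooled both directions)."""
    return float(_pooled_surface_distances(pred, gt, spacing_mm).mean())


def evaluate_case(
    pred: LabelVolume,
    gt: LabelVolume,
    case_id: str = "case",
    provenance: dict | None = None,
    hd_percentile: float = 95.0,
) -> CaseReport:
    """Per-structure metrics via one-vs-rest binarization of both volumes.

    A structure absent from *both* volumes is recorded as None rather
    than silently zeroed; a structure present in only one gets overlap
    metrics under the empty-mask conventions and NaN distances with an
    explanatory flag.
    """
    check_congruent(pred, gt, names=("pred", "gt"))
    structures: dict[str, StructureMetrics | None] = {}
    for name, label in STRUCTURE_LABELS.items():
        p = pred.data == label
        g = gt.data == label
        if not p.any() and not g.any():
            structures[name] = None
            continue
        flags: list[str] = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dsc, precision, recall = overlap_metrics(p, g)
        if p.any() and g.any():
            h = hd95(p, g, pred.spacing, percentile=hd_percentile)
            a = assd(p, g, pred.spacing)
        else:
            flags.append("one mask empty; distances undefined")
            h = a = float("nan")
        structures[name] = StructureMetrics(dsc, precision, recall, h, a, tuple(flags))
    return CaseReport(case_id, structures, provenance or {})


def dice_focal_loss(
    prob: np.ndarray,
    gt_onehot: np.ndarray,
    lambda_mix: float = 0.5,
    gamma: float = 2.0,
    alpha: float = 0.25,
) -> float:
    """Composite segmentation loss: lambda*(1 - soft Dice) + (1-lambda)*focal.

    ``prob`` and ``gt_onehot`` are channels-first ``(C, ...)`` arrays;
    probabilities must lie in [0, 1] and sum to 1 per voxel.  The focal
    term is the focal cross-entropy ``-alpha * (1 - p_t)^gamma * log(p_t)``
    averaged over voxels, with p_t clamped to [1e-7, 1 - 1e-7]; the Dice
    term is one minus the class-averaged soft Dice.  Large structures are
    well supervised by the Dice term while the focal term keeps gradients
    smooth for small ones.
    """
    prob = np.asarray(prob, dtype=np.float64)
    gt = np.asarray(gt_onehot, dtype=np.float64)
    if prob.shape != gt.shape:
        raise ValidationError(f"shape mismatch: {prob.shape} vs {gt.shape}")
    if prob.min() < -1e-9 or prob.max() > 1 + 1e-9:
        raise ValidationError("probabilities must lie in [0, 1]")
    sums = prob.sum(axis=0)
    if not np.allclose(sums, 1.0, atol=1e-5):
        raise ValidationError("probabilities must sum to 1 per voxel")
    if not 0.0 <= lambda_mix <= 1.0:
        raise ValidationError(f"lambda_mix must be in [0, 1], got {lambda_mix}")

    axes = tuple(range(1, prob.ndim))
    num = 2.0 * (prob * gt).sum(axis=axes)
    den = prob.sum(axis=axes) + gt.sum(axis=axes)
    dice_per_class = np.where(den > 0, num / np.maximum(den, 1e-12), 1.0)
    dice_term = 1.0 - float(dice_per_class.mean())

    p_t = np.clip((prob * gt).sum(axis=0), 1e-7, 1.0 - 1e-7)
    focal_term = float((-alpha * (1.0 - p_t) ** gamma * np.log(p_t)).mean())

    return lambda_mix * dice_term + (1.0 - lambda_mix) * focal_term
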