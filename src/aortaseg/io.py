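"""NIfTI volume I/O and report serialization."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import ValidationError
from .leaflet_analysis import ConfusionMatrix
from .metrics import CaseReport
from .volume import LABEL_VOCABULARY, ImageVolume, LabelVolume


def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    aff[:3, 3] = origin
    return aff


def write_volume(volume, path) -> None:
    """Write an Image/LabelVolume as NIfTI with a diagonal affine."""
    path = Path(path)
    if isinstance(volume, LabelVolume):
        data = volume.data.astype(np.uint8)
    else:
        data = volume.data.astype(np.float32)
    img = nib.Nifti1Image(data, _affine(volume.spacing, volume.origin))
    nib.save(img, str(path))


def read_volume(path, kind: str = "auto"):
    """Load a NIfTI file as an ImageVolume or LabelVolume.

    ``kind`` is "image", "labels", or "auto" (labels when the data is
    integral and within the label vocabulary).  Label files containing
    values outside the vocabulary raise a validation error.
    """
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    aff = img.affine
    spacing = tuple(float(s) for s in nib.affines.voxel_sizes(aff))
    origin = tuple(float(x) for x in aff[:3, 3])
    orientation = "".join(nib.aff2axcodes(aff))
    integral = np.issubdtype(data.dtype, np.integer) or np.allclose(data, np.round(data))
    if kind == "auto":
        if integral and set(np.unique(data).astype(int).tolist()) <= set(LABEL_VOCABULARY):
            kind = "labels"
        else:
            kind = "image"
    if kind == "labels":
        if not integral:
            raise ValidationError(f"{path.name}: label file contains non-integer values")
        return LabelVolume(data.astype(np.uint8), spacing, origin, orientation)
    if kind == "image":
        return ImageVolume(data.astype(np.float32), spacing, origin, orientation)
    raise ValidationError(f"kind must be 'image', 'labels' or 'auto', got {kind!r}")


_METRIC_ORDER = ("dsc", "precision", "recall", "hd95_mm", "assd_mm")


def reports_to_frame(reports: "list[CaseReport]") -> pd.DataFrame:
    """One row per case x structure x metric, in stable order."""
    rows = []
    for rep in reports:
        for structure, sm in rep.structures.items():
            if sm is None:
                rows.append(
                    {"case_id": rep.case_id, "structure": structure,
                     "metric": "absent", "value": np.nan}
                )
                continue
            for metric in _METRIC_ORDER:
                rows.append(
                    {"case_id": rep.case_id, "structure": structure,
                     "metric": metric, "value": getattr(sm, metric)}
                )
    return pd.DataFrame(rows, columns=["case_id", "structure", "metric", "value"])


def write_report(
    reports: "list[CaseReport]",
    out_dir,
    confusion: ConfusionMatrix | None = None,
    extra: dict | None = None,
) -> dict[str, Path]:
    """Emit the per-case CSV and cohort JSON summary.

    Floats are serialized at full precision (repr round-trip) so a
    re-serialization round trip preserves every numeric field exactly.
    """
    if not reports:
        raise ValidationError("write_report requires at least one report")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / "case_metrics.csv"
    frame = reports_to_frame(reports)
    frame.to_csv(csv_path, index=False, float_format="%.17g")
    summary: dict = {
        "n_cases": len(reports),
        "cases": [
            {"case_id": r.case_id, "provenance": r.provenance} for r in reports
        ],
    }
    if confusion is not None:
        summary["confusion_matrix"] = confusion.to_dict()
        summary["accuracy"] = confusion.accuracy
    if extra:
        summary.update(extra)
    json_path = out_dir / "cohort_summary.json"
    json_path.write_text(json.dumps(summary, indent=2, sort_keys=True))
    return {"csv": csv_path, "json": json_path}
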