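"""End-to-end orchestration: preprocess -> segment -> post-process ->
cuspid analysis -> metrics, with per-case failure isolation."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

from .errors import EmptyStructureError, ValidationError
from .leaflet_analysis import (
    ConfusionMatrix,
    CuspidResult,
    classify_valve,
    confusion_and_accuracy,
    determine_cuspid_number,
    keep_largest_component,
    name_leaflets,
    refine_leaflet_boundary,
    remove_small_components,
)
from .metrics import CaseReport, evaluate_case
from .preprocess import PreprocessConfig, clip_and_normalize
from .segmenter import get_segmenter
from .volume import (
    LABEL_AA,
    LABEL_CALCIFICATION,
    LABEL_LEAFLET,
    LABEL_LV,
    ImageVolume,
    LabelVolume,
)


@dataclass(frozen=True)
class LeafletParams:
    seed: int = 0
    n_neighbors: int = 15
    min_voxels: int = 200
    tie_tol: float = 0.02
    min_component_voxels: int = 30  # scattered-piece threshold for leaflets
    min_calc_voxels: int = 5  # calcium specks are legitimately tiny


@dataclass(frozen=True)
class MetricsParams:
    hd_percentile: float = 95.0


@dataclass(frozen=True)
class PipelineConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    leaflet: LeafletParams = field(default_factory=LeafletParams)
    metrics: MetricsParams = field(default_factory=MetricsParams)
    segmenter_name: str = "reference"
    segmenter_params: tuple = ()  # (key, value) pairs; kept hashable

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        sub = {}
        for name, sub_cls in (
            ("preprocess", PreprocessConfig),
            ("leaflet", LeafletParams),
            ("metrics", MetricsParams),
        ):
            if name in d:
                sd = dict(d.pop(name))
                sub_known = {f.name for f in dataclasses.fields(sub_cls)}
                sub_unknown = set(sd) - sub_known
                if sub_unknown:
                    raise ValidationError(
                        f"unknown config keys under {name!r}: {sorted(sub_unknown)}"
                    )
                sub[name] = sub_cls(**sd)
        if "segmenter_params" in d:
            d["segmenter_params"] = tuple(sorted(dict(d["segmenter_params"]).items()))
        return cls(**sub, **d)

    def to_dict(self) -> dict:
        return {
            "preprocess": dataclasses.asdict(self.preprocess),
            "leaflet": dataclasses.asdict(self.leaflet),
            "metrics": dataclasses.asdict(self.metrics),
            "segmenter_name": self.segmenter_name,
            "segmenter_params": dict(self.segmenter_params),
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class Case:
    case_id: str
    image: ImageVolume
    gt_labels: LabelVolume | None = None
    true_class: str | None = None


@dataclass
class CaseOutcome:
    case_id: str
    cuspid: CuspidResult | None = None
    report: CaseReport | None = None
    pred_labels: LabelVolume | None = None
    error: str | None = None


@dataclass
class PipelineResult:
    outcomes: list[CaseOutcome]
    confusion: ConfusionMatrix | None
    config_hash: str

    @property
    def reports(self) -> list[CaseReport]:
        return [o.report for o in self.outcomes if o.report is not None]

    @property
    def failures(self) -> dict[str, str]:
        return {o.case_id: o.error for o in self.outcomes if o.error}


def postprocess_labels(
    labels: LabelVolume, min_component_voxels: int = 30, min_calc_voxels: int = 5
) -> LabelVolume:
    """Scattered-piece removal after segmentation.

    The single-body structures (AA, LV) keep only their largest
    connected component; the genuinely multi-piece structures (leaflets,
    calcification) instead drop components below a small voxel-count
    threshold, since keeping one piece would delete real cusps or
    calcium specks.
    """
    out = labels.data.copy()
    for label in (LABEL_AA, LABEL_LV):
        mask = out == label
        if mask.any():
            keep = keep_largest_component(mask, connectivity=26)
            out[mask & ~keep] = 0
    for label, min_size in ((LABEL_LEAFLET, min_component_voxels),
                            (LABEL_CALCIFICATION, min_calc_voxels)):
        mask = out == label
        if mask.any():
            keep = remove_small_components(mask, min_size, connectivity=26)
            out[mask & ~keep] = 0
    return labels.with_data(out)


def analyze_leaflets(
    labels: LabelVolume,
    image: ImageVolume,
    params: LeafletParams,
) -> CuspidResult:
    """Cuspid count, KNN-refined assignment, names and valve class."""
    leaflet_mask = labels.data == LABEL_LEAFLET
    if not leaflet_mask.any():
        raise EmptyStructureError("empty structure: no leaflet voxels after postprocessing")
    k, assignment, sils = determine_cuspid_number(
        leaflet_mask,
        labels.spacing,
        seed=params.seed,
        min_voxels=params.min_voxels,
        tie_tol=params.tie_tol,
    )
    assignment = refine_leaflet_boundary(
        leaflet_mask, assignment, n_neighbors=params.n_neighbors, spacing_mm=labels.spacing
    )
    names = name_leaflets(assignment, leaflet_mask, labels)
    valve_class, raphe = classify_valve(k, leaflet_mask, image, assignment)
    return CuspidResult(
        k=k,
        assignment=assignment,
        silhouette=sils[k - 2],
        silhouettes=sils,
        leaflet_names=names,
        valve_class=valve_class,
        raphe_detected=raphe,
    )


def run_pipeline(config: PipelineConfig, cases: "list[Case]") -> PipelineResult:
    """Run every stage on each case; failures are recorded, not fatal.

    Per case: clip/normalize -> segment (plugin) -> scattered-piece
    removal -> cuspid-number determination -> KNN boundary refinement ->
    leaflet naming -> valve classification -> quality metrics against
    ground truth when supplied.  A cohort confusion matrix is emitted
    when expert valve classes are supplied.
    """
    if not cases:
        raise ValidationError("run_pipeline requires at least one case")
    segmenter = get_segmenter(config.segmenter_name, dict(config.segmenter_params))
    outcomes: list[CaseOutcome] = []
    predicted, expert = [], []
    for case in cases:
        outcome = CaseOutcome(case.case_id)
        try:
            norm = clip_and_normalize(
                case.image, config.preprocess.clip_low, config.preprocess.clip_high
            )
            seg = segmenter(norm)
            seg = postprocess_labels(
                seg, config.leaflet.min_component_voxels, config.leaflet.min_calc_voxels
            )
            outcome.pred_labels = seg
            cuspid = analyze_leaflets(seg, norm, config.leaflet)
            outcome.cuspid = cuspid
            provenance = {
                "segmenter": f"{segmenter.name}:{segmenter.version}",
                "config_hash": config.config_hash(),
                "seed": config.leaflet.seed,
                "valve_class": cuspid.valve_class,
                "k": cuspid.k,
                "silhouettes": list(cuspid.silhouettes),
                "leaflet_names": cuspid.leaflet_names,
            }
            if case.gt_labels is not None:
                outcome.report = evaluate_case(
                    seg,
                    case.gt_labels,
                    case_id=case.case_id,
                    provenance=provenance,
                    hd_percentile=config.metrics.hd_percentile,
                )
            else:
                outcome.report = CaseReport(case.case_id, {}, provenance)
            if case.true_class is not None:
                predicted.append(cuspid.valve_class)
                expert.append(case.true_class)
        except (ValidationError, EmptyStructureError) as exc:
            outcome.error = str(exc)
        outcomes.append(outcome)
    confusion = confusion_and_accuracy(predicted, expert) if predicted else None
    return PipelineResult(outcomes, confusion, config.config_hash())
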