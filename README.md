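# aortaseg

Post-processing and evaluation toolkit for aortic-root segmentation
from contrast CT angiography (CTA), aimed at TAVR (transcatheter aortic
valve replacement) planning pipelines.

A deep-learning network can label the four key aortic-root structures —
ascending aorta (AA), left ventricle (LV), valve leaflets, and
calcification — but turning that raw label map into a clinically
meaningful model still requires a post-processing stage: removing
scattered false-positive pieces, deciding whether the valve has two or
three cusps, splitting the single "leaflet" class into individually
named leaflets, classifying the valve as tricuspid (TAV) or bicuspid
(Sievers type 0 / type 1), and scoring segmentation quality.
`aortaseg` implements exactly that stage as a deterministic, fully
tested library, with the network itself abstracted behind a plugin
contract.

## What it computes

- **Cuspid-number determination** — seeded mini-batch K-means on the
  leaflet voxels' world coordinates at k = 2 and k = 3; the k with the
  higher mean silhouette coefficient s̄(k) wins (near-ties go to k = 3,
  the prevalent morphology).
- **Leaflet re-segmentation** — a K-nearest-neighbour majority vote
  re-labels the inter-leaflet boundary band, then leaflets are named
  (left-/right-/non-coronary, or anterior/posterior) from their angular
  position about the AA–LV axis.
- **Valve classification** — k = 3 ⇒ TAV; k = 2 ⇒ BAV, subtyped by a
  raphe-ridge detector (type 1 = one raphe, type 0 = none), with cohort
  agreement summarized in a confusion matrix.
- **Quality metrics** — Dice DSC = 2|P∩G|/(|P|+|G|), precision, recall,
  95th-percentile Hausdorff distance (HD95) and average symmetric
  surface distance (ASSD) in mm, plus the composite Dice + focal
  training loss as a standalone scalar.
- **Synthetic phantoms** — a seeded generator of CTA-like aortic-root
  volumes (tube + ventricle + k leaflet sheets + calcium specks, with
  optional raphe, noise and artifacts) providing exact ground truth for
  everything above.

See `docs/methods.md` for the model, conventions and parameter
rationale.

## Worked example

```python
from aortaseg import PhantomSpec, generate_phantom
from aortaseg.pipeline import Case, PipelineConfig, run_pipeline

spec = PhantomSpec(valve_type="BAV1", noise_sigma=0.02, seed=7)
image, labels = generate_phantom(spec)
result = run_pipeline(PipelineConfig(), [Case("demo", image, labels, spec.valve_type)])

out = result.outcomes[0]
c = out.cuspid
print(f"k = {c.k}  silhouettes (k=2, k=3) = ({c.silhouettes[0]:.3f}, {c.silhouettes[1]:.3f})")
print(f"valve class = {c.valve_class}  raphe detected = {c.raphe_detected}")
print(f"leaflet names = {c.leaflet_names}")
for name, sm in out.report.structures.items():
    print(f"{name:>13}: DSC {sm.dsc:.4f}  HD95 {sm.hd95_mm:.3f} mm  ASSD {sm.assd_mm:.3f} mm")
```

prints

```
k = 2  silhouettes (k=2, k=3) = (0.479, 0.441)
valve class = BAV1  raphe detected = True
leaflet names = ['anterior', 'posterior']
           AA: DSC 0.9981  HD95 0.000 mm  ASSD 0.016 mm
           LV: DSC 1.0000  HD95 0.000 mm  ASSD 0.000 mm
      leaflet: DSC 0.9218  HD95 1.000 mm  ASSD 0.080 mm
calcification: DSC 1.0000  HD95 0.000 mm  ASSD 0.000 mm
```

The mildly noisy type-1 bicuspid phantom is correctly recognized as a
two-cusp valve (silhouette 0.479 at k = 2 beats 0.441 at k = 3), the
raphe ridge is detected so the subtype is BAV1, and the segmentation
metrics show the expected pattern: near-perfect blood pool and calcium,
with the thin low-contrast leaflets the hardest structure.

## Command line

```bash
aortaseg phantom --n-per-class 5 --noise 0.02 --out cohort/ --seed 1
aortaseg run --in cohort/ --out reports/ --seed 0
aortaseg evaluate --pred preds/ --gt gts/ --out metrics.csv
aortaseg cusps --labels cohort/case_0000_lab.nii.gz
```

Volumes are NIfTI (`.nii/.nii.gz`); reports are a per-case CSV plus a
cohort JSON with the confusion matrix, accuracy, config hash and seeds.

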