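# Methods

`aortaseg` reimplements the post-deep-learning half of an aortic-root
CTA analysis pipeline as a testable, deterministic library.  The
deep-learning segmentation network itself is out of scope: it is
abstracted behind a plugin contract, and a deterministic
threshold-based reference segmenter stands in for it so that every
downstream stage — scattered-piece removal, cuspid-number
determination, KNN leaflet re-segmentation, leaflet naming, valve-type
classification and the segmentation-quality metric suite — can be
exercised end to end on synthetic phantoms with exact ground truth.

## The synthetic phantom

No public CTA data set with aortic-root labels in this vocabulary
exists, so the package ships a generator of idealized aortic-root
volumes.  Each phantom contains:

- an **ascending aorta**: a blood-filled cylinder (default annulus
  radius 12 mm, length 30 mm) along the grid's z axis;
- a **left ventricle**: an ellipsoid capping the tube from below,
  truncated at the annulus plane;
- **leaflets**: a flat sheet (default 2 mm thick) spanning the lumen
  just above the annulus plane, carved into k wedges (k = 3 for
  tricuspid, k = 2 for bicuspid morphologies) by slits of constant
  width at the commissure half-planes.  The constant-width slits (from
  the `cusp_gap_deg` parameter, default 16°, at least 2 voxels wide)
  guarantee the wedges are genuinely disconnected at every radius;
- for Sievers **type-1 bicuspid** valves, a **raphe**: a thin ridge of
  leaflet-labelled voxels rising 4 mm above the sheet along the
  conjoined (anterior) cusp's fusion line — the mark left by the fusion
  of two embryonic cusp positions;
- **calcification**: non-overlapping spherical specks (default four,
  radius 1.5 mm) seeded on the leaflet top surface.

Intensities use a fixed HU palette (blood 400, leaflets 150, calcium
1000, background −50) chosen to sit inside the standard contrast-CTA
clipping window [0, 1200] and to make the leaflets the
lowest-contrast class, which is also where real segmentation networks
struggle.  Optional degradation adds Gaussian noise (sigma expressed on
the normalized [0, 1] scale, i.e. sigma = 0.05 is a 60 HU noise floor)
and low-frequency bias/streak artifacts.  All randomness derives from
the spec seed; the generator is a pure function of its spec.

Defaults (64³ grid at 1 mm isotropic) keep a case small enough that
whole cohorts regenerate in seconds while leaving every structure
several voxels thick.  Cohorts are balanced across the three
morphologies with per-case seeds and ±10 % jitter on all lengths.

What the phantom does **not** emulate: sinuses of Valsalva, coronary
ostia, leaflet curvature and motion blur, partial-volume effects at
acquisition (they appear only after resampling/rotation), patient HU
variability, and anisotropic acquisition grids.  Tests passing on
phantoms therefore demonstrate the correctness of the *post-processing
logic* under controlled topology, not clinical-grade performance on
patient scans.

## Preprocessing

The preprocessing chain matches common volumetric-segmentation
practice: trilinear resampling of images to isotropic spacing (default
0.5 mm) with nearest-neighbour resampling of labels; intensity clipping
to [0, 1200] HU followed by min-max normalization to [0, 1]; cropping
to the body bounding box (threshold 0 HU, 2-voxel margin); cubic patch
extraction with zero padding.  Clipping is applied *before*
normalization: clipping normalized intensities against HU thresholds
would be dimensionally incoherent.

Grid convention: voxel `i` is centred at `origin + i * spacing`
(matching a diagonal NIfTI affine), so resampling maps output index `j`
to input index `j * target / source` with no half-voxel shift, and
nearest-neighbour lookup is `floor(x + 0.5)`.  Out-of-field values are
edge-clamped during resampling and filled with the background value
during rigid augmentation.

Augmentation applies the same rigid rotation (each axis within ±20°)
and isotropic zoom (0.85–1.15) to image (trilinear) and labels
(nearest), then noise/artifacts to the image only, all determined by
the parameter seed.  Out-of-range parameters are rejected rather than
clamped.

## Cuspid-number determination

Leaflet voxel coordinates (world mm) are clustered with seeded
mini-batch K-means (batch 1024, 10 restarts) at k = 2 and k = 3.  The k
with the higher mean silhouette coefficient is chosen; near-ties
(difference below 0.02) resolve toward k = 3, the prevalent tricuspid
morphology.  Silhouettes are computed on all points up to 4000, above
which a seeded subsample is used.  Masks below 200 voxels are rejected
as insufficient rather than clustered.

The chosen assignment is refined by a K-nearest-neighbour majority
vote: the boundary band (voxels with a 26-neighbour in another cluster,
dilated by one voxel) is re-labelled by the majority of each voxel's 15
nearest leaflet voxels *outside* the band; ties go to the lower cluster
index.  The voxel set itself is never changed, only its partition, and
a second pass changes fewer than 1 % of voxels on phantoms.

## Leaflet naming

The aortic long axis is estimated from the AA and LV centroids; cluster
centroids are projected onto the orthogonal annular plane.  Three cusps
are named {left-coronary, right-coronary, non-coronary} by the
permutation minimizing total circular distance to canonical angles
(90°/210°/330° from +x in the annular plane), which keeps names stable
under whole-case rotations well beyond ±30°.  Two cusps are named
{anterior, posterior} by their position along the anteroposterior (+y)
axis.  True coronary-ostium-based naming would require ostium labels,
which the vocabulary does not contain; the angular convention is a
documented stand-in.

## Valve classification and the raphe detector

k = 3 is tricuspid by definition.  k = 2 is bicuspid and subtyped by a
raphe detector: the leaflet sheet plane is fitted by PCA (normal =
least-variance direction) and voxels whose offset from the median plane
exceeds a robust thickness threshold (max of 1.6 mm and 1.3× the
interquartile spread) are ridge candidates.  A raphe is declared when
the largest 26-connected clump of candidates has ≥ 15 voxels and spans
at least 30 % of the leaflet radial extent — a ridge running from the
free-edge region toward the wall.  The detector is this package's own
construction (validated by phantom recovery); under noise and rotation
its failure mode is missing a thinned ridge, which misclassifies type-1
as type-0 bicuspid — the clinically observed confusion direction.

## Metrics

- **DSC / precision / recall** by direct voxel counting; if both masks
  are empty DSC is defined as 1.0 (with a warning), if exactly one is
  empty the undefined ratios are reported as 0.0, so that batch
  evaluation is total.
- **HD95 / ASSD**: surfaces are mask voxels with a 6-neighbour outside
  the mask (grid edge counts as outside); nearest-surface distances are
  computed voxel-centre to voxel-centre via KD-trees and pooled over
  both directions before taking the 95th percentile (HD95; percentile
  100 gives the exact Hausdorff distance) or mean (ASSD).  Both agree
  with an all-pairs brute-force oracle to 1e-9 mm.
- **Dice + focal loss**: `lambda * (1 − soft Dice) + (1 − lambda) *
  focal`, with soft Dice averaged over classes and the focal term
  `−alpha (1 − p_t)^gamma log(p_t)` averaged over voxels, p_t clamped
  to [1e-7, 1 − 1e-7].  Defaults gamma = 2, alpha = 0.25,
  lambda = 0.5 (the conventional focal-loss settings).

## Pipeline and post-processing

Per case: clip/normalize → segment (plugin) → scattered-piece removal →
cuspid analysis → naming → classification → metrics against ground
truth.  Scattered-piece removal keeps only the largest connected
component (26-connectivity; thin oblique sheets fragment under
6-connectivity) for the single-body structures AA and LV, but for
leaflets and calcification — which are legitimately multi-component —
it instead drops components below a small size threshold (30 voxels for
leaflets, 5 for calcium), since keeping one piece would delete real
cusps or specks.  Failures (e.g. an empty leaflet mask) are recorded
per case and do not abort the cohort.  Reports carry the segmenter
name/version, config hash and seeds, and identical configs and seeds
reproduce byte-identical report files.

The reference segmenter thresholds the normalized palette: calcium and
blood from raw intensity bands; the low-contrast leaflet band from a
3×3×3 median-filtered image (noise robustness) augmented by raw-band
voxels adjacent to that core (recovers the sheet rim the median filter
erodes), with candidates adjacent to background discarded to suppress
partial-volume shells after rotation.  The blood pool is split into AA
and LV by a plane orthogonal to its principal axis placed just below
the leaflets, orienting the axis toward the heavier side.

## Validation studies and problem sizes

The shipped experiments regenerate everything from seeds: (i) cuspid
and valve-class recovery on 60 noiseless phantoms (20 per morphology),
(ii) the same cohort with sigma = 0.05 noise and random ±15° rotations
run through the full pipeline, (iii) reference-segmenter DSC on 10
noiseless phantoms, and (iv) metric-oracle agreement on 50 random mask
pairs.  At the default 64³ grid these complete in well under a minute
each on one CPU.  Observed behaviour: perfect recovery on noiseless
cohorts; degraded-cohort valve-class accuracy around 0.87–0.95 with the
errors concentrated in the type-1→type-0 bicuspid cell; per-structure
DSC ordering blood pool ≈ calcium > leaflets.

## Known limitations

- The phantom's flat leaflet sheets make the PCA plane fit in the raphe
  detector easier than curved patient anatomy would.
- The reference segmenter is palette-specific by design; it validates
  the pipeline, not any claim about real CTA segmentation.
- The silhouette criterion assumes cusps are compact wedge-shaped point
  clouds; heavily fenestrated or fragmented leaflet masks may defeat
  it (such masks are rejected only if too small).
- Sievers type-2 (two raphes) and rarer morphologies (quadricuspid
  valves) are outside the class vocabulary.
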