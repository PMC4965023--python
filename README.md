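# spinemorph

3-D spinal morphometry for scoliosis research: per-region **anterior–posterior
length discrepancy** (Δ(A-P)), **coronal Cobb angle** and **vertebral axial
rotation**, computed from endplate contours, together with a parametric
**synthetic spine generator** that produces scoliotic and control cohorts with
exact ground truth, and the accompanying **statistical battery**
(t-tests, one-way ANOVA with Bonferroni post-hocs, paired tests, Pearson
regression, ICC(2,1) reliability, sample-size calculation).

## What it computes

For every subject the pipeline:

1. fits a least-squares plane per endplate contour and derives its
   anterior–posterior axis (spinal-canal centroid → endplate centroid,
   projected into the endplate plane);
2. extracts the true anterior/posterior landmark per endplate and sums
   vertebra and disc heights into regional anterior/posterior lengths;
3. reports `Δ(A-P) = (anterior − posterior) / posterior × 100%` per region,
   the Cobb angle between end-vertebra endplates in coronal projection, and
   signed axial rotation of each endplate versus the sacral plate
   (right positive);
4. decomposes the spine into main thoracic and (thoraco)lumbar curves,
   apical zones (apex ± 1 vertebra) and proximal/distal junctional segments
   (detected from the coronal tilt sequence, or `T4–T12` / `L1–L5` spans for
   curve-free controls).

All projections are anchored to the sacral plate, so every metric is
invariant under rigid motion of the subject.

The synthetic generator builds each spine as a chain of wedge elements
(vertebrae and discs) with sagittal/coronal wedges and axial twist, emits
elliptical endplate contours, and calibrates each subject by fixed-point
iteration until the analytic chain reproduces its drawn targets. Cohort
distributions are shipped in `src/spinemorph/configs/` (curve-pattern mix,
Cobb/rotation/Δ(A-P) levels, the 5°-rotation and 1.2%-length couplings per
10° of standing Cobb, and observer jitter for reliability studies). A voxel
round trip (`rasterize` / `extract_contours`, NIfTI-1 label maps) emulates
CT segmentation.

## CLI

```sh
# generate a cohort (contour JSON per subject + truth.csv + manifest)
spinemorph generate --group ais --n 77 --seed 1 --out out/ais
spinemorph generate --group control --n 22 --seed 2 --out out/ctl --raster

# measure a directory of contour JSON / NIfTI label maps into a cohort CSV
spinemorph measure --in out/ais --out cohort.csv

# statistical battery on a cohort CSV
spinemorph stats --in cohort.csv --out report.json --text report.txt

# full chain: calibrated AIS + control cohorts -> measurement -> statistics
spinemorph reproduce --seed 1 --out out/repro
```

Subject files are JSON contour documents
(`src/spinemorph/schemas/contours.schema.json`) in a right-handed patient
frame (+x left→right, +y posterior→anterior, +z caudal→cranial, mm).

## Library entry points

```python
from spinemorph import (
    CohortConfig, generate_cohort, perturb_observer,   # synthetic cohorts
    measure_contours, measure_cohort,                  # measurement pipeline
    run_paper_battery, icc_2_1, sample_size_two_means, # statistics
)

cohort = generate_cohort(CohortConfig(group="ais", n_subjects=77, seed=1))
table = measure_cohort([contours for contours, truth in cohort])
report = run_paper_battery(table)
```

Notes:

- a "two-sided Welch t" is the default two-sample test (`pooled=True` for the
  classical variant); ICC is the two-way random-effects, absolute-agreement,
  single-measure form; normality is screened (Kolmogorov–Smirnov) and
  reported but never switches a test.
- the sample-size routine uses the normal approximation
  `n = 2σ²(z₁₋α/₂ + z_power)² / (μ₁−μ₂)²` per group, rounded up.
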