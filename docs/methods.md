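# Methods

This note documents the models, conventions and numerical choices behind
`contourqa`, and what the synthetic cohort does and does not establish.

## Coordinate and grid conventions

All geometry lives on a regular voxel lattice (`ImageGrid`): voxel index
(i, j, k) maps to patient coordinates `origin + index · spacing` in mm,
axes (x, y, z), z increasing cranially. The z convention is load-bearing:
the spinal-cord caudal cut-off removes slices *below* the most cranial of
the compared cords' inferior ends, and the cut is defined on the z index.
Masks are boolean occupancy arrays; a voxel belongs to a structure iff its
*center* is inside the contour.

## Rasterization

Planar polygons are converted to masks by the even-odd rule evaluated at
voxel centers: a center inside an odd number of the slice's polygons is
set, so a second polygon drawn inside the first cuts a hole. Edge
crossings use the half-open rule `[y1 <= y < y2)`; centers lying exactly
on a polygon edge count as inside. This is deterministic and matches
common scanline rasterizers. Each contour's z must land within half a
slice spacing of a grid slice; anything farther is an error rather than a
silent snap.

## Surface metrics

Surfaces are the voxels removed by a face-connected (6-neighbourhood)
binary erosion with outside-of-volume treated as background, so voxels on
the array border are surface and a one-voxel-thick sheet is all surface.
Directed distances come from an anisotropic Euclidean distance transform
(per-axis sampling = spacing) of the opposing surface, evaluated at the
source surface voxels. HD is the symmetric maximum; MSD is the average of
the two directed means (the "average symmetric surface distance"
convention — the pooled-sum variant differs when the two surfaces have
unequal voxel counts). Distances are between surface-voxel centers; there
is no sub-voxel surface model, so on a grid with spacing s the metrics are
quantized at the s scale. For speed, each pair is evaluated on its union
bounding box plus one voxel of padding — erosion and distance transforms
are unchanged by this crop, so the results are bit-identical to the
full-grid computation (the test suite checks the EDT path against an
O(n²) brute-force pairwise oracle to 1e-9 mm).

Empty masks raise at the metric level; the pipeline converts these to
missing values (NaN) with a logged reason, so one degenerate structure
cannot abort a cohort run. DSC with exactly one empty mask is 0; with two
it is undefined. The relative volume difference uses the reference volume
as denominator and is NaN for an empty reference; the absolute form is
always computed.

## Dose metrics

DVH summaries are computed by direct voxel statistics over the mask: Dmax
is the absolute single-voxel maximum (on a 0.25 cm dose grid that voxel
represents 0.0156 cc), Dmedian is the voxel median (an interpolated D50%
from a cumulative DVH would differ in the tails; voxel-median was chosen
for transparency), and the median of an even count is the mean of the two
central values. Dose and mask must share a grid — no resampling is
implemented, mirroring the absence of a documented interpolation scheme in
clinical exports; the synthetic dose is generated directly on the mask
grid. The clinical-goal policy maps serial organs (brainstem, spinal
cord) and the mandible to Dmax and parallel organs (parotids, larynx,
oral cavity, pharynx constrictors, submandibular, thyroid, cochleas) to
Dmean; the mapping is configurable and laterality suffixes are
normalized. Dose deltas are computed on the *uncut* masks (the caudal
cut-off applies to the geometric comparison only, as a planning system's
DVH would see the full structure).

## Cohort statistics

Percentiles interpolate linearly between order statistics (numpy default);
SDs are sample SDs (n−1), with a singleton group reported as SD 0.
Per-OAR observer variability pools all (patient, observer) records of one
arm — patients and observers are deliberately not separated; a
mixed-effects decomposition of the patient–observer crossing is out of
scope. The headline "mean SD" averages per-OAR SDs unweighted, so an OAR
with few records counts as much as a well-populated one. Percent figures
round half-away-from-zero to integers for report parity (−43.75% → −44%);
exact values are kept alongside. Time saved is differenced on group
medians; the with-processing variant adds the AI processing/import median
to the adjusted median before differencing. Missing records are excluded
listwise per aggregation and surfaced in the exception log; the contour
bookkeeping (`planned − exceptions`) is checked against an explicit
exception count rather than inferred.

Cochleas default to the geometry-exclusion list (their extreme relative
size discrepancies distort geometric summaries) but remain in the dose and
time analyses. Exclusion removes them from geometric *tables and
variability headlines* only; record-level metrics are still computed.

## Synthetic cohort

The phantom is schematic head-and-neck anatomy: 12 organ analogues
(ellipsoids; z-aligned elliptic cylinders for spinal cord, brainstem and
pharynx constrictors; a half-torus mandible) on a 96×96×64 grid at 2 mm
isotropic spacing — coarse enough that a full cohort runs in seconds,
fine enough to leave ≥ 4 voxels across the smallest organs. Patients
differ by per-organ translations (SD 1.5 mm, clipped at 2 SD to preserve
grid margins). Cylinder z-intervals are half-open so a span lands on
span/spacing slices exactly.

Observer error is a smoothed Gaussian field added to the ground truth's
signed distance function: white noise smoothed with a 6 mm Gaussian,
rescaled to the arm's boundary SD, plus a constant systematic margin, then
re-thresholded at zero. This produces spatially correlated boundary
errors (an observer who is generous on one slice tends to be generous on
the neighbouring ones) rather than independent voxel noise. Defaults:
manual 2.0 mm SD and no bias; adjusted 0.8 mm SD; AI 0.6 mm SD; both AI
arms carry a +0.5 mm systematic margin, reflecting that AI's slight
expansion of serial organs largely survives clinician correction. Tubular
organs additionally get integer caudal-extent jitter (manual ±2 slices,
AI arms ±1). The signed distance field is referenced to the boundary
with a quarter-voxel offset per side — the even-handed compromise between
the face-neighbour gap (half a voxel) and larger diagonal gaps; on the
2 mm grid it keeps a ±2 mm margin dilation/erosion within ~10% of the
analytic volume change, where a half-voxel offset over-includes diagonal
neighbours and no offset under-dilates.

Timing is log-normal per patient (medians 55 / 17 / 10 min for manual /
adjusted / processing; dispersions 0.40 / 0.33 / 0.20 chosen so the 2.5–97.5%
range spans roughly the observed 17–151 / 7–42 / 7–21 min), rounded to the
half minute with ties up. All randomness derives from explicit seeds;
per-mask RNG streams are keyed by (seed, observer, patient, organ) so any
single contour regenerates in isolation, and a written study directory is
byte-reproducible.

What a green synthetic test establishes: that the pipeline's metrics,
harmonization, aggregation and bookkeeping are internally correct and
that the generator's stated noise ordering (manual > adjusted ≥ AI) is
recovered by the variability statistics. What it does not establish:
agreement with any clinical cohort's metric values — real observer error
is structured by anatomy, imaging and training in ways a smoothed random
field does not capture, organ shapes are idealized, and the dose field is
a single Gaussian falloff rather than an optimized plan.

## Runtime notes

The 100-replicate parameter-recovery check (10 patients, 5 manual / 3
adjusted observers per replicate) runs in roughly 8–10 minutes on one CPU
— somewhat over the ~5 minute design estimate; the cost is dominated by
the per-observer noise fields and per-pair distance transforms, both
already restricted to bounding-box crops.

## Known limitations

- No 95th-percentile Hausdorff variant (noted as complementary
  information only; a possible extension).
- No hypothesis tests or confidence intervals on the summaries, and no
  mixed-effects modelling of repeated measures on the same patients.
- No DICOM RT-STRUCT I/O; masks enter as NIfTI volumes or polygon JSON.
- NRRD mask input is not supported in this build (no NRRD reader in the
  dependency set); the DVH text dialect is a documented stand-in, not a
  vendor format.
- No dose-grid resampling: dose and masks must share a grid.
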