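# Methods

## Scope and rationale

`mitomorph` implements an integrated analysis platform linking mitochondrial
morphology to apoptotic signaling in single cells: image-based three-class
morphology scoring, membrane-potential (ΔΨm) collapse kinetics from TMRM
traces, GFP-Bax activation scoring, and a fuzzy-logic mirror-model search
for the directionality of interactions among these readouts.  The original
microscopy data behind this class of study are not publicly available, so
the platform is driven end to end by synthetic generators with known ground
truth; every analysis stage is therefore testable as a parameter-recovery
problem rather than by eyeballing real images.

## Synthetic data model

### Mitochondrion shapes

Three morphology classes are rendered at 0.1 µm/px (the pixel size is a
declared default — typical of a 63× oil objective with modern cameras — and
configurable):

| class      | family             | target perimeter | per-shape SD | count/cell |
|------------|--------------------|------------------|--------------|-----------|
| networked  | branched dilated random walk | 14.0 µm | 2.0 µm | 2–5 |
| swollen    | large ellipse (axis ratio 1.0–1.3) | 8.8 µm | 2.0 µm | 3–7 |
| fragmented | small ellipse (axis ratio 1.0–1.5) | 2.7 µm | 0.5 µm | 12–26 |

The targets are the class-typical perimeters measured manually on MCF-7
Mito-GFP images.  Calibration is closed against the pipeline's own
measurement operator (Crofton 4-direction perimeter × pixel size): ellipse
axes come from Ramanujan's perimeter approximation, and the skeleton length
of a networked tubule solves `P ≈ bias · (2L + π·w)` with a rasterization
bias factor (0.865) measured once on calibration walks — tortuous digital
curves lose boundary length to self-overlap at bends and junctions.
Shapes are cropped to a tight bounding box so placement inside cells is not
constrained by a worst-case canvas.

### Cell images

Cells are non-overlapping disks (radius 55–75 px) with one nucleus disk
(DNA channel) and a diffuse cytosolic GFP pool; mitochondria are placed in
the cytoplasm with a ~4 px spacing buffer (so that nearby objects remain
resolvable after blur — a real constraint the microscope's PSF imposes on
any segmentation).  Per-mitochondrion classes are drawn i.i.d. from the
requested class mix; recorded truth fractions are the *realized*
frequencies.  Failed placements re-draw the shape several times, otherwise
large networked shapes would drop out preferentially and bias the realized
mix.  Rendering: Gaussian PSF (σ = 1 px), multiplicative illumination ramp
(±20%), Poisson shot noise, Gaussian read noise (SD 8), 16-bit clipping.
Truth label masks record object pixels before blur and noise.

What the generator does *not* emulate: deconvolution artifacts, organelle
motion, out-of-focus light (single plane only), cell shape irregularity,
intensity heterogeneity within an organelle, and touching/overlapping cells.
Classification accuracies measured on these images therefore demonstrate
that the pipeline is correct and self-consistent, not that it reaches the
same accuracy on real micrographs.

### TMRM traces

Each per-cell StDev trace is a plateau followed by a logistic collapse
`v(t) = min + (max − min)/(1 + exp((t − t0)/τ))`, sampled at 1 Hz for 301
samples.  The logistic is parameterized directly by its `max/2` crossing
time, so extraction of t½_decay is a genuine parameter-recovery test, not a
circular re-fit.  Per-cell crossing times are jittered (SD 8 s) around the
condition preset; stochastic flickering is modeled as transient
multiplicative dips (Poisson-timed, ~3 s wide, ≤ 15% deep) plus additive
Gaussian noise.  Condition presets encode the published qualitative
structure: controls collapse late (full medium at 232 s), death-receptor and
bioenergetic drugs collapse early (~110–140 s), uncoupler/calcium-stress
conditions start already collapsed (low plateau, censored), cyclosporine A
delays collapse relative to its control, and bongkrekic acid blocks it
(censored at high plateau).  A preset whose `min_level ≥ max_level/2` with a
crossing time set is rejected as inconsistent.

### Condition tables with a planted chain

Nine conditions (the study's condition count) carry seven variables
(Bax %, N/F/S %, MAX, t½_decay, Y_spread).  The chain
Bax → Fragmented → Y_spread is planted through Hill links
(F: ymin 12, ymax 68, K 25, h 2; Y_spread: 5–38, K 30, h 3) with condition
noise (SD 3 and 2).  The chain root is drawn stratified-uniform over 2–95 so
several conditions sit on the saturating plateau — saturation is what breaks
the mirror symmetry: the forward map remains a clean function while the
reverse map is ill-conditioned where the response is flat.  N and S split
the non-fragmented remainder (networked share 55–75%) so N + F + S = 100
exactly; MAX and t½_decay are independent uniforms.

## Analysis pipeline

### Segmentation

* **Illumination correction** divides by a wide Gaussian blur of the image
  itself (σ = image size / 8) and rescales to preserve the mean.
* **Nuclei**: Otsu on the smoothed DNA channel, hole filling, watershed split
  on the distance transform (peaks ≥ 15 px apart), minimum size 200 px.
* **Cell borders**: watershed on the inverted smoothed GFP channel seeded at
  nuclei, restricted to foreground = lowest threshold of a three-class Otsu
  on log intensity ∪ dilated nuclei.  The log-domain multi-Otsu is a
  deliberate choice: the GFP histogram is trimodal (background, cytosol,
  organelles) with a decade of dynamic range, and a plain two-class Otsu
  collapses cells onto their brightest organelles.
* **Mitochondria**: per cell, white top-hat (disk radius 20 px) removes the
  diffuse cytosol and any constant offset; per-cell Otsu on the enhanced
  values, 8-connected components, minimum size 4 px.  The top-hat radius
  must exceed the half-width of the largest organelle — swollen mitochondria
  are ~28 px across at 0.1 µm/px, so a 10 px element would hollow them out;
  20 px is the default.

### Features (exactly 69 per cell)

6 nucleus shape + 6 cell shape (area, Crofton perimeter, form factor
4πA/P², eccentricity, solidity, extent) + 21 mitochondrial aggregates
(count; total area; cell-area fraction; mean and population-SD of the six
shape features; mean/SD centroid-to-nucleus distance; mean nearest-neighbour
distance; median area; median perimeter; integrated GFP intensity fraction)
+ 36 Zernike magnitudes (mean over mitochondria of |Z(n,m)|, n ≤ 10,
n − m even, m ≥ 0).  Lengths in µm, areas in µm²; a cell with zero detected
mitochondria gets declared defaults (count 0, aggregates 0) and a flag.
Zernike moments are evaluated directly from the radial polynomials on the
object's minimum enclosing disk; magnitudes are translation-, scale- and
rotation-invariant, which the tests verify.

### Random forest

500 trees by default (`mtry = ⌊√p⌋ = 8`, unlimited depth, Gini), each grown
on a bootstrap stratified by (class, batch) so no tree over-represents one
imaging session; falls back to class-only stratification (with a warning)
when a stratum is empty.  Scores are vote fractions; ties in the majority
reduction break in the fixed order networked > fragmented > swollen.  OOB
error comes from out-of-bootstrap majority votes; MDA importance permutes
each feature among a tree's own OOB cells (Breiman's per-tree scheme) and
averages the accuracy drop.  The representative tree is a depth-4 CART
whose split gains are multiplied by feature MDA (equivalently divided by the
1/MDA cost); non-positive MDAs are floored at (smallest positive MDA)/10.
It is for interpretation only, never classification.  On the synthetic
images the class the root split isolates is *fragmented* (median
mitochondrion area separates it perfectly); which class is "most distinct"
is a property of the data, not of the method.

### ΔΨm kinetics

MAX and MIN are medians of the first/last 10 samples; Y_spread = MAX − MIN
identically.  "Half of its initial value" is read literally: threshold =
MAX/2 (a `halflife_mode="midpoint"` switch uses (MAX+MIN)/2 instead).  The
crossing is the first downward crossing that stays at or below threshold for
≥ 5 consecutive samples (suppressing flicker dips), linearly interpolated
between the bracketing samples; traces that never cross are censored rather
than assigned an arbitrary time.  The StDev is the population (not sample)
standard deviation — the ROI contains the full population of its pixels.
Condition profiles are per-time-point means; clustering uses average-linkage
agglomeration on Euclidean distances between profile vectors (average
linkage is a declared choice; the distance is the substantive one).

### Bax scoring

Puncta are 8-connected components (≥ 3 px) of the white-top-hat-enhanced
GFP exceeding background + 5·MAD within the cell; a cell is positive when
n_puncta ≥ 3 AND the coefficient of variation of its raw GFP ≥ 1.0.  The
puncta detector is exactly invariant to constant intensity offsets; the CV
is not, but the decision has wide margins (diffuse cells sit near CV ≈ 0.1,
punctate cells near 1.5–2), so moderate offsets never flip a call.  The
rule is an automated surrogate for manual cluster scoring and is validated
against synthetic truth only; the thresholds are free parameters.

### Fuzzy directionality

A SISO Sugeno model has two Gaussian input membership functions (peak fixed
at 1) and two linear consequents — the rule count equals the number of
input-MF combinations, removing it as a free parameter.  Training is
hybrid: the consequents are solved exactly by least squares at every epoch
(the output is linear in them), and the premises (c, σ per MF) take one
normalized-gradient step (numeric central differences, step ∝ data range);
a step that raises the SSE is rolled back and the learning rate halved, so
the training SSE is non-increasing.  Defaults: 200 epochs, learning rate
0.05, relative-SSE convergence 1e-8, premises initialized at c_low = min x,
c_high = max x, σ = range/2 (guaranteeing overlap and full coverage).
RMSE is computed on the training set — model selection here is about which
direction explains the data better, not held-out prediction.

The exhaustive search trains all 30 ordered cross-group pairs over
{Bax} × {N, F, S} × {MAX, t½_decay, Y_spread}, tagged by the six direction
families.  Mirror selection discards models with RMSE > 15 (a.u., applied on
native scales: percentages 0–100, seconds, a.u.) and keeps the
smaller-RMSE direction of each surviving pair.  Variables can optionally be
min-max rescaled to 0–100 before fitting (`normalize=True`), since
comparing RMSEs across heterogeneous output units is scale-sensitive;
the default is raw scales.  Fitting uses per-condition means (nine rows):
the three assays come from different cell lines/sessions and cannot be
matched per cell.  Published reference RMSEs for the retained directions
(13.83, 8.46, 8.49, 6.69, 6.56) are recorded as documentation constants
only — the condition-level ΔΨm means needed to re-fit them were never
published, so they are not recomputed.

## Problem sizes and numerical choices

The test and acceptance workloads use desk-scale sizes chosen to exercise
every stage meaningfully: 60 cropped cells/class for cross-validation
(10 folds × 10 repeats, 200 trees per fold — accuracy on these separable
data is insensitive to the tree count beyond ~100), 150 cells for in-situ
classification, 200 shapes per calibration check, 100 traces for half-time
recovery, 50 seeds × 30 models for chain recovery.  Seeds propagate through
`numpy` Generators; identical (spec, seed) gives bit-identical outputs for
every generator, and the pipeline spawns per-stage seeds from the global
seed via `SeedSequence`.

Degenerate inputs are handled explicitly: all-zero images are rejected by
illumination correction; a blank DNA channel yields an empty labeling with a
warning; a cell without mitochondrial foreground is recorded as empty, not
an error; Sugeno inference with underflowed weights falls back to the
unweighted rule mean with a flag; trace presets that cannot cross their
half-maximum are rejected at construction.

## Known limitations

* The 69-feature schema is a declared reconstruction: the count and the
  group structure (nucleus / cell / mitochondria incl. Zernike) are fixed,
  but the exact identity of individual aggregate features in the original
  pipeline is not recoverable.
* Per-condition biological percentages from the original study are anchors
  for generator presets and arithmetic cross-checks only; nothing here
  claims to reproduce them from images.
* Single-plane rendering and analysis; no 3D, no tracking, no deconvolution,
  no photobleaching model.
* Mirror-model direction calls carry no statistical significance measure;
  with nine conditions they are descriptive model comparisons.
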