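# Methods

## Scope and model overview

`msiplex` is a generative model of 2-D multiplex immunofluorescence images of
colorectal tissue at the subcellular level, together with the inverse
(learning) pipeline and a validation layer. The generative chain is

    scaffold geometry → organelle placement → mutation status →
    per-cell expression → per-compartment channel rendering

with every stage driven by a single seeded `numpy` generator, so identical
configuration and seed reproduce identical output byte for byte.

## Tissue scaffold

The scaffold is a deliberately minimal re-creation of colonic mucosa: the
contribution of this package begins at the organelle and protein layers, so
the scaffold only needs to supply valid cell/nucleus geometry with phenotype
labels. Crypts are elliptical lumens ringed by a single layer of
epithelial/goblet cells (major axis radial, mimicking columnar epithelium);
stromal cells are dart-thrown into the inter-crypt space. Every cell is a
*deformed circle*: an ellipse sampled at `n_vertices` angles with each vertex
radius scaled by a factor in `[1−irregularity, 1+irregularity]`, which keeps
the polygon star-shaped about its centre and therefore simple.

Differentiation grade is reduced to two knobs (healthy → well → moderate →
poor): the goblet fraction of ring cells (0.35 → 0.20 → 0.08 → 0) and the
ring-breakage/irregularity of the crypts (0/0.06 → 0.35/0.18). Epithelial
nuclei are displaced toward the basal (anti-luminal) side of the cell by a
configurable fraction of the cell radius (default 0.3).

No published values exist for crypt or cell sizes in this setting; the
defaults (lumen radius 22 μm, epithelial cell radius 10 μm, stromal radius
6.5 μm, nucleus diameters 8.5–10.5 μm) were chosen once for visual
plausibility. Nucleus diameters deliberately sit inside the [5, 20] μm
validity band of the segmentation pipeline with headroom for its 2 px seed
erosion, so scaffold nuclei always survive the learning module's size filter.
Disjointness of cell interiors is guaranteed by construction (centre spacing
at least the sum of maximal perturbed radii), as is containment within the
image bounds.

Coordinates are 0-based pixel (x, y) positions; polygons are stored
counter-clockwise and closed implicitly.

## Organelle model

Each organelle type (nucleoli, golgi, vesicles) is described by four
univariate distributions:

| feature           | meaning                                    | family |
|-------------------|--------------------------------------------|--------|
| count             | organelles per cell                        | gamma |
| minor_axis_ratio  | organelle minor axis / nucleus minor axis  | gamma |
| axes_ratio        | minor/major axis of the organelle, (0, 1]  | gamma |
| position          | dimensionless D (below)                    | gamma (nucleoli), t location-scale (golgi, vesicles) |

The position feature along the ray from the nucleus centre through the
organelle centre is `D = 1 − (N − O)/(N + C)` with N the nucleus-centre →
nuclear-membrane distance, O the distance to the organelle centre and C the
nuclear-membrane → plasma-membrane distance. D < 1 is intranuclear, 1 on the
nuclear membrane, and up to 2 at the plasma membrane. Golgi and vesicles pile
up just outside the nuclear membrane, which the heavy-tailed t location-scale
law captures better than a gamma.

Placement per cell: draw a target count; per candidate draw the three
remaining features plus a uniform direction; invert D to a centre point
(`O = N − (1−D)(N+C)`); build a deformed-circle polygon (deformation 0.10,
20 vertices, random rotation); clip nucleoli to the nucleus and golgi/vesicles
to the cell (additionally subtracting the nucleus when the sampled D > 1);
accept only if the cumulative area of this organelle type *including the
candidate* stays within the cap — 20 % of the nuclear area for nucleoli, 12 %
(golgi) and 18 % (vesicles) of the cell area. The candidate-inclusive reading
makes the cap a hard, testable invariant. The organelle minor axis is floored
at 1 px; axes-ratio draws above 1 are reciprocal-folded into (0, 1];
nucleolus position draws with D > 1 are rejected and redrawn.

Numerical details decided here:

- A sampled D below the on-ray minimum `1 − N/(N+C)` has no realisation along
  that direction (the point would flip to the opposite ray); such draws are
  rejected and redrawn, like draws landing outside the cell in concave
  geometry.
- Candidate drawing is batched (vectorised inverse-CDF sampling) and stops
  early after 40 consecutive cap rejections — at that point the area budget is
  exhausted and further candidates cannot change the outcome. At most
  10 × target candidates are drawn in total. Placement failures silently
  reduce the realised count.
- Truncated distributions renormalise the density over their support and
  sample by inverse CDF restricted to it.

The shipped default parameters (`params/default_pdfs.json`) are **not**
published fits — the source fits exist only as plotted curves. They were
chosen once: count means follow the reported per-cell totals of the confocal
data the model emulates (≈ 5.6 nucleoli, 41 golgi, 177 vesicles per cell),
and size/shape/position parameters respect the reported area observations
(golgi up to ~4 % and vesicles ~6 % of cell area, nucleoli up to 19.3 % of
the nucleus). In tissue-scale cells the caps then bind for a share of cells,
which is the intended behaviour of the cap mechanism. Note that at 20×
resolution (0.5 μm/px) the smallest vesicles hit the 1 px minor-axis floor,
which distorts the realised size distribution slightly; at 40× (0.25 μm/px)
the floor is effectively inactive.

## Protein expression model

Sample-level mutation status (population-representative mode): an MMR
mutation with probability 0.15; given a mutation, gene MLH1/MSH2/MSH6/PMS2
with probability 0.50/0.40/0.07/0.03; P53 over-expression with probability
0.50 without a mutation and 0.20 with one; PTEN stromal fraction uniform on
[0.30, 0.70]. The draw order is fixed so seeded runs are reproducible; any
field can be pinned by user override.

Per-cell expression rules: every stromal cell expresses every MMR protein
(the clinical positive control); epithelial (and goblet) cells express each
MMR protein with a configured fraction **unless** the protein is lost under
the mutation (MLH1 loss silences MLH1+PMS2; MSH2 loss silences MSH2+MSH6;
PMS2/MSH6 losses are isolated). PMS2 epithelial expressors are drawn as a
subset of MLH1 expressors, and MSH6 of MSH2, reflecting the heterodimers.
P53 is epithelial-only; "over-expressed" is implemented as an expressing
fraction drawn uniform on (0.5, 1.0], otherwise on (0.05, 0.5), anchoring the
clinical > 50 %-of-cells criterion. PTEN stains the drawn stromal share plus
a configured epithelial fraction.

Rendering paints, for every expressing cell, each compartment of the
protein's profile (nucleoli, whole nucleus, nucleus-minus-nucleoli,
cytoplasm, golgi, vesicles) at a strong (1.0) or weak (0.3) level — the
ordinal contrast matters, the absolute levels are configurable — modulated by
a procedural texture: octave-summed value noise (4 octaves, persistence 0.55,
base period 64 px), with a tanh-sharpened "chromatin" variant for nuclear
granularity (used for the MSH2 channel and the DAPI-like reference). Weak
compartments are painted before strong ones so overlaps resolve in favour of
the stronger signal. One profile detail follows the imaging behaviour rather
than the curated location table: MSH2 keeps *weak* nucleolar staining next to
its strong nuclear signal. Acquisition noise (photon/camera) is not part of
the model; the fixture generator offers additive Gaussian noise for
robustness testing.

## Learning pipeline

- **Nuclei**: threshold the DAPI channel at the modal pixel intensity (256-bin
  histogram), erode (disk radius 2 px), drop objects under 50 px and objects
  touching the border, then remove nuclei whose equivalent-circular diameter
  is outside [5, 20] μm. Erosion radius and small-object cutoff are package
  choices (the procedure is prescribed, the magnitudes are not).
- **Cells**: seeded watershed on the inverted (median-filtered) ER channel,
  with nuclei as foreground seeds and large zero-intensity ER regions as the
  background seed; one region per nucleus, labelled to match.
- **Nucleoli**: modal-intensity background threshold (reused by analogy with
  the DAPI step; the original threshold value is unstated), seeded watershed,
  [0.5, 3] μm diameter filter, assignment to the nucleus containing the
  centroid.
- **Puncta (golgi/vesicles)**: subtract a 15 px local mean from a lightly
  smoothed (σ = 1 px) image to highlight punctate features; threshold by Otsu
  **floored at median + 5·MAD** of the highlight — on sparse punctate images
  plain Otsu splits the background mode — and grow by hysteresis (low =
  median + 2·MAD) so small objects keep their footprint; discard components
  whose *un-smoothed* highlight support is below 5 px, so smoothing cannot
  inflate a sub-threshold speck past the noise rule. Touching organelles merge
  into one object; this is an accepted resolution limit of
  thresholding-based segmentation.
- **Features**: per organelle — count per cell, minor-axis ratio and
  minor/major ratio from second-central-moment ellipse fits, position D by
  ray marching on the label masks, solidity (area / convex hull area), and
  area fraction (organelle area over nuclear area for nucleoli, cell area
  otherwise, per organelle row).
- **Fits**: maximum likelihood via scipy with truncation-aware
  renormalisation (Nelder-Mead refinement of the truncated likelihood from
  the untruncated MLE start). Counts are fitted with the continuous gamma
  density evaluated at the integers; zero counts are clipped to 0.5 first
  (gamma support is x > 0; the original choice is unstated). Fits refuse
  fewer than 20 values, non-finite values, and constant data.

## Fixture generator

Fixtures emulate single-marker confocal images of cultured cells: scattered
round cells on a jittered grid (no crypt architecture — segmentation
correctness is isolated from tissue geometry), with a DAPI channel, an ER
channel whose inter-cell background is exactly zero (so background seeding
works), and one organelle channel painted from instances drawn by the
simulator itself. Ground truth (label maps plus an analytic feature table) is
returned alongside; additive Gaussian noise is optional. An optional
minimum-separation constraint keeps the planted organelle set separable when
object-level recall is the question; it is off for distribution-level tests
so counts stay honest. Fixtures do not model the confocal point-spread
function; noise robustness shown on fixtures therefore speaks to threshold
logic, not to deconvolution.

## Validation

KL divergence is computed in nats between histogram estimates on a shared
binning spanning the pooled range (30 bins by default), with additive
smoothing 1e-6 on empty bins; it is asymmetric by construction and invariant
to a common affine rescaling of both samples. The feature report emits the
6-feature × organelle KL matrix. CMP analysis thresholds every imaged channel
(per-channel Otsu by default, user-overridable — the original thresholding
rule is unstated) and tabulates per-pixel binary codes with optional per-cell
occupancy fractions.

## Problem sizes used by tests and the acceptance script

Calibration rates use 2,000–20,000 sampler draws. Area caps are checked on
ten (script) or three (test) generated samples at 512×512 px, 0.5 μm/px,
two crypts (~50 cells, ~4,500 organelles each) — the package's desk-scale
sample geometry. The learn→simulate closed loop uses ~3,000 organelles in 576
cells at 0.25 μm/px with distributions chosen so the area caps stay slack and
organelle overlap is rare; with overlap, merged objects truncate each other's
measured axes and inflate the fitted variance, which is a real property of
dense organelle fields (and the reason golgi fits are the hardest case in
this domain), not of the estimator. Recall tests measure coverage recall
(≥ 50 % of the planted object's pixels recovered) over in-band objects —
nucleoli planted inside the [0.5, 3] μm filter band, puncta at or above the
5 px resolution floor — since out-of-band objects are removed by design.

## Known limitations

- The scaffold is geometric, not histological: no muscularis, no mucus
  texture, no stem-cell compartment, single-layer rings only.
- Organelles may overlap within a cell; rendered channels and label maps
  resolve overlap by overwriting, which slightly truncates measured sizes in
  dense fields.
- The position model assumes the nucleus is roughly central when inverting D
  with a uniformly random direction; in strongly displaced epithelial nuclei
  the realised D distribution widens, as it does in the data the model
  emulates.
- Expression fractions are per-cell Bernoulli structures; there is no spatial
  autocorrelation of expression within the epithelium, no antibody chemistry
  and no acquisition noise model.
- 3-D structure, organelle dynamics, endoplasmic reticulum and cytoskeleton
  are out of scope.
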