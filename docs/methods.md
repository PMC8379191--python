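# Methods

This note records the models, conventions and numerical choices behind each
stage, what the synthetic generator does and does not emulate, and the known
limitations.

## Coordinate and unit conventions

Pixel coordinates are 0-based `(row, col)` with the origin at the top-left;
`x` is the column, `y` the row.  Grid cells are half-open
`[k·s, (k+1)·s)`.  Physical quantities are micrometres and mm², converted
through the field's `pixel_size_um`.  The default render-scale field is
1580 × 1145 px at 0.9104 µm/px — a quarter linear scale of a
6322 × 4581 px, 1.5 mm² scanner field at 0.2276 µm/px — chosen so a full
simulate-to-statistics run takes seconds on a laptop while keeping several
hundred nuclei per lobule.  The hotspot defaults (`d` = 250 px, grid cell
50 px) are expressed in full-resolution scanner pixels and rescaled through
pixel size, so `d` is always 56.9 µm of tissue regardless of the raster.

## Synthetic fields

Geometry: each field carries `n_lobules` elliptical lobules (default
semi-axes 200 × 146 µm at render scale) along a shared unit growth axis;
each lobule contains ring-shaped two-layer ductules (radius 33 µm; luminal
nuclei on an inner ring, basal nuclei on an outer ring) on a jittered
hexagonal lattice that is symmetric about the lobule centre, so that under a
flat proliferation gradient the leading and trailing halves are statistically
identical.  Every epithelial cell gets a normalised axis coordinate
`u ∈ [0, 1]` (1 = leading edge); Ki67 positivity is Bernoulli with
probability `expit(logit(p0) + slope·(u − 0.5))`.  Age presets encode the
study conditions: young (< 2 months) `p0 = 0.30`, inter-macrophage spacing
60 µm; peri-pubertal `p0 = 0.12`, spacing 20 µm; the logistic slope defaults
to 4 for both.  No quantitative effect sizes exist for these gradients in
the source assays (only significance and images), so the presets are
illustrative magnitudes a histologist would call plausible, not calibrated
values.

Immune cells: intraepithelial macrophages sit at arc-length positions along
per-lobule duct polylines, gaps drawn Normal(spacing, CV·spacing) truncated
at 0.2·spacing; stromal macrophages are a Poisson process with separate
central (200 /mm²) and peripheral (100 /mm²) densities, where "central"
stroma lies more than 200 µm from the fat pad; epithelial T cells are placed
adjacent to luminal nuclei (2 per 100 by default) with basement-contact
fraction > 0.5; stromal T cells are Poisson at 150 /mm²; each tertiary
lymphoid structure is a Gaussian B-cell core (60 cells, σ = 18 µm) with an
80-cell T ring at 42–70 µm.

Rendering: all nuclei deposit haematoxylin; Ki67⁺ nuclei and macrophages
deposit DAB over their whole footprint with the counterstain confined to a
concentric core (half the radius), which gives strongly chromogenic nuclei
the DAB-dominant rim seen in real slides and, incidentally, provides the
near-pure colour pixels that percentile-based stain estimation relies on.
Concentrations: haematoxylin 0.85 (0.70 in DAB cores), DAB 1.10.  Stain
vectors default to the published H-DAB pair, haematoxylin (0.65, 0.70, 0.29)
and DAB (0.27, 0.57, 0.78).  Pixels follow `I = I0·exp(−S c)` plus Gaussian
OD noise (σ default 0.02, an approximation of multiplicative camera noise),
clipped and quantised to 8 bits.

Two spatial supports are used: the render-scale preset above for
stain/segmentation/hotspot work, and a slide-scale preset (3.64 µm/px,
≈ 5.8 × 4.2 mm, lobule semi-axes 800 × 580 µm) for count-box and TLS
morphometry — 400 × 230 µm frames with a 200 µm peripheral annulus only
make geometric sense against mm-scale lobules.

What the generator does **not** emulate: photorealistic texture, adipose
and vascular structure, out-of-focus and section artefacts, nuclear shape
variation (all footprints are discs), chromogen diffusion, and 3-D
structure.  Passing tests therefore demonstrate correctness of the
*computational chain* under a controlled colour/geometry model, not
performance on real slides.

A separate table generator draws per-animal measurements from a two-level
normal model (animal means around group means, repeated values within
animal), 7 + 6 animals by default, with the peripheral macrophage density
drawn as a within-animal multiple (0.55 ± 0.10) of the central value so the
paired contrast has a consistent direction.  Inter-macrophage distances are
pooled across animals within group, as in the source protocol; this pooling
pseudo-replicates (30 values per animal) and is reported but deliberately
not corrected.

## Stain model

`rgb_to_od` uses `OD = −log((I + 1)/I0)` with `I0 = 255`; the +1 guards
`log 0` and costs ≈ 0.004 OD at background, so a background pixel maps to a
tiny negative OD rather than exactly zero.  `od_to_rgb` inverts exactly
(`I0·exp(−OD) − 1`, clamped), making normalisation with source = reference
an identity to within one intensity unit.

Macenko estimation: tissue pixels are those with ‖OD‖ > β = 0.15; the OD
maps are first smoothed with a σ = 1.5 px Gaussian.  The smoothing is
deliberate: the α-percentile angle of raw per-pixel ODs is biased *outward*
by roughly the (2–2.5)·(σ_OD/‖OD‖) tail of the angular noise distribution,
which at σ_OD = 0.05 would alone exceed 2° of stain-vector error; averaging
over the kernel suppresses the per-pixel noise while leaving the interior
colour statistics (and hence the percentile geometry) intact.  α = 1 % and
the concentration fit by clipped pseudo-inverse are the standard Macenko
constants; exact non-negative least squares is available behind a flag.
Stain identity: the column with the larger red-channel OD component is
haematoxylin (blue stains absorb red).  On a pure single-stain image the
stain plane is degenerate and both percentile vectors collapse onto the
single true vector; callers get duplicated columns rather than an error.

## Segmentation

The classical pipeline reproduces the mask contract of a semantic
segmentation network pair (binary epithelium; three-class nuclei): colour
deconvolution against the reference stain matrix, σ = 1 px smoothing of the
concentration maps, per-channel thresholding, distance-transform watershed
(seed separation 5 px) and an area filter (12–2000 px² at render scale).
DAB objects win overlaps, since a Ki67⁺ nucleus is counterstained too.

Thresholding: each channel is cut at **half its robust (99th-percentile)
peak**, floored at 0.15 concentration units.  An Otsu cut is available but
not the default, because Otsu's threshold lands at a class-mix-dependent
fraction of the blur profile — measured ≈ 40 % of peak for DAB versus
≈ 47 % for haematoxylin on default fields — which systematically inflates
DAB object footprints relative to haematoxylin ones and biases the Ki67
pixel-area ratio by several per cent.  The matched half-peak cut removes
the inter-channel bias.

Epithelium: Gaussian density (bandwidth 6 px at render scale) of all nuclei
pixels, thresholded at 0.12, closed with a 4 px disc, lumina below 4000 px²
filled, components below 500 px² removed.  All operators are isotropic, so
the mask commutes with right-angle rotations.  Boundary-touching nuclei are
kept and flagged in the centroid table.

The original assays used trained networks (an encoder-decoder semantic
classifier for epithelium and a U-shaped three-class nuclei model; recorded
settings: 256×256×3 patches, 2000/image, reflection/rotation augmentation;
epithelium model 150 epochs, batch 8, SGD momentum 0.9, initial LR 0.001
dropping ×0.3 every 10 epochs, L2 5e-2; nuclei model 50 epochs, batch 8,
initial LR 0.05 dropping ×0.1 every 10 epochs, L2 1e-4).  Training and
inference of those networks are out of scope here; anyone wiring in the
deposited weights only needs to honour the same mask contract.

## Getis-Ord statistic

The self-excluded form is implemented: `w_ii = 0` and both sums in `G_i` run
over `j ≠ i`, because the conditional-randomisation expectation
`E[G_i] = W_i/(n−1)` is exact only for that form (the all-`j` variant
requires an `n` denominator and a different variance).  The variance uses
the canonical randomisation moments
`Var = W_i(n−1−W_i)/((n−1)²(n−2)) · Y_2/Y_1²` with `Y_1, Y_2` the mean and
variance of the remaining values; the permutation null in
`hotspot.permutation_null` (and its exhaustive mode) is the independent
check.  Degenerate cells: `Var = 0 → Z ≔ 0` (no evidence of clustering);
cells whose remaining counts sum to zero are flagged undefined and never
become hotspots.  Distances are Euclidean between cell centres with a
strict `d_ij < d` band; edge cells keep truncated neighbourhoods, so `Z` is
translation-equivariant only for cells whose neighbourhood is untruncated.
Ragged final rows/columns are kept with centres adjusted to the clipped
extent.  Grids above 6000 cells switch to an exactly equivalent
convolution of the count lattice with the disc kernel (verified against the
dense-weights path in tests); the sub-cell centre adjustment of ragged edge
cells is ignored on that path.

The moment-based Z is slightly anti-conservative at low counts (skewness of
a small sum of counts); at 1.96 one-sided the empirical rate under complete
spatial randomness is ≈ 2.6 % against the nominal 2.5 % at ~25 counts per
cell, and worse at very low intensity.  The permutation p-value is the
remedy where calibration matters.

The hotspot threshold (Z ≥ 1.96, one-sided) and the grid granularity are
configurable; neither was stated for the original figures.

## Morphometry rules

Counting rule: a cell is counted when more than half of its circular
nucleus footprint lies inside the frame; exactly-half (equivocal) cells are
counted only when the nucleus intersects the top or right edge — the
standard stereological convention that makes box tilings count every cell
exactly once (property-tested).  Single-edge crossings use the closed-form
circle/half-plane area so exact ties evaluate to exactly 0.5; corner
crossings fall back to a 64-segment polygonal intersection.

Box placement samples positions uniformly at random among those whose frame
intersects the parenchyma mask only (the in-silico analogue of placing
frames at low magnification where staining is not discernible); peripheral
classification: the frame touches fat directly or ≥ 20 % of a 200 µm
annulus around it is fat pad.  Both thresholds are configurable; the source
definition is visual.

Periodicity: maximal runs (grown greedily left to right) of ≥ 4 positions
whose gap coefficient of variation is ≤ 0.30; "evenly spaced" has no
numeric definition in the source protocol, so the CV bound is this
package's operationalisation.  Tightly clustered pairs (< 8 µm apart,
fewer than 3 cells) are merged to their centroid before run detection —
the exclusion sentence in the protocol is grammatically ambiguous and this
merge-then-detect reading is a documented choice, not the authors'
confirmed intent.  Spacing is pooled as successive arc-length differences
along the duct polyline, never chord distances.

Macrophage object filter: keep objects at least half the mean luminal
nucleus area of the same box ("at least" inclusive); with no luminal
nucleus in the box the threshold is undefined and the filter is skipped
with a warning.

TLS: B clusters via DBSCAN (radius 30 µm, ≥ 20 members); a cluster
qualifies when ≥ 20 T cells sit within a 50 µm annulus outside its convex
hull while the hull interior stays predominantly B (interior T fraction
< 30 %).  The radius/count defaults are invented — the cited definition
("discrete B aggregate with a distinct adjacent T area") gives none.

## Group statistics

Mann-Whitney is exact (full enumeration) when `n_a·n_b ≤ 400` and the
pooled sample is tie-free, otherwise tie-corrected normal approximation
with continuity correction; always two-tailed.  D'Agostino K² requires
n ≥ 8 and is recorded per group but never switches the test — the source
analysis reports Mann-Whitney regardless of the normality outcome, with a
single paired two-tailed t-test for the within-animal central-vs-peripheral
contrast.  Degenerate paired cases: all-zero differences return p = 1 by
convention; constant non-zero differences raise (t undefined).

## Problem sizes

Defaults were chosen so the full test suite and the acceptance script each
run in a few minutes on one CPU: render-scale fields of ~900–1000 nuclei;
50 random 20×20 grids with 9,999 conditional permutations for the
moment-vs-permutation check; 200 CSR fields of 40,000 points for
calibration; 4 slide-scale fields (~300 macrophage gaps) for spacing
recovery; 60 table seeds for the group-contrast power check.

## Known limitations

- The synthetic tissue model is geometric; none of the recovery results
  transfer claims to real histology.
- The binomial test behind the polarisation check treats hotspot grid
  cells as independent; they are spatially correlated, so its p-values are
  optimistic.  The planted-gradient effect (index ≈ 0.7 vs 0.5) is large
  against this.
- Pooling repeated measurements per animal pseudo-replicates the group
  contrasts, as in the source protocol.
- The moment-based Getis-Ord Z is anti-conservative at low counts (above).
- Count-box location classes are assigned per box; a frame straddling the
  planted central/peripheral density boundary dilutes the recovered ratio,
  which is why ratio recovery is specified over many boxes.
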