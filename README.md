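# mamspat

Spatial quantification of immunohistochemistry (IHC) in the developing
mammary gland: stain normalisation, Ki67 segmentation, Getis-Ord hotspot
mapping, immune-cell morphometry and group statistics — exercised end to end
on a synthetic H-DAB image generator with planted ground truth.

## Who this is for

Quantitative pathology of brightfield IHC typically chains several delicate
steps: colour standardisation across slides, nuclear segmentation by
chromogen, spatial statistics on the resulting centroids, and manual-style
morphometry (sampling frames, counting rules, densities).  Each step has
conventions that are easy to get subtly wrong and hard to validate on real
tissue, where no ground truth exists.  This package implements the full
chain for the H-DAB (haematoxylin counterstain + DAB chromogen) setting of
developing ruminant mammary gland — lobulated terminal-duct units growing
along an axis, proliferation (Ki67) polarised toward the leading edge,
periodically spaced intraepithelial macrophages, centrally enriched stromal
macrophages, T cells and B/T aggregates — together with a synthetic field
generator that plants all of those structures with known parameters, so
every stage can be tested quantitatively.

## The methods

**Colour model and normalisation.**  Stains mix linearly in optical density
(Beer-Lambert): `I = I0 · exp(−S c)` with `S` the 3×2 matrix of unit stain
OD vectors and `c` the per-pixel concentrations.  The stain matrix is
estimated by the Macenko procedure — SVD of tissue-pixel ODs, extreme
(α = 1 %) percentile angles in the top-2 singular plane — and fields are
normalised by refitting concentrations against the source matrix, rescaling
by robust maxima, and re-rendering through a reference matrix.

**Segmentation.**  A deterministic colour-deconvolution pipeline produces
the two mask products all downstream analysis consumes: a three-class
nuclei segmentation (Ki67⁺ / Ki67⁻ / background, DAB wins overlaps,
distance-transform watershed splits touching nuclei) and a binary epithelium
mask from the thresholded nuclear-density field.  The epithelial Ki67 index
is the **pixel-area ratio** of Ki67⁺ to Ki67⁻ nuclei within the epithelium
mask.

**Hotspot statistic.**  Nucleus centroids of one phenotype are binned into a
square grid (counts `x_i`).  For binary distance weights
`w_ij(d) = 1 iff d_ij < d` (`w_ii = 0`) the local Getis-Ord ratio and its
conditional-randomisation moments are

    G_i(d) = Σ_{j≠i} w_ij x_j / Σ_{j≠i} x_j
    E[G_i] = W_i / (n−1)
    Z_i    = (G_i − E[G_i]) / √Var[G_i]

with the canonical randomisation variance; cells with `Z ≥ 1.96` are
hotspots.  A seeded conditional-permutation null provides an independent
check of the closed-form moments.  The polarisation index is the fraction
of hotspot cells on the leading half (`u > 0.5`) of the lobule growth axis.

**Morphometry.**  400 × 230 µm count boxes are placed blind to staining and
classified central/peripheral by a fat-pad annulus rule; cells are counted
by the >50 %-inside rule with top/right edge inclusion for equivocal cells;
densities use the protocol normalisations (stromal macrophages per mm²
intralobular stroma, epithelial T per 100 luminal nuclei, stromal T per mm²
total stroma).  Macrophage periodicity is a run of ≥ 4 evenly spaced
(gap CV ≤ 0.3) intraepithelial macrophages, with spacing measured as arc
length along the duct.  Tertiary lymphoid structures are B-cell clusters
(DBSCAN) with a distinct adjacent T-cell zone.

**Statistics.**  D'Agostino K² normality is recorded per group; group
contrasts use the two-tailed Mann-Whitney test (exact for small tie-free
samples), and the central-vs-peripheral contrast a paired two-tailed t-test.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
fields and write their tables under `results/` (images under `scratch/`):

```sh
python analysis/01_simulate_fields.py
python analysis/02_stain_normalisation.py
python analysis/03_segment_ki67.py
python analysis/04_hotspot_polarisation.py
python analysis/05_immune_morphometry.py
python analysis/06_group_statistics.py
```

Representative output:

```
young: 927 cells (825 epithelial, Ki67+ fraction 0.316)
old:   982 cells (825 epithelial, Ki67+ fraction 0.137)
young/haematoxylin: angular error 0.91 deg
young/dab: angular error 0.80 deg
young: 918 nuclei (planted 927), Dice 0.970, Ki67 ratio 0.501
young_gradient: 1454 hotspot cells of 11684, polarisation index 0.733
flat_control:   1876 hotspot cells of 11684, polarisation index 0.525
inter-macrophage spacing: 60.4 um over 75 gaps (planted 60 um)
TLS: 2 qualifying structures in 4.37 mm^2 -> 0.457 /mm^2
inter_macrophage_distance_um: U=37691.0, p=2.64e-64
central vs peripheral (paired t): t=10.89, p=1.41e-07
```

Reading this: the stain matrix planted by the simulator is recovered to
within ~1° of arc; segmentation finds 918 of 927 planted nuclei with an
epithelium Dice of 0.97; with the planted leading-edge Ki67 gradient
(logistic slope 4) 73 % of hotspot grid cells sit on the leading half of
the growth axis, collapsing to ~0.5 when the gradient is removed; the
planted 60 µm macrophage spacing is recovered to ~1 %; and the young-vs-old
spacing contrast and the paired central-vs-peripheral macrophage density
contrast are strongly significant at study-scale animal numbers.

The same stages are scriptable via the CLI (`mamspat simulate|normalize|
segment|ki67-ratio|hotspot|stats|run-all`) or the library API
(`mamspat.pipeline.run_pipeline`).

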