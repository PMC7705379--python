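# Methods

This note documents the models, operators and design choices behind
`perivesiq`: what each stage computes, the assumptions it makes, and what
the synthetic benchmarks do and do not demonstrate.

## Perivascular punctum quantification

### Input model

The imaging pipeline ingests calibrated two-channel 3D stacks: a vessel
channel (UEA I lectin, staining the endothelial basement membrane) and a
punctum channel (claudin-5). The reference acquisition geometry is
1344×1024 px fields at 103.75 nm XY pixel size, 300 nm z-spacing, and
≥30 optical sections (a 9 μm deep field); any calibration can be supplied.
Stacks are assumed to be **deconvolved upstream** — deconvolution is
deliberately outside this package — which matters for the noise and PSF
regime the operators are tuned for (see *Phantom generator* below).

Axis order is fixed to (z, y, x); channels are stored separately and never
interleaved in arithmetic. Coordinates are 0-based voxel indices; physical
positions are voxel centre × voxel pitch.

### Detection chain

All detection operates on 8-bit images. 16-bit input is converted by
per-channel linear min–max rescale with half-up rounding (a constant
channel maps to 0). The chain is:

1. **Rolling-ball background subtraction** (radius 10 px, slice-wise).
   The background is the grayscale opening of each slice by a non-flat
   ball structuring function (Sternberg's formulation): erosion pushes the
   ball up under the intensity landscape, dilation traces its apex. The
   subtraction is clipped at 0 and bounded by the input. Note that
   `skimage.restoration.rolling_ball` computes only the erosion pass, so
   the opening is built from `scipy.ndimage` grey morphology and verified
   in tests against a direct-definition sliding-window oracle.
2. **CLAHE local contrast enhancement** (10 px square tiles, slice-wise),
   via `skimage.exposure.equalize_adapthist`. The clip parameter is
   expressed as a histogram slope limit (default 3.0, mapped to
   scikit-image's normalised `clip_limit` as slope/256). Constant slices
   are passed through unchanged.
3. **Binarisation at the background mean**: voxels strictly above the
   global mean of the processed stack are kept. The mean is computed over
   all voxels; a per-slice variant exists as an option.
4. **3D connected components** at 26-connectivity (configurable to 6/18),
   labelled deterministically in order of each component's minimum flat
   voxel index.
5. **Size exclusion**: components larger than 60 voxels are removed (the
   scale cut-off separating vesicle-sized puncta from larger structures);
   a lower bound (default 1) is also applied. Removed sizes are logged.

### Vessel geometry and distance classification

The vessel channel is thresholded (Otsu by default, fixed threshold
optional). Because the lectin stains the basement membrane — a shell —
"inside the vessel" must include the lumen: holes are filled in 2D slices
of **all three orthogonal slice families** and the union taken, followed
by a 1-voxel 3D closing. A vessel crossing the field is an open-ended
tube, so no single slice family sees its lumen as a closed hole; the
union over the three views closes any tube that crosses the field.

Signed distances are anisotropy-aware exact Euclidean distance transforms
with physical voxel sizes (z ≈ 2.89× the XY pitch): positive outside the
vessel (distance to the nearest vessel voxel), negative inside (distance
to the nearest surface voxel, where the surface is the set of mask voxels
with an outside 6-neighbour), zero on the surface itself.

Each detected spot takes the distance at its (rounded) centroid voxel —
a nearest-voxel option exists. Compartments:

- **luminal**: distance < 0 (strictly inside);
- **abluminal**, binned at 1 μm over [0, 5] μm (distance 0 falls in the
  0–1 μm bin; distance 5.0 in the 4–5 μm bin);
- **excluded**: beyond the 5 μm shell; counted separately and not part of
  any percentage.

Spot volume is voxel count × voxel volume (0.003230 μm³ at the reference
calibration, so a 6-voxel punctum is 0.0194 μm³). Per-field summaries
report counts, the luminal percentage of counted spots, the percentage
distribution of abluminal spots over the 1 μm bins, mean spot volume, and
the field mean gray value (0–255 for 8-bit input).

## Phantom generator

`simulate.make_vessel_phantom` renders a straight tube (radius 3 μm, wall
0.6 μm) along y through a 30×256×256 stack at the reference calibration,
with puncta placed at requested signed distances from the tube surface
and requested volumes (default draws: 0.017–0.022 μm³, i.e. 5–7 voxels).
Puncta are kept ≥1.5 μm apart: they model distinct vesicles, and the
separation keeps planted objects individually resolvable so that recovery
scores measure the detector rather than blob merging.

The optics model is a separable Gaussian PSF. The default widths
(σxy = 0.05 μm, σz = 0.15 μm) represent the **effective PSF of a
deconvolved stack** (roughly a two-fold resolution gain over raw confocal
widths of ~0.2/0.6 μm, which remain selectable for raw-like data). The
default noise model is likewise the deconvolved product: a small Gaussian
reconstruction residual (σ = 3 counts on a ~30000-count signal) over a
low baseline, with Poisson shot noise available as an option for raw
acquisitions. These two defaults are load-bearing: with raw-PSF widths a
6-voxel punctum blurs into a component far exceeding the 60-voxel cut,
and raw shot noise shatters blob tails into one-voxel false components —
both behaviours belong to un-deconvolved data, which this pipeline does
not claim to handle.

What the phantom does **not** emulate: diffuse parenchymal claudin-5
staining, curved or branching vessels, uneven illumination, spectral
bleed-through, and anisotropic or spatially varying PSFs. Passing the
recovery benchmarks therefore demonstrates correctness of the operator
chain on deconvolved, punctate data with clean backgrounds — not
performance on raw tissue images.

On this generator the full chain achieves, over 10 seeded phantoms × 20
puncta: detection sensitivity 1.00, zero false discoveries, signed
distance MAE ≈ 0.13 μm (below the 0.34 μm voxel diagonal), and exact
recovery of the planted 70/30 luminal/abluminal split. The measured blob
volume of a detected punctum (~0.17 μm³) exceeds its planted physical
volume because the global-mean threshold cuts the blurred spot at a low
isophote; distances and counts are unaffected.

## EV size statistics

Diameter samples are summarised by the arithmetic mean and the D10, D50
and D90 percentiles, using linear interpolation between order statistics
(the common NTA convention; the instrument's exact rule is undocumented).
Size-interval counts use half-open [lo, hi) μm bins — 0.1–1, 1–3, 3–6 by
default, the last bin closed at 6 μm — with out-of-window particles
reported separately, so counts always sum to n.

Group comparison runs one-way ANOVA with Tukey's HSD, or Kruskal–Wallis
with Dunn's rank test (tie-corrected, Bonferroni-adjusted over pairs) on
the non-parametric path. By default the path is chosen by a Shapiro–Wilk
gate per group at α = 0.05, overridable. Dunn's test is implemented
in-package (no installed library provides it); the two-group ANOVA is
algebraically the pooled-variance t-test (F = t²), which the tests verify
to 1e-10.

The diameter generator draws from a truncated log-normal mixture
(defaults: 60% at 120 nm median, 40% at 250 nm, σ_log 0.3–0.35, window
50–700 nm — an exosome + microvesicle mixture inside an NTA detection
window), by rejection so the window is exact.

## Proteomics multivariate analysis

Input is a proteins × samples abundance matrix with group labels; zeros
are missing values, and a protein needs ≥2 observed values per compared
group or it yields an NA record rather than an error.

- **Heatmap matrix**: per-sample log2 ratio to the reference-group
  (CNT) mean; a protein is retained when some group's mean differs from
  the reference by ≥1.2× in either direction. Proteins with an
  unobserved reference mean are dropped with a log entry.
- **Volcano**: log2 ratio of group means against one-way ANOVA p for the
  two groups compared (≡ t-test), flagged at p < 0.05 and fold change
  ≥ 2 (|log2FC| ≥ 1), with a label flag at |log2FC| > 1. No multiple-
  testing correction by default (the raw-p boundary is the convention
  reproduced here); Benjamini–Hochberg can be applied downstream.
- **PLS-DA**: NIPALS PLS2 of autoscaled X (centre + unit variance;
  constant variables dropped) against one-hot group indicators, default
  3 latent variables. Scores, weights, loadings and the regression vector
  are exposed; per-group 95% confidence ellipses on the first two score
  dimensions come from the group score covariance and the χ²(2) quantile.
  Autoscaling (rather than Pareto) is the chemometrics default; the
  scaling is configurable.
- **VIP**: VIP_j = √(p·Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a) with SSY_a
  the Y sum of squares explained by component a. The mean of VIP² over
  variables is exactly 1 — asserted for every fit.
- **sMC** (significance multivariate correlation): target-projection
  scores t_TP = Xβ/‖β‖, variable reconstruction x̂_j = t_TP p_TP,j, and an
  F-like ratio ‖x̂_j‖² / (‖x_j−x̂_j‖²/(n−2)). With multiple groups β is
  taken per one-vs-rest response, reported per response with an
  element-wise max aggregate; zero-residual variables report ∞.
- **Neighbor joining** (Saitou–Nei) on Euclidean distances between log2
  ratio profiles (samples or proteins), with deterministic lowest-index
  tie-breaking, emitted as Newick. Exact on additive matrices — verified
  against random edge-weighted trees and cross-checked against
  scikit-bio's implementation. Negative branch lengths are possible on
  non-additive inputs, as is standard for NJ.

The LFQ generator plants multiplicative group fold changes on a
log-normal baseline (log2-scale mean 20, SD 2, per-sample noise SD 0.25)
with optional missingness. Two calibration notes, both established
empirically and recorded here as design constraints of the benchmarks:
recovery tests plant folds at 2.5× because a fold planted exactly at the
2× decision boundary makes the flag a coin flip under any sampling noise;
and the cross-validated recovery test uses two groups whose two
informative variables are opposite markers, since a third group defined
only by the absence of markers is not reliably classifiable at n = 30
with 18 noise variables (scikit-learn's PLS scores the same ~83% there).

## Assay formulas

Closed-form metrics, applied exactly as defined:

- **Transcytosis %** = 100·(1.5·F_bl)/(a·F_ap + 1.5·F_bl), with apical
  volume factor a ∈ {0.5, 0.6} mL (default 0.5; both protocols occur) and
  1.5 mL basolateral. Bounded in [0, 100] (clamped against floating-point
  round-up only).
- **Cytotoxicity %** = 100·(A − low)/(high − low) from LDH absorbances;
  values outside [0, 100] are flagged, never clipped — they indicate
  control failure and the information is preserved.
- **ΔF/F0**: ΔF = F_frame − F_lowest (minimum over the whole trace),
  F0 = mean ΔF of the first five frames (the pre-stimulus baseline).
  A trace whose first five frames sit at the global minimum has F0 = 0
  and raises a degenerate-baseline error rather than returning infinities.
- **Fold change** = treated/untreated, vectorised; untreated 0 is an
  error.
- **Morphometrics**: a 2D field is binarised at a fixed threshold that
  the caller must supply (the same threshold must be used across
  conditions — it is an explicit argument for exactly that reason, and
  no default is derived from the image). The mask-low polarity (gaps in
  an F-actin image) is the default and configurable. Outputs: mask area
  as % of the field and the areas of 8-connected mask components; the
  component areas always sum to the masked pixel count.

## Numerical choices and degenerate inputs

- Half-up rounding for all 8-bit quantisation (ties away from the FIJI
  half-even convention are irrelevant at these bit depths but make the
  rule explicit and testable).
- Strictly-greater comparisons at both thresholds (background mean,
  vessel fixed threshold); the 60-voxel size cut is inclusive.
- Distance at 0 is "on the surface": assigned to the 0–1 μm bin, not
  luminal (luminal is strictly negative).
- Empty vessel mask: a warning plus an empty summary downstream, except
  `signed_distance_map`, which raises (a distance field to nothing is
  undefined).
- All-zero processed image → empty spot mask, no error.
- NIPALS stops early if a component degenerates (zero weight norm);
  requesting more components than the data support silently returns the
  supported number.

## Problem sizes

Benchmarks run at desk scale: 10 phantoms of 30×256×256 voxels for
recovery, 100 random ≤20³ masks for the distance oracle, 50 random 64×64
fields for the rolling-ball oracle, 200-protein LFQ matrices with 5
samples/group, 2000 replicates for null-p calibration. These sizes give
stable metrics (identical conclusions across seeds) while keeping the
full suite around a minute.

## Known limitations

- The detector is specified for deconvolved input; on raw noisy stacks
  the global-mean threshold and CLAHE interact badly (background
  percolates into the size-excluded giant component and sensitivity
  collapses). This is a property of the reimplemented chain itself, not
  of this implementation.
- Spot distances use the centroid voxel; for elongated spots straddling
  the vessel surface the nearest-voxel option can disagree.
- The luminal/abluminal split assumes the lumen can be closed by
  orthogonal hole filling; a vessel entering and leaving through the
  same stack face with strong curvature may fill incompletely.
- sMC for >2 groups has no canonical definition; the one-vs-rest
  decomposition with max aggregation is this package's choice.
- PLS-DA significance is not assessed (no permutation testing); VIP/sMC
  rank variables, they do not provide p-values.
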