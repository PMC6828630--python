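# Methods

`imsroi` implements a chemometric workflow for imaging mass spectrometry
(IMS): preprocess pixel spectra, discover anatomical regions with image
PCA, annotate them with region-based active-contour segmentation in PCA
score space, and rank the preprocessing methods objectively by the
cross-validated predictive quality (Q²Y) of OPLS-DA models built on the
segmented region classes. This note records the models, the numerical
choices, and the design decisions that were genuinely open.

## Data model

An IMS dataset is a `DataCube`: an `n_pixels × n_peaks` intensity matrix on
a common m/z axis plus a coordinate index mapping each spectrum row to an
(x, y) position on the acquisition grid (0-based, x = column). Acquisitions
need not be rectangular; grid positions without a spectrum carry a missing
marker (NaN in images, −1 in class maps) and are excluded from every
statistic, mean, and perimeter count. Processed-mode imzML input is
rebinned by summation onto a uniform axis (configurable bin width in Da)
because all downstream algebra requires a shared peak axis. The
tab-delimited export prints m/z at 4 decimals — beyond instrument precision,
and it makes the dialect bit-exact — and intensities at 9 significant
digits, so text round trips are exact for integers and < 1e-8 relative for
floats.

## Preprocessing

Transformations (`sqrt`, `ln`, `log10`) target heteroscedastic,
multiplicative noise; per-spectrum normalizations (`tic`, `median`, `mean`,
`rms`, `max`) target global per-pixel artifacts such as ionization and
matrix effects. Choices that the common definitions leave open:

* **Log of zero.** Logs use `log(x + offset)` with offset 1.0 by default,
  so zeros map to zero and order is preserved. The offset is a parameter;
  it must be positive for log transforms.
* **Median normalization** uses the median of *strictly positive*
  intensities. Sparse spectra can have an overall median of zero, which
  would make the scale undefined for most rows.
* **Combination order** is transform first, then normalize the transformed
  values (`ln-median` = ln, then median). The reverse order is available
  (`normalize_first=True`) but is not the default.
* Rows whose scale is zero or undefined (e.g. an empty spectrum) pass
  through unchanged and are logged as skipped, never dropped: dropping
  pixels would break the pixel ↔ grid correspondence.
* Normalizations scale each spectrum to a unit statistic (sum 1, max 1,
  RMS 1). Because every downstream model mean-centers its inputs, results
  are invariant to any global rescaling convention.

## Image PCA

PCA is computed on the mean-centered (never variance-scaled) pixels × peaks
matrix with a deterministic full SVD — no randomized solver — up to 25
components by default, deep enough to inspect the minor components where
low-abundance structures surface. Each loading is signed so its
largest-magnitude element is positive, making score images reproducible.
Per-component R²X is the explained variance fraction; score vectors
re-folded onto the grid are the score images used both for visual
inspection and as segmentation features.

## Active-contour segmentation

Region annotation minimizes the piecewise-constant (Chan-Vese) energy of a
binary mask on a multichannel feature image:

    E(mask) = mu * Perimeter(mask)
              + (1/C) * sum_c [ sum_in (u_c - c1_c)^2 + sum_out (u_c - c2_c)^2 ]

with per-channel inside/outside means c1, c2, equal channel weights, no
area term, and the perimeter counted as 4-neighbour in/out edges between
valid pixels. The minimizer is a boundary-restricted iterated-conditional-
modes scheme: each sweep visits the pixels adjacent to the current contour
in raster order and applies every single-pixel flip that strictly lowers
the exact energy (running sums make each trial O(C)). Consequences:

* energy is monotonically non-increasing and the evolution is
  deterministic — no level-set reinitialization, no time step;
* the contour can both grow and shrink, and needs no edge/gradient
  information;
* flips that would empty or fill the mask are refused; a seed that cannot
  move is returned with a warning;
* the returned mask's energy never exceeds the seed's. Hole filling and
  small-object removal run afterwards and are kept only if they do not
  raise the energy above the seed's.

Defaults: 30 sweeps (5–50 is the practical range), smoothing weight
mu = 0.2 (0.1–0.3 for roughly unit-variance features), hole filling on.
The energy is invariant under complementing the mask, so the minimizer is
unique only up to complement; seeds resolve the ambiguity.

**Feature channels.** Two-phase Chan-Vese finds the best *two-region*
piecewise-constant split of whatever features it is given. On a full score
stack the deepest energy wells belong to the largest anatomical contrasts,
so a rough seed of a thin structure (a 2-px band) can drift into a
neighbouring layer. `segment_rois` therefore selects, per ROI, the score
channel(s) in which the seed is most anomalous: the mean squared
standardized score over the seed pixels (default: the single best
channel). Unlike a seed-vs-rest mean contrast, this second moment stays
large when the seed only partially overlaps a thin high-contrast band,
because the overlapping pixels are extreme outliers of that channel's
distribution. With per-ROI channels, each region is the dominant contrast
of its own feature image and the band becomes the global attractor.

**Class maps.** Evolved ROI masks are assembled into a per-pixel class
map: a pixel in exactly one mask gets that label; pixels in several masks
(ambiguous) or in none are missing-class and are excluded from model
fitting, but still receive predicted scores afterwards. The overlap between
two binary maps is reported as Jaccard (|A∩B|/|A∪B|); Dice is also
available since the field uses both conventions.

## OPLS-DA and Q²Y

The class map becomes a 0/1 indicator Y-block (one column per class,
missing-class pixels excluded). X and Y are mean-centered, never scaled. A
single multiclass model is fitted (default: K−1 predictive components).
Orthogonal components are extracted first: for each one, a bilinear PLS2
component is fitted, its X-loading is projected onto the orthogonal
complement of the column space of XᵀY to give the orthogonal weight, and X
is deflated by the resulting component. By construction every orthogonal
score satisfies t_oᵀY = 0 exactly. Predictive components are then ordinary
PLS2 components (weights from the exact SVD of XᵀY — deterministic, no
iteration) on the filtered X.

Prediction of new pixels centers with the *training* means, applies the
training orthogonal filter, and projects through the rotation
W(PᵀW)⁻¹; training rows reproduce the fitted scores exactly. Missing-class
pixels get score values purely from the similarity of their spectra to the
class-assigned training pixels.

**Cross-validation.** Q²Y = 1 − PRESS/SS under deterministic venetian-blind
blocks (row i → block i mod 7, seven blocks by default). Each fold refits
the full model on the remaining rows; held-out Y is centered with training
means only, so there is no information leak, and identical inputs give
bit-identical metrics. The number of components to keep is chosen by a Q²
gain cutoff (default 0.01 per added component): the cutoff balances
sensitivity against overfitting, and lowering it admits weakly predictive
deeper components such as the one separating a thin minority class.

`evaluate_preprocessing` fits one model per preprocessing recipe on
identically labelled pixels with identical CV blocks and returns the table
sorted by Q²Y; per-recipe failures become table annotations rather than
aborting the comparison.

## Diagnostics

* **Heteroscedasticity index**: Spearman rank correlation between per-peak
  mean and per-peak sample SD within one ROI (zero-SD peaks excluded).
  Spearman rather than Pearson because intensity distributions are heavily
  right-tailed; a rank statistic is also invariant to monotone relabeling
  of the peaks. Near +1 under multiplicative noise, near 0 after a
  successful variance-stabilizing transform.
* **RSD**: SD/|mean| of one ion within one ROI, on the cube's current
  processing state. Sample SD (n−1) throughout the package.
* **Hotelling ellipse**: the 95% T² ellipse on two score columns uses the
  F-based critical value T² = 2(n−1)/(n−2)·F₀.₉₅(2, n−2); the reported
  quantity is the fraction of points strictly outside.
* **Box plots**: Tukey statistics of ROI-mean-centered intensities,
  quartiles by linear interpolation, whiskers at the most extreme points
  within 1.5 IQR.
* ROI variance statistics use all labelled pixels by default; no core
  erosion is applied before the calculation (an erosion radius can be
  emulated by refining the masks first).

## The phantom

The synthetic generator provides ground truth for every pipeline stage. It
emulates a cerebellar section as concentric curved bands on a 96×96 grid —
white matter core (WM), granular layer (GL), a 2-px Purkinje-cell layer
(PCL, the sensitivity challenge), molecular layer (ML) — with off-tissue
corners so non-rectangular handling is always exercised. Curved bands
rather than straight strips make the boundary-length penalty meaningful.

Each region has a fixed signature vector over 120 peaks: base intensities
log-uniform in 2000–20000 a.u. with mild region modulation (lognormal,
σ = 0.2), plus marker ions mirroring the lipid classes of real cerebellum
data — shared WM/GL markers (sulfatide-like), ML-specific markers
(ceramide-1-phosphate-like), GL-specific markers (PI 38:3/38:2-like) and
one PCL-exclusive marker (PI 38:4-like, 60000 vs 100 a.u.). Intensities
are generated as

    I_ij = g_i * mu_{r(i),j} * exp(sigma_mult * eps_ij) + |sigma_add_j * eta_ij|

with per-pixel gain g_i = exp(sigma_gain · ζ_i) (lognormal, σ = 0.25 —
the global ionization/matrix artifact that normalization is meant to
remove) and heteroscedastic multiplicative noise σ_mult = 0.3. The
additive floor is half-normal, per peak (1% of the peak's maximum
signature), and exists only to keep intensities positive: it is small
relative to every peak everywhere, so the noise stays
multiplicative-dominated. That placement is deliberate — a floor that is
large relative to the weak peaks would reintroduce a mean-dependent SD in
log space and the ln transform could no longer stabilize the variance, an
effect the diagnostics would (correctly) report. All randomness flows from
one integer seed through a single generator; same seed, bit-identical
cube.

`perturb_seeds` degrades the true region masks into "rough outline" seeds:
4-connected erosion by a configurable number of pixels plus a random
integer shift. A seed must remain an outline of its region, so if an
erosion would leave less than ~20% of a region (a 2-px band erodes to a few
scattered pixels, or to nothing), the erosion falls back per-ROI to the
largest value that keeps the outline, with a warning; a strict mode raises
instead.

**What the phantom does not emulate:** peak shapes and m/z profiles,
isotope patterns, detector saturation, baseline drift, spatial noise
correlation, partial-volume mixing at layer boundaries, and section-to-
section biological variability. Passing tests therefore show that the
algorithms are correct and that the pipeline behaves as designed under
multiplicative noise and gain artifacts — not that any particular
preprocessing choice is optimal for a given real dataset.

## Problem sizes and runtime choices

The test suite and the acceptance script run the full study conditions
(96×96 grid, 120 peaks, ≈ 7400 tissue pixels) where the contract demands
them — segmentation recovery, variance stabilization, ranking — and a
geometrically similar 48×48 phantom (≈ 1800 pixels) where only algebraic
correctness is at stake. Cross-validated rankings cap the orthogonal
component search at 2; the exhaustive Chan-Vese oracle enumerates all 2¹⁶
masks of a 4×4 instance. The acceptance script averages stochastic
quantities over 5 phantom noise realizations derived from its `--seed`.

## Known limitations

* Two-phase segmentation evolves one ROI at a time (one seed per region,
  as in the workflow it implements); it is not a joint multiphase
  segmentation, and overlaps are resolved only at class-map assembly.
* The ICM minimizer is greedy: it guarantees monotone descent and attains
  the global optimum on the exhaustively checkable instances, but like
  every Chan-Vese scheme it can stop in a local minimum for adversarial
  seeds.
* Q²-gain component selection emulates the common commercial rule only
  through its cutoff parameter; the exact proprietary significance rule of
  SIMCA-style software is not reproduced.
* Class imbalance is not reweighted; with a 2-px band as one of four
  classes, per-class fit quality should be inspected alongside the global
  metrics.
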