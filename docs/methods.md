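# Methods

This note documents the models implemented in `osteounit`, the defaults and
why they were chosen, what the synthetic phantoms do and do not emulate, and
the numerical choices that matter when reproducing results.

## Packaged species table

`osteounit/data/species_table.tsv` lists 16 records for 15 species (6
aquatic, 9 terrestrial): average body mass (kg), average articular cartilage
thickness of the humeral head (mm), and per-modality specimen counts. Two
records (Shetland pony and horse) share the binomial *Equus ferus caballus*;
species counting deduplicates on the binomial. Masses for the two largest
whales use thousands notation in the original source and are stored as
47,300 and 48,000 kg. The file is checksum-pinned; a corrupted fixture
raises `FixtureIntegrityError` rather than silently loading.

Known internal inconsistencies of the source are preserved, not resolved:
the per-row modality counts sum to 34/29/20 while the source's prose refers
to 85 animals in one place and 84 samples (30 for micro-CT) in another; and
the rat/whale thicknesses quoted in the source's running text (209 µm,
7660 µm) differ from its table values (0.21 mm for the rat; 6.51 mm sperm
whale, 7.53 mm fin whale). The packaged fixture follows the table.

## Stress-relaxation model

A cylindrical cartilage plug is compressed (default protocol: 0.01 N
preload, ramp at 10 µm/s to 15 % strain, 900 s hold; specimen geometry per
sample) and the stress decay during the hold is modelled as

σ(t) = A₁·e^(−t/τ₁) + B₁ (t < t_split), A₂·e^(−t/τ₂) + B₂ (t ≥ t_split),

with t = 0 at the end of the ramp and t_split = 100 s. Stress is force over
the unloaded cross-section (kPa); strain is platen displacement over
unloaded thickness. Peak stress is the record maximum; equilibrium stress
is the mean over the final `eq_window` (default 100 s) of the hold; the
moduli are these stresses divided by the applied strain. The ramp is
recorded but never fitted.

**Constraints and reparameterisation.** The fit minimises the RMSE between
model and measured stress subject to (i) σ(0) = A₁+B₁ = σ_peak, (ii) the
model's mean over the final equilibrium window equals the measured σ_eq,
and (iii) branch continuity at t_split. The constraints are eliminated
exactly: free parameters are (A₁, τ₁, τ₂); B₁ = σ_peak − A₁, and for any
τ₂ the pair (A₂, B₂) is the unique solution of (ii)+(iii), which are linear
in A₂ and B₂. Bounded least squares (scipy `least_squares`, trf) runs from
five log-spaced τ₁ initialisations (τ₂ = 8·τ₁) and keeps the lowest-cost
solution. On noiseless synthetic curves all six parameters are recovered to
better than 1e-3 relative and constraint residuals are at machine precision.

Form (ii) deserves a remark: constraining the *window mean* of the model
(rather than its endpoint value) to σ_eq makes the constraint exactly
satisfiable by the generating parameters of a synthetic curve, because
σ_eq is itself a window mean. An endpoint constraint would make the true
parameters infeasible whenever the slow exponential has not fully decayed.

**Precision under noise.** The constrained estimator is unbiased for the
time constants, but its per-record precision is limited by the anchors:
because the fitted curve is forced through the *measured* peak and
equilibrium stresses, noise in those measured anchors propagates into τ₂.
Monte-Carlo on the terrestrial preset (τ₂ = 300 s, 900-s hold, 1 Hz, noise
2 % of peak stress) puts the median per-record |τ₂| error at ≈ 5 % (τ₁:
≈ 2 %); with oracle noiseless anchors it would be ≈ 2 %. Studies needing
tighter slow-phase estimates should lengthen the hold relative to τ₂ or
average fits across replicates.

**Degenerate inputs.** A constant trace fits with A₁ = A₂ = 0 and
B₁ = B₂ = σ. Curves shorter than t_split, or with fewer than 10 samples per
branch, are rejected. Scale equivariance holds exactly: scaling stress by c
scales all amplitudes by c and leaves both time constants unchanged.

## Fiber orientation and zonal segmentation

**Angle convention.** 0° = fibers parallel to the articular surface (image
x-axis), ±90° = perpendicular; orientations live on (−90°, 90°] with 180°
periodicity. Images are laid out surface-up (row index grows with depth).

**Spectral directionality** (`directionality_histogram`). The image is
Hann-windowed, the 2-D power spectrum computed, DC removed, and radial
frequencies below 4 cycles/image (illumination gradients) and above 0.45 of
Nyquist (pixel noise) excluded. Spectral energy is binned by structure
orientation (spectrum angle rotated 90°) into 2° bins and normalised to
unit mass. The anisotropy score is the resultant length of the
doubled-angle circular distribution (0 isotropic, 1 perfectly aligned);
constant images yield a uniform histogram flagged `low_signal`. Sinusoidal
gratings are recovered within one bin across the half-turn, and rotation of
the image shifts the histogram by the same angle within one bin.

**Peak areas** (`integrate_peaks`). A constant baseline plus two wrapped
Gaussians with fixed centres (0° and ±90°, the ±90° pair sharing
parameters across the wrap) is fitted to the histogram by bounded least
squares; the areas are the fitted peak weights as fractions of total mass
(a 0.7/0.3 mixture at SD 10° is recovered within ±0.02). If the fit fails
the areas fall back to direct summation over ±22.5° windows, flagged via
`method`. Dominant orientation away from both centres triggers a warning.
The source material does not state the normalisation of its peak areas;
fractional area of total mass is used here.

**Depth profiles** (`depth_profiles`). The image is cut into n horizontal
bands (default 40); per band the modal orientation and the mean intensity
(birefringence proxy) are recorded. Per-band orientation uses a *gradient*
orientation histogram (structure orientation perpendicular to the local
intensity gradient, votes weighted by squared gradient magnitude, after a
1-px Gaussian pre-smooth) rather than the spectral estimator: depth bands
are ~10 px tall by hundreds wide, and a 10-row FFT has essentially no
vertical frequency resolution (the window main lobe spans the usable band),
which systematically distorts oblique textures. Spectral and gradient
estimators share the angle convention and agree within a few degrees on
full-size textures; both are standard directionality estimators in
image-analysis practice.

**Segmentation** (`segment_layers`). The middle/deep boundary is the start
of the shallowest run of `plateau_window` consecutive bands (default 10 %
of bands) whose modal angle stays within `plateau_tol` (default 10°) of
90° — the deep-zone plateau. The superficial/middle boundary is the global
minimum of the median-smoothed (5 bands) birefringence profile above that
plateau. If no plateau exists the section is returned as "unstratified"
with no boundaries — the expected outcome for isotropic, aquatic-like
cartilage. Layer fractions are the boundary depths expressed as percent of
section thickness and always sum to 100.

## Bone morphometry

**Bernsen thresholding.** Per 2-D slice (matching common micro-CT
practice), the local threshold is (local max + local min)/2 within a
circular window (default radius 15 px); where the local contrast falls
below `contrast_threshold` (default 15 on the 8-bit scale) the voxel is
assigned foreground iff the local mid-gray ≥ `midgray` (default 128). On a
two-level image this reduces exactly to the global midpoint threshold; on a
ramp-illuminated lattice phantom it recovers ≥ 99 % of voxels.

**BV/TV** is foreground over total voxels in the VOI, in percent; it is
bounded in [0, 100], invariant to padding outside the mask, and satisfies
complement symmetry.

**Trabecular thickness** is the model-independent local thickness: per
foreground voxel, the diameter of the largest sphere fully inside the
structure that contains it. Implementation: Euclidean distance transform
(EDT), distance-ridge reduction (a voxel is dropped when a neighbour's
maximal sphere contains its own), then sphere painting in descending radius
order with ties resolved toward the larger sphere. Because the EDT measures
distance to the nearest background voxel *centre* while the solid surface
sits half a voxel closer, the thickness assigned by a sphere of EDT radius
r is 2r − 1 voxels; painting uses radius r so boundary voxels inherit their
maximal sphere. Validation: a radius-20 ball reads 39.05 voxels (true
discrete diameter within one voxel), 5-voxel plates read exactly 5.0, and
voxel-refinement (same geometry sampled 2× finer) changes the thickness in
µm by < 2 %. Thickness never decreases under morphological dilation.
Volumes are assumed isotropic; the volume border is treated as a structure
continuation, so structures should not touch the border (the packaged
generators keep clear of it).

**VOIs.** The subchondral VOI is a slab starting at the first slice
containing bone along the interface axis, spanning a depth fraction
(default 5 %); the trabecular VOI is a centred box spanning a fraction
(default 40 %) of each dimension. The defaults are exposed as parameters;
they must not overlap. The original VOI geometry used for the in-vivo data
was not reconstructable, so fixed-fraction defaults are used.

## Allometric statistics

Power laws are fitted as OLS of log₁₀(response) on log₁₀(mass) — the
standard in the scaling literature — giving the exponent a (slope),
prefactor b = 10^intercept, R² of the log-log regression and a 95 % CI on
a. Fits require n ≥ 3 strictly positive values; a CI wider than 0.5 flags
weak mass leverage. The exponent is invariant under mass unit changes. On
the packaged table this reproduces the reported per-habitat statistics from
species-average data: aquatic a = 0.26, terrestrial R² = 0.80 (2 dp). The
overall-fit values reported for the full per-specimen dataset (a = 0.28,
R² = 0.91) come out as 0.29/0.88 from species averages and are therefore
treated as approximate, not asserted.

Group comparisons run one-way ANOVA plus either all-pairs t-tests with
Bonferroni adjustment (p_adj = min(1, m·p)) or Tukey's HSD, with per-group
Shapiro–Wilk and across-group Levene checks reported alongside. Degenerate
inputs (identical groups, zero-variance groups) return F = 0 / p = 1 with
an exact-tie warning rather than NaNs.

## Synthetic phantoms: what they emulate

All generators are seed-deterministic (identical parameters + seed ⇒
bit-identical output) and return their ground truth.

* **Relaxation curves** are the piecewise model itself plus additive white
  Gaussian noise, sampled at 1 Hz over the 900-s hold. Branch continuity of
  the truth is enforced at construction
  (`RelaxationTruth.from_fast_phase`). Presets: terrestrial-style (peak
  3.5 kPa, τ₁ = 8 s), aquatic-style (peak 1.8 kPa, τ₁ = 40 s), both
  τ₂ = 300 s. Not emulated: ramp dynamics, drift, temperature effects,
  poroelastic radial flow.
* **Orientation images** are oriented-noise textures: white noise whose
  angular spectrum is reweighted by a von Mises law (concentration κ;
  κ = 0 → isotropic) around the layer's modal angle, stacked in
  surface-to-deep layer bands, with a V-shaped per-row brightness dip of
  width 6 % at the superficial/middle border as the synthetic
  birefringence minimum. Habitat presets jitter the true superficial and
  deep fractions by N(0, 2 points) per seed to emulate per-specimen
  variation (terrestrial 10/35/55 %, aquatic 12/58/30 % on average). Not
  emulated: real retardance optics, staining variability, chondrocyte
  lacunae, curved arcades within the middle zone (the transition is a
  piecewise-constant 45° band). Passing tests therefore show estimator
  correctness on textures with known statistics, not histology-grade
  realism.
* **Trabecular volumes**: periodic orthogonal rod lattices (pitch solved
  from the inclusion-exclusion solid fraction 3πr²/p² − 8√2·r³/p³, so the
  analytic fraction is stored as truth), parallel plates (count and
  placement chosen to hit the target fraction with no border contact), or
  Gaussian random fields thresholded at the exact target quantile
  (geometric truth empirical). An optional dense band over the top depth
  fraction emulates the presence of a subchondral plate; the aquatic-style
  preset omits it. Not emulated: scanner artifacts (beam hardening, ring
  artifacts), cortical shells, marrow contrast.
* **Allometric tables**: log-uniform masses and y = b·Mᵃ with
  multiplicative lognormal noise of coefficient of variation `noise_cv`
  (mean-one correction applied).

## Problem sizes used in the test suite

Tests and the demo pipeline run on sizes chosen to keep the full suite
under a minute on a laptop core while leaving every estimator in its
asymptotic regime: 512² orientation phantoms (50 depth bands), 96³–160³
volumes for morphometry, 901-point relaxation records, 50-seed Monte-Carlo
for the noisy-recovery checks. All results quoted above are computed by the
test suite or the worked examples, not transcribed from elsewhere.

## Known limitations

* The Fourier directionality estimator needs tens of rows; for thin bands
  the gradient estimator is used (see above). Neither measures
  out-of-plane fiber inclination.
* Local thickness is exact for sphere-representable geometry but inherits
  half-voxel surface ambiguity; sub-voxel struts are not resolvable.
* The piecewise relaxation model is phenomenological; it does not identify
  poroviscoelastic material constants, and τ₂ precision is anchor-limited
  (see above).
* Species-average regressions understate within-species variance; no
  phylogenetic correction (PGLS) is applied.
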