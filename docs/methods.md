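# Methods

This note documents the models implemented in `sonogold`, the assumptions
behind them, the defaults and why they were chosen, and what the synthetic
data do and do not establish about real instrument data.

## Study design emulated by the generators

The pipeline targets a 4 × 3 factorial design: GNP-treated cells are exposed
to 40 kHz ultrasound for 0, 5, 10 or 20 min and fixed 0, 3 or 24 h after
irradiation. Because particles are administered 3 h before irradiation, the
fixation times map to t = 3, 6 and 27 h on the treatment clock; t = 0 is GNP
administration, and the kinetic fits anchor a noiseless zero at t = 0
(no intracellular particles before treatment).

## Mass-to-particle conversion

ICP-AES reports the gold mass concentration of the digested, diluted sample.
The per-cell particle count is

    N_np = C_m[g/L] · V_sample · N_A / (M_Au · N_Au · N_C)

reported on the ×10⁴-particles-per-cell scale. The effective sample volume
is V_sample = 0.010 L: 2 mL of digested sample diluted 5-fold to 10 mL, so
diluted concentration × 0.010 L equals the gold mass — equivalently,
dilution-adjusted concentration × 0.002 L. This reconstruction was validated
against the bundled reference table: with the default constants the
conversion slope is 0.79412 ×10⁴ particles per cell per mg/L, and 11 of the
12 reference cells agree with the printed conversions within ±0.01 after
rounding to 2 decimals. The remaining cell (20 min group, 6 h) differs by
0.02, consistent with the printed concentration having been rounded to
2 decimals before the conversion was originally computed; the reference
verification reports this cell honestly as a failure.

The conversion is exactly linear in C_m; `N_Au = 3 849 991` is the atom
count of a ~50 nm gold sphere and `N_C = 10⁶` the plated cell count. All
constants are overridable through `KineticConstants`.

## First-order uptake kinetics

Uptake is modelled as `Y(t) = A_max(1 − e^(−kt))` with `A_max` fixed, not
estimated: the observed mean at the latest sampling time (27 h) is taken as
the maximum uptake capacity. This deliberately mirrors the parsimony
argument of the underlying experimental analysis — with the origin anchor
plus three sampling times and one free parameter, inference on k runs on
df = n − 1 = 3 — even though the model then slightly under-predicts the
anchor point itself. Consequences of this construction:

* k is estimated by least squares with k ≥ 0, using a coarse geometric grid
  to bracket the optimum before bounded refinement (the SSE flattens to a
  plateau once the exponential has saturated at every sampling time, which
  starves pure golden-section searches of signal).
* `se_k` comes from the linearized Jacobian `∂Y/∂k = A_max · t · e^(−kt)` at
  the optimum with residual variance SSE/df.
* R² is centered on the mean of all fitted observations, origin included —
  the only convention consistent with df = 3 on the 4-point series.
* `p_k` is the two-sided t-test of k = 0; `p_model` an F-test of the fit
  against the constant-mean model with (1, df) df. The distinction the
  reference table draws between its two p-values is not fully specified
  there; this package's F-test construction reproduces their order of
  magnitude but is not claimed to match cell-for-cell.
* Fitting on group means (default) or on all replicates is a flag.

Calibration of the uncertainty was checked by simulation: across 200 seeded
series (k ∈ [0.05, 0.5], replicate noise 0.05 mg/L, A_max fixed at its true
value so the linearization is correctly specified), the median relative
error of k̂ is below 10% and the nominal 95% interval k̂ ± 1.96·se_k covers
the truth at a rate inside [90%, 99%].

## Label-free cluster segmentation

Pixels of a min–max-normalized reflectance image are clustered by K-means on
intensity (k = 3 by default: background, cytoplasmic reflectance, bright GNP
signal; 10 seeded restarts). Foreground is the **intersection** of the
brightest K-means cluster with pixels above the 0.95 intensity quantile —
the conservative combination of clustering and thresholding. Components are
8-connected; components under 4 pixels are discarded as noise. Cluster size
is the equivalent circular diameter in µm; group statistics pool clusters
across a group's images (the large reported SDs are only consistent with
per-cluster pooling, not per-image means).

Detection limits worth stating explicitly:

* The minimum-component filter imposes a floor of ~2-pixel equivalent
  radius: at 0.2 µm/pixel, clusters below ~0.45 µm equivalent diameter
  cannot be recovered. Count-recovery tests therefore sample scenes at
  0.1 µm/pixel so every drawn cluster lies above the floor; on real data the
  floor truncates the size distribution from below and biases pooled means
  upward.
* The quantile threshold assumes foreground occupies less than
  `1 − threshold_quantile` of the frame (5% by default). Scenes dominated by
  bright area defeat it.
* A constant (all-background) image returns an empty mask; an image with
  more than one but fewer than k distinct intensities raises a degenerate-
  clustering error.

Exposure–size association is summarized two ways, as in the underlying
analysis: Pearson r on individual cluster sizes (weak by construction, since
within-group variance dominates) and OLS R² of the four group means on a
linear and a quadratic polynomial of exposure time. For degree 1,
R² = r² identically.

## Log-normal size fitting

Histograms (right-open fixed-width bins spanning the observed range; 5 nm
default for NTA-scale data, 0.1 µm for cluster sizes) are fitted with
`A · LogNormalPDF(x; μ, σ)` by Levenberg–Marquardt on the bin centers,
matching the curve-fit framing of NTA software rather than raw-sample MLE.
Positivity of σ and A is enforced by optimizing their logarithms, with the
exponentials clamped so divergent steps produce large finite residuals
rather than overflow. Initialization uses the histogram-weighted log-moments
(deterministic). At least 3 occupied bins are required; non-convergence
within the iteration cap is reported via `converged=False`, and callers
should additionally check that the fitted mode lies inside the observed
range — a size distribution truncated at the detection floor can be monotone
decreasing, in which case the least-squares "log-normal" degenerates to a
power-law-like tail with a mode at zero. The modal diameter is the closed
form `exp(μ − σ²)`.

## Sonoporation morphometry

Voxels of a refractive-index tomogram are classified by band: membrane
1.33–1.34, nucleus 1.35–1.36, lipid droplets > 1.37, with remaining cell
voxels (above a configurable background RI, default 1.335) as cytoplasm.
The cell surface used for the area-to-volume indicator is the outer
iso-surface of the cell support (the RI-band-restricted membrane shell is
available behind a flag, since whether "membrane area" means the outer
surface or the shell is genuinely ambiguous).

Surface area is computed by marching-cubes triangulation at the 0.5 level of
the zero-padded binary mask after smoothing with a 1-voxel Gaussian.
The smoothing is load-bearing: iso-surfacing a raw 0/1 field inflates a
digitized sphere's area by ~9% (and naive voxel-face counting by ~50% — kept
in the package only as a negative control), while the smoothed estimator is
accurate to ~0.3% across radii 5–20 µm at 0.25 µm voxels. Volume is voxel
count × voxel volume. Disconnected masks are measured on their largest
component with a warning.

## Synthetic-data generators

All generators take explicit seeds; the study-level generator spawns an
independent `SeedSequence` stream per modality, so generating any subset of
modalities reproduces exactly the values of the full bundle.

* **Diameters**: i.i.d. log-normal, median `exp(log_mu)`.
* **Reflectance scenes**: clusters are filled disks of the stated equivalent
  diameter (real cluster morphology is irregular, but disks make the ground
  truth "equivalent diameter" well-defined for recovery tests), placed
  uniformly in a cytoplasmic annulus by rejection sampling with a
  10 000-attempt budget. Overlap is allowed by default (and flagged in the
  ground truth, since overlapping disks may merge into one component);
  non-overlapping placement is available for recovery tests. Scenes are
  blurred with a Gaussian PSF (σ = 0.1 µm, matching ~200 nm lateral
  resolution) and corrupted with additive Gaussian noise clipped to [0, 1] —
  the simplest noise model with a controllable SNR; real reflectance noise
  statistics are not public, so this is a choice, not a fact. Defaults:
  1024 × 1024 px at 0.2 µm/px, 60 clusters, control-group sizes with median
  0.45 µm and log-σ 0.74 (chosen so pooled mean ± SD lands near the reported
  0.597 ± 0.514 µm), irradiated-group medians scaled by the reported mean
  ratios (0.809/0.779/0.829).
* **Uptake series**: the first-order law plus Gaussian replicate noise
  (0.15 mg/L, mid-range of the reference SDs). Per-group conditions are the
  rate constants obtained by fitting the reference group means once
  (k = 0.150/0.151/0.107/0.158 h⁻¹) with asymptotes equal to the 27 h means.
* **Cell masks**: radially perturbed spheres `r(θ,φ) = R + A·s(θ,φ)` with
  `s` a seeded band-limited sum of sinusoids bounded in [−1, 1] (azimuthal
  frequencies integral for continuity). Default R = 8 µm with 5% per-cell
  variability (clipped at 2 SD to fit the grid), 0.25 µm voxels on a 96³
  grid. The roughness amplitudes for irradiated groups — 2.4 µm immediately
  after irradiation, 1.95 µm at 3 h, 0 at 24 h — were calibrated once so the
  default masks show the ~17% / ~11% / ~0% A/V elevation time course of
  sonoporation, and then frozen.

What the synthetic data do **not** emulate: real cluster morphology and
spatial clustering of clusters, structured cytoplasmic reflectance texture,
optical artifacts (the axial blur that superimposes perinuclear particles on
the nucleus in 2D projections), membrane pores as discrete structures, and
instrument-level noise spectra. Passing the recovery tests therefore shows
the estimators are correct for their stated models, not that the models
capture every property of real images.

## Problem sizes

Tests and the analysis drivers run reduced problem sizes chosen as sensible
desk-scale defaults: 512 × 512 or smaller scenes, 4 images per group and 8
cells per condition in the demo study (`demo_study_config`), 48³–96³ voxel
grids, 200 kinetic simulations and 1000 null ANOVA simulations. The full
study defaults (1024 × 1024 scenes, 10 images per group, 15 cells per
condition) remain the package defaults for real-scale runs.

## Known limitations

* The K-means feature space is intensity only; texture features are out of
  scope.
* Segmentation is strictly 2D; no z-stack handling or axial-blur correction.
* The log-normal fit is unweighted least squares; Poisson-weighted fitting
  of count histograms is not implemented.
* Absolute A/V values depend on voxel size and smoothing; the indicator is
  meaningful as a within-study comparison, which is how it is used.
* The NTA total-concentration figure is instrument-reported; the package
  only books user-supplied concentrations and does not model flow or
  exposure.
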