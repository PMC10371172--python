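# Methods

This note documents the models implemented in `chancluster`, the defaults
and units of their parameters, what the synthetic-data generators do and do
not emulate, the numerical choices, and the known limitations. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Stochastic self-assembly of membrane clusters (`assembly_sim`)

**Model.** Channels occupy sites of a 2D square lattice with periodic
boundaries. One simulation step applies, in order:

1. *Nucleation* — with probability `P_n`, one channel is inserted at a
   uniformly random empty site.
2. *Growth* — each existing cluster, independently with probability `P_g`,
   recruits one channel at a uniformly random empty perimeter site
   (4-neighborhood). At most one site per cluster per step.
3. *Removal* — every channel is removed independently with probability
   `P_r`.

Clusters are the 4-connected components of the occupancy grid, recomputed
when needed; components merge implicitly when growth or nucleation makes
them adjacent. At steady state the nucleation/growth/removal balance yields
an exponential cluster-size distribution, consistent with the exponential
(Poisson-process) size distributions observed for KV2.1 and CaV1.2 clusters
in membranes.

**Parameters.** `P_n`, `P_g`, `P_r` are per-step probabilities in [0, 1].
The shipped defaults (`P_n=0.5, P_g=0.2, P_r=0.02`) are plausible
placeholders flagged `UNVERIFIED_FROM_SUPPLEMENT = True` in the module:
published parameter tables for the source datasets were not available, so
the defaults were chosen once to give a well-mixed steady state (removal
time constant 1/P_r = 50 steps, mean cluster size ≈ 10 sites on a 128²
lattice) and are not tuned to any dataset. Physical calibration is optional
via `area_per_site` (default one site = one 20 nm render pixel = 400 nm²).

**Update-rule provenance.** The exact update rules of the original
stochastic self-assembly treatment are described in literature supplements
not reproduced here; the rules above are a faithful reconstruction of the
nucleation/growth/removal framework. The event order within a step
(nucleation → growth → removal) is a documented convention; the
order-sensitive bookkeeping invariant (occupancy change = insertions −
removals, exactly, every step) is tested.

**Steady-state detection** compares mean total occupancy over consecutive
windows (default 200 steps) and stops when the relative change drops below
`tol` (default 5%). Monotonically growing systems (`P_r = 0`) terminate at
the `n_steps` cap with the convergence flag unset; note that on a finite
lattice slow growth or saturation can legitimately plateau.

**Exponential fit.** The maximum-likelihood scale of a left-shifted
exponential is `mean(size − min_size)`. By default `min_size` is the sample
minimum — correct for lattice sizes whose support starts at one channel.
For segmented image sizes, whose physical support starts at zero but whose
observed minimum is the resolution/quantization floor (one pixel or two
voxels), pass `min_size=0`; subtracting the floor would bias the scale down
by roughly floor/scale (≈15% for 2500 nm² areas rendered at 20 nm/px).
Goodness of fit is the R² of an ordinary least-squares line through the
log-transformed positive histogram counts (default 25 bins); log-linearity
of the histogram is the operational check that a single exponential
describes the sizes. Sparse tails make single-run histograms noisy, so the
tests pool cluster sizes over a few seeds (≈3,000 clusters) before
computing R², mirroring the large-lattice setting at desk scale.

**Parameter recovery** is a grid search minimizing the mean two-sample
Kolmogorov–Smirnov distance between the observed sizes and ≥3 replicate
simulations per candidate; ties break toward smaller `P_n`, then `P_g`.

**Problem sizes.** Tests and examples run 96–128² lattices for 800–2,000
steps (16–40 removal time constants, comfortably past equilibration),
chosen as the package's desk-scale working sizes; larger lattices sharpen
the histograms but do not change the steady-state statistics.

## Synthetic data (`synthetic_data`)

**What is emulated.** (a) 2D localization-microscopy renders: clusters with
exponentially distributed areas placed uniformly without overlap on a 20
nm/px canvas; (b) confocal-like stacks (default 100 nm lateral pitch, 0.13
µm z-step) with exponentially distributed cluster volumes, optionally
confined to a membrane shell near the volume boundary (the WGA-mask
geometry); (c) sparklet fluorescence traces k(t)·ΔF + Gaussian noise at 100
Hz from the coupled-gating model; (d) raw exponential size samples.

**Rendering model.** A cluster is painted as the `round(size /
pixel_or_voxel_size)` pixels/voxels nearest its center (at least one) —
area/volume-matched painting, so rendered sizes track drawn sizes without
the ±1-pixel jitter of a center-inside rule. The render is then optionally
blurred by a Gaussian PSF and corrupted by additive Gaussian noise.
Defaults: 2D renders use `psf_sigma_nm=0, noise_sd=0`, because localization
renders are exported by acquisition software as thresholded, near-binary
images; stacks use `psf_sigma_nm=50, noise_sd=0.02`. The 50 nm sigma is a
*sub-voxel residual* blur on top of the 100 nm voxel quantization: the
design requirement on the generator is that rendering preserve size
statistics through the package's fixed-threshold segmentation, and blurs
much wider than a voxel make naive voxel-count volumes threshold-dependent
(inflated at low thresholds, eroded at half-maximum). That bias is a real
property of fixed-threshold particle analysis and can be reintroduced by
raising `psf_sigma_nm`.

**What is not emulated.** Photophysics (blinking, localization precision,
drift, chromatic effects), Poisson shot noise, non-uniform background,
cluster shape irregularity, and overlap between clusters (placement is
non-overlapping by rejection, ≤1,000 retries, with a 2-pixel margin).
Passing round-trip tests therefore demonstrates correctness of the
measurement chain on well-posed inputs, not robustness to every real-image
artifact.

## Cluster morphometry (`cluster_metrics`)

Segmentation uses a single fixed manual threshold per image set;
connectivity is 26 (3D) / 8 (2D), matching common particle-analysis
defaults. 3D components are discarded if smaller than two voxels or smaller
than the minimum physical extents (defaults 100 nm in x/y, 150 nm in z,
both configurable; note a single 0.13 µm z-slice fails the 150 nm rule).
Membrane restriction keeps clusters with ≥1 voxel inside the mask
(`any-overlap`, default) or with their centroid voxel inside
(`centroid-inside`). All outputs are in physical units (µm³ / nm²; voxel
centers, 0-based indices internally).

**Macro/micro classification.** Macro iff volume **strictly** exceeds the
cutoff. The default cutoff is 0.03 µm³; 0.025 µm³ also appears in the
source analyses and is accepted via `MacroThreshold(0.025)`. The
sphere-equivalent diameter is d = (6V/π)^(1/3) (optionally rounded to 10
nm): 0.09 µm³ → 560 nm. Two internal inconsistencies of the source
description are surfaced rather than resolved: (i) 0.03 µm³ corresponds to
385 nm by sphere geometry, not the quoted 326 nm (326 nm ↔ 0.018 µm³);
(ii) a "mean − 2 SD" derivation with mean 0.09 and SD 0.32 is negative on
the linear scale, so the transform behind the quoted derivation is unknown.
The package implements the closed-form geometry and the configurable cutoff
and does not guess the intended transform.

**Resolution-matching blur.** `gaussian_blur_match` replaces each pixel by
a Gaussian-weighted average of its neighbors within `kernel_radius_nm`
(default 200 nm, the confocal resolution scale): sigma = radius/2, kernel
truncated at the radius, reflect padding. Total intensity is conserved to
better than 1e-6 (relative); two point sources 160 nm apart merge into one
supra-half-maximum component while sources 400 nm apart remain resolvable,
reproducing the micro-/macro-cluster appearance transition between
super-resolution and confocal imaging.

**GSD density convention.** "Clusters per micron" of footprint is reported
as clusters per µm² (`density_per_um2`); the footprint area is the
reference passed by the caller.

## Sparklet analysis (`sparklet`)

**Generative coupling model.** N two-state channels per site. Per frame,
with probability κ a coordination event forces all channels into one common
state (open with probability p); otherwise each channel draws its state
independently. This realizes the defining endpoints exactly — κ=0
independent, κ=1 all-or-none — and keeps the per-channel marginal open
probability at p for every κ, giving the closed-form frame likelihood

    P(k) = κ[(1−p)𝟙{k=0} + p𝟙{k=N}] + (1−κ)·C(N,k) p^k (1−p)^(N−k).

The published expanded derivation of the coupled Markov chain (and whether
its κ is defined per transition or per frame) was not available; this
frame-wise mixture is a documented reconstruction, and `coupling_model:
"frame-wise coordination mixture"` is recorded in analysis output metadata.
Frames are treated as exchangeable — no dwell-time kinetics — so κ is a
per-site summary, not a kinetic rate; the frame histogram of k is a
sufficient statistic, which makes likelihood evaluation O(N) per candidate
κ.

**Estimation.** κ̂ maximizes the mixture likelihood over [0, 1] (bounded
1D optimization with endpoint checks; the log-likelihood is concave in κ).
p defaults to the moment estimate mean(k)/N, consistent for every κ because
the marginal is preserved. Confidence intervals are percentile bootstrap
over frames (default 500 resamples). Degenerate all-identical series return
a boundary estimate with a warning. With 20,000 frames at p=0.1, recovery
error |κ̂−κ| is well under 0.05 across κ ∈ [0,1] and N ∈ {2,3,4} (tested).

**Idealization and activity.** k(t) is the nearest integer in [0, N_max] to
trace/ΔF (nearest-integer quantization rather than an HMM — simpler and
adequate at sparklet signal-to-noise, where noise ≈ 0.2 ΔF gives <2% frame
misclassification). The quantal amplitude ΔF, when not supplied, is
estimated by profiling a 1D Gaussian mixture with equally spaced means
(spacing = ΔF, weights and common sigma profiled out by EM) over the
all-points histogram; traces with no events (peak-to-peak below six robust
noise SDs, estimated from successive differences) raise an error advising a
manual ΔF. nPs = Σₜ k(t)/T, the time-averaged open-channel count (the
n·Ps decomposition's product); sites are classified high-activity iff
nPs ≥ 0.2, with the boundary counting as high (documented convention; the
source states the cutoff without a tie rule).

**Not implemented.** Spatial detection of sparklet sites from TIRF movies
(the original detection operators are not described); analysis starts from
per-site traces.

## KV2.1 current model (`kv_current`)

**Model.** One activation gate x with Boltzmann steady state x∞(V) =
1/(1+exp(−(V−V½)/k)) and bell-shaped time constant τ(V) = τ_base +
τ_amp/cosh((V−V½)/2k); optional first-order inactivation gate. Current
density I/Cₘ = f·g_max·x(t)[·y(t)]·(V−E_K) in pA/pF, strictly linear in
both the functional fraction f and g_max.

**Defaults and units.** V½ = +9 mV, k = 9 mV, τ_base = 2 ms, τ_amp = 20 ms
— placeholders in the right range for a delayed rectifier, flagged
`UNVERIFIED_FROM_REF_MODEL = True`: the absolute gating/conductance
parameters of the source electrophysiology model live in cited work not
reproduced here. The calibration workflow makes all reported densities
independent of these placeholders at steady state: `calibrate_gmax`
rescales g_max (closed form, since I ∝ g_max) so the f=1 late-current
density at a reference voltage matches a supplied value, after which
scaled-fraction predictions follow exactly from linearity. E_K defaults to
the Nernst potential of the whole-cell recording solutions (5 mM K⁺ out,
87 + 20 = 107 mM K⁺ in) at 295 K: −77.9 mV. (A −84 mV figure sometimes
associated with these solutions is not consistent with the Nernst equation;
the computed value is used, and E_K is configurable.)

**Protocol and integration.** Default protocol: hold −70 mV, 500 ms steps
from −70 to +70 mV in 10 mV increments; the late current is the mean over
the final 10% of the step (the measurement window is a documented choice).
Fixed-step RK4 with dt = 0.05 ms; the contract is dt-invariance (halving dt
changes densities by <0.01%, tested) and an error if dt > τ_min/10.
`ry785_subtract` is a pointwise trace difference (blocker-sensitive current
isolation); negative excursions are preserved.

**Known non-linearity in the source.** Published 0.1%-functional densities
(5.57 / 16.7 pA/pF) are sub-linear relative to the 1% values (70.1 / 173);
a strictly linear model cannot and does not reproduce them (possibly
integer channel-count rounding upstream). They are deliberately not targets
of this package.

## Pipeline (`pipeline`, `cli`)

Per-stage seeds are SHA-256(global_seed, stage_name) mod 2³¹ — stable
across versions; all randomness flows through one seeded generator per
stage. The run manifest records the package version, config hash, per-stage
seeds, and a SHA-256 checksum of every output file; identical config + seed
reproduces bit-identical outputs (tested, including TIFF bytes).

## Limitations

- The assembly update rules, the coupled-gating generative form, and the
  KV2.1 gating placeholders are reconstructions where primary parameter
  tables/derivations were unavailable; each is flagged in code and above.
- Segmented sizes are voxel/pixel counts; with PSFs much wider than a
  voxel they become threshold-dependent (see rendering model) and a
  half-maximum or deconvolution-based sizing would be needed.
- The κ estimator assumes the frame-wise mixture; data generated by a
  kinetic (dwell-time) coupling scheme with the same endpoints could yield
  a different κ scale.
- The whole-cell model contains only the KV2.1 conductance: no other
  currents, Ca²⁺ handling, or free membrane potential.
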