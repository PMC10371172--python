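# chancluster

Tools for the quantitative analysis of ion-channel clustering and its
functional consequences in excitable cells, built around four linked
questions that arise when studying KV2.1 and CaV1.2 channels in arterial
smooth muscle:

1. **How do membrane channel clusters form?** Channel clusters in the
   plasma membrane show exponentially distributed sizes — the hallmark of a
   Poisson process — suggesting stochastic self-assembly. A lattice
   simulator with per-step nucleation (P_n), cluster growth (P_g) and
   channel removal (P_r) probabilities reproduces such steady-state size
   distributions, and a grid-search fitter maps an observed distribution
   back to the probabilities that generated it.
2. **How big are the clusters?** Segmentation of confocal stacks and
   super-resolution (GSD/TIRF) renders with the standard particle-analysis
   rules: fixed manual threshold, 26/8-connectivity, minimum two voxels,
   minimum 100 nm (x/y) and 150 nm (z) extent, restriction to a WGA-stained
   membrane mask. Cluster volumes are classified as **macro** (> 0.03 µm³)
   or **micro**; sphere-equivalent diameters follow d = (6V/π)^(1/3), so
   the mean macro-cluster volume of 0.09 µm³ corresponds to 560 nm.
3. **Do the channels gate cooperatively?** Ca²⁺ sparklet traces (100 Hz)
   are idealized to per-frame open-channel counts k(t); site activity is
   nPs = Σₜ k(t)/T, split into low/high at an nPs cutoff of 0.2. Coupling
   among the N channels of a site is summarized by κ ∈ [0, 1] (0 =
   independent gating, 1 = all-or-none), estimated by maximum likelihood
   under a coupled Markov chain model in which each frame is, with
   probability κ, a coordinated event forcing a single common state:
   P(k) = κ[(1−p)𝟙{k=0} + p𝟙{k=N}] + (1−κ)·Binomial(N, p).
4. **Does clustering matter for conduction?** A Hodgkin–Huxley-type KV2.1
   current model, I/Cₘ = f·g_max·x(t)·(V−E_K), with a functional fraction
   f scaling the conducting channel pool. After calibrating g_max to a
   reference current density, the model predicts the whole-cell density at
   any f — the comparison that shows fewer than 1% of membrane KV2.1
   channels conduct in arterial myocytes.

All inputs can be produced by the built-in synthetic-data module (seeded
TIFF stacks, localization renders, membrane masks, sparklet traces with
known ground truth), so every stage is testable end to end without any
external data.

## Worked example

```python
import numpy as np
from dataclasses import replace
from chancluster.synthetic_data import FieldSpec, gen_confocal_stack
from chancluster.cluster_metrics import (segment_3d, restrict_to_membrane,
    MacroThreshold, classify_macro_micro, sphere_diameter_from_volume)
from chancluster.assembly_sim import fit_exponential
from chancluster.kv_current import (KvModelParams, VoltageProtocol,
    calibrate_gmax, iv_curve)

# a synthetic myocyte-like stack: 200 membrane clusters, exponential
# volumes with mean 0.09 um^3, confined to a 1 um membrane shell
spec = FieldSpec(width_nm=15000, height_nm=15000, depth_um=6.0,
                 pixel_nm=100.0, voxel_z_um=0.13, psf_sigma_nm=50.0,
                 noise_sd=0.02, seed=42)
stack, mask, truth = gen_confocal_stack(spec, 200, 0.09, shell=1.0)

clusters = segment_3d(stack, (100.0, 0.13), threshold=0.3, min_diameter=(0, 0))
clusters = restrict_to_membrane(clusters, mask)
fit = fit_exponential(clusters.sizes, min_size=0.0)
macro, micro = classify_macro_micro(clusters, MacroThreshold(0.03))
print(f"clusters detected: {len(clusters)} (200 simulated)")
print(f"exponential mean volume: {fit.scale:.3f} um^3 (truth 0.09)")
print(f"macro fraction (>0.03 um^3): {macro:.1f}%  micro: {micro:.1f}%")
print(f"sphere diameter of mean volume: {sphere_diameter_from_volume(fit.scale):.0f} nm")

# functional-fraction scaling of the KV2.1 current at +50 mV
protocol = VoltageProtocol(step_mVs=(50.0,))
params = calibrate_gmax(KvModelParams(), 7006.0, 50.0, protocol)
for f in (1.0, 0.5, 0.1, 0.01):
    d = iv_curve(replace(params, f_functional=f), protocol).at(50.0)
    print(f"f = {f:>5}: {d:8.1f} pA/pF at +50 mV")
```

prints

```
clusters detected: 197 (200 simulated)
exponential mean volume: 0.088 um^3 (truth 0.09)
macro fraction (>0.03 um^3): 70.6%  micro: 29.4%
sphere diameter of mean volume: 550 nm
f =   1.0:   7006.0 pA/pF at +50 mV
f =   0.5:   3503.0 pA/pF at +50 mV
f =   0.1:    700.6 pA/pF at +50 mV
f =  0.01:     70.1 pA/pF at +50 mV
```

The segmenter recovers the simulated cluster count within a few percent and
the exponential mean volume to ~2%; the current model, once calibrated at
f = 1, predicts the scaled densities exactly (the current is linear in f).

## Command line

```
chancluster make-synthetic {field|stack|sparklets|sizes} --seed N --out-dir DIR
chancluster simulate-assembly --config params.json --seed N --out sizes.csv
chancluster fit-assembly --observed sizes.csv --grid grid.json
chancluster analyze-clusters --image stack.tif --mode 3d --threshold 0.3 \
    --voxel 100 0.13 --macro-thr 0.03 --mask mask.tif
chancluster sparklets simulate --kappa 0.5 --n 3 --p 0.1 --frames 20000 --seed 1
chancluster sparklets analyze --traces traces/ --nmax 4 --cutoff 0.2
chancluster iv-sim --fraction 0.5 --fraction 0.1 --calibrate-to 7006@50
chancluster demo --seed 1 --out-dir demo_out
```

`chancluster run --config run.yaml` executes a multi-stage pipeline under a
single global seed and writes a manifest (config hash, per-stage seeds,
checksums of every output) so runs are bit-identical on repetition.

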