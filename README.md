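# axondiff

Monte-Carlo diffusion simulation and time-dependent diffusivity analysis
in synthetic axons with caliber variation ("beading").

## The problem

Diffusion MRI probes brain tissue at millimeter resolution, yet the
along-axon diffusion coefficient D(t) measured at clinical diffusion
times t ≈ 10–100 ms carries a signature of *micrometer*-scale axonal
morphology. When caliber restrictions (beads, varicosities, swellings at
mitochondria) are randomly placed along an axon with a finite correlation
length — short-range disorder in one dimension — coarse-graining theory
predicts the power-law approach

    D(t) ≃ D∞ + c · t^(−ϑ),    ϑ = (p + d)/2 = 1/2,

where the structural exponent p = 0 is read off the low-k plateau of the
1d power spectrum of cross-sectional-area fluctuations, and the amplitude
c measures the strength of restrictions. Axonal beading changes in many
pathologies (multiple sclerosis, traumatic brain injury, ischemia), which
makes (D∞, c) candidate microstructural biomarkers.

`axondiff` implements the full computational chain needed to study this
mechanism without any microscopy or MRI data:

* **`axondiff.substrate`** — synthetic 3d axons: gamma-renewal bead
  placement, cosine-lobe caliber profiles r(z), volume normalization,
  undulating skeletons, voxelized labeled volumes (exterior / axoplasm /
  mitochondrion), the comparison scenarios (caliber-only, undulation-only,
  straight, ± mitochondria), and Watson orientation sampling.
* **`axondiff.morphometry`** — cross-section series from labeled volumes,
  1d fluctuation power spectra Γ_1d(k), restriction statistics (ā, σ_a),
  the plateau relation Γ_1d/ā = (σ_a²/ā²)(l̄²/ā²) and its inversion for
  the restriction width l̄.
* **`axondiff.walk`** — continuous-space random walk with fixed step
  √(6 D δt), specular reflection at membranes, min(1, √(D₂/D₁)) permeation
  at the mitochondrial interface, mirrored boundaries, optional T2
  weighting, and full second/fourth displacement-moment accumulation.
* **`axondiff.cumulants`** — apparent D(t), K(t) along any direction by
  tensor contraction, ensemble averaging over axons, analytic orientation
  dispersion via the direction-reflection identity, cumulant signal
  synthesis S(b, t), and the weighted-linear-least-squares DKI estimator.
* **`axondiff.timedep`** — OLS fits of D(t) = D∞ + c/√t (optionally
  + c′/t for dispersed bundles), one-sided slope significance, ensemble
  parameters, the dispersion scaling ⟨cos²θ⟩, ζ = (D₀−D∞)/D∞ versus
  CV²(r), and the one-sided Wilcoxon signed-rank test.
* **`axondiff.io` / `axondiff.pipeline` / CLI** — NIfTI volumes, CSV
  profiles/moments/cumulants, validated YAML configuration, JSON run
  manifests, and an end-to-end driver.

Intended users: diffusion-MRI microstructure researchers who want a
transparent, tested reference implementation of the beading signature and
a phantom generator to exercise their own estimators.

## Worked example

Generate a calibrated beaded axon, run the walk, and fit the power law:

```python
import numpy as np
from axondiff import substrate as sb, walk as wk, cumulants as cm
from axondiff import timedep as td, morphometry as mm

spec = sb.BeadSpec()  # abar=5.70, sigma_a=2.88, lbar=5.6 um, calibrated amplitude
profile = sb.beaded_profile(L=40.0, spec=spec, dz=0.1, seed=7)
stats = mm.caliber_stats(profile)
print(f"CV(r) = {stats.cv:.3f}, mean radius = {stats.mean_r:.3f} um")

vol = sb.voxelize(profile, h=0.15)
cfg = wk.SimConfig(dt=0.075**2 / 12, n_walkers=8000,
                   sample_times=np.linspace(5, 80, 12), seed=1)
rec = wk.run_walk(vol, sb.CompartmentProps(), cfg)

series = cm.cumulant_series(rec, np.array([0.0, 0.0, 1.0]))
fit = td.fit_power_law(series.t, series.D, window=(20, 80))
print(f"D_inf = {fit.D_inf:.3f} +- {fit.D_inf_se:.3f} um^2/ms")
print(f"c     = {fit.c:.3f} +- {fit.c_se:.3f} um^2 ms^-1/2")
print(f"one-sided p (positive 1/sqrt(t) slope): {fit.p_value:.1e}")
```

Output (a few minutes on one CPU):

```
CV(r) = 0.241, mean radius = 1.147 um
D_inf = 1.474 +- 0.023 um^2/ms
c     = 0.923 +- 0.150 um^2 ms^-1/2
one-sided p (positive 1/sqrt(t) slope): 4.3e-04
```

Read: along this beaded axon the apparent axial diffusivity is still ~14%
above its asymptote at t = 20 ms and relaxes as 1/√t toward
D∞ ≈ 1.5 µm²/ms, well below the intrinsic D_a = 2 µm²/ms — restrictions
both slow the long-time diffusion and imprint the t^(−1/2) transient. The
same pipeline applied to a straight cylinder of equal volume returns
c statistically indistinguishable from zero.

The same chain is available from the shell:

```bash
axondiff run-all --config config.yaml --seed 1 --out run1/
axondiff fit-dt --in roi_table.csv --window 20 80 --out fits/
```

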