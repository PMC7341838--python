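# Methods

`axondiff` simulates water diffusion inside synthetic three-dimensional
axons and analyzes the resulting time-dependent diffusion MRI observables.
Its scientific core is the link between *structure* — how caliber
restrictions (beads, varicosities) are placed along an axon — and
*dynamics* — the power-law approach of the along-axon diffusivity to its
long-time limit,

    D(t) ≃ D∞ + c · t^(−ϑ),   ϑ = 1/2.

A t^(−1/2) tail is the fingerprint of short-range disorder in one
dimension: the dynamical exponent is ϑ = (p + d)/2 with d = 1 and
structural exponent p = 0, where p characterizes the k → 0 behavior of the
power spectrum of the restriction density, Γ(k) ~ k^p.

## Substrate model

An axon is an axially symmetric tube of radius r(z) around a (possibly
undulating) centerline:

* **Restriction placement.** Caliber maxima form a renewal process with
  gamma-distributed spacings of mean ā and SD σ_a (gamma: positive
  support, both first moments free; the data this emulates constrain only
  those two moments). σ_a = 0 degenerates to a periodic lattice. The first
  restriction carries a uniform phase so the process is stationary.
* **Bead shape.** Each restriction adds a unit-height cosine lobe of FWHM
  l̄, truncated at ±l̄, to the fractional radius:
  r(z) = r₀ (1 + A Σ_k g((z − z_k)/l̄)). Overlapping beads superpose
  linearly in radius; adjacent maxima closer than l̄ merge into one — a
  property shared by any smooth unimodal bump.
* **Defaults.** ā = 5.70 µm, σ_a = 2.88 µm, l̄ = 5.6 µm are the published
  restriction statistics of segmented myelinated axons in mouse corpus
  callosum. The bump amplitude is *not* identifiable from those statistics
  (an acknowledged free parameter of the generator); it was calibrated
  once so the generated ensemble reproduces the published normalized
  spectral plateau Γ_1d/ā ≈ 0.25 of the same axons, giving A = 1.2 at
  r₀ = 0.5 µm (CV(r) ≈ 0.27, inside the observed per-axon range). With
  heavily overlapping l̄ ≈ ā bumps, small amplitudes (A ≲ 0.3) produce a
  nearly smooth tube with ~6× weaker disorder than the measured axons.
* **Scenarios.** From one profile the generator derives the comparison
  geometries: the full tube with (I) or without (II) mitochondria,
  the straight axially symmetric tube with the same A(z) (III, "caliber
  variation only"), a constant-CSA tube following the σ_s = 1 µm
  Gaussian-smoothed skeleton (IV, "undulation only"), and a straight
  constant-radius cylinder of equal volume. Scenario IV is voxelized as
  the set of voxel centers within one radius of the 3d curve
  (cross-sections perpendicular to the skeleton) and the radius is
  corrected by a few fixed-point iterations so the *voxelized* volume
  matches the source volume to 1×10⁻³ relative — plain analytic radii
  leave O(h²) discretization error above that tolerance.
* **Mitochondria.** Rods (cylinders along z, radius 0.25⟨r⟩, length
  1–2 µm) are placed with axial acceptance probability proportional to the
  local cross-sectional area until the target volume fraction f_m
  (default 6%) is reached. This is a generative stand-in for the observed
  coupling "mitochondria sit where axons are thick"; the data constrain
  the correlation, not a mechanism.
* **Voxelization.** A voxel belongs to the tube iff its center is inside
  (half-open convention); default h = 0.1 µm for morphometry, 0.15 µm for
  desk-scale simulation substrates. Cross-sectional areas recovered from
  voxel counts converge to πr² first-order in h.

## Random-walk engine

Walkers take fixed-length steps √(6 D δt) in isotropic random directions,
with D the intrinsic diffusivity of the compartment they occupy
(axoplasm D_a = 2 µm²/ms, mitochondria D_m = 0.13 µm²/ms; T2 80/20 ms).

* **Boundaries.** A step landing in the exterior is specularly reflected
  off the crossed voxel face(s); axis-aligned faces preserve the
  tangential displacement exactly, which keeps axial diffusion in a
  straight tube unbiased. (Pure step rejection — the walker waits — was
  measured to bias axial D by ≈ −3.5% in a radius-1 µm cylinder at step
  0.1 µm and to mimic a spurious time dependence; it remains only as the
  corner-case fallback when no reflected image stays inside.)
* **Permeation.** Crossing the axoplasm–mitochondrion interface is
  accepted with the highly-permeable-membrane transit probability
  min(1, √(D_to/D_from)), else the walker reflects. Acceptance is
  whole-step (the remainder is not rescaled). A continuous 1d oracle shows
  this fixed-step scheme carries an O(step) occupancy artifact localized
  at flat interfaces (≈ +1.2% in the slow compartment at step 0.05 µm
  across a 40 µm slab, halving with step); it is negligible for µm-scale
  mitochondrial inclusions at the default steps.
* **Mirroring.** All box faces are handled by triangle-wave folding of the
  coordinate for the label lookup while the true displacement accumulates
  unfolded; the finite tube therefore behaves as an infinite mirrored
  medium along z, and an all-axoplasm box is exact free space.
* **T2 weighting.** Optional trajectory weight exp(−Σ δt/T2(label)),
  applied at each sampling time. The weighted second/fourth displacement
  moments are accumulated at sample times (all 6 + 15 unique tensor
  components, so cumulants along *any* direction can be evaluated after
  the fact).
* **RNG.** SplitMix64 streams keyed by (seed, walker index): results are
  independent of execution order and reproducible bit-for-bit.
* **Step-size choices.** Desk-scale default is step = h/2 (δt = step²/6D_a,
  e.g. 4.7×10⁻⁴ ms at h = 0.15 µm) — coarser than the reference
  2×10⁻⁴ ms; a convergence-in-δt test verifies halving δt does not shift
  D. Two discretization facts matter for tests: a fixed-step walk has
  exactly known negative excess kurtosis ~ −6/(5 n_steps), so Gaussianity
  is only asserted at sample times ≥ 10³ steps; and the interface artifact
  above sets the slab-equilibrium test's step.

## Cumulants and dispersion

Apparent diffusivity and kurtosis along n̂ are moment contractions
D = ⟨s²⟩/2t and K = ⟨s⁴⟩/⟨s²⟩² − 3 with s = n̂·x. Ensemble quantities
follow from the O(b), O(b²) terms of the multi-compartment cumulant signal
S(b,t) = Σ f_i exp(−bD_i + b²D_i²K_i/6): D = ⟨D_i⟩ and
K = D⁻² Σ_i [3f_i(D_i − D)² + f_i D_i² K_i], reported with its
inter-/intra-axonal split. The DKI estimator is weighted linear least
squares on ln S with weights S² (the standard choice that undoes the
log-transform distortion; iterating the weights changes nothing for
noiseless synthetic signals).

Orientation dispersion is applied analytically: an axon tilted along n̂′
contributes, measured along the bundle axis ẑ, its own-frame cumulants
along the reflected direction n̂ = 2(n̂′·ẑ)ẑ − n̂′. Directions are drawn
from the axially symmetric Watson density ∝ exp(κ cos²ψ) (rejection
sampling; ⟨cos²ψ⟩ by quadrature; θ ≡ acos√⟨cos²θ⟩ maps κ = ∞, 15.4, 4.7,
1.65 to 0°, 15°, 30°, 45°). Both D∞ and c of a dispersed bundle scale as
⟨cos²θ⟩; for strong dispersion the transverse 1/t tail of tilted axons
leaks into the axial projection, which the three-term fit
D = D∞ + c/√t + c′/t absorbs.

## Fitting and statistics

D(t) is fit by OLS against 1/√t over t = 20–80 ms by default (bounded by
the ~18 µm axon length of the emulated data via τ_L = L²/2D₀ ≈ 80 ms);
ϑ is held at 1/2, with a free-exponent fit available as a diagnostic only.
Significance of time dependence is the one-sided t-test of a positive
slope. Ensemble (D∞, c) are volume-weighted means of per-axon fits
(equivalently, by linearity, the fit of the volume-weighted D(t)).
Paired comparisons use the one-sided Wilcoxon signed-rank test (exact
null for n ≤ 15, normal approximation beyond, zeros dropped; the smallest
attainable p at n = 5 is 1/2⁵ = 0.03125). The relative diffusivity
reduction ζ = (D₀ − D_{i,∞})/D_{i,∞}, with D₀ = (1 − f_m)D_a + f_m D_m,
is regressed against CV²(r) — a first-order coarse-graining relation valid
for small ζ.

## Structural spectra

The 1d spectrum of a profile is the rectangular-window periodogram of the
CSA fluctuations, Γ_1d(k) = |δA(k)|²/(V·Ā), in units of µm. The sample
mean is subtracted before the DFT (flag to disable): the theory concerns
the correlator of fluctuations, and at finite length the spectral leakage
of the mean otherwise swamps the plateau. The plateau and exponent are
estimated over (2π/L, 0.5/ā]; short-range disorder is declared for
|p| < 0.3. The closed-form plateau Γ_1d/ā = (σ_a²/ā²)(l̄²/ā²) is a
*first-order* statement in the restriction density; for the radius-bump
generator the width entering it is the effective width
l_eff = v₀/Ā (excess bead volume over mean CSA). Measured plateaus match
this prediction to ~10–15% at small amplitude (A ≤ 0.1 wide beads,
A ≤ 0.5 narrow beads); by A = 0.3 with overlapping beads the quadratic
terms already push the discrepancy to ~30%, and at the calibrated A = 1.2
the closed form is out of its validity range (the calibration therefore
targets the *measured* plateau). The ~10% residual at small amplitude is
the k-window bias of the renewal structure factor, which rises from its
k → 0 plateau over the default window.

## What the synthetic data do and do not show

The generator emulates the published restriction statistics, volume
normalization, caliber–mitochondria coupling, and orientation dispersion
of real white-matter axons. It does not emulate: non-circular
cross-sections, myelin, the extra-axonal space, axon-to-axon diameter
distributions, or any within-axon correlation between spacing and bead
height. Passing tests therefore demonstrate the *mechanism* (caliber
variation ⇒ 1/√t tail; undulation alone ⇒ none) and the correctness of
the estimators, not a quantitative match to any particular tissue.

## Problem sizes

Test-suite simulations use 60 µm tubes at h = 0.15–0.2 µm with
10⁴–2×10⁴ walkers (moments to t = 80 ms), 10⁵ walkers for free diffusion,
and 50-seed ensembles for spectral statistics. At these sizes the beaded
substrate's fitted c carries ≈ 6 standard errors; the amplitude-sweep and
spacing comparisons share the study substrate's seeds (common random
numbers) and are sized so each asserted ordering carries ≥ 2 standard
errors of margin at the chosen seeds.

## Known limitations

* Endpoint voxel-label membrane detection (no sub-voxel ray tracing):
  accuracy is O(step/h), controlled by step = h/2.
* The O(step) interface-occupancy artifact of the fixed-step permeation
  scheme (above).
* The closed-form plateau and the ζ ∝ CV² relation are perturbative;
  the calibrated study substrate sits beyond their strict validity, as do
  strongly beaded pathological axons.
* Kurtosis time dependence is reported but no power-law is fit to K(t)
  (the emulated axon length bounds usable diffusion times).
* The fitted c over a fixed window is *not* monotone in bead amplitude
  indefinitely: by amplitude ≈ 2 the deep constrictions push the
  asymptotic regime beyond the 20–80 ms window and the apparent slope
  falls (measured c ≈ 0.4 at amplitude 2.2 versus ≈ 0.8 at 1.2) even as
  D∞ keeps dropping. Amplitude-ordering statements are therefore made in
  the moderate-beading regime (amplitude ≤ 1.2), and comparisons across
  restriction spacings use the common 20–80 ms window where both
  substrates are past their correlation times — at earlier times the
  wider-spaced substrate is still pre-asymptotic and its apparent slope
  underestimates c.
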