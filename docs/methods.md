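# Methods

`dermafiber` quantifies the 3D microarchitecture of dermal collagen and
elastin fibers from two-channel multiphoton z-stacks (SHG for collagen, TPEF
for elastin) and relates it to the uniaxial stress–strain response of the
same tissue. This note documents the models, the numerical choices, and what
the synthetic validation does and does not establish.

## Coordinate conventions and calibration

Stacks are `(z, y, x)` with `x` the stretch axis. The azimuth θ is measured
from +x in the imaging plane and is axial (π-periodic, range [0°, 180°)); the
polar angle φ is measured from +z, so φ = 90° is in-plane. Raw acquisitions
cover a 500 µm field at 0.5 µm/px laterally; the dark border is cropped
centrally to 400 µm (1000×1000 → 800×800 px). The axial step is nominally
1 µm, but the refractive-index mismatch between immersion oil (n = 1.518) and
skin (n = 1.37) compresses the true focal displacement: the actual depth is
half the apparent depth, giving isotropic 0.5 µm voxels after correction. The
halving is stored as an explicit factor with both indices kept as metadata.

Contrast-limited adaptive histogram equalization is applied per z-plane
(tile 64 px, clip limit 0.01 — exposed in configuration; the plane-wise
choice mirrors 2D processing of each optical section). Density measurements
use raw intensities by default, because equalization shifts the stack mean
that the density threshold is tied to; a switch allows enhanced input.

## Orientation estimation

For every voxel brighter than 0.45× the stack mean (the same relative
threshold used for the fiber mask, so that orientation statistics and
density refer to the same voxel population) an 11×11×11 window is projected
by maximum intensity onto the xy, xz and yz planes. In each projection,
every candidate direction d ∈ {1°, …, 180°} through the window center is
scored

    w(d) = L(d) · max(0, 1 − CV(d)),

where L(d) is the length of the contiguous above-threshold chord through the
center and CV(d) the coefficient of variation of intensity along it: long,
evenly bright chords are fiber-like, short or flickering ones are not. The
per-projection angle is the doubled-angle weighted resultant,
½·atan2(Σ w sin 2d, Σ w cos 2d), the standard axial-data vector summation;
it is noise-robust where an argmax over d is not. This weight functional is
the module's canonical realization of "length × intensity-fluctuation"
weighting; it is pluggable.

The xy angle is θ; the xz and yz angles β and γ give the out-of-plane tilt
through tan²φ = 1/tan²β + 1/tan²γ, with the limits φ = 90° when either
projection is horizontal (in-plane fiber) and φ = 0° when both are vertical
(fiber along z). That formula alone yields φ ∈ [0°, 90°], which would make
the z-component of the orientation center of mass a mean of non-negative
terms — a disordered stack would then score a spuriously high orientation
index (≈0.44 in simulation). The tilt *sign* is, however, recoverable for
axial data: fixing the in-plane representative (cos θ, sin θ) determines the
sign of u_z from the quadrant of β (tan β = u_z/u_x) or of γ (tan γ =
u_z/u_y), whichever projection is better conditioned. The estimator
therefore returns a signed φ ∈ [0°, 180°], under which the sign-index rule
in the summary statistics cancels symmetric tilts and pure noise scores
3DOI < 0.05.

Border voxels without a full window are invalid (padding would fabricate
structure); windows in which no direction carries weight are invalid.

## Directional summary and 3DOI

With b = tan φ, the center of mass of the axial orientation distribution
reduces to

    C̄ = ⟨sin φ · cos 2θ⟩,  S̄ = ⟨sin φ · sin 2θ⟩,  Z̄ = ⟨SI · |cos φ|⟩,

where SI is the sign of (90° − φ) with SI = +1 at φ = 90°, and averages run
over valid voxels. The 3D orientation index is the mean resultant length
√(C̄² + S̄² + Z̄²): 0 for disordered, 1 for perfectly aligned fibers. The main
in-plane angle is ½·atan2(S̄, C̄), folded to [0°, 90°] when only the angle to
the stretch axis matters (θ → 180° − θ above 90°). Whether sub-threshold
voxels should enter these sums is ambiguous in principle; this package sums
over valid (above-threshold) voxels only, since background voxels carry no
orientation.

Aggregate θ distributions use 180 one-degree bins spanning (0°, 180°], per
z-layer (each layer normalized to 1, empty layers flagged) and summed and
renormalized across layers.

## Two-family von Mises mixture

The aggregate θ distribution is modeled as an axial mixture of two von Mises
components plus a constant:

    ρ(θ) = b + w·exp{a₁cos 2(θ−α₁)}/(π I₀(a₁)) + (1−w)·exp{a₂cos 2(θ−α₂)}/(π I₀(a₂)).

Fitting is least squares of this density (per-radian units) against the
binned histogram evaluated at bin centers, bounded b, w ∈ [0, 1],
a ∈ [0, 100] (the cap keeps I₀ finite in double precision; hits are
flagged), α free and wrapped mod 180°. Histogram least squares is the
canonical path; a maximum-likelihood fit on raw angles is provided as an
alternative. Initialization is multi-start from the two strongest peaks of a
Gaussian-smoothed (σ = 3°), circularly padded histogram, plus the swapped
assignment and both low/moderate concentration starts; the lowest-RSS
solution wins and families are reordered so α₁ ≤ α₂. Label swap is a density
symmetry (w ↔ 1−w), so ordering resolves identifiability. Fits that collapse
to one family (w outside [0.02, 0.98] or coincident means within 2°) are
flagged "degenerate second family" — real cohorts occasionally produce
exactly this. Exponentially scaled Bessel functions (`i0e`) are used
throughout so concentrations up to the bound are stable.

Sampling draws the component per Bernoulli(w), then 2θ from the circular von
Mises with mean 2α, halves and wraps — valid only for the normalized mixture
(b = 0).

## Fiber density

A binary mask thresholds at 0.45× the mean stack intensity (strict `>`;
for an exactly constant positive stack the mask is defined as all-true,
since every voxel exceeds the threshold by construction). Density is the
fiber-voxel fraction of the whole stack; it is invariant to uniform
intensity rescaling because the threshold scales with the mean. Fiber
thickness is a manual measurement entering only as a metadata column.

## Stress–strain characterization

Engineering strain ε = ΔL/L₀ and nominal stress σ = F/(w₀·e₀) (MPa; default
dog-bone geometry L₀ = 40 mm, w₀ = 20 mm, e₀ = 0.8 mm, loading at 0.5 mm/s).
Force is lightly smoothed (moving average, window 1% of samples, min 3).
Stepwise-loading curves with relaxation drops during imaging pauses are
reduced to their upper envelope (running maximum of σ over sorted ε) before
parameterization; continuous curves bypass the envelope.

Five descriptors: E₁ (toe modulus), E₂ (linear modulus), σ_max, ε_max, ε_mid
(strain at 50% σ_max, linearly interpolated at the first crossing; multiple
crossings are flagged). Region boundaries are defined operationally, since
no convention fixes them:

* **Toe** — the widest initial window [0, ε*] whose least-squares slope
  agrees with that of its first half within 2% (plus twice the half-window
  slope standard error, so noise widens rather than destabilizes the
  window). A stress-fraction rule ("toe ends at x% of σ_max") fails for
  dermis-like curves: with E₂/E₁ ≈ 200 the toe stress never approaches any
  appreciable fraction of σ_max before the heel, and such a rule drags the
  toe fit deep into the heel (≈3× bias on E₁ in simulation).
* **Linear** — the widest window containing the maximum-local-slope point
  with linear-fit R² ≥ 0.99 *and* slope within 2% of the maximum
  sliding-window slope, followed by a start-trim while R² improves. R²
  alone admits windows diluted by the heel (5–8% downward bias on E₂).

All window fits use prefix-sum linear regression (O(1) per window). Under
force noise of 0.005 MPa the toe slope of a dermis-like curve carries an
irreducible ~6% standard error (the toe stress rise is only ~0.01 MPa), so
tight E₁ recovery is asserted on clean curves and a looser tolerance on
noisy ones; E₂ and ε_mid are insensitive to this noise level.

Curves are grouped by strain midpoint as low (ε_mid < 0.27) versus high
(≥ 0.27); the source material prints the same inequality for both groups,
an evident typo resolved this way.

## Dependency screening

Per-sample features (E₁, E₂, σ_max, ε_max, ε_mid, age, and density /
thickness / 3DOI / main θ per channel) are screened pairwise with the sample
distance correlation (V-statistic: double-centered Euclidean distance
matrices, dCor = dCov/√(dVar_x·dVar_y); the unbiased U-statistic variant is
available behind a flag). dc = 0 is returned, flagged, for constant vectors.
Significance uses a permutation null (2000 resamples by default;
p = (1 + exceedances)/(1 + resamples)); permutation is the canonical
independence test for this statistic, with a bootstrap-with-replacement
variant behind a flag for users who want the resampling reading. Rows with
any missing requested feature are dropped (complete-case analysis — with 24
samples, imputation is less defensible than transparency about n). No
multiple-testing correction is applied by default across the 78 pairs of the
13-feature table; a Benjamini–Hochberg option exists and is used in the
end-to-end adjacency-recovery test, where raw α = 0.05 over 78 pairs would
otherwise guarantee several false positives.

3DOI across stress regions (toe/heel/linear) is compared by one-way ANOVA
with Tukey HSD post hoc, starred at 0.05/0.01/0.001.

## Synthetic data: what it emulates, and what it does not

* **Fiber stacks** — straight cylinders (radius ≥ 1 px) with θ drawn from a
  two-family axial von Mises mixture (dermis shows families near 45°/135°
  relative to the stretch axis) and φ from an axial von Mises concentrated
  at 90° (fibers lie nearly in-plane), rasterized by stamping spheres along
  the axis until a target fill fraction (0.3–0.7 covers the collagen range)
  is reached, then Gaussian noise. Overlaps take the maximum intensity
  (SHG-like brightness, no additivity); the label volume keeps the first
  painter. Real fibers are crimped and curved; because orientation
  estimation is purely local (11-voxel windows), straight segments exercise
  the estimator fully — a sinusoidal-crimp option exists but is not part of
  the validation battery. No PSF convolution or polarization physics is
  simulated, so tests validate the geometry pipeline, not image formation.
* **Curves** — the tangent modulus switches logistically from E₁ to E₂
  across a heel of given center and width; integrating gives a
  softplus-elbow J-curve, scaled to hit σ_max at ε_max, plus Gaussian force
  noise (default 0: the reference curves are clean). Nominal ground truth:
  E₁/E₂ are clean-curve least-squares slopes over the regions where the
  modulus is within 2% of its toe/linear asymptote, ε_mid is read off the
  dense clean curve. A heel too close to the origin (relative to E₂/E₁)
  leaves no toe plateau and is warned about. No viscoelasticity or failure.
* **Cohorts** — features drawn independently from uniform marginals matching
  the observed cohort ranges, then planted dependency links (target, source,
  link function, noise) applied in acyclic order, then the standard
  missingness pattern: 3 samples missing E₁, 2 missing the elastin block,
  leaving 19 of 24 complete.

All generators are deterministic given a seed. Passing tests on these
phantoms shows the estimators recover known ground truth under controlled
conditions; it does not certify performance on real tissue, where crimp,
depth-dependent attenuation and segmentation ambiguity add error.

## Validation problem sizes

Orientation phantoms for routine tests use 24×96×96 to 28×128×128 voxel
volumes at fills 0.08–0.3 (the sparse parallel-tube phantom isolates
single-fiber behavior; at realistic fills, window overlap at fiber crossings
biases the mean φ low by a few degrees while the median stays at 90°).
Distance-correlation calibration runs 500 null repetitions at n = 50 with
200 permutations. Von Mises recovery uses 5·10⁴ samples per draw. These
sizes keep the full suite in well under a minute apart from the orientation
phantoms.

## Known limitations

* The orientation weight functional is one faithful realization of
  length-and-fluctuation weighting; other choices shift per-voxel angles by
  a few degrees on noisy data (summary statistics are much more stable).
* Mean φ at realistic fiber densities is biased a few degrees below 90° by
  fiber crossings; use the median or the directional summary.
* E₁ of very compliant toes is noise-limited (see above).
* Distance-correlation p-values are raw by default; with 78 pairs expect
  ~4 false positives at α = 0.05 under full independence.
* Stacks are assumed isotropic (0.5 µm) after depth correction; anisotropic
  input must be rescaled before orientation estimation.
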