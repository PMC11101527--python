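# dermafiber

Quantitative analysis linking the 3D collagen/elastin fiber architecture of
human dermis to its uniaxial mechanical response.

Skin's characteristic J-shaped stress–strain curve emerges from its two main
structural proteins: compliant elastin networks carry load at small strain,
stiff collagen bundles engage in the linear regime. `dermafiber` provides
the full measurement pipeline for studies that image dermal tissue with
label-free multiphoton microscopy (second-harmonic generation for collagen,
two-photon fluorescence for elastin) while stretching it:

* **Orientation** — per-voxel 3D fiber orientation (azimuth θ, polar φ) by
  weighted vector summation over 11×11×11 voxel windows, summarized by the
  axial center of mass (C̄, S̄, Z̄) and its length, the **3D orientation index**

  3DOI = √(C̄² + S̄² + Z̄²) ∈ [0, 1],

  with C̄ = ⟨sin φ cos 2θ⟩, S̄ = ⟨sin φ sin 2θ⟩, Z̄ = ⟨SI·|cos φ|⟩ over valid
  voxels (0 = disordered, 1 = perfectly aligned).
* **Angular mixtures** — the aggregate θ distribution modeled as a
  two-family axial von Mises mixture
  ρ(θ) = b + w·e^{a₁cos 2(θ−α₁)}/(π I₀(a₁)) + (1−w)·e^{a₂cos 2(θ−α₂)}/(π I₀(a₂)),
  with density evaluation, sampling, and least-squares fitting.
* **Density** — fiber volume fraction by thresholding at 0.45× the mean
  stack intensity.
* **Mechanics** — tensile logs → engineering stress–strain curves
  (ε = ΔL/L₀, σ = F/(w₀e₀)) and their five descriptors: toe modulus E₁,
  linear modulus E₂, σ_max, ε_max, and the strain midpoint ε_mid at 50% of
  σ_max, with automatic toe/heel/linear segmentation.
* **Dependency screening** — per-sample feature tables tested pairwise with
  the distance correlation (captures nonlinear association; zero iff
  independent) and permutation p-values; ANOVA + Tukey HSD for 3DOI across
  stress regions.
* **Synthetic data** — fiber phantoms, J-curves and cohorts with known
  ground truth, so every stage is testable without proprietary microscopy
  data.

## Worked example

```python
import dermafiber as df

# structural channel: synthetic collagen stack with known two-family anisotropy
stack, truth = df.gen_fiber_stack(df.FiberPhantomSpec(
    shape=(24, 96, 96),
    theta_mixture=df.VonMisesMixture(b=0, w=0.5, alpha1=45, a1=8.0,
                                     alpha2=135, a2=8.0),
    target_fill=0.25, noise_sd=3.0, seed=11))
density = df.fiber_density(stack)
field = df.estimate_orientation(stack)            # per-voxel (theta, phi)
summary = df.directional_summary(field)
fit = df.vm_fit(df.layer_histograms(field))

# mechanical channel: J-shaped curve with known moduli
curve, nominal = df.gen_stress_strain(df.CurveSpec(
    E1_nominal=0.1, E2_nominal=20.0, sigma_max_nominal=4.0,
    eps_max_nominal=0.4, heel_center=0.25, heel_width=0.02, seed=3))
ch = df.extract_characteristics(curve)
```

Output of the run above:

```
fiber density            : 0.254  (target fill 0.25)
valid voxels             : 28852
3D orientation index     : 0.066
main theta (folded)      : 42.2 deg
von Mises fit            : w=0.66, alpha=(48.4, 137.9) deg, a=(0.76, 5.51)
E1 = 0.135 MPa (nominal 0.133)
E2 = 26.42 MPa (nominal 26.31)
sigma_max = 4.00 MPa, eps_max = 0.40, eps_mid = 0.324 (high midpoint group)
```

Reading it: the density estimate matches the phantom's fill; the 3DOI is low
(0.066) because the two fiber families at ~45° and ~135° cancel each other's
resultant — exactly the disorder signature seen in unstretched dermis — while
the mixture fit still localizes both family angles near the truth. The folded
main angle (42°) is the acute angle between the mean fiber direction and the
stretch axis. On the mechanical side, the extracted toe and linear moduli
agree with the generator's nominal values within a few percent and the curve
falls in the high strain-midpoint group (ε_mid ≥ 0.27).

A command-line interface wraps the same functions:

```bash
dermafiber simulate curve --seed 1 --out pull.csv
dermafiber mechanics --in pull.csv --l0 40 --w0 20 --e0 0.8
dermafiber preprocess --in stack.tif --channel collagen --out calib.tif
dermafiber orient --in calib.tif --window 11 --out orient/
dermafiber density --in calib.tif
dermafiber correlate --table features.csv --resamples 2000 --seed 7
dermafiber run --config cohort.yaml
```

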