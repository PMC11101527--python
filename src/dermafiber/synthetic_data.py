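"""Synthetic phantoms with known ground truth for every pipeline stage.

Three generators emulate the study's data:

* ``gen_fiber_stack`` — 3D stacks of straight tubular fibers whose in-plane
  angles follow a two-family axial von Mises mixture (dermal collagen shows
  two families near 45°/135° relative to the stretch axis) and whose
  out-of-plane angles concentrate near 90° (fibers lie almost in-plane).
  Fill fractions are controllable over the 0.3–0.7 range seen for collagen.
* ``gen_stress_strain`` — J-shaped stress–strain curves with controllable
  toe/linear moduli, maximum stress/strain and heel position, built from a
  logistic switch between the two slopes.
* ``gen_cohort`` — per-sample feature tables with planted dependencies and
  an optional missingness pattern (three samples missing E₁, two missing the
  elastin block) mirroring a 24-sample cohort with 19 complete cases.

Everything is deterministic given a seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fiber_metrics import DEFAULT_FACTOR
from .mechanics import MechanicalCharacteristics, SampleGeometry, StressStrainCurve
from .stack_io import ImageStack
from .vonmises import VonMisesMixture, vm_sample

#: standard cohort missingness: rows missing E1 / rows missing the elastin block
DEFAULT_MISSING_E1 = 3
DEFAULT_MISSING_ELASTIN = 2
ELASTIN_BLOCK = ["D_EL", "T_EL", "OI3D_EL", "main_theta_EL"]


@dataclass
class FiberPhantomSpec:
    shape: tuple = (30, 128, 128)
    theta_mixture: VonMisesMixture = field(
        default_factory=lambda: VonMisesMixture(b=0.0, w=0.5, alpha1=45.0,
                                                a1=2.0, alpha2=135.0, a2=2.0))
    phi_concentration: float = 40.0
    fiber_radius_px: float = 2.0
    target_fill: float = 0.4
    fiber_intensity: float = 200.0
    background_intensity: float = 10.0
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.theta_mixture.b != 0:
            raise ValueError("phantom mixture must be normalized (b = 0)")
        if not 0 < self.target_fill < 0.9:
            raise ValueError("target_fill must lie in (0, 0.9)")
        if self.fiber_radius_px < 1:
            raise ValueError("fiber radius must be >= 1 px")
        if min(self.fiber_intensity, self.background_intensity) < 0:
            raise ValueError("intensities must be >= 0")


@dataclass
class CurveSpec:
    E1_nominal: float = 0.1     # MPa, toe slope
    E2_nominal: float = 20.0    # MPa, linear slope
    sigma_max_nominal: float = 4.0
    eps_max_nominal: float = 0.4
    heel_center: float = 0.25
    heel_width: float = 0.02
    n_points: int = 2000
    noise_sd: float = 0.0       # MPa
    seed: int = 0

    def __post_init__(self) -> None:
        if self.E1_nominal > self.E2_nominal:
            raise ValueError("requires E1 <= E2")
        if self.heel_center >= self.eps_max_nominal:
            raise ValueError("heel_center must precede eps_max")


def _sample_phi(concentration: float, n: int, rng) -> np.ndarray:
    """Axial polar angles concentrated at 90° (in-plane)."""
    two_phi = rng.vonmises(math.radians(180.0), concentration, n)
    return (np.degrees(two_phi) / 2.0) % 180.0


def gen_fiber_stack(spec: FiberPhantomSpec):
    """Rasterize straight cylindrical fibers until the fill target is reached.

    Returns ``(stack, truth)`` where truth holds per-fiber (θ, φ) and the
    label volume (0 = background; overlaps keep the first-drawn fiber's
    label, intensities take the maximum).
    """
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.shape
    vol = np.full(spec.shape, spec.background_intensity, dtype=float)
    labels = np.zeros(spec.shape, dtype=np.int32)
    occupied = np.zeros(spec.shape, dtype=bool)
    total = vol.size

    r = spec.fiber_radius_px
    ri = int(math.ceil(r))
    zz, yy, xx = np.mgrid[-ri:ri + 1, -ri:ri + 1, -ri:ri + 1]
    ball = np.argwhere(zz**2 + yy**2 + xx**2 <= r * r) - ri

    thetas, phis = [], []
    max_fibers = 100000
    diag = math.sqrt(nz * nz + ny * ny + nx * nx)
    for fiber_id in range(1, max_fibers + 1):
        if occupied.mean() >= spec.target_fill:
            break
        theta = float(vm_sample(spec.theta_mixture, 1,
                                rng.integers(2**31 - 1))[0]) % 180.0
        phi = float(_sample_phi(spec.phi_concentration, 1, rng)[0])
        t, p = math.radians(theta), math.radians(phi)
        # direction: x along the stretch axis, phi measured from +z
        d = np.array([math.cos(p), math.sin(p) * math.sin(t),
                      math.sin(p) * math.cos(t)])  # (dz, dy, dx)
        anchor = rng.random(3) * np.array([nz, ny, nx])
        steps = np.arange(-diag, diag, 0.5)
        pts = np.rint(anchor[None, :] + steps[:, None] * d[None, :]).astype(int)
        inside = ((pts[:, 0] >= 0) & (pts[:, 0] < nz)
                  & (pts[:, 1] >= 0) & (pts[:, 1] < ny)
                  & (pts[:, 2] >= 0) & (pts[:, 2] < nx))
        pts = np.unique(pts[inside], axis=0)
        if pts.size == 0:
            continue
        vox = (pts[:, None, :] + ball[None, :, :]).reshape(-1, 3)
        ok = ((vox[:, 0] >= 0) & (vox[:, 0] < nz)
              & (vox[:, 1] >= 0) & (vox[:, 1] < ny)
              & (vox[:, 2] >= 0) & (vox[:, 2] < nx))
        vz, vy, vx = vox[ok].T
        vol[vz, vy, vx] = np.maximum(vol[vz, vy, vx], spec.fiber_intensity)
        new = labels[vz, vy, vx] == 0
        labels[vz[new], vy[new], vx[new]] = fiber_id
        occupied[vz, vy, vx] = True
        thetas.append(theta)
        phis.append(phi)
    else:
        raise RuntimeError("fill target unreachable within the iteration cap")

    if spec.noise_sd > 0:
        vol = np.clip(vol + rng.normal(0.0, spec.noise_sd, vol.shape), 0.0, None)
    stack = ImageStack(voxels=vol, channel="collagen",
                       sample_id=f"phantom-{spec.seed}")
    truth = {"theta": np.array(thetas), "phi": np.array(phis),
             "labels": labels, "fill": float(occupied.mean())}
    return stack, truth


def gen_stress_strain(spec: CurveSpec):
    """J-shaped curve from a logistic switch between toe and linear slopes.

    The tangent modulus switches logistically from E₁ to E₂ across the heel,
    dσ/dε = E₁ + (E₂−E₁)·W(ε) with W a logistic of width ``heel_width``
    centered at ``heel_center``; integrating gives the softplus elbow

        σ_raw(ε) = E₁ε + (E₂−E₁)·width·log(1 + exp((ε−c)/width)),

    which reduces to a sharp piecewise-linear elbow as width → 0.  The curve
    is then scaled so σ(ε_max) = σ_max.  Nominal characteristics (asymptotic
    slopes after scaling, numeric ε_mid) are returned alongside the samples.
    """
    rng = np.random.default_rng(spec.seed)
    eps = np.linspace(0.0, spec.eps_max_nominal, spec.n_points)

    def raw(e):
        de = spec.E2_nominal - spec.E1_nominal
        if spec.heel_width <= 0:
            elbow = np.maximum(e - spec.heel_center, 0.0)
        else:
            u = (e - spec.heel_center) / spec.heel_width
            elbow = spec.heel_width * np.logaddexp(0.0, u)
        return spec.E1_nominal * e + de * elbow

    sig_end = raw(np.array([spec.eps_max_nominal]))[0]
    if sig_end <= 0:
        raise ValueError("inconsistent spec: sigma_max unreachable")
    scale = spec.sigma_max_nominal / sig_end
    clean = scale * raw(eps)
    dense = np.linspace(0.0, spec.eps_max_nominal, 20001)
    clean_dense = scale * raw(dense)
    eps_mid = float(np.interp(0.5 * spec.sigma_max_nominal, clean_dense, dense))
    # nominal regions: where the tangent modulus is within 2% of its toe /
    # linear asymptote (the heel's exponential tails decide the bounds, and
    # with E2/E1 of order 100 the toe bound sits many widths before the heel)
    de = spec.E2_nominal - spec.E1_nominal
    if de > 0 and spec.heel_width > 0:
        toe_hi = spec.heel_center - spec.heel_width * math.log(
            de / (0.02 * spec.E1_nominal))
        lin_lo = spec.heel_center + spec.heel_width * math.log(
            de / (0.02 * spec.E2_nominal))
        if toe_hi <= 0:
            warnings.warn("heel too close to the origin: no toe plateau; "
                          "nominal E1 is ill-defined", stacklevel=2)
            toe_hi = spec.heel_center / 2
        lin_lo = min(lin_lo, (spec.heel_center + spec.eps_max_nominal) / 2)
    elif de > 0:
        toe_hi, lin_lo = spec.heel_center, spec.heel_center
    else:  # degenerate straight line
        toe_hi, lin_lo = spec.eps_max_nominal, 0.0

    def _slope(lo, hi):
        sel = (dense >= lo) & (dense <= hi)
        return float(np.polyfit(dense[sel], clean_dense[sel], 1)[0])

    nominal = MechanicalCharacteristics(
        E1=_slope(0.0, toe_hi), E2=_slope(lin_lo, spec.eps_max_nominal),
        sigma_max=spec.sigma_max_nominal, eps_max=spec.eps_max_nominal,
        eps_mid=eps_mid, toe_end=toe_hi, linear_start=lin_lo,
        linear_end=spec.eps_max_nominal, fit_r2_linear=np.nan)
    sig = clean + rng.normal(0.0, spec.noise_sd, eps.shape) if spec.noise_sd > 0 else clean
    sig = np.clip(sig, 0.0, None)
    curve = StressStrainCurve(eps, sig, SampleGeometry())
    return curve, nominal


def gen_cohort(n_samples: int = 24, dependency_spec=None, seed: int = 0,
               missing_e1: int = DEFAULT_MISSING_E1,
               missing_elastin: int = DEFAULT_MISSING_ELASTIN,
               apply_missingness: bool = True):
    """Cohort feature table with planted dependencies and known truth.

    ``dependency_spec`` is a list of ``(target, source, link, noise_sd)``
    tuples applied in order (acyclic); targets overwrite the independent
    baseline draw.  Returns ``(table, truth)`` with truth holding the planted
    adjacency set.
    """
    rng = np.random.default_rng(seed)
    dependency_spec = list(dependency_spec or [])
    # acyclic in application order: a source must not be (re)defined later
    defined_after = {t for t, *_ in dependency_spec}
    for tgt, src, *_ in dependency_spec:
        defined_after.discard(tgt)
        if src == tgt or src in defined_after:
            raise ValueError("dependency spec must be acyclic in application order")

    n = n_samples
    base = {
        "E1": rng.uniform(0.02, 0.3, n),
        "E2": rng.uniform(5.0, 40.0, n),
        "sigma_max": rng.uniform(1.0, 8.0, n),
        "eps_max": rng.uniform(0.25, 0.5, n),
        "eps_mid": rng.uniform(0.18, 0.46, n),
        "age": rng.uniform(61.0, 95.0, n),
        "D_CO": rng.uniform(0.3, 0.7, n),
        "T_CO": rng.uniform(16.7, 111.8, n),
        "OI3D_CO": rng.uniform(0.06, 0.25, n),
        "main_theta_CO": rng.uniform(27.0, 49.5, n),
        "D_EL": rng.uniform(0.002, 0.45, n),
        "T_EL": rng.uniform(2.58, 5.09, n),
        "OI3D_EL": rng.uniform(0.01, 0.24, n),
        "main_theta_EL": rng.uniform(20.0, 60.0, n),
    }
    table = pd.DataFrame(base)
    for tgt, src, link, noise_sd in dependency_spec:
        vals = link(table[src].to_numpy())
        table[tgt] = vals + rng.normal(0.0, noise_sd, n)

    if apply_missingness:
        rows = rng.choice(n, size=min(missing_e1 + missing_elastin, n),
                          replace=False)
        table.loc[rows[:missing_e1], "E1"] = np.nan
        for col in ELASTIN_BLOCK:
            table.loc[rows[missing_e1:], col] = np.nan

    truth = {"edges": {(t, s) for t, s, *_ in dependency_spec},
             "missing_rows": int(min(missing_e1 + missing_elastin, n))
             if apply_missingness else 0}
    table.insert(0, "sample_id", [f"S{i + 1}" for i in range(n)])
    return table, truth
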