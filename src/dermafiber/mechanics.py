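"""Stress–strain curves of uniaxially stretched dermis and their descriptors.

Tensile logs (motor displacement, force) become engineering stress–strain
curves: ε = ΔL/L₀ and σ = F/(w₀·e₀) in MPa.  Soft tissue shows a J-shaped
curve — a compliant toe region (elastin-dominated), a transitional heel, and
a stiff linear region (collagen-dominated).  Five descriptors are extracted:

  E₁     toe-region slope (initial Young's modulus, MPa)
  E₂     linear-region slope (elastic Young's modulus, MPa)
  σ_max  maximum stress (MPa)
  ε_max  strain at maximum stress
  ε_mid  strain at 50% of σ_max (interpolated)

Region boundaries are not prescribed by convention, so the module defines
them operationally.  The toe is the widest window [0, ε*] whose least-squares
slope still agrees (within a tolerance) with the slope of its first half — a
self-consistency test that stops exactly where the heel starts bending the
fit.  (A stress-fraction toe rule is unusable here: with E₂/E₁ ≈ 200, as for
dermis, the toe stress never reaches any appreciable fraction of σ_max before
the heel.)  The linear region is the widest contiguous strain window that
contains the maximum-local-slope point, has linear-fit R² ≥ 0.99, and whose
slope stays within a tolerance of the maximum sliding-window slope (pure R²
admits windows diluted by the heel).  All thresholds are configuration.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

DEFAULT_SPEED_MM_S = 0.5
TOE_SLOPE_TOL = 0.02     # toe grows while slope(0,j) <= (1+tol)*slope(0,j/2)
LINEAR_R2_MIN = 0.99
LINEAR_SLOPE_TOL = 0.02  # linear-window slope must reach (1-tol)*max slope
EPS_MID_GROUP_CUT = 0.27  # low (<) vs high (>=) strain-midpoint grouping


@dataclass(frozen=True)
class SampleGeometry:
    """Undeformed specimen dimensions (mm): dog-bone tensile geometry."""

    L0: float = 40.0
    w0: float = 20.0
    e0: float = 0.8

    def __post_init__(self) -> None:
        if min(self.L0, self.w0, self.e0) <= 0:
            raise ValueError("geometry dimensions must be positive")

    @property
    def cross_section_mm2(self) -> float:
        return self.w0 * self.e0


@dataclass
class StressStrainCurve:
    strain: np.ndarray
    stress: np.ndarray  # MPa
    geometry: SampleGeometry
    speed_mm_per_s: float = DEFAULT_SPEED_MM_S

    def __post_init__(self) -> None:
        self.strain = np.asarray(self.strain, dtype=float)
        self.stress = np.asarray(self.stress, dtype=float)
        if self.strain.shape != self.stress.shape:
            raise ValueError("strain and stress must have equal length")
        if self.strain.size < 10:
            raise ValueError("curve needs at least 10 samples")


@dataclass
class MechanicalCharacteristics:
    E1: float
    E2: float
    sigma_max: float
    eps_max: float
    eps_mid: float
    toe_end: float
    linear_start: float
    linear_end: float
    fit_r2_linear: float
    eps_mid_group: str = ""
    flags: tuple = ()


def build_curve(displacement_mm, force_N, geometry: SampleGeometry | None = None,
                smooth: bool = True, speed_mm_per_s: float = DEFAULT_SPEED_MM_S,
                force_tol_N: float = 0.05) -> StressStrainCurve:
    """Convert a tensile log to an engineering stress–strain curve.

    N/mm² is MPa, so σ = F/(w₀·e₀) needs no unit factor.  A light moving
    average (window 1% of samples, min 3) suppresses sensor noise in force.
    """
    geometry = geometry or SampleGeometry()
    disp = np.asarray(displacement_mm, dtype=float)
    force = np.asarray(force_N, dtype=float)
    if disp.shape != force.shape:
        raise ValueError("displacement and force must have equal length")
    if np.any(force < -force_tol_N):
        raise ValueError("negative forces beyond tolerance")
    if smooth and force.size >= 3:
        win = max(3, int(round(0.01 * force.size)))
        kernel = np.ones(win) / win
        pad = win // 2
        padded = np.pad(force, pad, mode="edge")
        force = np.convolve(padded, kernel, mode="valid")[:force.size]
    strain = disp / geometry.L0
    stress = force / geometry.cross_section_mm2
    return StressStrainCurve(strain, stress, geometry, speed_mm_per_s)


def upper_envelope(curve: StressStrainCurve) -> StressStrainCurve:
    """Running maximum of σ over ε — removes relaxation drops of stepwise loading."""
    order = np.argsort(curve.strain, kind="stable")
    eps = curve.strain[order]
    sig = np.maximum.accumulate(curve.stress[order])
    return StressStrainCurve(eps, sig, curve.geometry, curve.speed_mm_per_s)


def _linfit(x, y):
    """Least-squares slope, intercept and R² (R² = 1 for a flat perfect fit)."""
    slope, intercept = np.polyfit(x, y, 1)
    pred = slope * x + intercept
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(slope), float(intercept), r2


class _WindowFit:
    """O(1) linear fits on contiguous index windows via prefix sums."""

    def __init__(self, x: np.ndarray, y: np.ndarray):
        z = np.zeros(1)
        self.sx = np.concatenate([z, np.cumsum(x)])
        self.sy = np.concatenate([z, np.cumsum(y)])
        self.sxx = np.concatenate([z, np.cumsum(x * x)])
        self.syy = np.concatenate([z, np.cumsum(y * y)])
        self.sxy = np.concatenate([z, np.cumsum(x * y)])

    def r2(self, lo: int, hi: int) -> float:
        """R² of the least-squares line over indices [lo, hi]."""
        n = hi - lo + 1
        sx = self.sx[hi + 1] - self.sx[lo]
        sy = self.sy[hi + 1] - self.sy[lo]
        sxx = self.sxx[hi + 1] - self.sxx[lo]
        syy = self.syy[hi + 1] - self.syy[lo]
        sxy = self.sxy[hi + 1] - self.sxy[lo]
        vx = sxx - sx * sx / n
        vy = syy - sy * sy / n
        cxy = sxy - sx * sy / n
        if vy <= 0:
            return 1.0  # flat segment: a horizontal line fits exactly
        if vx <= 0:
            return 0.0
        return min(cxy * cxy / (vx * vy), 1.0)

    def slope(self, lo: int, hi: int) -> float:
        n = hi - lo + 1
        sx = self.sx[hi + 1] - self.sx[lo]
        sy = self.sy[hi + 1] - self.sy[lo]
        sxx = self.sxx[hi + 1] - self.sxx[lo]
        sxy = self.sxy[hi + 1] - self.sxy[lo]
        vx = sxx - sx * sx / n
        return (sxy - sx * sy / n) / vx if vx > 0 else 0.0

    def slope_se(self, lo: int, hi: int) -> float:
        """Standard error of the window slope from the residual variance."""
        n = hi - lo + 1
        if n < 3:
            return np.inf
        sx = self.sx[hi + 1] - self.sx[lo]
        sy = self.sy[hi + 1] - self.sy[lo]
        sxx = self.sxx[hi + 1] - self.sxx[lo]
        syy = self.syy[hi + 1] - self.syy[lo]
        sxy = self.sxy[hi + 1] - self.sxy[lo]
        vx = sxx - sx * sx / n
        vy = syy - sy * sy / n
        cxy = sxy - sx * sy / n
        if vx <= 0:
            return np.inf
        ss_res = max(vy - cxy * cxy / vx, 0.0)
        return math.sqrt(ss_res / ((n - 2) * vx))


def segment_regions(curve: StressStrainCurve,
                    toe_slope_tol: float = TOE_SLOPE_TOL,
                    r2_min: float = LINEAR_R2_MIN,
                    linear_slope_tol: float = LINEAR_SLOPE_TOL,
                    envelope: bool = False) -> tuple[float, float, float]:
    """Toe / heel / linear segmentation; returns (toe_end, linear_start, linear_end).

    Toe: widest [0, j] whose slope agrees with the slope of [0, j/2] within
    ``toe_slope_tol`` plus twice the half-window slope standard error.
    Linear: widest window containing the maximum-local-slope point with
    R² >= ``r2_min`` and slope >= (1 − ``linear_slope_tol``) times the
    maximum sliding-window slope; widths are scanned from widest downward on
    a coarse grid.
    """
    if envelope:
        curve = upper_envelope(curve)
    eps, sig = curve.strain, curve.stress
    smax = float(sig.max())
    if smax <= 0:
        raise ValueError("degenerate flat curve: no positive stress")
    imax = int(np.argmax(sig))
    eps, sig = eps[:imax + 1], sig[:imax + 1]
    n = eps.size
    if n < 10:
        raise ValueError("too few points before the stress maximum")
    wf = _WindowFit(eps, sig)

    # tangent modulus from sliding least-squares windows
    mwin = max(n // 20, 4)
    starts = np.arange(0, max(n - mwin, 1), max(mwin // 4, 1))
    slopes = np.array([wf.slope(lo, min(lo + mwin - 1, n - 1)) for lo in starts])
    seed = int(starts[np.argmax(slopes)] + mwin // 2)
    seed = min(max(seed, 1), n - 2)
    mmax = float(slopes.max())

    # toe: self-consistent initial linear window
    grid = max(n // 100, 1)
    toe_idx = max(n // 50, 5)
    for j in range(seed, toe_idx, -grid):
        half = wf.slope(0, j // 2)
        if half <= 0:
            continue
        guard = 2.0 * wf.slope_se(0, j // 2)
        if wf.slope(0, j) <= half * (1.0 + toe_slope_tol) + guard:
            toe_idx = j
            break
    toe_end = float(eps[min(toe_idx, n - 1)])

    lo_best, hi_best = max(seed - 2, 0), min(seed + 2, n - 1)
    for width in range(n, 4, -grid):
        found = False
        for lo in range(max(seed - width + 1, 0), min(seed, n - width) + 1, grid):
            hi = lo + width - 1
            if (wf.r2(lo, hi) >= r2_min
                    and wf.slope(lo, hi) >= (1.0 - linear_slope_tol) * mmax):
                lo_best, hi_best = lo, hi
                found = True
                break
        if found:
            break
    # fine pass: the coarse window can overhang the heel by up to one grid
    # step, diluting the slope — trim the start while the fit improves
    best_r2 = wf.r2(lo_best, hi_best)
    while hi_best - lo_best > 10:
        r2 = wf.r2(lo_best + 1, hi_best)
        if r2 <= best_r2:
            break
        lo_best, best_r2 = lo_best + 1, r2
    linear_start, linear_end = float(eps[lo_best]), float(eps[hi_best])
    if linear_start < toe_end:
        toe_end = linear_start  # heel collapses for near-linear curves
    return toe_end, linear_start, linear_end


def extract_characteristics(curve: StressStrainCurve,
                            toe_slope_tol: float = TOE_SLOPE_TOL,
                            r2_min: float = LINEAR_R2_MIN,
                            envelope: bool = False) -> MechanicalCharacteristics:
    """Extract the five descriptors plus region boundaries from a curve."""
    work = upper_envelope(curve) if envelope else curve
    toe_end, lin_start, lin_end = segment_regions(work, toe_slope_tol, r2_min)
    eps, sig = work.strain, work.stress
    imax = int(np.argmax(sig))
    sigma_max = float(sig[imax])
    eps_max = float(eps[imax])

    toe_sel = eps <= toe_end
    if np.count_nonzero(toe_sel) < 3:
        toe_sel = np.zeros_like(toe_sel)
        toe_sel[:3] = True
    e1, _, _ = _linfit(eps[toe_sel], sig[toe_sel])

    lin_sel = (eps >= lin_start) & (eps <= lin_end)
    e2, _, r2_lin = _linfit(eps[lin_sel], sig[lin_sel])

    flags = []
    half = 0.5 * sigma_max
    crossings = np.nonzero((sig[:-1] < half) & (sig[1:] >= half))[0]
    if crossings.size == 0:
        eps_mid = float(np.interp(half, sig[:imax + 1], eps[:imax + 1]))
        flags.append("eps_mid_interpolated_on_sorted")
    else:
        if crossings.size > 1:
            flags.append("multiple_half_max_crossings_first_taken")
        i = int(crossings[0])
        frac = (half - sig[i]) / (sig[i + 1] - sig[i])
        eps_mid = float(eps[i] + frac * (eps[i + 1] - eps[i]))

    group = "low" if eps_mid < EPS_MID_GROUP_CUT else "high"
    return MechanicalCharacteristics(
        E1=e1, E2=e2, sigma_max=sigma_max, eps_max=eps_max, eps_mid=eps_mid,
        toe_end=toe_end, linear_start=lin_start, linear_end=lin_end,
        fit_r2_linear=r2_lin, eps_mid_group=group, flags=tuple(flags),
    )
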