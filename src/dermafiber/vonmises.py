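"""Two-component axial von Mises mixture for fiber-angle distributions.

The aggregate azimuth distribution of dermal fibers is bimodal: two fiber
families symmetric about the stretch axis.  It is modeled as

    ρ(θ) = b + w·exp{a₁ cos 2(θ−α₁)}/(π I₀(a₁))
             + (1−w)·exp{a₂ cos 2(θ−α₂)}/(π I₀(a₂)),

a π-periodic (axial) density over θ ∈ (0, π]: b is a constant offset, w the
family weight, α the mean fiber angles and a the concentration parameters
(a → 0 gives a uniform family).  With b = 0 the density integrates to 1.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import find_peaks
from scipy.special import i0e

CONCENTRATION_MAX = 100.0


@dataclass
class VonMisesMixture:
    """Parameters of the axial two-family mixture; angles in degrees."""

    b: float = 0.0
    w: float = 0.5
    alpha1: float = 45.0
    a1: float = 1.0
    alpha2: float = 135.0
    a2: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.w <= 1.0:
            raise ValueError("w must lie in [0, 1]")
        if self.a1 < 0 or self.a2 < 0:
            raise ValueError("concentrations must be >= 0")
        if self.b < 0:
            raise ValueError("offset b must be >= 0")
        self.alpha1 = float(self.alpha1) % 180.0
        self.alpha2 = float(self.alpha2) % 180.0

    def ordered(self) -> "VonMisesMixture":
        """Return the same mixture with families sorted so alpha1 <= alpha2."""
        if self.alpha1 <= self.alpha2:
            return self
        return replace(self, w=1.0 - self.w, alpha1=self.alpha2, a1=self.a2,
                       alpha2=self.alpha1, a2=self.a1)

    def to_json(self) -> str:
        return json.dumps(self.__dict__)

    @classmethod
    def from_json(cls, s: str) -> "VonMisesMixture":
        return cls(**json.loads(s))


@dataclass
class FitResult:
    params: VonMisesMixture
    rss: float
    converged: bool
    degenerate_second_family: bool = False
    at_concentration_bound: bool = False


def _axial_vm(theta_rad, alpha_rad, a):
    # exponentially scaled Bessel keeps large concentrations finite
    return np.exp(a * (np.cos(2.0 * (theta_rad - alpha_rad)) - 1.0)) / (np.pi * i0e(a))


def vm_density(theta_deg, params: VonMisesMixture):
    """Mixture density (per radian) at θ given in degrees; π-periodic."""
    t = np.radians(np.asarray(theta_deg, dtype=float))
    a1r = np.radians(params.alpha1)
    a2r = np.radians(params.alpha2)
    rho = (params.b
           + params.w * _axial_vm(t, a1r, params.a1)
           + (1.0 - params.w) * _axial_vm(t, a2r, params.a2))
    return rho if rho.ndim else float(rho)


def vm_sample(params: VonMisesMixture, n: int, seed=None) -> np.ndarray:
    """Draw n axial angles in (0°, 180°] from the normalized mixture (b = 0).

    Each draw picks a family per Bernoulli(w), samples 2θ from the circular
    von Mises with mean 2α and the family's concentration, halves, and wraps.
    """
    if params.b != 0:
        raise ValueError("sampling requires the normalized mixture (b = 0)")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    pick1 = rng.random(n) < params.w
    two_theta = np.where(
        pick1,
        rng.vonmises(np.radians(2.0 * params.alpha1), params.a1, n),
        rng.vonmises(np.radians(2.0 * params.alpha2), params.a2, n),
    )
    theta = (np.degrees(two_theta) / 2.0) % 180.0
    theta[theta == 0.0] = 180.0
    return theta


def _pack(p: VonMisesMixture) -> np.ndarray:
    return np.array([p.b, p.w, p.alpha1, p.a1, p.alpha2, p.a2])


def _unpack(x) -> VonMisesMixture:
    return VonMisesMixture(b=max(x[0], 0.0), w=min(max(x[1], 0.0), 1.0),
                           alpha1=x[2], a1=max(x[3], 0.0),
                           alpha2=x[4], a2=max(x[5], 0.0))


def _histogram_density(hist) -> tuple[np.ndarray, np.ndarray]:
    """Bin centers (degrees) and per-radian density of a normalized histogram."""
    centers = np.asarray(hist.bin_centers if hasattr(hist, "bin_centers")
                         else hist[0], dtype=float)
    freq = np.asarray(hist.aggregate if hasattr(hist, "aggregate")
                      else hist[1], dtype=float)
    widths_rad = np.radians(np.diff(
        hist.bin_edges if hasattr(hist, "bin_edges")
        else np.arange(len(freq) + 1.0)))
    dens = freq / freq.sum() / widths_rad
    return centers, dens


def _initial_guesses(centers, dens):
    """Candidate starts from the two strongest smoothed peaks (plus swap)."""
    kernel = np.exp(-0.5 * (np.arange(-8, 9) / 3.0) ** 2)
    kernel /= kernel.sum()
    n = len(dens)
    smooth = np.convolve(np.concatenate([dens, dens, dens]), kernel,
                         mode="same")[n:2 * n]
    peaks, props = find_peaks(smooth, height=0.0)
    order = np.argsort(props["peak_heights"])[::-1] if peaks.size else np.array([], int)
    if peaks.size >= 2:
        m1, m2 = centers[peaks[order[0]]], centers[peaks[order[1]]]
    elif peaks.size == 1:
        m1 = centers[peaks[order[0]]]
        m2 = (m1 + 90.0) % 180.0
    else:
        m1, m2 = 45.0, 135.0
    guesses = []
    for u, v in ((m1, m2), (m2, m1)):
        for conc in (0.5, 2.0):
            guesses.append(VonMisesMixture(b=0.0, w=0.5, alpha1=u, a1=conc,
                                           alpha2=v, a2=conc))
    return guesses


def vm_fit(hist, max_nfev: int = 2000) -> FitResult:
    """Least-squares fit of the mixture density to an aggregate θ histogram.

    The histogram is converted to per-radian units, the model is evaluated at
    bin centers, and the best of several peak-derived starts is kept.  The
    second family is flagged degenerate when the fit collapses onto a single
    family (w near 0/1 or coincident mean angles).
    """
    centers, dens = _histogram_density(hist)
    if np.count_nonzero(dens) < 2:
        raise ValueError("histogram needs at least 2 distinct nonzero bins")

    def resid(x):
        return vm_density(centers, _unpack(x)) - dens

    lo = np.array([0.0, 0.0, -360.0, 0.0, -360.0, 0.0])
    hi = np.array([1.0, 1.0, 360.0, CONCENTRATION_MAX, 360.0, CONCENTRATION_MAX])
    best = None
    any_converged = False
    for guess in _initial_guesses(centers, dens):
        x0 = np.clip(_pack(guess), lo, hi)
        try:
            res = least_squares(resid, x0, bounds=(lo, hi), max_nfev=max_nfev)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
        any_converged = any_converged or res.success
    if best is None:
        raise RuntimeError("von Mises fit failed from every start")
    params = _unpack(best.x).ordered()
    rss = float(2.0 * best.cost)
    ang_gap = abs(params.alpha1 - params.alpha2)
    ang_gap = min(ang_gap, 180.0 - ang_gap)
    degenerate = bool(params.w < 0.02 or params.w > 0.98 or ang_gap < 2.0)
    at_bound = bool(params.a1 >= CONCENTRATION_MAX - 1e-6
                    or params.a2 >= CONCENTRATION_MAX - 1e-6)
    if not any_converged:
        warnings.warn("von Mises fit did not converge from any start; "
                      "returning best effort", stacklevel=2)
    if degenerate:
        warnings.warn("degenerate second family in von Mises fit", stacklevel=2)
    return FitResult(params=params, rss=rss, converged=any_converged,
                     degenerate_second_family=degenerate,
                     at_concentration_bound=at_bound)


def vm_fit_mle(angles_deg, x0: VonMisesMixture | None = None) -> FitResult:
    """Maximum-likelihood fit on raw angles (b fixed at 0); alternative route."""
    from scipy.optimize import minimize

    ang = np.asarray(angles_deg, dtype=float)
    start = x0 or VonMisesMixture()

    def nll(x):
        p = VonMisesMixture(b=0.0, w=min(max(x[0], 1e-6), 1 - 1e-6),
                            alpha1=x[1], a1=max(x[2], 0.0),
                            alpha2=x[3], a2=max(x[4], 0.0))
        d = vm_density(ang, p)
        return -np.sum(np.log(np.maximum(d, 1e-300)))

    res = minimize(nll, [start.w, start.alpha1, start.a1, start.alpha2, start.a2],
                   method="Nelder-Mead",
                   options={"maxiter": 4000, "xatol": 1e-6, "fatol": 1e-9})
    x = res.x
    params = VonMisesMixture(b=0.0, w=min(max(x[0], 0.0), 1.0), alpha1=x[1],
                             a1=max(x[2], 0.0), alpha2=x[3],
                             a2=max(x[4], 0.0)).ordered()
    return FitResult(params=params, rss=float(res.fun), converged=bool(res.success))
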