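"""Voxelwise 3D fiber orientation by weighted vector summation.

For every sufficiently bright voxel an 11x11x11 window is projected
(maximum-intensity) onto the xy, xz and yz planes.  In each projection every
candidate direction d in {1..180} degrees through the window center is scored
by w(d) = L(d) * max(0, 1 - CV(d)), where L(d) is the length of the contiguous
above-threshold chord through the center and CV(d) the coefficient of
variation of the intensity along that chord: long, evenly bright chords are
fiber-like.  The per-projection angle is the doubled-angle weighted vector
sum, ½·atan2(Σ w sin 2d, Σ w cos 2d), which treats directions as axial
(π-periodic) data.  The xy angle is the azimuth θ (from the +x stretch axis);
the xz and yz angles β and γ determine the polar angle φ via

    tan² φ = 1/tan² β + 1/tan² γ,

with φ = 90° meaning in-plane.  Stack-level alignment is summarized by the
center of mass of the axial orientation distribution (C̄, S̄, Z̄) and its
length, the 3D orientation index (3DOI = mean resultant length): 0 for
disordered, 1 for perfectly aligned fibers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit

from .stack_io import ImageStack

DEFAULT_WINDOW = 11
DEFAULT_THRESHOLD_FACTOR = 0.45
#: voxel aspect ratio between lateral and axial sampling (isotropic stacks)
SAMPLING_RATIO = 1.0


@dataclass
class OrientationField:
    """Per-voxel azimuth/polar angles (degrees) with a validity mask."""

    theta: np.ndarray  # [0, 180), defined where valid
    phi: np.ndarray    # [0, 180]; estimation yields [0, 90]
    valid: np.ndarray
    window_size: int = DEFAULT_WINDOW
    sampling_ratio: float = SAMPLING_RATIO

    def __post_init__(self) -> None:
        if self.window_size < 3 or self.window_size % 2 == 0:
            raise ValueError("window_size must be odd and >= 3")
        if not (self.theta.shape == self.phi.shape == self.valid.shape):
            raise ValueError("theta, phi and valid must share a shape")

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


@dataclass
class DirectionalSummary:
    """Center of mass of the axial orientation distribution and derived angles."""

    c_bar: float
    s_bar: float
    z_bar: float
    oi3d: float
    main_theta: float
    main_theta_folded: float
    main_phi: float
    n_valid: int


@dataclass
class AngularHistogram:
    """One-degree binned θ distributions, per z-layer and aggregated.

    Bins span (0°, 180°] so bin i collects angles in (i, i+1]; an angle of
    exactly 0° is counted as 180°.  Each nonempty layer row is normalized to
    sum 1; ``empty_layers`` flags layers without any valid voxel.
    """

    bin_edges: np.ndarray
    per_layer: np.ndarray
    aggregate: np.ndarray
    empty_layers: np.ndarray

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0


def polar_from_projections(beta, gamma):
    """Polar angle φ (degrees, [0, 90]) from the xz and yz projection angles.

    In-plane fibers project to horizontal lines (tan β or tan γ = 0), giving
    φ = 90; a fiber along z has β = γ = 90 and φ = 0.
    """
    beta = np.asarray(beta, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    if np.any((beta < 0) | (beta >= 180)) or np.any((gamma < 0) | (gamma >= 180)):
        raise ValueError("beta and gamma must lie in [0, 180)")
    tb = np.tan(np.radians(beta))
    tg = np.tan(np.radians(gamma))
    with np.errstate(divide="ignore", invalid="ignore"):
        t2 = 1.0 / tb**2 + 1.0 / tg**2
    phi = np.degrees(np.arctan(np.sqrt(t2)))
    phi = np.where((tb == 0) | (tg == 0), 90.0, phi)
    return phi if phi.ndim else float(phi)


def fold_angle(theta):
    """Fold an axial angle in [0, 180) onto [0, 90] (θ → 180 − θ above 90)."""
    theta = np.asarray(theta, dtype=float)
    if np.any((theta < 0) | (theta >= 180)):
        raise ValueError("theta must lie in [0, 180)")
    folded = np.where(theta > 90, 180.0 - theta, theta)
    return folded if folded.ndim else float(folded)


@njit(cache=True)
def _chord_weights(img, thr, du, dv, cos2d, sin2d):
    """Weighted axial vector sum over candidate directions in one projection.

    Returns the doubled-angle resultant (wc, ws); the caller halves atan2.
    """
    half = img.shape[0] // 2
    nd = du.shape[0]
    wc = 0.0
    ws = 0.0
    center = img[half, half]
    for d in range(nd):
        s = center
        ss = center * center
        cnt = 1
        for sign in (1, -1):
            for k in range(1, half + 1):
                v = img[half + sign * dv[d, k - 1], half + sign * du[d, k - 1]]
                if v <= thr:
                    break
                s += v
                ss += v * v
                cnt += 1
        mean = s / cnt
        if mean <= 0.0:
            continue
        var = ss / cnt - mean * mean
        if var < 0.0:
            var = 0.0
        cv = math.sqrt(var) / mean
        w = cnt * max(0.0, 1.0 - cv)
        wc += w * cos2d[d]
        ws += w * sin2d[d]
    return wc, ws


@njit(cache=True)
def _half_atan2(ws, wc):
    ang = 0.5 * math.degrees(math.atan2(ws, wc))
    if ang < 0.0:
        ang += 180.0
    if ang >= 180.0:
        ang -= 180.0
    return ang


@njit(cache=True)
def _orient_volume(vol, thr, half, du, dv, cos2d, sin2d, theta, phi, valid):
    nz, ny, nx = vol.shape
    win = 2 * half + 1
    mip_xy = np.empty((win, win), dtype=np.float64)
    mip_xz = np.empty((win, win), dtype=np.float64)
    mip_yz = np.empty((win, win), dtype=np.float64)
    for z in range(half, nz - half):
        for y in range(half, ny - half):
            for x in range(half, nx - half):
                if vol[z, y, x] <= thr:
                    continue
                # maximum-intensity projections of the window onto the three planes
                for a in range(win):
                    for b in range(win):
                        mip_xy[a, b] = 0.0
                        mip_xz[a, b] = 0.0
                        mip_yz[a, b] = 0.0
                for dz in range(win):
                    for dy in range(win):
                        for dx in range(win):
                            v = vol[z - half + dz, y - half + dy, x - half + dx]
                            if v > mip_xy[dy, dx]:
                                mip_xy[dy, dx] = v
                            if v > mip_xz[dz, dx]:
                                mip_xz[dz, dx] = v
                            if v > mip_yz[dz, dy]:
                                mip_yz[dz, dy] = v
                wc_t, ws_t = _chord_weights(mip_xy, thr, du, dv, cos2d, sin2d)
                wc_b, ws_b = _chord_weights(mip_xz, thr, du, dv, cos2d, sin2d)
                wc_g, ws_g = _chord_weights(mip_yz, thr, du, dv, cos2d, sin2d)
                if wc_t * wc_t + ws_t * ws_t < 1e-24:
                    continue  # degenerate window: no direction carries weight
                th = _half_atan2(ws_t, wc_t)
                beta = _half_atan2(ws_b, wc_b)
                gamma = _half_atan2(ws_g, wc_g)
                tb = math.tan(math.radians(beta))
                tg = math.tan(math.radians(gamma))
                if tb == 0.0 or tg == 0.0:
                    ph = 90.0
                else:
                    ph = math.degrees(math.atan(math.sqrt(1.0 / (tb * tb) + 1.0 / (tg * tg))))
                # signed out-of-plane tilt: with the in-plane representative
                # fixed by theta (ux, uy) = (cos th, sin th), the sign of uz
                # follows from the quadrant of beta (tan beta = uz/ux) or of
                # gamma (tan gamma = uz/uy), whichever projection is better
                # conditioned; phi > 90 encodes a downward tilt
                ct = math.cos(math.radians(th))
                st = math.sin(math.radians(th))
                if abs(ct) >= abs(st):
                    uz_sign = 1.0 if (tb > 0.0) == (ct > 0.0) else -1.0
                else:
                    uz_sign = 1.0 if tg > 0.0 else -1.0
                if uz_sign < 0.0 and ph < 90.0:
                    ph = 180.0 - ph
                theta[z, y, x] = th
                phi[z, y, x] = ph
                valid[z, y, x] = True


def _direction_offsets(half: int):
    """Rounded pixel offsets along each candidate direction (1..180 deg)."""
    degs = np.arange(1, 181, dtype=float)
    rad = np.radians(degs)
    ks = np.arange(1, half + 1, dtype=float)
    du = np.rint(np.outer(np.cos(rad), ks)).astype(np.int64)
    dv = np.rint(np.outer(np.sin(rad), ks)).astype(np.int64)
    cos2d = np.cos(2 * rad)
    sin2d = np.sin(2 * rad)
    return du, dv, cos2d, sin2d


def estimate_orientation(stack: ImageStack, window_size: int = DEFAULT_WINDOW,
                         intensity_threshold_factor: float = DEFAULT_THRESHOLD_FACTOR,
                         ) -> OrientationField:
    """Estimate per-voxel (θ, φ) for every above-threshold voxel.

    The intensity threshold is ``factor x mean(stack)`` — the same rule used
    for the fiber-density mask.  Voxels whose window does not fit inside the
    volume are left invalid (no padding).

    The returned φ is signed: the magnitude comes from the tan² combination
    of β and γ, and the side of the imaging plane (φ above or below 90°)
    from the β/γ quadrants, so that disordered input yields a z component
    that cancels in :func:`directional_summary` rather than accumulating.
    """
    if window_size < 3 or window_size % 2 == 0:
        raise ValueError("window_size must be odd and >= 3")
    vol = np.asarray(stack.voxels, dtype=np.float64)
    if any(s < window_size for s in vol.shape):
        raise ValueError(f"stack shape {vol.shape} smaller than window {window_size}")
    half = window_size // 2
    thr = intensity_threshold_factor * float(vol.mean())
    theta = np.full(vol.shape, np.nan)
    phi = np.full(vol.shape, np.nan)
    valid = np.zeros(vol.shape, dtype=bool)
    if vol.max() <= 0:
        warnings.warn("all-zero stack: empty orientation field", stacklevel=2)
        return OrientationField(theta, phi, valid, window_size)
    du, dv, cos2d, sin2d = _direction_offsets(half)
    _orient_volume(vol, thr, half, du, dv, cos2d, sin2d, theta, phi, valid)
    return OrientationField(theta, phi, valid, window_size)


def directional_summary(field_or_theta, phi=None) -> DirectionalSummary:
    """Center of mass (C̄, S̄, Z̄) of the axial data and the 3DOI.

    With b = tan φ the per-voxel weights reduce to b/√(1+b²) = sin φ for the
    in-plane components and SI/√(1+b²) = SI·|cos φ| for the z component, where
    SI is the sign of (90° − φ) and +1 at φ = 90°.  Accepts either an
    :class:`OrientationField` or explicit theta/phi degree arrays.
    """
    if isinstance(field_or_theta, OrientationField):
        f = field_or_theta
        theta = f.theta[f.valid]
        phi = f.phi[f.valid]
    else:
        theta = np.asarray(field_or_theta, dtype=float).ravel()
        phi = np.asarray(phi, dtype=float).ravel()
    if theta.size == 0:
        raise ValueError("no valid voxels")
    t = np.radians(theta)
    p = np.radians(phi)
    sin_p = np.sin(p)
    si = np.where(phi <= 90.0, 1.0, -1.0)  # sign rule; +1 at phi == 90
    c_bar = float(np.mean(sin_p * np.cos(2 * t)))
    s_bar = float(np.mean(sin_p * np.sin(2 * t)))
    z_bar = float(np.mean(si * np.abs(np.cos(p))))
    oi3d = math.sqrt(c_bar**2 + s_bar**2 + z_bar**2)
    main_theta = math.degrees(0.5 * math.atan2(s_bar, c_bar)) % 180.0
    main_phi = math.degrees(math.atan2(math.hypot(c_bar, s_bar), z_bar))
    return DirectionalSummary(
        c_bar=c_bar, s_bar=s_bar, z_bar=z_bar, oi3d=oi3d,
        main_theta=main_theta, main_theta_folded=fold_angle(main_theta),
        main_phi=main_phi, n_valid=int(theta.size),
    )


def layer_histograms(field: OrientationField) -> AngularHistogram:
    """Per-z-layer and aggregate normalized θ histograms (1° bins)."""
    nz = field.theta.shape[0]
    edges = np.arange(0.0, 181.0)
    per_layer = np.zeros((nz, 180))
    empty = np.zeros(nz, dtype=bool)
    for z in range(nz):
        th = field.theta[z][field.valid[z]]
        if th.size == 0:
            empty[z] = True
            continue
        idx = np.ceil(th).astype(int)  # (i, i+1] bins; theta == 0 -> bin 180
        idx[idx == 0] = 180
        counts = np.bincount(idx - 1, minlength=180).astype(float)
        per_layer[z] = counts / counts.sum()
    if empty.all():
        raise ValueError("orientation field has no valid voxels in any layer")
    agg = per_layer.sum(axis=0)
    agg /= agg.sum()
    return AngularHistogram(bin_edges=edges, per_layer=per_layer,
                            aggregate=agg, empty_layers=empty)


def write_field(field: OrientationField, theta_path, phi_path, mask_path) -> None:
    """Serialize an orientation field as 32-bit θ/φ TIFFs plus a mask TIFF."""
    import tifffile

    tifffile.imwrite(theta_path, field.theta.astype(np.float32))
    tifffile.imwrite(phi_path, field.phi.astype(np.float32))
    tifffile.imwrite(mask_path, field.valid.astype(np.uint8))
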