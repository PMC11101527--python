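"""Image-stack I/O, geometric calibration and contrast enhancement.

Stacks are two-channel multiphoton z-stacks of dermal tissue: second-harmonic
generation (collagen) and two-photon excited fluorescence (elastin).  Axes are
0-based ``(z, y, x)`` with ``x`` the stretch axis.  The immersion-oil / tissue
refractive-index mismatch makes the apparent axial step twice the actual one;
the correction is stored as an explicit factor so that calibrated stacks carry
isotropic 0.5 um voxels.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, replace

import numpy as np
import tifffile
import yaml
from skimage import exposure

#: refractive indices behind the depth halving (immersion oil / skin)
N_IMMERSION_OIL = 1.518
N_SKIN = 1.37

CHANNELS = ("collagen", "elastin")


@dataclass(frozen=True)
class AcquisitionConfig:
    """Geometry of the acquisition: field of view, sampling, depth correction."""

    fov_raw_um: float = 500.0
    fov_clipped_um: float = 400.0
    lateral_res_um: float = 0.5
    axial_res_um_actual: float = 0.5
    depth_correction_factor: float = 0.5

    def __post_init__(self) -> None:
        vals = (self.fov_raw_um, self.fov_clipped_um, self.lateral_res_um,
                self.axial_res_um_actual, self.depth_correction_factor)
        if any(v <= 0 for v in vals):
            raise ValueError("all acquisition parameters must be positive")
        if self.fov_clipped_um > self.fov_raw_um:
            raise ValueError("clipped field of view exceeds raw field of view")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "AcquisitionConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class ImageStack:
    """A single-channel 3D intensity volume with voxel calibration.

    ``axial_spacing_actual`` is the apparent axial spacing multiplied by the
    depth-correction factor; after correction both spacings are 0.5 um so the
    volume is isotropic.
    """

    voxels: np.ndarray
    lateral_spacing: float = 0.5
    axial_spacing_apparent: float = 1.0
    axial_spacing_actual: float = 0.5
    channel: str = "collagen"
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D (z, y, x) array, got ndim={self.voxels.ndim}")
        if self.voxels.size and self.voxels.min() < 0:
            raise ValueError("intensities must be non-negative")
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}")
        if self.lateral_spacing <= 0 or self.axial_spacing_actual <= 0:
            raise ValueError("voxel spacings must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


def read_stack(path: str | os.PathLike, channel: str = "collagen",
               config: AcquisitionConfig | None = None,
               sample_id: str = "") -> ImageStack:
    """Read a multi-page TIFF into an :class:`ImageStack`.

    Page order is preserved as z order; spacings come from ``config``.
    """
    config = config or AcquisitionConfig()
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        if len(tif.pages) == 0:
            raise ValueError(f"{path}: TIFF contains no image planes")
        planes = [p.asarray() for p in tif.pages]
    shapes = {p.shape for p in planes}
    if len(shapes) > 1:
        raise ValueError(f"{path}: ragged plane dimensions {sorted(shapes)}")
    voxels = np.stack(planes, axis=0)
    if voxels.ndim == 2:  # single plane stored without a page axis
        voxels = voxels[None]
    apparent = config.axial_res_um_actual / config.depth_correction_factor
    return ImageStack(
        voxels=voxels,
        lateral_spacing=config.lateral_res_um,
        axial_spacing_apparent=apparent,
        axial_spacing_actual=config.axial_res_um_actual,
        channel=channel,
        sample_id=sample_id or os.path.splitext(os.path.basename(path))[0],
    )


def write_stack(stack: ImageStack, path: str | os.PathLike) -> None:
    """Write the stack as a multi-page TIFF, one page per z plane."""
    # grayscale planes even when z happens to be 3 or 4 (never RGB)
    tifffile.imwrite(path, stack.voxels, photometric="minisblack")


def clip_fov(stack: ImageStack, config: AcquisitionConfig | None = None) -> ImageStack:
    """Central crop of each plane to the retained field of view.

    Dark, invalid borders of the raw scan are removed, e.g. a 500 um raw field
    at 0.5 um/px (1000x1000) is cropped to 400 um (800x800).  Odd margins are
    split with the floor on the leading edge.  z is untouched.
    """
    config = config or AcquisitionConfig()
    npx = int(round(config.fov_clipped_um / config.lateral_res_um))
    nz, ny, nx = stack.shape
    if npx > ny or npx > nx:
        raise ValueError(f"requested crop {npx} px exceeds plane extent ({ny}, {nx})")
    y0 = (ny - npx) // 2
    x0 = (nx - npx) // 2
    return replace(stack, voxels=stack.voxels[:, y0:y0 + npx, x0:x0 + npx])


def apply_depth_correction(apparent_depths_um, config: AcquisitionConfig | None = None):
    """Convert apparent imaging depths to actual depths.

    The refractive-index mismatch between immersion oil and tissue halves the
    true focal displacement relative to the nominal one.
    """
    config = config or AcquisitionConfig()
    depths = np.asarray(apparent_depths_um, dtype=float)
    if np.any(depths < 0):
        raise ValueError("depths must be non-negative")
    return depths * config.depth_correction_factor


def clahe_enhance(stack: ImageStack, tile_size: int = 64,
                  clip_limit: float = 0.01) -> ImageStack:
    """Contrast-limited adaptive histogram equalization, applied per z plane.

    Output is rescaled to the input dtype range; shape is preserved.  A plane
    with no contrast is returned unchanged.
    """
    if tile_size < 2:
        raise ValueError("tile_size must be >= 2")
    if not 0 < clip_limit <= 1:
        raise ValueError("clip_limit must be in (0, 1]")
    nz, ny, nx = stack.shape
    if tile_size > ny or tile_size > nx:
        raise ValueError("tile larger than plane")
    dtype = stack.voxels.dtype
    if np.issubdtype(dtype, np.integer):
        lo, hi = 0, np.iinfo(dtype).max
    else:
        lo, hi = 0.0, max(float(stack.voxels.max()), 1.0)
    out = np.empty_like(stack.voxels, dtype=float)
    ntiles_y = max(ny // tile_size, 1)
    ntiles_x = max(nx // tile_size, 1)
    for z in range(nz):
        plane = stack.voxels[z]
        if plane.max() == plane.min():
            out[z] = plane  # constant plane: nothing to equalize
            continue
        norm = (plane.astype(float) - lo) / (hi - lo)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            eq = exposure.equalize_adapthist(
                np.clip(norm, 0.0, 1.0),
                kernel_size=(max(ny // ntiles_y, 2), max(nx // ntiles_x, 2)),
                clip_limit=clip_limit,
            )
        out[z] = eq * hi
    if np.issubdtype(dtype, np.integer):
        out = np.clip(np.rint(out), lo, hi).astype(dtype)
    return replace(stack, voxels=out)


def read_table(path: str | os.PathLike):
    """Read a two-column tensile log or metadata CSV into a DataFrame."""
    import pandas as pd

    return pd.read_csv(path)
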