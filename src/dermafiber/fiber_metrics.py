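"""Fiber volume fraction from intensity thresholding.

Density is the fraction of voxels whose intensity exceeds 0.45 times the mean
stack intensity — a relative threshold, so the measure is invariant to
uniform intensity rescaling.  Computed on raw (unenhanced) intensities by
default, since contrast enhancement shifts the stack mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .stack_io import ImageStack

DEFAULT_FACTOR = 0.45


@dataclass
class FiberMask:
    mask: np.ndarray
    threshold_value: float
    threshold_factor: float = DEFAULT_FACTOR


def binary_mask(stack: ImageStack, factor: float = DEFAULT_FACTOR) -> FiberMask:
    """Threshold at ``factor x mean(stack)``.

    The comparison is strict (>) except for a constant positive stack, where
    every voxel equals the mean and sits above the threshold by construction;
    there the mask is all-true (>=).
    """
    vox = np.asarray(stack.voxels)
    if vox.size == 0:
        raise ValueError("empty stack")
    mean = float(vox.mean())
    thr = factor * mean
    if mean == 0:
        warnings.warn("all-zero stack: empty fiber mask", stacklevel=2)
        return FiberMask(np.zeros(vox.shape, dtype=bool), 0.0, factor)
    if vox.min() == vox.max():
        return FiberMask(np.ones(vox.shape, dtype=bool), thr, factor)
    return FiberMask(vox > thr, thr, factor)


def fiber_density(mask: FiberMask | ImageStack, factor: float = DEFAULT_FACTOR) -> float:
    """Fiber voxel count divided by total voxel count, in [0, 1]."""
    if isinstance(mask, ImageStack):
        mask = binary_mask(mask, factor)
    m = mask.mask
    if m.size == 0:
        raise ValueError("empty mask")
    return float(np.count_nonzero(m)) / m.size
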