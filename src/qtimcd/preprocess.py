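"""Preprocessing: 3-D Gaussian smoothing and CSF-contamination exclusion.

Smoothing uses the *discrete Gaussian* (scale-space) kernel
``T(n, t) = exp(-t) I_n(t)`` with ``t = sigma^2`` in voxel units, rather
than a sampled-and-truncated continuous Gaussian.  At the small default
width (sigma = 0.42 voxels) the sampled kernel badly violates the semigroup
property -- smoothing twice with sigma is far from smoothing once with
sigma*sqrt(2) -- whereas the discrete Gaussian satisfies it exactly on the
grid and has exactly variance sigma^2 per axis.  Each axis uses
``sigma = sigma_factor * voxel dimension`` expressed on the grid, i.e. a
constant ``sigma_factor`` voxels, so the physical kernel width scales with
the (possibly anisotropic) voxel size.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
from scipy import ndimage, special

__all__ = [
    "SmoothingConfig",
    "discrete_gaussian_kernel",
    "gaussian_smooth",
    "exclude_csf_voxels",
    "translate_volume",
]


@dataclass(frozen=True)
class SmoothingConfig:
    """Per-axis kernel width as a multiple of the voxel dimension."""

    sigma_factor: float = 0.42

    def __post_init__(self) -> None:
        if self.sigma_factor <= 0:
            raise ValueError("sigma_factor must be positive")


def discrete_gaussian_kernel(sigma: float, tail: float = 1e-12) -> np.ndarray:
    """Symmetric 1-D discrete Gaussian kernel for standard deviation ``sigma``.

    Taps are ``exp(-t) I_n(t)`` with ``t = sigma**2``, truncated where the
    tail mass drops below ``tail`` and renormalized to unit sum.  The kernel
    is non-negative, and before truncation has exact total mass 1, mean 0
    and variance ``t``; convolving two such kernels gives the kernel for
    ``t1 + t2`` exactly (semigroup on the grid).
    """
    t = float(sigma) ** 2
    radius = 1
    while special.ive(radius, t) > tail and radius < 1000:
        radius += 1
    n = np.arange(-radius, radius + 1)
    taps = special.ive(np.abs(n), t)  # ive(n, t) = exp(-t) iv(n, t)
    return taps / taps.sum()


def gaussian_smooth(
    data: np.ndarray,
    voxel_size: tuple[float, float, float],
    config: SmoothingConfig = SmoothingConfig(),
) -> np.ndarray:
    """Smooth a 3-D volume or a stack of 4-D volumes.

    The per-axis standard deviation is ``sigma_factor`` voxels (equivalently
    ``sigma_factor * voxel dimension`` in mm).  Boundaries use
    nearest-neighbor replication, which preserves total intensity away from
    the edges and avoids rim darkening inside brain masks.  Smoothing is
    applied independently to each volume of a 4-D stack.
    """
    data = np.asarray(data, dtype=float)
    if any(v <= 0 for v in voxel_size):
        raise ValueError(f"voxel size must be positive, got {voxel_size}")
    if data.ndim not in (3, 4):
        raise ValueError("expected a 3-D volume or 4-D stack")
    kernel = discrete_gaussian_kernel(config.sigma_factor)
    out = data.copy()
    for axis in range(3):
        out = ndimage.correlate1d(out, kernel, axis=axis, mode="nearest")
    return out


def exclude_csf_voxels(
    roi_mask: np.ndarray,
    md: np.ndarray,
    md_csf_threshold: float = 1.5,
) -> tuple[np.ndarray, int]:
    """Remove CSF-contaminated voxels from an ROI mask.

    A voxel is considered contaminated when its fitted mean diffusivity
    exceeds ``md_csf_threshold`` (um^2/ms; default 1.5, well above
    parenchyma and well below free water).  Voxels with undefined (NaN) MD
    are also removed.  Returns the cleaned mask and the number of voxels
    removed; idempotent.
    """
    roi_mask = np.asarray(roi_mask).astype(bool)
    md = np.asarray(md, dtype=float)
    if roi_mask.shape != md.shape:
        raise ValueError(f"ROI shape {roi_mask.shape} does not match MD grid {md.shape}")
    with np.errstate(invalid="ignore"):
        bad = roi_mask & (~np.isfinite(md) | (md > md_csf_threshold))
    cleaned = roi_mask & ~bad
    return cleaned, int(bad.sum())


def translate_volume(data: np.ndarray, shift: tuple[int, int, int]) -> np.ndarray:
    """Integer 3-D translation (manual realignment aid; never automatic).

    Voxels shifted in from outside are zero-filled.  Works on 3-D volumes
    and 4-D stacks (shift applies to the spatial axes).
    """
    data = np.asarray(data)
    shift_full = tuple(int(s) for s in shift) + (0,) * (data.ndim - 3)
    out = np.zeros_like(data)
    src = [slice(None)] * data.ndim
    dst = [slice(None)] * data.ndim
    for ax, s in enumerate(shift_full):
        if s > 0:
            src[ax], dst[ax] = slice(0, data.shape[ax] - s), slice(s, None)
        elif s < 0:
            src[ax], dst[ax] = slice(-s, None), slice(0, data.shape[ax] + s)
    out[tuple(dst)] = data[tuple(src)]
    return out
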