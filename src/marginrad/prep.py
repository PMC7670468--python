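"""Image preparation: ADC computation, intensity normalization, gray-level
discretization.

The ADC map is the two-point closed form of the mono-exponential DWI decay
S(b) = S0 * exp(-b * ADC), i.e. ADC = ln(S0 / S(b)) / b in mm^2/s for
b-values in s/mm^2. Voxels where either signal is non-positive cannot be
inverted and are flagged NaN; downstream VOIs drop them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .volumes import ImageVolume

__all__ = ["DiscretizedVolume", "compute_adc", "normalize_intensity", "discretize"]

#: sentinel gray level for out-of-mask voxels
OUT_OF_MASK = 0


@dataclass
class DiscretizedVolume:
    """Integer gray levels 1..n_levels inside ``mask``; 0 outside."""

    levels: np.ndarray
    n_levels: int
    mask: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=np.int64)
        self.mask = np.asarray(self.mask, dtype=bool)
        inside = self.levels[self.mask]
        if inside.size and (inside.min() < 1 or inside.max() > self.n_levels):
            raise ValueError("in-mask gray levels must lie in 1..n_levels")


def compute_adc(b0: ImageVolume, bx: ImageVolume, b_value: float) -> ImageVolume:
    """Invert the mono-exponential decay to an ADC map (mm^2/s).

    Voxels with ``S0 <= 0`` or ``S(b) <= 0`` are set to NaN (invalid);
    negative ADC values are legal output (noise can push S(b) above S0)
    and are reported via a warning.
    """
    if b_value <= 0:
        raise ValueError("b_value must be positive")
    if b0.shape != bx.shape:
        raise ValueError(f"DWI grids differ: {b0.shape} vs {bx.shape}")
    s0 = b0.values
    sb = bx.values
    valid = (s0 > 0) & (sb > 0)
    adc = np.full(s0.shape, np.nan)
    adc[valid] = np.log(s0[valid] / sb[valid]) / b_value
    n_neg = int(np.sum(adc[valid] < 0))
    if n_neg:
        warnings.warn(f"ADC map contains {n_neg} negative voxels", stacklevel=2)
    return ImageVolume(adc, b0.spacing_mm, id=(b0.id + "_adc") if b0.id else "adc")


def normalize_intensity(vol: ImageVolume, mask: np.ndarray) -> ImageVolume:
    """Z-score the volume using the in-mask mean and SD.

    The sample (ddof=1) standard deviation is used, so e.g. in-mask values
    {1, 2, 3} map to {-1, 0, 1}. The same affine transform is applied to
    every voxel, which makes the result invariant to positive affine
    rescaling of the input and idempotent. A constant in-mask region maps
    to all zeros with a warning.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("normalization mask is empty")
    inside = vol.values[mask]
    mu = float(inside.mean())
    sd = float(inside.std(ddof=1)) if inside.size > 1 else 0.0
    if sd == 0.0:
        warnings.warn("constant-valued region: normalized output is all zeros", stacklevel=2)
        return vol.with_values(np.zeros_like(vol.values))
    return vol.with_values((vol.values - mu) / sd)


def discretize(vol: ImageVolume, mask: np.ndarray, n_levels: int = 32) -> DiscretizedVolume:
    """Equal-width binning of the in-mask intensity range into n_levels.

    The in-mask minimum maps to level 1 and the maximum to level
    ``n_levels``. A constant region collapses to a single level 1 (with a
    warning). Out-of-mask voxels carry the sentinel 0.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be at least 2")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("discretization mask is empty")
    inside = vol.values[mask]
    if not np.all(np.isfinite(inside)):
        raise ValueError("non-finite intensities inside the mask; drop invalid voxels first")
    lo, hi = float(inside.min()), float(inside.max())
    levels = np.zeros(vol.shape, dtype=np.int64)
    if hi == lo:
        warnings.warn("constant region: all voxels assigned gray level 1", stacklevel=2)
        levels[mask] = 1
    else:
        width = (hi - lo) / n_levels
        lev = np.floor((vol.values[mask] - lo) / width).astype(np.int64) + 1
        np.clip(lev, 1, n_levels, out=lev)
        levels[mask] = lev
    return DiscretizedVolume(levels, n_levels, mask, vol.spacing_mm)
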