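"""Z-spectrum data model, normalization and spline smoothing.

A CEST acquisition produces one image per saturation frequency offset plus
an unsaturated reference image.  The z-spectrum of a voxel is the saturated
intensity divided by the reference intensity,

    Z(dw) = M_z(dw) / M_z0,

a dimensionless quantity in [0, 1] up to noise.  Offsets are in ppm from the
water resonance; positive ppm is downfield of water.  Spectra may be stored
in acquisition order (commonly high-to-low ppm); all computation here sorts
ascending internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.interpolate import CubicSpline, UnivariateSpline

from .errors import (
    DegenerateVoxelError,
    InsufficientDataError,
    InvalidInputError,
)

__all__ = [
    "OffsetAxis",
    "ZSpectrumStack",
    "ZSpectrum",
    "normalize_to_z",
    "spline_smooth",
    "cest_axis",
    "wassr_axis",
]


@dataclass(frozen=True)
class OffsetAxis:
    """Ordered saturation-offset axis in ppm (positive = downfield of water)."""

    offsets_ppm: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.offsets_ppm, dtype=float)
        if arr.ndim != 1 or arr.size < 2:
            raise InvalidInputError("offset axis needs >= 2 one-dimensional entries")
        if not np.all(np.isfinite(arr)):
            raise InvalidInputError("offset axis contains non-finite values")
        d = np.diff(arr)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise InvalidInputError("offset axis must be strictly monotonic")
        object.__setattr__(self, "offsets_ppm", arr)

    def __len__(self) -> int:
        return self.offsets_ppm.size

    @property
    def ascending(self) -> np.ndarray:
        """Offsets sorted ascending (the internal computation order)."""
        return self.offsets_ppm if self.offsets_ppm[0] < self.offsets_ppm[-1] else self.offsets_ppm[::-1]

    @property
    def span(self) -> float:
        return float(self.offsets_ppm.max() - self.offsets_ppm.min())


def cest_axis(start: float = 6.0, stop: float = -6.0, step: float = 0.1,
              n: int | None = None) -> OffsetAxis:
    """Default CEST axis: +6 to -6 ppm in 0.1 ppm steps (121 nominal points).

    The acquired count is configuration-driven; pass ``n`` to truncate the
    nominal grid (e.g. ``n=120`` drops the final endpoint).
    """
    npts = int(round(abs(stop - start) / step)) + 1
    grid = np.linspace(start, stop, npts)
    if n is not None:
        grid = grid[:n]
    return OffsetAxis(grid)


def wassr_axis(start: float = 1.5, stop: float = -1.5, step: float = 0.1) -> OffsetAxis:
    """Default WASSR axis: +1.5 to -1.5 ppm (narrow, low-power water scan)."""
    npts = int(round(abs(stop - start) / step)) + 1
    return OffsetAxis(np.linspace(start, stop, npts))


@dataclass
class ZSpectrumStack:
    """Per-voxel saturated image stack plus unsaturated reference.

    ``sat_images`` has shape ``grid_shape + (n_offsets,)``; ``ref_image`` has
    shape ``grid_shape``.  ``mask`` marks voxels included in analysis.
    """

    sat_images: np.ndarray
    ref_image: np.ndarray
    axis: OffsetAxis
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sat_images = np.asarray(self.sat_images, dtype=float)
        self.ref_image = np.asarray(self.ref_image, dtype=float)
        if self.sat_images.shape[:-1] != self.ref_image.shape:
            raise InvalidInputError(
                f"sat grid {self.sat_images.shape[:-1]} != ref grid {self.ref_image.shape}")
        if self.sat_images.shape[-1] != len(self.axis):
            raise InvalidInputError(
                f"{self.sat_images.shape[-1]} offset frames but axis has {len(self.axis)}")
        if self.mask is None:
            self.mask = np.ones(self.ref_image.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.ref_image.shape:
                raise InvalidInputError("mask shape does not match image grid")

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.ref_image.shape


@dataclass
class ZSpectrum:
    """One voxel's normalized z-spectrum.

    ``z`` values live on ``axis``; ``b0_shift_ppm`` records an applied B0
    correction.  Values may exceed 1 from noise — they are flagged by
    :meth:`out_of_range`, never silently clipped.
    """

    z: np.ndarray
    axis: OffsetAxis
    b0_shift_ppm: float | None = None
    repair_log: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.z.shape != (len(self.axis),):
            raise InvalidInputError("z length does not match axis")

    def out_of_range(self, noise_margin: float = 0.05) -> np.ndarray:
        """Boolean flags for z outside [0, 1 + noise_margin]."""
        return (self.z < 0.0) | (self.z > 1.0 + noise_margin)

    def sorted_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(offsets ascending, z in that order) for interpolation."""
        off = self.axis.offsets_ppm
        if off[0] < off[-1]:
            return off, self.z
        return off[::-1], self.z[::-1]

    def interpolate(self, at_ppm) -> np.ndarray:
        """Cubic-spline evaluation of the spectrum at arbitrary ppm."""
        x, y = self.sorted_arrays()
        return CubicSpline(x, y)(np.asarray(at_ppm, dtype=float))


def normalize_to_z(stack: ZSpectrumStack, voxel: tuple) -> ZSpectrum:
    """Normalize one voxel: Z(dw) = M_sat(dw) / M_ref.

    Raises :class:`DegenerateVoxelError` when the reference is nonpositive
    and :class:`InvalidInputError` on non-finite intensities.
    """
    sat = stack.sat_images[voxel]
    ref = stack.ref_image[voxel]
    if not np.isfinite(ref) or ref <= 0:
        raise DegenerateVoxelError(f"reference intensity {ref!r} at voxel {voxel}")
    if not np.all(np.isfinite(sat)):
        raise InvalidInputError(f"non-finite saturated intensity at voxel {voxel}")
    return ZSpectrum(z=sat / ref, axis=stack.axis)


def _repair_nonfinite(x: np.ndarray, z: np.ndarray, log: list,
                      descending: bool = False) -> np.ndarray:
    """Impute non-finite z entries by linear interpolation over neighbors.

    Logged indices refer to the spectrum's storage (acquisition) order.
    """
    bad = ~np.isfinite(z)
    if not bad.any():
        return z
    if bad.all():
        raise InvalidInputError("all z values non-finite; cannot repair")
    out = z.copy()
    out[bad] = np.interp(x[bad], x[~bad], z[~bad])
    n = z.size
    for i in np.flatnonzero(bad):
        log.append({"index": int(n - 1 - i) if descending else int(i),
                    "offset_ppm": float(x[i]),
                    "imputed": float(out[i]), "reason": "non-finite entry"})
    return out


def spline_smooth(spec: ZSpectrum, smoothing: float = 0.0) -> ZSpectrum:
    """Smoothing-spline fit of the z-spectrum, evaluated on its own axis.

    ``smoothing`` is the residual-sum budget of a cubic smoothing spline
    (``scipy`` ``UnivariateSpline`` ``s``); 0 interpolates the data exactly
    at the knots.  ``smoothing=None`` lets the spline choose its budget by
    the standard GCV-like default.  Non-finite entries are imputed from
    neighbors first and reported in the returned spectrum's ``repair_log``.
    """
    if len(spec.axis) < 8:
        raise InsufficientDataError("spline smoothing needs >= 8 offsets")
    if smoothing is not None and smoothing < 0:
        raise InvalidInputError("smoothing must be >= 0")
    x, y = spec.sorted_arrays()
    descending = spec.axis.offsets_ppm[0] >= spec.axis.offsets_ppm[-1]
    log: list = list(spec.repair_log)
    y = _repair_nonfinite(x, y, log, descending=descending)
    if smoothing is not None and smoothing == 0.0:
        fitted = y.copy()  # s=0 spline interpolates: knot values are the data
    else:
        spl = UnivariateSpline(x, y, k=3, s=smoothing)
        fitted = spl(x)
    # restore original storage order
    if spec.axis.offsets_ppm[0] >= spec.axis.offsets_ppm[-1]:
        fitted = fitted[::-1]
    return ZSpectrum(z=fitted, axis=spec.axis, b0_shift_ppm=spec.b0_shift_ppm,
                     repair_log=log)
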