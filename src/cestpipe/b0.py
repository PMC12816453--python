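"""WASSR-based B0 field estimation and z-spectrum re-referencing.

Static-field (B0) inhomogeneity shifts the water resonance away from the
nominal 0 ppm, which corrupts every offset-referenced CEST metric.  WASSR
acquires a narrow, low-power z-spectrum (default +1.5 to -1.5 ppm) whose
only feature is the direct water dip; the dip position is the per-voxel B0
offset.  The estimator here locates the minimum of a spline interpolation
of the WASSR spectrum on a fine grid and refines it by symmetry matching:
the water lineshape is symmetric, so the true center s minimizes

    sum_w [ z(s + w) - z(s - w) ]^2

over a window of distances w around the dip.  CEST spectra are corrected by
resampling Z at (offset + shift), moving the spectrum onto a common grid
with water at 0 ppm rather than relabeling the axis, so that all voxels
share one grid for map arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import minimize_scalar

from .errors import NoDipError, UnreliableShiftError
from .zspec import OffsetAxis, ZSpectrum

__all__ = ["B0Field", "estimate_b0_shift", "apply_b0_correction", "estimate_b0_field"]


@dataclass
class B0Field:
    """Per-voxel water-resonance offset map (ppm) with fit residuals."""

    shift_ppm: np.ndarray
    quality: np.ndarray
    mask: np.ndarray

    def summary(self) -> dict:
        ok = self.mask & np.isfinite(self.shift_ppm)
        vals = self.shift_ppm[ok]
        return {
            "n_voxels": int(self.mask.size),
            "n_estimated": int(ok.sum()),
            "n_masked_out": int(self.mask.size - ok.sum()),
            "shift_mean_ppm": float(vals.mean()) if vals.size else float("nan"),
            "shift_sd_ppm": float(vals.std()) if vals.size else float("nan"),
            "shift_min_ppm": float(vals.min()) if vals.size else float("nan"),
            "shift_max_ppm": float(vals.max()) if vals.size else float("nan"),
        }


def estimate_b0_shift(wassr: ZSpectrum, fine_step_ppm: float = 0.001,
                      symmetry_halfwidth_ppm: float = 0.5) -> tuple[float, float]:
    """Estimate the water-dip position of a WASSR spectrum.

    Returns ``(shift_ppm, residual)`` where the residual is the mean squared
    left/right asymmetry at the returned center (0 for a perfectly symmetric
    dip).  Raises :class:`NoDipError` for a flat spectrum and
    :class:`UnreliableShiftError` when the minimum sits at an axis endpoint.
    """
    x, y = wassr.sorted_arrays()
    if np.ptp(y) < 1e-6:
        raise NoDipError("WASSR spectrum is flat; no water dip to locate")
    spl = CubicSpline(x, y)
    fine = np.arange(x[0], x[-1] + fine_step_ppm / 2, fine_step_ppm)
    zi = spl(fine)
    i0 = int(np.argmin(zi))
    edge = max(2, int(round(0.05 / fine_step_ppm)))  # within 0.05 ppm of an endpoint
    if i0 <= edge or i0 >= fine.size - 1 - edge:
        raise UnreliableShiftError(
            f"WASSR minimum at {fine[i0]:.3f} ppm lies at the axis edge")
    c0 = float(fine[i0])

    # symmetry refinement: probe distances must stay on the sampled range
    wmax = min(symmetry_halfwidth_ppm, x[-1] - c0 - 0.05, c0 - x[0] - 0.05)
    if wmax <= fine_step_ppm:
        return c0, float("nan")
    w = np.linspace(fine_step_ppm, wmax, 50)

    def asym(s: float) -> float:
        return float(np.mean((spl(s + w) - spl(s - w)) ** 2))

    res = minimize_scalar(asym, bounds=(c0 - 0.1, c0 + 0.1), method="bounded",
                          options={"xatol": 1e-5})
    shift = float(res.x)
    return shift, float(res.fun)


def apply_b0_correction(spec: ZSpectrum, shift: float) -> ZSpectrum:
    """Re-reference a z-spectrum so the water minimum sits at 0 ppm.

    The corrected spectrum is Z evaluated (by cubic spline) at
    ``offsets + shift``; the axis itself is unchanged.  Offsets that require
    extrapolation beyond the acquired range are evaluated by the spline's
    natural extension and flagged in ``repair_log``.
    """
    if abs(shift) >= spec.axis.span / 4:
        raise UnreliableShiftError(
            f"shift {shift:.3f} ppm exceeds a quarter of the axis span")
    if shift == 0.0:
        return ZSpectrum(z=spec.z.copy(), axis=spec.axis, b0_shift_ppm=0.0,
                         repair_log=list(spec.repair_log))
    x, y = spec.sorted_arrays()
    spl = CubicSpline(x, y)
    target = spec.axis.offsets_ppm + shift
    zc = spl(target)
    log = list(spec.repair_log)
    extrap = (target < x[0]) | (target > x[-1])
    for i in np.flatnonzero(extrap):
        log.append({"index": int(i), "offset_ppm": float(spec.axis.offsets_ppm[i]),
                    "reason": "extrapolated during B0 correction"})
    return ZSpectrum(z=zc, axis=spec.axis, b0_shift_ppm=float(shift), repair_log=log)


def estimate_b0_field(wassr_specs, grid_shape: tuple, mask: np.ndarray,
                      max_abs_shift_ppm: float = 1.5) -> B0Field:
    """Estimate a B0 map from per-voxel WASSR spectra.

    ``wassr_specs`` maps voxel index -> :class:`ZSpectrum`.  Voxels whose
    estimate fails or exceeds ``max_abs_shift_ppm`` are masked out; the
    returned field's mask reflects the exclusions (counted in the QC report).
    """
    shift = np.full(grid_shape, np.nan)
    quality = np.full(grid_shape, np.nan)
    out_mask = np.asarray(mask, dtype=bool).copy()
    for voxel, spec in wassr_specs.items():
        if not out_mask[voxel]:
            continue
        try:
            s, r = estimate_b0_shift(spec)
        except (NoDipError, UnreliableShiftError):
            out_mask[voxel] = False
            continue
        if abs(s) > max_abs_shift_ppm:
            out_mask[voxel] = False
            continue
        shift[voxel] = s
        quality[voxel] = r
    return B0Field(shift_ppm=shift, quality=quality, mask=out_mask)
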