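"""Voxelwise T1 mapping from a variable-TR saturation-recovery series.

The AREX metric divides MTR_REX by the observed longitudinal relaxation
time T1_obs.  T1_obs is fitted per voxel from a series of images acquired
at increasing repetition times (default range 867-6000 ms) under the ideal
saturation-recovery signal model

    S(TR) = S0 * (1 - exp(-TR / T1)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import InsufficientDataError, InvalidInputError

__all__ = ["VariableTRSeries", "T1Map", "fit_t1", "fit_t1_map",
           "T1_LOWER_S", "T1_UPPER_S"]

T1_LOWER_S = 0.05
T1_UPPER_S = 10.0


@dataclass
class VariableTRSeries:
    """Image series over repetition times: ``images`` is grid x TR."""

    images: np.ndarray
    trs_ms: np.ndarray

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=float)
        self.trs_ms = np.asarray(self.trs_ms, dtype=float)
        if self.trs_ms.ndim != 1 or self.trs_ms.size < 3:
            raise InsufficientDataError("T1 fit needs >= 3 repetition times")
        if np.any(self.trs_ms <= 0) or np.any(np.diff(self.trs_ms) <= 0):
            raise InvalidInputError("TRs must be positive and strictly increasing")
        if self.images.shape[-1] != self.trs_ms.size:
            raise InvalidInputError("image frame count does not match TR table")

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.images.shape[:-1]


def fit_t1(series: VariableTRSeries, voxel: tuple) -> tuple[float, float, float, bool]:
    """Fit (t1_s, s0, rss) at one voxel; the last element flags reliability.

    Bounded least squares with T1 in (0.05, 10] s, initialized at s0 = max
    intensity, T1 = 1.5 s (robust over the mouse-tissue range at 9.4 T).
    A fit pinned at a T1 bound is flagged unreliable (``ok=False``) so the
    voxel can be excluded from AREX.
    """
    s = np.asarray(series.images[voxel], dtype=float)
    if np.any(~np.isfinite(s)) or np.any(s < 0):
        raise InvalidInputError(f"negative or non-finite intensities at voxel {voxel}")
    tr_s = series.trs_ms / 1000.0
    s0_init = max(float(s.max()), 1e-12)

    def residual(p: np.ndarray) -> np.ndarray:
        s0, t1 = p
        return s0 * (1.0 - np.exp(-tr_s / t1)) - s

    res = least_squares(residual, x0=[s0_init, 1.5],
                        bounds=([0.0, T1_LOWER_S], [np.inf, T1_UPPER_S]),
                        method="trf", ftol=1e-14, xtol=1e-14, gtol=1e-14)
    s0, t1 = res.x
    rss = float(2.0 * res.cost)
    at_bound = t1 <= T1_LOWER_S * (1 + 1e-6) or t1 >= T1_UPPER_S * (1 - 1e-6)
    ok = bool(res.status > 0 and not at_bound)
    return float(t1), float(s0), rss, ok


@dataclass
class T1Map:
    """Per-voxel T1_obs (seconds) with equilibrium signal and residuals."""

    t1_s: np.ndarray
    s0: np.ndarray
    rss: np.ndarray
    mask: np.ndarray


def fit_t1_map(series: VariableTRSeries, mask: np.ndarray | None = None) -> T1Map:
    """Fit T1 over all masked voxels; flagged voxels drop out of the mask."""
    shape = series.grid_shape
    mask = np.ones(shape, bool) if mask is None else np.asarray(mask, bool)
    t1 = np.full(shape, np.nan)
    s0 = np.full(shape, np.nan)
    rss = np.full(shape, np.nan)
    out = mask.copy()
    for voxel in zip(*np.nonzero(mask)):
        t1_v, s0_v, rss_v, ok = fit_t1(series, voxel)
        t1[voxel], s0[voxel], rss[voxel] = t1_v, s0_v, rss_v
        if not ok:
            out[voxel] = False
    return T1Map(t1_s=t1, s0=s0, rss=rss, mask=out)
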