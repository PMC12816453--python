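"""The four CEST quantification metrics and parametric-map arithmetic.

* MTR_asym(d) = Z(-d) - Z(+d): the classic asymmetry metric, reported in
  percent.  Simple, but confounded by NOE, semi-solid MT and spillover.
* Lorentzian amplitude: the fitted label-pool amplitude a_label.
* MTR_REX(d) = 1/Z_lab(d) - 1/Z_ref(d): inverse-difference metric that
  removes spillover dilution from neighboring pools.
* AREX(d) = MTR_REX(d) / T1_obs: divides out the observed longitudinal
  relaxation so the metric tracks the exchange-weighted solute signal
  rather than the tissue's T1.

Delta maps (post-challenge minus baseline) and the two-ROI contrast-to-noise
ratio CNR = |mu1 - mu2| / sqrt(s1^2 + s2^2) complete the map toolbox.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    EmptyROIError,
    IncompatibleMapsError,
    InvalidT1Error,
    NonPhysicalFitError,
    OutOfRangeError,
    UndefinedCNRError,
)
from .lorentz import LorentzFitResult, PoolModelConfig
from .zspec import ZSpectrum

__all__ = [
    "ParametricMap",
    "mtr_asym",
    "lorentz_amplitude",
    "mtr_rex",
    "arex",
    "delta_map",
    "cnr",
]

METRIC_NAMES = {"mtr_asym", "lorentz_amp", "mtr_rex", "arex"}


@dataclass
class ParametricMap:
    """One 2D metric map with its mask and provenance metadata.

    MTR_asym is stored in percent; amplitude and MTR_REX are dimensionless;
    AREX is per second (per the configured T1 unit).
    """

    values: np.ndarray
    metric_name: str
    label_freq_ppm: float
    mask: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        base = self.metric_name.removeprefix("delta_")
        if base not in METRIC_NAMES:
            raise IncompatibleMapsError(f"unknown metric name {self.metric_name!r}")
        if self.mask is None:
            self.mask = np.isfinite(self.values)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise IncompatibleMapsError("mask shape does not match values")

    def roi_values(self, roi: np.ndarray) -> np.ndarray:
        """Metric values over the ROI, restricted to the map's valid mask."""
        roi = np.asarray(roi, dtype=bool)
        sel = roi & self.mask & np.isfinite(self.values)
        if not sel.any():
            raise EmptyROIError("ROI does not intersect the valid-voxel mask")
        return self.values[sel]


def mtr_asym(spec: ZSpectrum, delta_ppm: float, as_percent: bool = True) -> float:
    """Asymmetry Z(-d) - Z(+d), interpolated at exactly +/-d.

    The spectrum should be B0-corrected and spline-smoothed.  Evaluation is
    by cubic-spline interpolation because the acquisition grid need not
    contain +/-d exactly (e.g. +/-1.28 ppm on a 0.1 ppm grid).
    """
    x, _ = spec.sorted_arrays()
    if not (x[0] <= -abs(delta_ppm) and abs(delta_ppm) <= x[-1]):
        raise OutOfRangeError(f"+/-{delta_ppm} ppm outside axis [{x[0]}, {x[-1]}]")
    d = abs(delta_ppm)
    zm, zp = spec.interpolate([-d, d])
    value = float(zm - zp)
    return value * 100.0 if as_percent else value


def lorentz_amplitude(fit: LorentzFitResult, config: PoolModelConfig) -> float:
    """Fitted amplitude of the label pool; NaN for a non-converged fit."""
    if not fit.converged:
        return float("nan")
    return float(fit.amplitudes[config.label_index])


def mtr_rex(z_lab: float, z_ref: float) -> float:
    """Inverse-difference metric 1/Z_lab - 1/Z_ref (>= 0 when Z_ref >= Z_lab)."""
    if not (np.isfinite(z_lab) and np.isfinite(z_ref)) or z_lab <= 1e-6 or z_ref <= 1e-6:
        raise NonPhysicalFitError(
            f"MTR_REX needs positive Z values, got Z_lab={z_lab!r}, Z_ref={z_ref!r}")
    return 1.0 / z_lab - 1.0 / z_ref


def arex(mtr_rex_value: float, t1_obs_s: float) -> float:
    """Relaxation-compensated metric MTR_REX / T1_obs (per second)."""
    if not np.isfinite(t1_obs_s) or t1_obs_s <= 0:
        raise InvalidT1Error(f"T1_obs must be positive and finite, got {t1_obs_s!r}")
    return mtr_rex_value / t1_obs_s


def delta_map(pre: ParametricMap, post: ParametricMap) -> ParametricMap:
    """Voxelwise post - pre map for challenge experiments (e.g. 2-DG infusion).

    Masks propagate by intersection; the metric name gains a ``delta_``
    prefix.  Requires matching metric, grid and label frequency.
    """
    if pre.metric_name != post.metric_name:
        raise IncompatibleMapsError(
            f"metric mismatch: {pre.metric_name} vs {post.metric_name}")
    if pre.values.shape != post.values.shape:
        raise IncompatibleMapsError("grid shapes differ")
    if pre.label_freq_ppm != post.label_freq_ppm:
        raise IncompatibleMapsError("label frequencies differ")
    return ParametricMap(
        values=post.values - pre.values,
        metric_name=f"delta_{pre.metric_name}",
        label_freq_ppm=pre.label_freq_ppm,
        mask=pre.mask & post.mask,
        provenance={"pre": pre.provenance, "post": post.provenance},
    )


def cnr(roi1_values, roi2_values, ddof: int = 1) -> float:
    """Contrast-to-noise ratio |mu1 - mu2| / sqrt(s1^2 + s2^2) between two ROIs.

    ``ddof=1`` (sample standard deviation) by default.  Symmetric in the two
    ROIs and invariant to adding a common constant.
    """
    v1 = np.asarray(roi1_values, dtype=float)
    v2 = np.asarray(roi2_values, dtype=float)
    if v1.size == 0 or v2.size == 0:
        raise EmptyROIError("CNR requires two non-empty ROIs")
    s1 = v1.std(ddof=ddof) if v1.size > ddof else 0.0
    s2 = v2.std(ddof=ddof) if v2.size > ddof else 0.0
    denom = np.sqrt(s1 ** 2 + s2 ** 2)
    if denom == 0:
        raise UndefinedCNRError("both ROIs have zero variance; CNR undefined")
    return float(abs(v1.mean() - v2.mean()) / denom)
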