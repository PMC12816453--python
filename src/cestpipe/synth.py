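"""Synthetic CEST data: phantoms, cohorts, WASSR/T1 series and a
Bloch-McConnell physics oracle.

Two generators produce z-spectra:

* a Lorentzian generator — the generative twin of the fit model, used for
  parameter-recovery and pipeline tests;
* a numerical Bloch-McConnell (BM) simulator of two exchanging pools under
  continuous-wave saturation — an independent physics oracle that shares no
  code with the Lorentzian model, used to check physical properties such as
  the T1-compensation of AREX.

Higher-level builders emulate the study designs the pipeline targets:

* a five-vial concentration phantom (label-pool amplitude proportional to
  concentration; 2-DG series at 4.5/9/13.5/18/22.5 mM, or an egg-white-like
  amide series at 20-100%);
* three-group tumor cohorts whose ROI-mean metric distributions follow
  configurable per-group mean/SD targets (defaults mirror the APTw and
  delta-2-DG group statistics of the murine study design), with smooth
  polynomial B0 fields, Gaussian noise on Z, and optional pre/post
  challenge pairs.

All generators are deterministic under their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .errors import CalibrationError, DesignError, InvalidParameterError
from .lorentz import (PoolModelConfig, PRESETS, aptw_config, dg2_config,
                      fit_pools, model_eval)
from .metrics import arex as arex_metric
from .metrics import mtr_asym as mtr_asym_metric
from .metrics import mtr_rex as mtr_rex_metric
from .lorentz import compute_zlab_zref
from .t1 import VariableTRSeries
from .zspec import OffsetAxis, ZSpectrum, ZSpectrumStack, cest_axis, wassr_axis

__all__ = [
    "simulate_zspectrum_lorentzian",
    "simulate_bm_zspectrum",
    "single_pool_cw_steady_state",
    "polynomial_b0_field",
    "PhantomDesign",
    "PhantomBundle",
    "generate_phantom",
    "CohortDesign",
    "generate_cohort",
    "amplitude_response_curve",
    "TABLE_APTW",
    "TABLE_DELTA_DG",
    "DEFAULT_TRS_MS",
]

GAMMA_HZ_PER_UT = 42.577  # proton gyromagnetic ratio, Hz per microtesla

DEFAULT_TRS_MS = np.array([867.0, 1500.0, 2500.0, 4000.0, 6000.0])

# Group-level targets the cohort generator calibrates to: per metric,
# (mean, sd) for the Luminal A / HER2+ / triple-negative breast-cancer
# subtype groups.  APTw metrics at +3.50 ppm (MTR_asym in percent, others
# a.u.); delta-2-DG metrics at +1.28 ppm, all in percent-scaled a.u.
TABLE_APTW = {
    "mtr_asym":    {"LuminalA": (2.43, 1.69), "HER2pos": (2.34, 1.32), "TripleNegative": (3.06, 0.80)},
    "lorentz_amp": {"LuminalA": (0.037, 0.025), "HER2pos": (0.055, 0.018), "TripleNegative": (0.062, 0.022)},
    "mtr_rex":     {"LuminalA": (0.023, 0.020), "HER2pos": (0.059, 0.051), "TripleNegative": (0.079, 0.057)},
    "arex":        {"LuminalA": (0.016, 0.009), "HER2pos": (0.033, 0.025), "TripleNegative": (0.041, 0.027)},
}
TABLE_DELTA_DG = {
    "mtr_asym":    {"LuminalA": (0.653, 0.490), "HER2pos": (1.35, 1.45), "TripleNegative": (1.28, 0.67)},
    "lorentz_amp": {"LuminalA": (1.16, 0.38), "HER2pos": (1.59, 0.33), "TripleNegative": (1.64, 0.63)},
    "mtr_rex":     {"LuminalA": (4.45, 2.13), "HER2pos": (6.67, 2.07), "TripleNegative": (6.52, 1.36)},
    "arex":        {"LuminalA": (2.31, 0.88), "HER2pos": (3.59, 1.04), "TripleNegative": (3.21, 0.82)},
}

APTW_GROUP_SIZES = {"LuminalA": 12, "HER2pos": 14, "TripleNegative": 13}
DG_GROUP_SIZES = {"LuminalA": 9, "HER2pos": 9, "TripleNegative": 10}


# ---------------------------------------------------------------------------
# Lorentzian generator
# ---------------------------------------------------------------------------

def simulate_zspectrum_lorentzian(amplitudes, centers_ppm, widths_ppm,
                                  axis: OffsetAxis, z_base: float = 1.0,
                                  b0_shift_ppm: float = 0.0,
                                  noise_sd: float = 0.0,
                                  rng: np.random.Generator | None = None,
                                  ref_intensity: float = 1000.0,
                                  noise_model: str = "gaussian"):
    """Simulate one voxel: z = Z_base - sum L_k at (offset - b0_shift) + noise.

    ``noise_model`` is ``"gaussian"`` (additive on Z, the default) or
    ``"rician"`` (magnitude of Z plus complex Gaussian noise, as in
    magnitude MR images at low SNR).  Returns ``(z, sat_intensities,
    ref_intensity)`` — the noisy z values and the saturated/reference
    intensities a scanner would record for them.
    """
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be >= 0")
    if noise_model not in ("gaussian", "rician"):
        raise InvalidParameterError(f"unknown noise model {noise_model!r}")
    shifted = OffsetAxis(axis.offsets_ppm - b0_shift_ppm)
    z = model_eval(amplitudes, centers_ppm, widths_ppm, z_base, shifted).z
    if noise_sd > 0:
        if rng is None:
            raise InvalidParameterError("noise_sd > 0 requires an rng")
        if noise_model == "gaussian":
            z = z + rng.normal(0.0, noise_sd, size=z.shape)
        else:
            z = np.hypot(z + rng.normal(0.0, noise_sd, size=z.shape),
                         rng.normal(0.0, noise_sd, size=z.shape))
    return z, z * ref_intensity, ref_intensity


# ---------------------------------------------------------------------------
# Bloch-McConnell oracle
# ---------------------------------------------------------------------------

def simulate_bm_zspectrum(axis: OffsetAxis, f_b: float, k_b: float,
                          shift_b_ppm: float = 3.5,
                          t1a_s: float = 2.0, t2a_s: float = 0.07,
                          t1b_s: float = 1.0, t2b_s: float = 0.01,
                          b1_uT: float = 3.0, sat_duration_s: float = 3.0,
                          field_MHz: float = 400.0) -> ZSpectrum:
    """Two-pool Bloch-McConnell z-spectrum under continuous-wave saturation.

    Pool a is water, pool b the solute with fraction ``f_b`` and
    solute-to-water exchange rate ``k_b`` (1/s).  For each offset the
    coupled 6-dimensional magnetization system (with longitudinal recovery)
    is propagated for ``sat_duration_s`` from thermal equilibrium via the
    exact matrix exponential of the affine system; Z = M_za(end) / M0a.
    Defaults mirror a 9.4 T acquisition (3 uT, 3 s CW saturation).
    """
    if not (0.0 <= f_b <= 0.1):
        raise InvalidParameterError("f_b must lie in [0, 0.1]")
    if k_b < 0 or min(t1a_s, t2a_s, t1b_s, t2b_s) <= 0:
        raise InvalidParameterError("rates and relaxation times must be positive")
    r1a, r2a = 1.0 / t1a_s, 1.0 / t2a_s
    r1b, r2b = 1.0 / t1b_s, 1.0 / t2b_s
    kba = k_b                     # solute -> water
    kab = f_b * k_b               # water -> solute (detailed balance)
    w1 = 2.0 * np.pi * GAMMA_HZ_PER_UT * b1_uT      # rad/s
    m0 = np.array([0.0, 0.0, 1.0, 0.0, 0.0, f_b])
    z = np.empty(len(axis))
    for j, off_ppm in enumerate(axis.offsets_ppm):
        da = 2.0 * np.pi * field_MHz * (0.0 - off_ppm)        # water offset
        db = 2.0 * np.pi * field_MHz * (shift_b_ppm - off_ppm)
        A = np.array([
            [-r2a - kab, -da, 0.0, kba, 0.0, 0.0],
            [da, -r2a - kab, w1, 0.0, kba, 0.0],
            [0.0, -w1, -r1a - kab, 0.0, 0.0, kba],
            [kab, 0.0, 0.0, -r2b - kba, -db, 0.0],
            [0.0, kab, 0.0, db, -r2b - kba, w1],
            [0.0, 0.0, kab, 0.0, -w1, -r1b - kba],
        ])
        b = np.array([0.0, 0.0, r1a, 0.0, 0.0, r1b * f_b])
        aug = np.zeros((7, 7))
        aug[:6, :6] = A * sat_duration_s
        aug[:6, 6] = b * sat_duration_s
        m = expm(aug) @ np.append(m0, 1.0)
        z[j] = m[2]
    return ZSpectrum(z=z, axis=axis, b0_shift_ppm=0.0)


def single_pool_cw_steady_state(axis: OffsetAxis, t1_s: float, t2_s: float,
                                b1_uT: float, field_MHz: float = 400.0) -> np.ndarray:
    """Closed-form single-pool CW steady state (analytical cross-check).

    Mz_ss / M0 = R1 (R2^2 + D^2) / (R1 (R2^2 + D^2) + w1^2 R2) with D the
    offset in rad/s.
    """
    r1, r2 = 1.0 / t1_s, 1.0 / t2_s
    w1 = 2.0 * np.pi * GAMMA_HZ_PER_UT * b1_uT
    d = 2.0 * np.pi * field_MHz * axis.offsets_ppm
    return r1 * (r2 ** 2 + d ** 2) / (r1 * (r2 ** 2 + d ** 2) + w1 ** 2 * r2)


# ---------------------------------------------------------------------------
# Smooth B0 fields
# ---------------------------------------------------------------------------

def polynomial_b0_field(grid_shape: tuple[int, int], amplitude_ppm: float = 0.2,
                        rng: np.random.Generator | None = None) -> np.ndarray:
    """Smooth low-order polynomial B0 surface scaled to +/- amplitude_ppm."""
    ny, nx = grid_shape
    y, x = np.mgrid[0:ny, 0:nx]
    xn = 2.0 * x / max(nx - 1, 1) - 1.0
    yn = 2.0 * y / max(ny - 1, 1) - 1.0
    if rng is None:
        coeffs = np.array([0.3, 0.5, -0.4, 0.2, -0.3, 0.1])
    else:
        coeffs = rng.uniform(-1, 1, size=6)
    surf = (coeffs[0] + coeffs[1] * xn + coeffs[2] * yn + coeffs[3] * xn * yn
            + coeffs[4] * xn ** 2 + coeffs[5] * yn ** 2)
    peak = np.abs(surf).max()
    if peak == 0:
        return np.zeros(grid_shape)
    return surf * (amplitude_ppm / peak)


def _wassr_spectrum(axis: OffsetAxis, b0_shift_ppm: float, width_ppm: float = 0.35,
                    depth: float = 0.95, noise_sd: float = 0.0,
                    rng: np.random.Generator | None = None) -> np.ndarray:
    """Narrow low-power water dip for WASSR stacks."""
    z = 1.0 - depth / (1.0 + 4.0 * ((axis.offsets_ppm - b0_shift_ppm) / width_ppm) ** 2)
    if noise_sd > 0 and rng is not None:
        z = z + rng.normal(0.0, noise_sd, size=z.shape)
    return z


# ---------------------------------------------------------------------------
# Phantom generator
# ---------------------------------------------------------------------------

@dataclass
class PhantomDesign:
    """Five-vial concentration phantom on a square grid.

    The label-pool amplitude in vial v is ``amp_per_unit * concentration_v``
    on top of a constant background (water + broad MT).  Defaults follow the
    2-DG series (4.5/9/13.5/18/22.5 mM); ``preset='aptw'`` with
    concentrations 20..100 emulates the egg-white protein series.
    """

    grid_shape: tuple[int, int] = (64, 64)
    vial_centers: tuple = ()
    vial_radius: float = 4.0
    concentrations: tuple = (4.5, 9.0, 13.5, 18.0, 22.5)
    preset: str = "dg2"
    amp_per_unit: float = 0.002
    water_amp: float = 0.85
    water_width: float = 1.4
    mt_amp: float = 0.05
    mt_width: float = 8.0
    other_pool_fraction: float = 0.35
    noise_sd: float = 0.0
    b0_amplitude_ppm: float = 0.0
    t1_s: float = 2.0
    ref_intensity: float = 1000.0

    def resolved_centers(self) -> list[tuple[int, int]]:
        if self.vial_centers:
            return list(self.vial_centers)
        ny, nx = self.grid_shape
        k = len(self.concentrations)
        xs = np.linspace(0.15, 0.85, k) * (nx - 1)
        return [(ny // 2, int(round(x))) for x in xs]

    def validate(self) -> None:
        if len(self.concentrations) < 2 or np.any(np.diff(self.concentrations) <= 0):
            raise DesignError("concentrations must be positive and increasing")
        if np.any(np.asarray(self.concentrations) <= 0):
            raise DesignError("concentrations must be positive")
        centers = self.resolved_centers()
        for i in range(len(centers)):
            for j in range(i + 1, len(centers)):
                d = np.hypot(centers[i][0] - centers[j][0], centers[i][1] - centers[j][1])
                if d < 2 * self.vial_radius:
                    raise DesignError(f"vials {i} and {j} overlap")
        if self.preset not in PRESETS:
            raise DesignError(f"unknown pool preset {self.preset!r}")


@dataclass
class PhantomBundle:
    """Everything the pipeline needs for one phantom acquisition."""

    cest: ZSpectrumStack
    wassr: ZSpectrumStack
    t1_series: VariableTRSeries
    roi_labels: np.ndarray          # 0 = background, 1..n = vials
    truth: pd.DataFrame
    b0_ppm: np.ndarray


def _pool_parameter_grid(design: PhantomDesign):
    """Per-vial pool parameters (amplitudes/centers/widths arrays)."""
    config = PRESETS[design.preset]()
    names = [p.name for p in config.pools]
    centers = np.array([p.center_ppm for p in config.pools])
    widths = np.array([p.width_init for p in config.pools])
    li = config.label_index
    per_vial = []
    for conc in design.concentrations:
        amps = np.zeros(len(names))
        amps[names.index("water")] = design.water_amp
        if "mt" in names:
            amps[names.index("mt")] = design.mt_amp
        label_amp = design.amp_per_unit * conc
        amps[li] = label_amp
        # non-label solute pools scale with the same concentration
        for i, nm in enumerate(names):
            if nm.startswith("dg") and i != li:
                amps[i] = design.other_pool_fraction * label_amp
            if nm in ("amide", "amine", "noe") and i != li:
                amps[i] = design.other_pool_fraction * label_amp
        per_vial.append(amps)
    return config, names, centers, widths, per_vial


def generate_phantom(design: PhantomDesign, seed: int = 0) -> PhantomBundle:
    """Build a geometrically consistent CEST/WASSR/T1 phantom bundle."""
    design.validate()
    rng = np.random.default_rng(seed)
    ny, nx = design.grid_shape
    axis = cest_axis()
    waxis = wassr_axis()
    config, names, centers, widths, per_vial = _pool_parameter_grid(design)

    roi = np.zeros(design.grid_shape, dtype=int)
    yy, xx = np.mgrid[0:ny, 0:nx]
    for v, (cy, cx) in enumerate(design.resolved_centers(), start=1):
        roi[(yy - cy) ** 2 + (xx - cx) ** 2 <= design.vial_radius ** 2] = v

    b0 = (polynomial_b0_field(design.grid_shape, design.b0_amplitude_ppm)
          if design.b0_amplitude_ppm > 0 else np.zeros(design.grid_shape))

    bg_amps = np.zeros(len(names))
    bg_amps[names.index("water")] = design.water_amp
    if "mt" in names:
        bg_amps[names.index("mt")] = design.mt_amp

    sat = np.empty((ny, nx, len(axis)))
    wassr = np.empty((ny, nx, len(waxis)))
    rows = []
    for iy in range(ny):
        for ix in range(nx):
            v = roi[iy, ix]
            amps = per_vial[v - 1] if v > 0 else bg_amps
            z, s, _ = simulate_zspectrum_lorentzian(
                amps, centers, widths, axis, b0_shift_ppm=b0[iy, ix],
                noise_sd=design.noise_sd, rng=rng if design.noise_sd > 0 else None,
                ref_intensity=design.ref_intensity)
            sat[iy, ix] = s
            wassr[iy, ix] = _wassr_spectrum(
                waxis, b0[iy, ix], noise_sd=design.noise_sd,
                rng=rng if design.noise_sd > 0 else None)
            if v > 0:
                rows.append({"vial": v, "y": iy, "x": ix,
                             "concentration": design.concentrations[v - 1],
                             "label_amp": amps[config.label_index],
                             "b0_ppm": b0[iy, ix], "t1_s": design.t1_s})

    ref = np.full(design.grid_shape, design.ref_intensity)
    cest = ZSpectrumStack(sat_images=sat, ref_image=ref, axis=axis, mask=roi > 0)
    wassr_stack = ZSpectrumStack(
        sat_images=wassr * design.ref_intensity, ref_image=ref.copy(),
        axis=waxis, mask=roi > 0)
    tr_s = DEFAULT_TRS_MS / 1000.0
    t1_imgs = design.ref_intensity * (1.0 - np.exp(-tr_s[None, None, :] / design.t1_s))
    t1_imgs = np.broadcast_to(t1_imgs, (ny, nx, tr_s.size)).copy()
    if design.noise_sd > 0:
        t1_imgs += rng.normal(0.0, design.noise_sd * design.ref_intensity,
                              size=t1_imgs.shape)
        t1_imgs = np.clip(t1_imgs, 0.0, None)
    series = VariableTRSeries(images=t1_imgs, trs_ms=DEFAULT_TRS_MS)
    return PhantomBundle(cest=cest, wassr=wassr_stack, t1_series=series,
                         roi_labels=roi, truth=pd.DataFrame(rows), b0_ppm=b0)


# ---------------------------------------------------------------------------
# Cohort generator
# ---------------------------------------------------------------------------

@dataclass
class CohortDesign:
    """Three-group tumor cohort with per-metric mean/SD targets.

    ``targets[metric][group] = (mean, sd)`` on the metric's reporting scale
    (MTR_asym in percent).  The generator calibrates each subject's
    label-pool amplitude through a precomputed amplitude->metric response
    curve so the ROI means realize the targets.  ``standardize`` rescales
    each group's latent draws to the exact target mean/SD so finite-sample
    luck does not masquerade as calibration error.
    """

    group_sizes: dict = field(default_factory=lambda: dict(APTW_GROUP_SIZES))
    targets: dict = field(default_factory=lambda: {"arex": TABLE_APTW["arex"]})
    calibration_metric: str = "arex"
    preset: str = "aptw"
    image_shape: tuple[int, int] = (12, 12)
    roi_halfwidth: int = 1
    b0_amplitude_ppm: float = 0.05
    noise_sd: float = 0.0
    t1_s: float = 2.0
    pre_post: bool = False
    post_increment_fraction: float = 0.5
    standardize: bool = True
    seed: int = 0

    def validate(self) -> None:
        if any(n < 3 for n in self.group_sizes.values()):
            raise DesignError("each group needs >= 3 subjects")
        tgt = self.targets.get(self.calibration_metric)
        if tgt is None:
            raise DesignError(f"no targets for calibration metric {self.calibration_metric!r}")
        if any(sd <= 0 for _, sd in tgt.values()):
            raise DesignError("target SDs must be positive")


def _metric_from_amplitude(label_amp: float, config: PoolModelConfig,
                           names, centers, widths, base_amps,
                           metric: str, t1_s: float, axis: OffsetAxis) -> float:
    """Noiseless amplitude -> metric response (one point of the curve)."""
    amps = base_amps.copy()
    amps[config.label_index] = label_amp
    z = model_eval(amps, centers, widths, 1.0, axis)
    if metric == "mtr_asym":
        return mtr_asym_metric(z, config.label_freq_ppm)
    fit = fit_pools(z, config)
    if metric == "lorentz_amp":
        return float(fit.amplitudes[config.label_index])
    zl, zr = compute_zlab_zref(fit, config)
    rex = mtr_rex_metric(zl, zr)
    if metric == "mtr_rex":
        return rex
    if metric == "arex":
        return arex_metric(rex, t1_s)
    raise CalibrationError(f"unknown metric {metric!r}")


def amplitude_response_curve(config: PoolModelConfig, metric: str,
                             t1_s: float = 2.0, amp_max: float = 0.25,
                             n_points: int = 200,
                             base_amps: np.ndarray | None = None,
                             axis: OffsetAxis | None = None):
    """Precompute label-amplitude -> metric lookup over [0, amp_max].

    MTR_asym / amplitude responses are cheap closed paths; MTR_REX and AREX
    go through the actual fitter, so the curve embodies exactly the
    pipeline's nonlinearity.  Returns (amplitudes, metric values), metric on
    its reporting scale.
    """
    axis = axis or cest_axis()
    names = [p.name for p in config.pools]
    centers = np.array([p.center_ppm for p in config.pools])
    widths = np.array([p.width_init for p in config.pools])
    if base_amps is None:
        base_amps = np.zeros(len(names))
        base_amps[names.index("water")] = 0.85
        if "mt" in names:
            base_amps[names.index("mt")] = 0.05
        if "noe" in names:
            base_amps[names.index("noe")] = 0.04
        if "amine" in names:
            base_amps[names.index("amine")] = 0.02
        for nm in names:
            if nm.startswith("dg") and nm != config.label_pool:
                base_amps[names.index(nm)] = 0.01
    grid = np.linspace(0.0, amp_max, n_points)
    vals = np.array([_metric_from_amplitude(a, config, names, centers, widths,
                                            base_amps, metric, t1_s, axis)
                     for a in grid])
    if not np.all(np.diff(vals) > 0):
        # keep the longest strictly increasing prefix; metrics can saturate
        bad = np.flatnonzero(np.diff(vals) <= 0)
        cut = int(bad[0]) + 1 if bad.size else grid.size
        if cut < 8:
            raise CalibrationError("amplitude response curve is not increasing")
        grid, vals = grid[:cut], vals[:cut]
    return grid, vals, base_amps, centers, widths


def generate_cohort(design: CohortDesign):
    """Generate per-subject bundles plus a truth table.

    Each subject receives a latent target metric value drawn from its
    group's Normal(mean, sd) (standardized to the exact group mean/SD when
    ``standardize``), inverted through the response curve to a label-pool
    amplitude, and rendered as a small image bundle (tumor ROI, smooth B0
    field, Gaussian noise on Z, matching WASSR and variable-TR series).
    Returns ``(subjects, truth)``; ``subjects`` maps subject_id to a dict
    with pre (and optionally post) :class:`PhantomBundle`-like inputs.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    config = PRESETS[design.preset]()
    axis = cest_axis()
    waxis = wassr_axis()
    grid, vals, base_amps, centers, widths = amplitude_response_curve(
        config, design.calibration_metric, t1_s=design.t1_s)
    names = [p.name for p in config.pools]

    targets = design.targets[design.calibration_metric]
    subjects: dict = {}
    rows = []
    sid = 0
    for group, n in design.group_sizes.items():
        mean, sd = targets[group]
        draws = rng.normal(mean, sd, size=n)
        if design.standardize and n > 1 and draws.std(ddof=1) > 0:
            draws = (draws - draws.mean()) / draws.std(ddof=1) * sd + mean
        lo, hi = vals[0], vals[-1]
        clipped = np.clip(draws, lo + 1e-9, hi - 1e-9)
        for target_value, raw in zip(clipped, draws):
            sid += 1
            label_amp = float(np.interp(target_value, vals, grid))
            bundle = _render_subject(design, config, names, centers, widths,
                                     base_amps, label_amp, axis, waxis, rng)
            post_amp = None
            if design.pre_post:
                post_amp = label_amp * (1.0 + design.post_increment_fraction)
                bundle["post"] = _render_subject(
                    design, config, names, centers, widths, base_amps,
                    post_amp, axis, waxis, rng)["pre"]
            subjects[f"S{sid:03d}"] = bundle
            rows.append({"subject_id": f"S{sid:03d}", "group": group,
                         "metric_name": design.calibration_metric,
                         "target_value": float(target_value),
                         "raw_draw": float(raw), "clipped": bool(raw != target_value),
                         "label_amp": label_amp, "post_label_amp": post_amp,
                         "t1_s": design.t1_s, "noise_sd": design.noise_sd})
    return subjects, pd.DataFrame(rows)


def _render_subject(design: CohortDesign, config, names, centers, widths,
                    base_amps, label_amp, axis, waxis,
                    rng: np.random.Generator) -> dict:
    ny, nx = design.image_shape
    h = design.roi_halfwidth
    cy, cx = ny // 2, nx // 2
    roi = np.zeros((ny, nx), dtype=bool)
    roi[cy - h:cy + h + 1, cx - h:cx + h + 1] = True
    b0 = (polynomial_b0_field(design.image_shape, design.b0_amplitude_ppm, rng)
          if design.b0_amplitude_ppm > 0 else np.zeros(design.image_shape))
    amps = base_amps.copy()
    amps[config.label_index] = label_amp
    ref_val = 1000.0
    sat = np.empty((ny, nx, len(axis)))
    wassr = np.empty((ny, nx, len(waxis)))
    for iy, ix in zip(*np.nonzero(roi)):
        z, s, _ = simulate_zspectrum_lorentzian(
            amps, centers, widths, axis, b0_shift_ppm=b0[iy, ix],
            noise_sd=design.noise_sd, rng=rng if design.noise_sd > 0 else None,
            ref_intensity=ref_val)
        sat[iy, ix] = s
        wassr[iy, ix] = ref_val * _wassr_spectrum(
            waxis, b0[iy, ix], noise_sd=design.noise_sd,
            rng=rng if design.noise_sd > 0 else None)
    sat[~roi] = ref_val
    wassr[~roi] = ref_val
    ref = np.full((ny, nx), ref_val)
    tr_s = DEFAULT_TRS_MS / 1000.0
    t1_imgs = np.broadcast_to(
        ref_val * (1.0 - np.exp(-tr_s[None, None, :] / design.t1_s)),
        (ny, nx, tr_s.size)).copy()
    return {
        "pre": PhantomBundle(
            cest=ZSpectrumStack(sat, ref, axis, mask=roi),
            wassr=ZSpectrumStack(wassr, ref.copy(), waxis, mask=roi),
            t1_series=VariableTRSeries(t1_imgs, DEFAULT_TRS_MS),
            roi_labels=roi.astype(int), truth=pd.DataFrame(), b0_ppm=b0),
    }
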