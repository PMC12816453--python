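"""End-to-end postprocessing: stacks in, parametric maps and reports out.

Stage order follows the standard CEST postprocessing scheme: normalization
to Z, per-voxel B0 estimation from WASSR, re-referencing of the CEST
spectrum, spline smoothing, MTR_asym, multi-pool Lorentzian fit, label
amplitude, MTR_REX, T1 fit, AREX, optional delta maps, ROI statistics with
outlier exclusion and group tests.  Every run writes a QC report (masked
voxel counts, non-convergence counts) and a JSON manifest sufficient to
reproduce it.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import b0 as b0mod
from .errors import CestPipeError, NonPhysicalFitError
from .lorentz import PRESETS, compute_zlab_zref, fit_pools
from .metrics import ParametricMap, arex, lorentz_amplitude, mtr_asym, mtr_rex
from .t1 import T1Map, fit_t1_map, VariableTRSeries
from .zspec import ZSpectrum, ZSpectrumStack, normalize_to_z, spline_smooth

__all__ = ["PipelineResult", "process_stack", "run_pipeline"]


@dataclass
class PipelineResult:
    """Maps and diagnostics from one processed acquisition."""

    maps: dict
    fits: dict
    b0_field: b0mod.B0Field | None
    t1_map: T1Map | None
    qc: dict
    spectra: dict = field(default_factory=dict)


def process_stack(cest: ZSpectrumStack, wassr: ZSpectrumStack | None = None,
                  t1_series: VariableTRSeries | None = None,
                  preset: str = "aptw", label_freq_ppm: float | None = None,
                  smoothing: float | None = 0.0,
                  keep_spectra: bool = False) -> PipelineResult:
    """Run the voxelwise pipeline over the masked voxels of a CEST stack.

    WASSR and the variable-TR series are optional: without WASSR no B0
    correction is applied (shift 0 recorded); without T1 the AREX map is
    omitted.  Returns all four parametric maps plus QC counters.
    """
    config = PRESETS[preset]()
    delta = label_freq_ppm if label_freq_ppm is not None else config.label_freq_ppm
    shape = cest.grid_shape
    qc = {"n_voxels_in_mask": int(cest.mask.sum()), "n_b0_masked": 0,
          "n_fit_nonconverged": 0, "n_nonphysical": 0, "n_t1_flagged": 0}

    b0_field = None
    if wassr is not None:
        wassr_specs = {}
        for voxel in zip(*np.nonzero(cest.mask & wassr.mask)):
            wassr_specs[voxel] = normalize_to_z(wassr, voxel)
        b0_field = b0mod.estimate_b0_field(wassr_specs, shape, cest.mask & wassr.mask)
        qc["n_b0_masked"] = int((cest.mask & ~b0_field.mask).sum())
        work_mask = b0_field.mask
    else:
        work_mask = cest.mask

    t1map = None
    if t1_series is not None:
        t1map = fit_t1_map(t1_series, work_mask)
        qc["n_t1_flagged"] = int((work_mask & ~t1map.mask).sum())

    maps = {m: np.full(shape, np.nan) for m in
            ("mtr_asym", "lorentz_amp", "mtr_rex", "arex")}
    valid = np.zeros(shape, dtype=bool)
    fits = {}
    spectra = {}
    for voxel in zip(*np.nonzero(work_mask)):
        spec = normalize_to_z(cest, voxel)
        shift = 0.0
        if b0_field is not None and np.isfinite(b0_field.shift_ppm[voxel]):
            shift = float(b0_field.shift_ppm[voxel])
        corrected = b0mod.apply_b0_correction(spec, shift)
        smoothed = spline_smooth(corrected, smoothing)
        maps["mtr_asym"][voxel] = mtr_asym(smoothed, delta)
        fit = fit_pools(smoothed, config)
        fits[voxel] = fit
        if keep_spectra:
            spectra[voxel] = smoothed
        if not fit.converged:
            qc["n_fit_nonconverged"] += 1
            continue
        maps["lorentz_amp"][voxel] = lorentz_amplitude(fit, config)
        try:
            zl, zr = compute_zlab_zref(fit, config, delta)
            rex = mtr_rex(zl, zr)
        except NonPhysicalFitError:
            qc["n_nonphysical"] += 1
            continue
        maps["mtr_rex"][voxel] = rex
        valid[voxel] = True
        if t1map is not None and t1map.mask[voxel]:
            maps["arex"][voxel] = arex(rex, float(t1map.t1_s[voxel]))

    out_maps = {}
    for name, vals in maps.items():
        if name == "arex" and t1_series is None:
            continue
        out_maps[name] = ParametricMap(
            values=vals, metric_name=name, label_freq_ppm=delta,
            mask=np.isfinite(vals),
            provenance={"preset": preset, "smoothing": smoothing})
    return PipelineResult(maps=out_maps, fits=fits, b0_field=b0_field,
                          t1_map=t1map, qc=qc, spectra=spectra)


def run_pipeline(config, log=print) -> Path:
    """File-driven end-to-end run from a :class:`cestpipe.io.PipelineConfig`.

    Reads the configured stacks, processes them, writes every metric map as
    NIfTI (+ sidecar), the QC report and ROI statistics as delimited text,
    and a JSON run manifest.  Returns the output directory.
    """
    from . import io as iomod
    from .stats import CohortTable, roi_mean

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    cest = iomod.read_stack(config.cest_stack, config.cest_offsets,
                            ref_path=config.ref_image, ref_frame=config.ref_frame,
                            mask_path=config.mask)
    wassr = None
    if config.wassr_stack is not None:
        if config.ref_image is None:
            raise CestPipeError("WASSR correction requires a separate ref_image")
        wassr = iomod.read_stack(config.wassr_stack, config.wassr_offsets,
                                 ref_path=config.ref_image, mask_path=config.mask)
    t1_series = None
    if config.t1_series is not None:
        t1_series = iomod.read_tr_series(config.t1_series, config.t1_trs)

    result = process_stack(cest, wassr, t1_series, preset=config.preset,
                           label_freq_ppm=config.label_freq_ppm,
                           smoothing=config.smoothing)
    for name, pmap in result.maps.items():
        iomod.write_map(pmap, out / f"{name}.nii.gz")
    if result.b0_field is not None:
        iomod._save_nifti(out / "b0_shift_ppm.nii.gz", result.b0_field.shift_ppm)

    rows = []
    if config.mask is not None:
        rois = iomod.read_mask_labels(config.mask)
        for label, roi in rois.items():
            for name, pmap in result.maps.items():
                try:
                    mean, n = roi_mean(pmap, roi)
                except CestPipeError:
                    continue
                rows.append({"roi": label, "metric_name": name,
                             "mean": mean, "n_voxels": n})
    pd.DataFrame(rows).to_csv(out / "roi_stats.tsv", sep="\t", index=False)

    qc = dict(result.qc)
    if result.b0_field is not None:
        qc["b0_summary"] = result.b0_field.summary()
    (out / "qc_report.json").write_text(json.dumps(qc, indent=2))

    manifest = {
        "config": {k: getattr(config, k) for k in config.__dataclass_fields__},
        "elapsed_s": round(time.time() - t0, 3),
        "outputs": sorted(p.name for p in out.iterdir()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    log(f"pipeline complete: {out} ({manifest['elapsed_s']} s, "
        f"{qc['n_voxels_in_mask']} voxels)")
    return out
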