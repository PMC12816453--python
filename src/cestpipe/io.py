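"""NIfTI / delimited-text readers and writers plus configuration loading.

Conventions
-----------
* CEST/WASSR stacks: one NIfTI volume whose last axis indexes saturation
  offsets, accompanied by a two-column delimited table (index, offset_ppm).
  The unsaturated reference is a separate NIfTI or a designated frame index
  within the stack.
* Variable-TR series: NIfTI volume + (index, tr_ms) table.
* Masks/ROIs: NIfTI integer label volumes (0 = background).
* Parametric maps: NIfTI + JSON sidecar with metric name, label frequency
  and pipeline provenance.
* Pipeline configuration: YAML, validated against a small schema.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, InvalidInputError
from .metrics import ParametricMap
from .t1 import VariableTRSeries
from .zspec import OffsetAxis, ZSpectrumStack

__all__ = [
    "read_offset_table", "write_offset_table",
    "read_stack", "write_stack",
    "read_tr_series", "write_tr_series",
    "read_mask_labels", "write_labels",
    "read_map", "write_map",
    "PipelineConfig", "load_config",
]


def _load_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def _save_nifti(path, data: np.ndarray, affine: np.ndarray | None = None) -> None:
    if affine is None:
        affine = np.eye(4)
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))


def read_offset_table(path) -> np.ndarray:
    """Two-column (index, offset_ppm) delimited table -> offsets array."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    cols = [c.strip().lower() for c in df.columns]
    if "offset_ppm" not in cols:
        raise InvalidInputError(f"{path}: expected a column named 'offset_ppm'")
    return df[df.columns[cols.index("offset_ppm")]].to_numpy(dtype=float)


def write_offset_table(path, offsets_ppm: np.ndarray) -> None:
    pd.DataFrame({"index": np.arange(len(offsets_ppm)),
                  "offset_ppm": offsets_ppm}).to_csv(path, sep="\t", index=False)


def read_stack(stack_path, offsets_path, ref_path=None,
               ref_frame: int | None = None, mask_path=None) -> ZSpectrumStack:
    """Read a saturated stack with its offset table and reference image.

    Exactly one of ``ref_path`` / ``ref_frame`` must be given; a frame
    index designates one stack frame as the unsaturated reference (removed
    from the spectral axis).
    """
    data, _ = _load_nifti(stack_path)
    offsets = read_offset_table(offsets_path)
    if (ref_path is None) == (ref_frame is None):
        raise ConfigError("specify exactly one of ref_path / ref_frame")
    if ref_frame is not None:
        if not (0 <= ref_frame < data.shape[-1]):
            raise ConfigError(f"ref_frame {ref_frame} outside stack")
        ref = data[..., ref_frame]
        data = np.delete(data, ref_frame, axis=-1)
    else:
        ref, _ = _load_nifti(ref_path)
    if data.shape[-1] != offsets.size:
        raise InvalidInputError(
            f"stack has {data.shape[-1]} frames but offset table {offsets.size} rows")
    mask = None
    if mask_path is not None:
        m, _ = _load_nifti(mask_path)
        mask = m > 0
    return ZSpectrumStack(sat_images=data, ref_image=ref,
                          axis=OffsetAxis(offsets), mask=mask)


def write_stack(stack: ZSpectrumStack, stack_path, offsets_path, ref_path) -> None:
    _save_nifti(stack_path, stack.sat_images)
    _save_nifti(ref_path, stack.ref_image)
    write_offset_table(offsets_path, stack.axis.offsets_ppm)


def read_tr_series(series_path, tr_path) -> VariableTRSeries:
    data, _ = _load_nifti(series_path)
    df = pd.read_csv(tr_path, sep=None, engine="python", comment="#")
    cols = [c.strip().lower() for c in df.columns]
    if "tr_ms" not in cols:
        raise InvalidInputError(f"{tr_path}: expected a column named 'tr_ms'")
    trs = df[df.columns[cols.index("tr_ms")]].to_numpy(dtype=float)
    if data.shape[-1] != trs.size:
        raise InvalidInputError(
            f"series has {data.shape[-1]} frames but TR table {trs.size} rows")
    return VariableTRSeries(images=data, trs_ms=trs)


def write_tr_series(series: VariableTRSeries, series_path, tr_path) -> None:
    _save_nifti(series_path, series.images)
    pd.DataFrame({"index": np.arange(series.trs_ms.size),
                  "tr_ms": series.trs_ms}).to_csv(tr_path, sep="\t", index=False)


def read_mask_labels(path) -> dict[int, np.ndarray]:
    """Integer label volume -> {label: boolean ROI mask} (label 0 excluded)."""
    data, _ = _load_nifti(path)
    labels = np.unique(data[np.isfinite(data)]).astype(int)
    return {int(l): data.astype(int) == l for l in labels if l != 0}


def write_labels(path, labels: np.ndarray) -> None:
    _save_nifti(path, np.asarray(labels, dtype=np.int16))


def write_map(pmap: ParametricMap, nifti_path, sidecar_path=None) -> None:
    _save_nifti(nifti_path, pmap.values)
    if sidecar_path is None:
        sidecar_path = str(nifti_path).replace(".nii.gz", "").replace(".nii", "") + ".json"
    meta = {"metric_name": pmap.metric_name,
            "label_freq_ppm": pmap.label_freq_ppm,
            "provenance": pmap.provenance}
    Path(sidecar_path).write_text(json.dumps(meta, indent=2, default=str))


def read_map(nifti_path, sidecar_path=None) -> ParametricMap:
    data, _ = _load_nifti(nifti_path)
    if sidecar_path is None:
        sidecar_path = str(nifti_path).replace(".nii.gz", "").replace(".nii", "") + ".json"
    meta = json.loads(Path(sidecar_path).read_text())
    return ParametricMap(values=data, metric_name=meta["metric_name"],
                         label_freq_ppm=meta["label_freq_ppm"],
                         provenance=meta.get("provenance", {}))


@dataclass
class PipelineConfig:
    """Validated run configuration (see ``load_config`` for the YAML schema)."""

    cest_stack: str
    cest_offsets: str
    out_dir: str
    ref_image: str | None = None
    ref_frame: int | None = None
    wassr_stack: str | None = None
    wassr_offsets: str | None = None
    t1_series: str | None = None
    t1_trs: str | None = None
    mask: str | None = None
    preset: str = "aptw"
    label_freq_ppm: float | None = None
    smoothing: float | None = 0.0
    quartile_convention: str = "linear"
    cnr_ddof: int = 1
    noise_margin: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.preset not in ("aptw", "dg2"):
            raise ConfigError(f"preset must be 'aptw' or 'dg2', got {self.preset!r}")
        if self.label_freq_ppm is None:
            self.label_freq_ppm = 3.50 if self.preset == "aptw" else 1.28
        if (self.ref_image is None) == (self.ref_frame is None):
            raise ConfigError("specify exactly one of ref_image / ref_frame")


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    allowed = set(PipelineConfig.__dataclass_fields__)
    unknown = set(raw) - allowed
    if unknown:
        raise ConfigError(f"{path}: unknown config fields {sorted(unknown)}")
    for req in ("cest_stack", "cest_offsets", "out_dir"):
        if req not in raw:
            raise ConfigError(f"{path}: missing required field '{req}'")
    cfg = PipelineConfig(**raw)
    base = Path(path).parent
    for fld in ("cest_stack", "cest_offsets", "ref_image", "wassr_stack",
                "wassr_offsets", "t1_series", "t1_trs", "mask"):
        val = getattr(cfg, fld)
        if val is not None:
            p = Path(val)
            if not p.is_absolute():
                p = base / p
            if not p.exists():
                raise ConfigError(f"config field '{fld}': file not found: {p}")
            setattr(cfg, fld, str(p))
    return cfg
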