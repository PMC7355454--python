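"""On-disk case layout: NIfTI volumes, CSV manifests, JSON sidecars.

Conventions
-----------
* Internal axis order is ``(slice, row, col)`` for 3D volumes and
  ``(frame, slice, row, col)`` for the DSC series; the slice axis is the
  axial stack.  On disk the standard NIfTI order ``(col, row, slice[, frame])``
  is used and transposed on load.
* Voxel indexing is 0-based.  The NIfTI affine is consulted only for voxel
  spacing; volumes are assumed co-registered and axially acquired, so no
  reorientation is performed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

MANIFEST_COLUMNS = [
    "case_id",
    "scenario",
    "mrs",
    "onset_to_mri_min",
    "tr_s",
    "te_s",
    "adc_path",
    "pwi_path",
    "day7_path",
]


@dataclass
class CaseVolumeSet:
    """One patient's co-registered baseline volumes plus clinical metadata.

    ADC is in 1e-6 mm^2/s (so the ischemic-core threshold is 600 on this
    scale); the PWI series is raw signal intensity with the frame axis first.
    """

    case_id: str
    adc: np.ndarray                      # (slice, row, col)
    pwi: np.ndarray | None               # (frame, slice, row, col)
    spacing_mm: tuple[float, float, float]  # (slice, row, col)
    tr_s: float
    te_s: float
    day7_mask: np.ndarray | None = None
    scenario: str = "unknown"            # SR | UR | unknown
    mrs: int | None = None
    onset_to_mri_min: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.tr_s <= 0 or self.te_s <= 0:
            raise ValueError("TR and TE must be positive")
        if self.pwi is not None and self.pwi.shape[1:] != self.adc.shape:
            raise ValueError(
                f"PWI spatial shape {self.pwi.shape[1:]} does not match "
                f"ADC shape {self.adc.shape}"
            )
        if self.day7_mask is not None:
            if self.day7_mask.shape != self.adc.shape:
                raise ValueError(
                    f"day-7 mask shape {self.day7_mask.shape} does not match "
                    f"ADC shape {self.adc.shape}"
                )
            vals = np.unique(self.day7_mask)
            if not np.isin(vals, [0, 1]).all():
                raise ValueError("day-7 mask must be binary")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.adc.shape

    @property
    def pixel_spacing_mm(self) -> float:
        return self.spacing_mm[2]

    @property
    def voxel_volume_mm3(self) -> float:
        ds, dr, dc = self.spacing_mm
        return ds * dr * dc


def _affine(spacing_mm: tuple[float, float, float]) -> np.ndarray:
    # (col, row, slice) zooms in NIfTI order
    return np.diag([spacing_mm[2], spacing_mm[1], spacing_mm[0], 1.0])


def write_volume(
    path: str | Path,
    volume: np.ndarray,
    spacing_mm: tuple[float, float, float],
    overwrite: bool = True,
) -> Path:
    """Write a 3D (slice,row,col) or 4D (frame,slice,row,col) array as NIfTI.

    Binary masks are stored as uint8; everything else as float32.
    """
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace")
    vol = np.asarray(volume)
    if vol.ndim == 3:
        data = vol.transpose(2, 1, 0)
    elif vol.ndim == 4:
        data = vol.transpose(3, 2, 1, 0)
    else:
        raise ValueError("expected a 3D or 4D array")
    if vol.dtype == bool or (np.issubdtype(vol.dtype, np.integer)
                             and np.isin(np.unique(vol), [0, 1]).all()):
        data = data.astype(np.uint8)
    else:
        data = data.astype(np.float32)
    img = nib.Nifti1Image(data, _affine(spacing_mm))
    img.header.set_zooms((spacing_mm[2], spacing_mm[1], spacing_mm[0])
                         + ((1.0,) if vol.ndim == 4 else ()))
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return path


def read_volume(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a NIfTI volume into internal axis order; spacing from the header."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    zooms = img.header.get_zooms()
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    if data.ndim == 3:
        return data.transpose(2, 1, 0), spacing
    if data.ndim == 4:
        return data.transpose(3, 2, 1, 0), spacing
    raise ValueError(f"{path}: expected 3D/4D NIfTI, got {data.ndim}D")


def save_case(case: CaseVolumeSet, case_dir: str | Path, overwrite: bool = True) -> dict:
    """Write one case's volumes plus a JSON metadata sidecar; returns paths."""
    case_dir = Path(case_dir)
    case_dir.mkdir(parents=True, exist_ok=True)
    paths = {"adc_path": case_dir / f"{case.case_id}_adc.nii.gz"}
    write_volume(paths["adc_path"], case.adc, case.spacing_mm, overwrite)
    if case.pwi is not None:
        paths["pwi_path"] = case_dir / f"{case.case_id}_pwi.nii.gz"
        write_volume(paths["pwi_path"], case.pwi, case.spacing_mm, overwrite)
    if case.day7_mask is not None:
        paths["day7_path"] = case_dir / f"{case.case_id}_day7.nii.gz"
        write_volume(paths["day7_path"], case.day7_mask.astype(np.uint8),
                     case.spacing_mm, overwrite)
    sidecar = {
        "case_id": case.case_id,
        "scenario": case.scenario,
        "mrs": case.mrs,
        "onset_to_mri_min": case.onset_to_mri_min,
        "tr_s": case.tr_s,
        "te_s": case.te_s,
        "spacing_mm": list(case.spacing_mm),
        "voxel_volume_mm3": case.voxel_volume_mm3,
        **case.meta,
    }
    sidecar_path = case_dir / f"{case.case_id}_meta.json"
    sidecar_path.write_text(json.dumps(sidecar, indent=2, default=float))
    paths["meta_path"] = sidecar_path
    return {k: str(v) for k, v in paths.items()}


def load_case(row: pd.Series | dict, require_day7: bool = False) -> CaseVolumeSet:
    """Load a case from one manifest row; enforces shape/spacing consistency."""
    row = dict(row)
    adc, spacing = read_volume(row["adc_path"])
    pwi, pwi_spacing = read_volume(row["pwi_path"])
    if pwi.shape[1:] != adc.shape:
        raise ValueError(
            f"case {row['case_id']}: PWI spatial shape {pwi.shape[1:]} "
            f"!= ADC shape {adc.shape}"
        )
    if not np.allclose(pwi_spacing, spacing, atol=1e-4):
        raise ValueError(f"case {row['case_id']}: ADC/PWI voxel spacing mismatch")
    day7 = None
    day7_path = row.get("day7_path")
    if day7_path and str(day7_path) not in ("", "nan"):
        day7, _ = read_volume(day7_path)
        day7 = (day7 > 0).astype(np.uint8)
    elif require_day7:
        raise ValueError(f"case {row['case_id']}: day-7 mask required but missing")
    mrs = row.get("mrs")
    onset = row.get("onset_to_mri_min")
    return CaseVolumeSet(
        case_id=str(row["case_id"]),
        adc=adc.astype(np.float32),
        pwi=pwi.astype(np.float32),
        spacing_mm=spacing,
        tr_s=float(row["tr_s"]),
        te_s=float(row["te_s"]),
        day7_mask=day7,
        scenario=str(row.get("scenario", "unknown")),
        mrs=None if pd.isna(mrs) else int(mrs),
        onset_to_mri_min=None if pd.isna(onset) else float(onset),
    )


def write_manifest(rows: list[dict], path: str | Path) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    if df["case_id"].duplicated().any():
        raise ValueError("duplicate case_ids in manifest")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return df


def read_manifest(path: str | Path, check_files: bool = True) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    if df["case_id"].duplicated().any():
        raise ValueError("duplicate case_ids in manifest")
    if check_files:
        base = Path(path).parent
        for col in ("adc_path", "pwi_path"):
            for p in df[col]:
                q = Path(p)
                if not q.is_absolute():
                    q = base / q
                if not q.exists():
                    raise FileNotFoundError(f"manifest references missing file {p}")
    return df


def save_maps(
    case: CaseVolumeSet,
    named_maps: dict[str, np.ndarray],
    out_dir: str | Path,
    overwrite: bool = False,
) -> dict[str, str]:
    """Write derived maps (rTTP, probability, masks, ...) on the case grid.

    Probability and rTTP maps are stored as float32 without rescaling; binary
    masks as uint8.  Refuses to overwrite unless asked.
    """
    out = {}
    for name, vol in named_maps.items():
        if vol.shape != case.shape:
            raise ValueError(f"map '{name}' shape {vol.shape} != case grid {case.shape}")
        p = Path(out_dir) / f"{case.case_id}_{name}.nii.gz"
        write_volume(p, vol, case.spacing_mm, overwrite=overwrite)
        out[name] = str(p)
    return out


def brain_mask_from_signal(pwi: np.ndarray, n_baseline: int = 8,
                           fraction: float = 0.2) -> np.ndarray:
    """Threshold brain mask: mean baseline signal above a fraction of its
    robust (99th-percentile) maximum.  A pragmatic stand-in for skull
    stripping; adequate for phantoms and roughly masked clinical data.
    """
    s0 = pwi[:n_baseline].mean(axis=0)
    ref = np.percentile(s0, 99)
    return s0 > fraction * ref
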