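"""TTP / rTTP perfusion maps from a DSC signal time series.

The relative time-to-peak (rTTP) approach deliberately avoids arterial-input-
function selection and deconvolution: the MR signal is converted to a
concentration-proportional curve, the time of its peak (TTP) is taken per
voxel, and the median TTP of the less-delayed ("contralateral") hemisphere is
subtracted as the per-case baseline.  An rTTP > 4.5 s mask serves as the
perfusion-lesion surrogate for the conventional Tmax > 6 s criterion, and a
configurable higher rTTP cut stands in for the severe-lesion Tmax > 10 s
criterion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

#: Default thresholds: core ADC (1e-6 mm^2/s), perfusion-lesion rTTP (s),
#: severe-lesion rTTP surrogate (s).
ADC_CORE_THRESHOLD = 600.0
RTTP_PERFUSION_THRESHOLD_S = 4.5
RTTP_SEVERE_THRESHOLD_S = 8.0


@dataclass(frozen=True)
class RTTPMap:
    """Voxel-wise rTTP (s) and the hemispheric baseline that produced it."""

    rttp_s: np.ndarray
    baseline_ttp_s: float
    contralateral: str                  # "left" | "right"

    @property
    def lesion_side(self) -> str:
        return "right" if self.contralateral == "left" else "left"


@dataclass(frozen=True)
class LesionVolumes:
    core_ml: float
    perfusion_ml: float
    severe_ml: float
    adc_threshold: float = ADC_CORE_THRESHOLD
    perfusion_threshold_s: float = RTTP_PERFUSION_THRESHOLD_S
    severe_threshold_s: float = RTTP_SEVERE_THRESHOLD_S

    def as_dict(self) -> dict:
        return {
            "core_ml": self.core_ml,
            "perfusion_ml": self.perfusion_ml,
            "severe_ml": self.severe_ml,
            "adc_threshold": self.adc_threshold,
            "perfusion_threshold_s": self.perfusion_threshold_s,
            "severe_threshold_s": self.severe_threshold_s,
        }


def signal_to_concentration(
    series: np.ndarray,
    te_s: float,
    n_baseline: int = 8,
    floor_fraction: float = 1e-3,
) -> tuple[np.ndarray, np.ndarray]:
    """Convert DSC signal to a concentration-proportional curve.

    C(t) = -ln(S(t) / S0) / TE with the proportionality constant taken as 1
    (TTP is invariant to positive scaling).  S0 is the per-voxel mean of the
    first ``n_baseline`` (pre-bolus) frames.  Non-positive signal samples are
    clamped to ``floor_fraction * S0``; voxels with S0 <= 0 are invalid.

    Returns ``(concentration, valid)`` where ``valid`` is a spatial boolean
    map of voxels with a usable baseline.
    """
    if n_baseline < 3:
        raise ValueError("need at least 3 pre-bolus baseline frames")
    if te_s <= 0:
        raise ValueError("TE must be positive")
    series = np.asarray(series)
    dtype = np.float32 if series.dtype == np.float32 else np.float64
    s0 = series[:n_baseline].mean(axis=0, dtype=np.float64).astype(dtype)
    valid = s0 > 0
    s0_safe = np.where(valid, s0, dtype(1.0))
    # clamping S at floor*S0 == clamping the ratio at floor; done in place to
    # keep the 4D temporaries to a single allocation
    conc = series / s0_safe
    np.maximum(conc, dtype(floor_fraction), out=conc)
    np.log(conc, out=conc)
    conc *= dtype(-1.0 / te_s)
    conc[:, ~valid] = np.nan
    return conc, valid


def compute_ttp(concentration: np.ndarray, tr_s: float) -> np.ndarray:
    """TTP map (s): frame index of the concentration maximum times TR.

    Ties break to the earliest frame (``argmax`` convention); no sub-frame
    interpolation is applied.  All-invalid voxels are NaN.
    """
    if tr_s <= 0:
        raise ValueError("TR must be positive")
    conc = np.asarray(concentration, dtype=np.float64)
    invalid = np.isnan(conc).all(axis=0)
    filled = np.where(np.isnan(conc), -np.inf, conc)
    ttp = np.argmax(filled, axis=0).astype(np.float64) * tr_s
    ttp[invalid] = np.nan
    return ttp


def compute_rttp(
    ttp_s: np.ndarray,
    left_mask: np.ndarray,
    right_mask: np.ndarray,
    lesion_hint: str | None = None,
) -> RTTPMap:
    """Subtract the hemispheric baseline TTP to obtain rTTP.

    The hemisphere with the lower median TTP is the contralateral (healthy)
    side; its median is the baseline.  On an exact median tie the hemisphere
    opposite ``lesion_hint`` is chosen (left if no hint), with a warning.
    """
    left_mask = np.asarray(left_mask, dtype=bool)
    right_mask = np.asarray(right_mask, dtype=bool)
    if not left_mask.any() or not right_mask.any():
        raise ValueError("both hemisphere masks must be non-empty")
    med_left = float(np.nanmedian(ttp_s[left_mask]))
    med_right = float(np.nanmedian(ttp_s[right_mask]))
    if med_left < med_right:
        contra = "left"
    elif med_right < med_left:
        contra = "right"
    else:
        contra = ({"left": "right", "right": "left"}.get(lesion_hint)
                  if lesion_hint else None) or "left"
        warnings.warn(
            "hemispheric median TTPs tie; contralateral side set to "
            f"{contra!r}", stacklevel=2,
        )
    baseline = med_left if contra == "left" else med_right
    return RTTPMap(rttp_s=ttp_s - baseline, baseline_ttp_s=baseline,
                   contralateral=contra)


def lesion_masks(
    adc: np.ndarray,
    rttp: RTTPMap,
    brain_mask: np.ndarray,
    adc_threshold: float = ADC_CORE_THRESHOLD,
    perfusion_threshold_s: float = RTTP_PERFUSION_THRESHOLD_S,
    severe_threshold_s: float = RTTP_SEVERE_THRESHOLD_S,
) -> dict[str, np.ndarray]:
    """Threshold masks: ischemic core (low ADC), perfusion lesion and severe
    lesion (high rTTP), all restricted to the brain mask."""
    brain = np.asarray(brain_mask, dtype=bool)
    with np.errstate(invalid="ignore"):
        core = brain & (np.asarray(adc) < adc_threshold)
        perf = brain & (rttp.rttp_s > perfusion_threshold_s)
        severe = brain & (rttp.rttp_s > severe_threshold_s)
    return {"core": core, "perfusion": perf, "severe": severe}


def mask_volume_ml(mask: np.ndarray, spacing_mm: tuple[float, float, float]) -> float:
    """Volume in mL: voxel count times voxel volume / 1000."""
    if spacing_mm is None or any(s <= 0 for s in spacing_mm):
        raise ValueError("voxel spacing must be positive")
    voxvol = spacing_mm[0] * spacing_mm[1] * spacing_mm[2]
    return float(np.count_nonzero(mask)) * voxvol / 1000.0


def lesion_masks_and_volumes(
    adc: np.ndarray,
    rttp: RTTPMap,
    brain_mask: np.ndarray,
    spacing_mm: tuple[float, float, float],
    adc_threshold: float = ADC_CORE_THRESHOLD,
    perfusion_threshold_s: float = RTTP_PERFUSION_THRESHOLD_S,
    severe_threshold_s: float = RTTP_SEVERE_THRESHOLD_S,
) -> tuple[LesionVolumes, dict[str, np.ndarray]]:
    masks = lesion_masks(adc, rttp, brain_mask, adc_threshold,
                         perfusion_threshold_s, severe_threshold_s)
    volumes = LesionVolumes(
        core_ml=mask_volume_ml(masks["core"], spacing_mm),
        perfusion_ml=mask_volume_ml(masks["perfusion"], spacing_mm),
        severe_ml=mask_volume_ml(masks["severe"], spacing_mm),
        adc_threshold=adc_threshold,
        perfusion_threshold_s=perfusion_threshold_s,
        severe_threshold_s=severe_threshold_s,
    )
    return volumes, masks
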