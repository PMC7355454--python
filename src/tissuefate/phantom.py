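"""Synthetic stroke phantom: ADC + DSC time series with known tissue fates.

Each case is an ellipsoidal "brain" split by a configurable midsagittal plane.
One hemisphere carries an ellipsoidal hypoperfused region (per-voxel bolus
delay with smooth spatial jitter) containing an ellipsoidal ischemic core of
low ADC.  The DSC signal follows a gamma-variate first-pass bolus

    S(t) = S0 * exp(-TE * C(t)),
    C(t) = A * ((t - ta)/tp)^alpha * exp(alpha * (1 - (t - ta)/tp)),  t > ta,

with per-voxel arrival ta = t0*TR + delay.  Ground-truth final infarcts under
successful (SR) and unsuccessful (UR) recanalization are the core plus the
(1 - f) fraction of penumbral voxels with the largest true delay, where f is
the scenario's salvage fraction — so UR fates nest SR fates whenever
f_UR <= f_SR.  A 90-day mRS score is drawn from a noisy logistic function of
final infarct volume; only its monotone association with volume is meaningful.

Default geometry and acquisition settings mimic a 3T DSC protocol:
256 x 256 matrix, 0.9375 mm pixels, 6.5 mm slice spacing, 50 frames at
TR 1.5 s, TE 35 ms, lesions confined to one middle-cerebral-artery territory.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .geometry import MidlineTransform
from .io import CaseVolumeSet, save_case, write_manifest


@dataclass(frozen=True)
class PhantomConfig:
    shape: tuple[int, int, int] = (22, 256, 256)   # (slices, rows, cols)
    pixel_spacing_mm: float = 0.9375
    slice_spacing_mm: float = 6.5
    n_frames: int = 50
    tr_s: float = 1.5
    te_s: float = 0.035
    t0_frame: int = 8                  # bolus arrival frame in normal tissue
    delay_s: float = 6.0               # extra arrival delay in hypoperfusion
    delay_jitter_sd_s: float = 1.5     # smooth spatial jitter of the delay
    delay_jitter_scale_mm: float = 7.5  # in-plane correlation length of jitter
    # reference delay for the tissue-fate threshold; defaults to delay_s.
    # Cohorts anchor it to the nominal delay so that fate is one global
    # function of the voxel delay across all cases.
    fate_delay_ref_s: float | None = None
    core_adc: tuple[float, float] = (450.0, 50.0)      # mean, SD; 1e-6 mm^2/s
    penumbra_adc: tuple[float, float] = (750.0, 50.0)
    normal_adc: tuple[float, float] = (900.0, 60.0)
    s0: float = 100.0                  # pre-bolus signal level
    noise_sd: float = 2.0              # additive Gaussian signal noise
    # salvage fractions implied by clinical cohort medians: with successful
    # recanalization the day-7 infarct barely exceeds the baseline core
    # (near-complete penumbra salvage), without it most penumbra infarcts
    f_sr: float = 0.95                 # salvaged penumbra fraction, SR
    f_ur: float = 0.3                  # salvaged penumbra fraction, UR
    hypo_volume_ml: float = 90.0       # hypoperfusion lesion volume
    core_volume_ml: float = 15.0       # ischemic core volume
    midline_angle_deg: float = 0.0     # ground-truth midline rotation
    midline_shift_mm: float = 0.0      # ground-truth midline translation
    bolus_alpha: float = 3.0
    bolus_tp_s: float = 6.0
    bolus_amplitude: float = 17.0      # peak concentration, 1/s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.f_ur > self.f_sr:
            raise ValueError("f_UR must not exceed f_SR")
        if not (0 <= self.f_ur <= 1 and 0 <= self.f_sr <= 1):
            raise ValueError("salvage fractions must lie in [0, 1]")
        if self.delay_s < 0:
            raise ValueError("hypoperfusion delay must be non-negative")
        if self.pixel_spacing_mm <= 0 or self.slice_spacing_mm <= 0:
            raise ValueError("voxel spacings must be positive")
        if self.n_frames < self.t0_frame + 10:
            raise ValueError("need at least 10 frames after bolus arrival")
        if self.core_volume_ml >= self.hypo_volume_ml:
            raise ValueError("core volume must be smaller than the "
                             "hypoperfusion volume")

    @property
    def spacing_mm(self) -> tuple[float, float, float]:
        return (self.slice_spacing_mm, self.pixel_spacing_mm, self.pixel_spacing_mm)

    @property
    def voxel_volume_mm3(self) -> float:
        return self.slice_spacing_mm * self.pixel_spacing_mm**2


@dataclass
class GroundTruth:
    """Per-case truth: masks, delay field, fates, and the midline used."""

    brain_mask: np.ndarray
    hemisphere_labels: np.ndarray      # 0 background, 1 contralateral, 2 lesion side
    core_mask: np.ndarray
    hypoperfusion_mask: np.ndarray
    true_rttp_s: np.ndarray
    final_mask_sr: np.ndarray
    final_mask_ur: np.ndarray
    mrs_sr: int
    mrs_ur: int
    midline: MidlineTransform
    lesion_slices: tuple[int, int] = (0, 0)   # inclusive slice range of lesion

    def final_mask(self, scenario: str) -> np.ndarray:
        if scenario not in ("SR", "UR"):
            raise ValueError(f"unknown scenario {scenario!r}")
        return self.final_mask_sr if scenario == "SR" else self.final_mask_ur

    def mrs(self, scenario: str) -> int:
        return self.mrs_sr if scenario == "SR" else self.mrs_ur


def _canonical_coords(config: PhantomConfig):
    """(u, v, z) mm coordinates: u = signed distance to the midline plane,
    v = in-plane coordinate along the plane, z = axial offset from centre."""
    ns, nr, nc = config.shape
    rows, cols = np.mgrid[0:nr, 0:nc]
    x = (cols - (nc - 1) / 2.0) * config.pixel_spacing_mm
    y = (rows - (nr - 1) / 2.0) * config.pixel_spacing_mm
    a = np.deg2rad(config.midline_angle_deg)
    nx, ny = np.cos(a), np.sin(a)
    u2d = x * nx + y * ny - config.midline_shift_mm
    v2d = -x * ny + y * nx
    z1d = (np.arange(ns) - (ns - 1) / 2.0) * config.slice_spacing_mm
    u = np.broadcast_to(u2d, (ns, nr, nc))
    v = np.broadcast_to(v2d, (ns, nr, nc))
    z = z1d[:, None, None] * np.ones((1, nr, nc))
    return u, v, z


def _ellipsoid_semiaxes(volume_ml: float, axial_semi_mm: float) -> float:
    """In-plane semi-axis (a = b) of an ellipsoid with the given volume."""
    vol_mm3 = volume_ml * 1000.0
    ab = 3.0 * vol_mm3 / (4.0 * np.pi * axial_semi_mm)
    return float(np.sqrt(ab))


def _norm_ppf(q: float) -> float:
    from scipy.stats import norm

    return float(norm.ppf(q))


def _mrs_from_volume(volume_ml: float, rng: np.random.Generator,
                     v50_ml: float = 60.0, scale_ml: float = 30.0,
                     noise_sd: float = 0.7) -> int:
    p = 1.0 / (1.0 + np.exp(-(volume_ml - v50_ml) / scale_ml))
    return int(np.clip(np.rint(6.0 * p + rng.normal(0.0, noise_sd)), 0, 6))


def generate_case(
    config: PhantomConfig,
    case_id: str = "case",
    with_pwi: bool = True,
) -> tuple[CaseVolumeSet, GroundTruth]:
    """Generate one synthetic case and its ground truth.

    ``with_pwi=False`` skips the 4D series (for geometry-only experiments).
    The returned case carries the SR-scenario day-7 mask by default; use
    :func:`as_scenario` to re-label a case for a specific scenario.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    ns, nr, nc = config.shape
    u, v, z = _canonical_coords(config)

    # brain: ellipsoid occupying most of the FOV, symmetric about the midline
    fov_r = (nr - 1) / 2.0 * config.pixel_spacing_mm
    fov_s = (ns - 1) / 2.0 * config.slice_spacing_mm
    au, av, az = 0.62 * fov_r, 0.80 * fov_r, 0.92 * fov_s
    brain = (u / au) ** 2 + (v / av) ** 2 + (z / az) ** 2 <= 1.0

    midline = MidlineTransform(
        config.midline_angle_deg, config.midline_shift_mm,
        config.shape, config.pixel_spacing_mm,
    )

    # lesion geometry in the u < 0 hemisphere (MCA-territory-like placement)
    az_hypo = min(0.75 * az, max(3.6 * config.slice_spacing_mm, 0.45 * az))
    a_hypo = _ellipsoid_semiaxes(config.hypo_volume_ml, az_hypo)
    az_core = 0.8 * az_hypo
    a_core = _ellipsoid_semiaxes(config.core_volume_ml, az_core)
    u0 = -0.55 * au
    hypo = ((u - u0) / a_hypo) ** 2 + (v / a_hypo) ** 2 + (z / az_hypo) ** 2 <= 1.0
    core = ((u - u0) / a_core) ** 2 + (v / a_core) ** 2 + (z / az_core) ** 2 <= 1.0
    hypo &= brain
    core &= brain & hypo
    if not core.any() or not (hypo & ~core).any():
        raise ValueError("degenerate lesion geometry: empty core or penumbra")

    # per-voxel bolus delay: constant + smooth jitter inside the lesion
    delay = np.zeros(config.shape, dtype=np.float64)
    if config.delay_jitter_sd_s > 0:
        noise = rng.standard_normal(config.shape)
        sig_px = config.delay_jitter_scale_mm / config.pixel_spacing_mm
        smooth = ndimage.gaussian_filter(noise, sigma=(1.0, sig_px, sig_px))
        sd = smooth[hypo].std()
        jitter = smooth * (config.delay_jitter_sd_s / sd) if sd > 0 else 0.0
        delay[hypo] = np.maximum(config.delay_s + jitter[hypo], 0.0)
    else:
        delay[hypo] = config.delay_s

    # ADC per tissue compartment (1e-6 mm^2/s)
    adc = np.zeros(config.shape, dtype=np.float32)
    for mask, (mu, sd) in (
        (brain, config.normal_adc),
        (hypo & ~core, config.penumbra_adc),
        (core, config.core_adc),
    ):
        n = int(mask.sum())
        adc[mask] = rng.normal(mu, sd, size=n).astype(np.float32)
    adc = np.clip(adc, 0.0, None)

    # ground-truth tissue fates: the core infarcts always; a penumbral voxel
    # infarcts iff its delay exceeds the f-quantile of the nominal delay
    # distribution, so the expected salvaged fraction is f and fate is a
    # deterministic function of the voxel's true delay
    penumbra = hypo & ~core

    def final_mask(f: float) -> np.ndarray:
        if f >= 1.0:
            return core.copy()
        if f <= 0.0:
            return hypo.copy()
        ref = (config.fate_delay_ref_s if config.fate_delay_ref_s is not None
               else config.delay_s)
        thr = ref + _norm_ppf(f) * config.delay_jitter_sd_s
        return core | (penumbra & (delay > thr))

    final_ur = final_mask(config.f_ur)
    final_sr = final_mask(config.f_sr)
    # nesting is guaranteed by the shared worst-first ordering
    voxvol = config.voxel_volume_mm3
    mrs_sr = _mrs_from_volume(final_sr.sum() * voxvol / 1000.0, rng)
    mrs_ur = _mrs_from_volume(final_ur.sum() * voxvol / 1000.0, rng)

    pwi = None
    if with_pwi:
        t = np.arange(config.n_frames, dtype=np.float64) * config.tr_s
        ta = config.t0_frame * config.tr_s + delay           # (S, R, C)
        # gamma-variate concentration, evaluated frame by frame
        pwi = np.empty((config.n_frames,) + config.shape, dtype=np.float32)
        alpha, tp, amp = config.bolus_alpha, config.bolus_tp_s, config.bolus_amplitude
        for k in range(config.n_frames):
            rel = (t[k] - ta) / tp
            conc = np.where(
                rel > 0,
                amp * rel**alpha * np.exp(alpha * (1.0 - rel)),
                0.0,
            )
            frame = config.s0 * np.exp(-config.te_s * conc)
            pwi[k] = np.where(brain, frame, 0.0)
        if config.noise_sd > 0:
            pwi += rng.normal(0.0, config.noise_sd, size=pwi.shape).astype(np.float32)

    lesion_slabs = np.flatnonzero(hypo.any(axis=(1, 2)))
    gt = GroundTruth(
        brain_mask=brain,
        hemisphere_labels=np.where(brain, np.where(u < 0, 2, 1), 0).astype(np.uint8),
        core_mask=core,
        hypoperfusion_mask=hypo,
        true_rttp_s=delay,
        final_mask_sr=final_sr,
        final_mask_ur=final_ur,
        mrs_sr=mrs_sr,
        mrs_ur=mrs_ur,
        midline=midline,
        lesion_slices=(int(lesion_slabs[0]), int(lesion_slabs[-1])),
    )
    case = CaseVolumeSet(
        case_id=case_id,
        adc=adc,
        pwi=pwi,
        spacing_mm=config.spacing_mm,
        tr_s=config.tr_s,
        te_s=config.te_s,
        day7_mask=final_sr.astype(np.uint8),
        scenario="SR",
        mrs=mrs_sr,
        onset_to_mri_min=float(rng.uniform(60, 240)),
    )
    return case, gt


def as_scenario(case: CaseVolumeSet, gt: GroundTruth, scenario: str) -> CaseVolumeSet:
    """Return a copy of the case labelled with the given scenario's fate."""
    c = CaseVolumeSet(
        case_id=case.case_id,
        adc=case.adc,
        pwi=case.pwi,
        spacing_mm=case.spacing_mm,
        tr_s=case.tr_s,
        te_s=case.te_s,
        day7_mask=gt.final_mask(scenario).astype(np.uint8),
        scenario=scenario,
        mrs=gt.mrs(scenario),
        onset_to_mri_min=case.onset_to_mri_min,
    )
    return c


def generate_cohort(
    config: PhantomConfig,
    n_cases: int,
    seed: int = 0,
    sr_fraction: float = 0.5,
) -> tuple[list[tuple[CaseVolumeSet, GroundTruth]], "pd.DataFrame"]:
    """Generate a cohort with per-case lesion-size/delay variation.

    Cases are assigned SR or UR scenarios (first ``sr_fraction`` SR), and
    per-case lesion volumes and delays are drawn from clinically plausible
    ranges around the configured defaults.  Reproducible for a fixed seed.
    """
    import pandas as pd

    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    ss = np.random.SeedSequence(seed)
    case_seeds = ss.generate_state(n_cases)
    rng = np.random.default_rng(ss.spawn(1)[0])
    n_sr = int(round(sr_fraction * n_cases))

    cases = []
    rows = []
    for i in range(n_cases):
        scenario = "SR" if i < n_sr else "UR"
        # lesion sizes are drawn wide (log-normal), echoing the large
        # interquartile spread of clinical perfusion/diffusion volumes; the
        # per-case delay level varies only mildly so that tissue fate is
        # governed by the voxel-level delay field rather than a case offset
        hypo_ml = float(np.clip(config.hypo_volume_ml
                                * rng.lognormal(0.0, 0.45), 35.0, 220.0))
        core_ml = float(np.clip(config.core_volume_ml
                                * rng.lognormal(0.0, 1.0), 3.0, 70.0))
        core_ml = min(core_ml, 0.45 * hypo_ml)
        delay = float(rng.uniform(0.95, 1.05) * config.delay_s)
        cfg = replace(
            config,
            hypo_volume_ml=hypo_ml,
            core_volume_ml=core_ml,
            delay_s=delay,
            fate_delay_ref_s=(config.fate_delay_ref_s
                              if config.fate_delay_ref_s is not None
                              else config.delay_s),
            seed=int(case_seeds[i] % (2**31 - 1)),
        )
        case_id = f"case{i:03d}"
        case, gt = generate_case(cfg, case_id=case_id)
        case = as_scenario(case, gt, scenario)
        cases.append((case, gt))
        rows.append({
            "case_id": case_id,
            "scenario": scenario,
            "mrs": case.mrs,
            "onset_to_mri_min": case.onset_to_mri_min,
            "tr_s": cfg.tr_s,
            "te_s": cfg.te_s,
            "hypo_volume_ml": hypo_ml,
            "core_volume_ml": core_ml,
            "delay_s": delay,
        })
    return cases, pd.DataFrame(rows)


def write_cohort(
    cases: list[tuple[CaseVolumeSet, GroundTruth]],
    manifest_df,
    out_dir,
) -> str:
    """Write a generated cohort to disk (NIfTI + CSV manifest + truth masks)."""
    from pathlib import Path

    out_dir = Path(out_dir)
    rows = []
    for (case, gt), (_, mrow) in zip(cases, manifest_df.iterrows()):
        case_dir = out_dir / case.case_id
        paths = save_case(case, case_dir)
        # ground-truth sidecar volumes for audit / evaluation
        from .io import write_volume
        write_volume(case_dir / f"{case.case_id}_gt_core.nii.gz",
                     gt.core_mask.astype(np.uint8), case.spacing_mm)
        write_volume(case_dir / f"{case.case_id}_gt_hypo.nii.gz",
                     gt.hypoperfusion_mask.astype(np.uint8), case.spacing_mm)
        rows.append({
            "case_id": case.case_id,
            "scenario": case.scenario,
            "mrs": case.mrs,
            "onset_to_mri_min": case.onset_to_mri_min,
            "tr_s": case.tr_s,
            "te_s": case.te_s,
            "adc_path": paths["adc_path"],
            "pwi_path": paths.get("pwi_path", ""),
            "day7_path": paths.get("day7_path", ""),
        })
    manifest_path = out_dir / "manifest.csv"
    write_manifest(rows, manifest_path)
    return str(manifest_path)
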