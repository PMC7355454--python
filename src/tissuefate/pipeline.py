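"""End-to-end orchestration: maps -> features -> models -> clinical report.

`prepare_case` runs the per-case stages (brain mask, midline, TTP/rTTP,
threshold volumes, slice window, candidate features) and caches everything
downstream steps need; `run_cohort` trains the SR and UR models on their
respective scenario cases, predicts both fates for every case, and assembles
the clinical and agreement reports.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import clinical, evaluation, features, geometry, model, perfusion
from .io import CaseVolumeSet, brain_mask_from_signal
from .phantom import GroundTruth

log = logging.getLogger(__name__)


@dataclass
class PreparedCase:
    """Derived per-case data shared by training, prediction and reporting."""

    case: CaseVolumeSet
    brain_mask: np.ndarray
    midline: geometry.MidlineTransform
    rttp: perfusion.RTTPMap
    rttp_filled: np.ndarray          # NaN-free rTTP used for features
    volumes: perfusion.LesionVolumes
    lesion_masks: dict[str, np.ndarray]
    window: tuple[int, int]
    case_features: features.CaseFeatures


def prepare_case(
    case: CaseVolumeSet,
    n_baseline: int = 8,
    severe_threshold_s: float = perfusion.RTTP_SEVERE_THRESHOLD_S,
    brain_mask: np.ndarray | None = None,
    midline: geometry.MidlineTransform | None = None,
) -> PreparedCase:
    """Run the per-case map/feature stages.

    A known brain mask or midline (e.g. phantom ground truth) can be passed
    in to bypass their estimation; otherwise the brain mask is thresholded
    from the baseline signal and the midline is estimated on the ADC volume.
    """
    if case.pwi is None:
        raise ValueError(f"case {case.case_id}: PWI series required; "
                         "run the maps stage on full cases")
    if brain_mask is None:
        brain_mask = brain_mask_from_signal(case.pwi, n_baseline=n_baseline)
    if midline is None:
        midline = geometry.estimate_midline(
            case.adc, brain_mask, case.pixel_spacing_mm)

    conc, _valid = perfusion.signal_to_concentration(
        case.pwi, case.te_s, n_baseline=n_baseline)
    ttp = perfusion.compute_ttp(conc, case.tr_s)
    left, right = geometry.hemisphere_masks(brain_mask, midline)
    # median ties are common on quantized TTP; the side with the higher mean
    # TTP (delayed tail) is the lesion hint for that case
    mean_left = float(np.nanmean(ttp[left]))
    mean_right = float(np.nanmean(ttp[right]))
    hint = "left" if mean_left > mean_right else "right"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        rttp = perfusion.compute_rttp(ttp, left, right, lesion_hint=hint)
    volumes, masks = perfusion.lesion_masks_and_volumes(
        case.adc, rttp, brain_mask, case.spacing_mm,
        severe_threshold_s=severe_threshold_s)

    window = features.select_slice_window(masks["perfusion"], brain_mask)
    lesion_hemi = left if rttp.lesion_side == "left" else right
    voxels = features.candidate_voxels(brain_mask, lesion_hemi, window)
    rttp_filled = np.nan_to_num(rttp.rttp_s, nan=0.0)
    X = features.extract_case_features(case.adc, rttp_filled, midline, voxels)
    labels = None
    if case.day7_mask is not None:
        labels = case.day7_mask[voxels[:, 0], voxels[:, 1], voxels[:, 2]].astype(np.int8)
    cf = features.CaseFeatures(
        case_id=case.case_id,
        scenario=case.scenario,
        X=X.astype(np.float32),
        labels=labels,
        voxels=voxels,
        window=window,
        voxel_volume_mm3=case.voxel_volume_mm3,
    )
    return PreparedCase(
        case=case,
        brain_mask=brain_mask,
        midline=midline,
        rttp=rttp,
        rttp_filled=rttp_filled,
        volumes=volumes,
        lesion_masks=masks,
        window=window,
        case_features=cf,
    )


def prepare_cohort(
    cases: list[CaseVolumeSet],
    ground_truths: list[GroundTruth] | None = None,
    use_truth_geometry: bool = False,
    **kwargs,
) -> list[PreparedCase]:
    """Prepare every case; optionally reuse phantom truth masks/midlines."""
    prepared = []
    for i, case in enumerate(cases):
        extra = {}
        if use_truth_geometry and ground_truths is not None:
            extra = {
                "brain_mask": ground_truths[i].brain_mask,
                "midline": ground_truths[i].midline,
            }
        prepared.append(prepare_case(case, **extra, **kwargs))
        log.info("prepared case %s (%d candidates)", case.case_id,
                 len(prepared[-1].case_features.voxels))
    return prepared


@dataclass
class CohortResult:
    models: dict[str, model.TissueFateModel]
    predictions: dict[str, dict[str, model.PredictionResult]]  # case -> scenario
    report: pd.DataFrame
    agreement: dict


def train_models(
    prepared: list[PreparedCase],
    seed: int = 0,
    hyperparameters: dict | None = None,
) -> dict[str, model.TissueFateModel]:
    """Train the SR and UR forests, each on its own scenario's cases."""
    cfs = [p.case_features for p in prepared]
    matrix = features.build_training_matrix(cfs, seed=seed)
    models = {}
    for scenario in ("SR", "UR"):
        if any(sc == scenario for sc in matrix.scenarios.values()):
            models[scenario] = model.train(
                matrix, scenario, hyperparameters=hyperparameters, seed=seed)
    return models


def run_cohort(
    prepared: list[PreparedCase],
    seed: int = 0,
    hyperparameters: dict | None = None,
    models: dict[str, model.TissueFateModel] | None = None,
    tertile_cutoffs: tuple[float, float] | None = None,
) -> CohortResult:
    """Train (or reuse) both models, predict both fates for every case, and
    build the per-case clinical table plus cohort agreement statistics."""
    if models is None:
        models = train_models(prepared, seed=seed,
                              hyperparameters=hyperparameters)

    predictions: dict[str, dict[str, model.PredictionResult]] = {}
    rows = []
    for p in prepared:
        case = p.case
        preds = {
            scen: model.predict_case(m, p.case_features, case.shape)
            for scen, m in models.items()
        }
        predictions[case.case_id] = preds
        row = {
            "case_id": case.case_id,
            "scenario": case.scenario,
            "mrs": case.mrs,
            "core_ml": p.volumes.core_ml,
            "perfusion_ml": p.volumes.perfusion_ml,
            "severe_ml": p.volumes.severe_ml,
        }
        for scen, pr in preds.items():
            row[f"predicted_{scen.lower()}_ml"] = pr.volume_ml
        if case.day7_mask is not None:
            row["final_ml"] = perfusion.mask_volume_ml(
                case.day7_mask, case.spacing_mm)
            own = preds.get(case.scenario)
            if own is not None:
                row["dice"] = evaluation.dice(own.infarct_mask,
                                              case.day7_mask.astype(bool))
        rows.append(row)

    report = clinical.cohort_report(rows)

    # growth-tertile labels from the scenario-matched predicted growth
    if len(report) >= 3:
        own_pred = [
            r[f"predicted_{str(r['scenario']).lower()}_ml"]
            if f"predicted_{str(r['scenario']).lower()}_ml" in r else np.nan
            for _, r in report.iterrows()
        ]
        growth = np.asarray(own_pred) - report["core_ml"].to_numpy()
        if not np.isnan(growth).any():
            labels, cuts, mode = clinical.growth_tertiles(
                growth, cutoffs=tertile_cutoffs)
            report["predicted_growth_ml"] = growth
            report["growth_group"] = labels
            report.attrs["tertile_cutoffs"] = cuts
            report.attrs["tertile_mode"] = mode

    agreement = {}
    if "final_ml" in report and "dice" in report:
        for scen in models:
            sub = report[report["scenario"] == scen]
            if len(sub) >= 3:
                agreement[scen] = evaluation.agreement_report(
                    sub[f"predicted_{scen.lower()}_ml"].to_numpy(),
                    sub["final_ml"].to_numpy(),
                    per_case_dice=sub["dice"].tolist(),
                )
    return CohortResult(models=models, predictions=predictions,
                        report=report, agreement=agreement)


def outcome_groups(report: pd.DataFrame) -> list[clinical.OutcomeSummary]:
    """Favorable-outcome summaries by mismatch status and growth tertile."""
    groups: dict[str, list] = {}
    if "mismatch" in report:
        groups["mismatch_present"] = report.loc[report["mismatch"], "mrs"].tolist()
        groups["mismatch_absent"] = report.loc[~report["mismatch"], "mrs"].tolist()
    if "growth_group" in report:
        for g in ("low", "intermediate", "high"):
            groups[f"growth_{g}"] = report.loc[
                report["growth_group"] == g, "mrs"].tolist()
    return clinical.outcome_summary(groups)
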