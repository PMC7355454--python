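"""Random-forest tissue-fate models: tuning, patient-level CV, prediction.

Two classifiers are trained on class-balanced voxel features: an SR model
from cases with successful recanalization and a UR model from cases without.
Cross-validation folds partition *patients*, never voxels, so no voxel of a
held-out patient can leak into training.  Prediction applies a model to every
candidate voxel of a case (no balancing) and thresholds the infarct
probability at p >= 0.5; the predicted infarct volume is the voxel count
times the voxel volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .features import (
    N_FEATURES,
    FEATURE_SCHEMA,
    CaseFeatures,
    FeatureMatrix,
    build_training_matrix,
)

#: Forest settings used when hyperparameter tuning is skipped.
DEFAULT_HYPERPARAMETERS: dict = {
    "n_estimators": 300,
    "max_depth": None,
    "min_samples_leaf": 1,
    "max_features": "sqrt",
}

#: Random-search space for :func:`tune_hyperparameters`.
SEARCH_SPACE = {
    "n_estimators": list(range(100, 501, 50)),
    "max_depth": list(range(8, 33, 4)) + [None],
    "min_samples_leaf": [1, 5, 10, 50],
    "max_features": ["sqrt", "log2"],
}


@dataclass
class TissueFateModel:
    """A fitted scenario-specific forest plus everything needed to replay it."""

    classifier: RandomForestClassifier
    scenario: str
    schema: tuple[str, ...]
    hyperparameters: dict
    seed: int
    training_fingerprint: str = ""

    def __post_init__(self) -> None:
        if self.scenario not in ("SR", "UR"):
            raise ValueError("scenario must be 'SR' or 'UR'")

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if X.shape[1] != len(self.schema):
            raise ValueError(
                f"feature matrix has {X.shape[1]} columns; model schema "
                f"expects {len(self.schema)}")
        return self.classifier.predict_proba(X)[:, 1]


@dataclass
class PredictionResult:
    """Voxel-wise infarct probability and the derived mask and volume."""

    probability: np.ndarray          # 3D map, 0 outside the candidate region
    infarct_mask: np.ndarray         # p >= 0.5 within the candidate region
    volume_ml: float
    scenario: str


@dataclass
class CVReport:
    fold_accuracy: np.ndarray
    fold_patients: list[list[str]]
    mean: float = field(init=False)
    sd: float = field(init=False)
    ci95: tuple[float, float] = field(init=False)

    def __post_init__(self) -> None:
        acc = np.asarray(self.fold_accuracy, dtype=float)
        self.mean = float(acc.mean())
        self.sd = float(acc.std(ddof=1)) if len(acc) > 1 else 0.0
        half = 1.96 * self.sd
        self.ci95 = (self.mean - half, self.mean + half)


def _fingerprint(matrix: FeatureMatrix) -> str:
    ids = sorted(set(matrix.case_ids.tolist()))
    return f"{len(ids)} cases [{','.join(ids[:6])}{'...' if len(ids) > 6 else ''}], " \
           f"{matrix.X.shape[0]} samples, seed {matrix.seed}"


def _fit_forest(X: np.ndarray, y: np.ndarray, params: dict,
                seed: int) -> RandomForestClassifier:
    clf = RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    clf.fit(X, y)
    return clf


def _patient_folds(patients: list[str], k: int, rng: np.random.Generator
                   ) -> list[list[str]]:
    if k > len(patients):
        raise ValueError(f"k={k} folds but only {len(patients)} patients")
    order = rng.permutation(len(patients))
    folds: list[list[str]] = [[] for _ in range(k)]
    for pos, idx in enumerate(order):
        folds[pos % k].append(patients[idx])
    # assert: folds partition the patients
    flat = sorted(p for f in folds for p in f)
    assert flat == sorted(patients), "fold assignment is not a partition"
    return folds


def tune_hyperparameters(
    matrix: FeatureMatrix,
    n_iter: int = 10,
    seed: int = 0,
    cv_folds: int = 3,
) -> tuple[dict, float]:
    """Random search over the forest hyperparameter space, scored by
    patient-grouped CV accuracy on the balanced matrix."""
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    patients = sorted(set(matrix.case_ids.tolist()))
    k = min(cv_folds, len(patients))
    best_params, best_score = None, -np.inf
    for _ in range(n_iter):
        params = {key: vals[rng.integers(len(vals))]
                  for key, vals in SEARCH_SPACE.items()}
        folds = _patient_folds(patients, k, rng)
        accs = []
        for fold in folds:
            held = np.isin(matrix.case_ids, fold)
            if held.all() or not held.any():
                continue
            clf = _fit_forest(matrix.X[~held], matrix.labels[~held], params, seed)
            accs.append((clf.predict(matrix.X[held]) == matrix.labels[held]).mean())
        score = float(np.mean(accs)) if accs else -np.inf
        if score > best_score:
            best_params, best_score = params, score
    return best_params, best_score


def train(
    matrix: FeatureMatrix,
    scenario: str,
    hyperparameters: dict | None = None,
    seed: int = 0,
) -> TissueFateModel:
    """Fit the scenario's forest on that scenario's cases only."""
    if scenario not in ("SR", "UR"):
        raise ValueError("scenario must be 'SR' or 'UR'")
    if tuple(matrix.schema) != FEATURE_SCHEMA:
        raise ValueError("feature matrix schema does not match the expected "
                         "48-feature layout")
    params = dict(hyperparameters or DEFAULT_HYPERPARAMETERS)
    keep_cases = {cid for cid, sc in matrix.scenarios.items() if sc == scenario}
    rows = np.isin(matrix.case_ids, sorted(keep_cases))
    if not rows.any():
        raise ValueError(f"no {scenario} cases in the training matrix")
    clf = _fit_forest(matrix.X[rows], matrix.labels[rows], params, seed)
    return TissueFateModel(
        classifier=clf,
        scenario=scenario,
        schema=FEATURE_SCHEMA,
        hyperparameters=params,
        seed=seed,
        training_fingerprint=_fingerprint(matrix),
    )


def cross_validate(
    case_features: list[CaseFeatures],
    k: int = 5,
    seed: int = 0,
    hyperparameters: dict | None = None,
) -> CVReport:
    """Patient-level k-fold CV of voxel accuracy on balanced matrices.

    Patients are partitioned randomly into k folds; each fold's model is
    trained on the other folds' balanced samples and evaluated on the held-out
    fold's balanced samples (chance level 0.5 by construction).
    """
    params = dict(hyperparameters or DEFAULT_HYPERPARAMETERS)
    patients = sorted({cf.case_id for cf in case_features})
    rng = np.random.default_rng(seed)
    folds = _patient_folds(patients, k, rng)
    by_id = {cf.case_id: cf for cf in case_features}

    accs = []
    for fold in folds:
        train_cfs = [by_id[p] for p in patients if p not in fold]
        test_cfs = [by_id[p] for p in fold]
        m_train = build_training_matrix(train_cfs, seed=seed)
        m_test = build_training_matrix(test_cfs, seed=seed + 1)
        assert not set(m_train.case_ids) & set(m_test.case_ids), \
            "patient leaked between CV folds"
        clf = _fit_forest(m_train.X, m_train.labels, params, seed)
        accs.append(float((clf.predict(m_test.X) == m_test.labels).mean()))
    return CVReport(fold_accuracy=np.array(accs), fold_patients=folds)


def predict_case(
    model: TissueFateModel,
    case_features: CaseFeatures,
    grid_shape: tuple[int, int, int],
    threshold: float = 0.5,
) -> PredictionResult:
    """Apply a trained model to every candidate voxel of a case.

    Voxels with probability exactly at the threshold count as infarct.
    """
    if case_features.X.shape[1] != N_FEATURES:
        raise ValueError("candidate features do not match the model schema")
    p = model.predict_proba(case_features.X)
    prob_map = np.zeros(grid_shape, dtype=np.float32)
    v = case_features.voxels
    prob_map[v[:, 0], v[:, 1], v[:, 2]] = p
    mask = np.zeros(grid_shape, dtype=bool)
    mask[v[:, 0], v[:, 1], v[:, 2]] = p >= threshold
    volume_ml = float(mask.sum()) * case_features.voxel_volume_mm3 / 1000.0
    return PredictionResult(
        probability=prob_map,
        infarct_mask=mask,
        volume_ml=volume_ml,
        scenario=model.scenario,
    )
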