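"""Forest training, patient-level CV, prediction thresholding."""

import numpy as np
import pytest

from tissuefate import features, model


def _case(case_id, rng, n=120, scenario="SR", informative=True):
    """A small synthetic patient: label depends on one feature if informative."""
    X = rng.normal(size=(n, 48)).astype(np.float32)
    if informative:
        y = (X[:, 13] + 0.3 * rng.normal(size=n) > 0).astype(np.int8)
    else:
        y = rng.integers(0, 2, size=n).astype(np.int8)
    return features.CaseFeatures(
        case_id=case_id, scenario=scenario, X=X, labels=y,
        voxels=np.zeros((n, 3), np.intp), window=(0, 6),
        voxel_volume_mm3=5.7129)


@pytest.fixture(scope="module")
def informative_cases():
    rng = np.random.default_rng(0)
    return [_case(f"p{i}", rng) for i in range(10)]


FAST = {"n_estimators": 40, "max_depth": 8, "min_samples_leaf": 1,
        "max_features": "sqrt"}


class TestCrossValidate:
    def test_folds_partition_patients_without_leakage(self, informative_cases):
        rep = model.cross_validate(informative_cases, k=5, seed=1,
                                   hyperparameters=FAST)
        all_patients = sorted(p for f in rep.fold_patients for p in f)
        assert all_patients == sorted(c.case_id for c in informative_cases)
        assert all(len(f) == 2 for f in rep.fold_patients)
        assert len(rep.fold_accuracy) == 5

    def test_learnable_signal_beats_chance(self, informative_cases):
        rep = model.cross_validate(informative_cases, k=5, seed=1,
                                   hyperparameters=FAST)
        assert rep.mean > 0.7

    def test_random_labels_score_at_chance(self):
        rng = np.random.default_rng(42)
        cases = [_case(f"p{i}", rng, n=300, informative=False)
                 for i in range(10)]
        rep = model.cross_validate(cases, k=5, seed=2, hyperparameters=FAST)
        assert rep.mean == pytest.approx(0.5, abs=0.05)

    def test_too_many_folds_rejected(self, informative_cases):
        with pytest.raises(ValueError, match="folds"):
            model.cross_validate(informative_cases[:3], k=5)

    def test_ci_reporting(self, informative_cases):
        rep = model.cross_validate(informative_cases, k=5, seed=1,
                                   hyperparameters=FAST)
        lo, hi = rep.ci95
        assert lo == pytest.approx(rep.mean - 1.96 * rep.sd)
        assert hi == pytest.approx(rep.mean + 1.96 * rep.sd)


class TestTrain:
    def test_same_seed_identical_predictions(self, informative_cases):
        m = features.build_training_matrix(informative_cases, seed=0)
        probe = np.random.default_rng(9).normal(size=(50, 48)).astype(np.float32)
        a = model.train(m, "SR", FAST, seed=3).predict_proba(probe)
        b = model.train(m, "SR", FAST, seed=3).predict_proba(probe)
        assert (a == b).all()

    def test_scenario_filtering(self):
        rng = np.random.default_rng(1)
        cases = ([_case(f"s{i}", rng, scenario="SR") for i in range(3)]
                 + [_case(f"u{i}", rng, scenario="UR") for i in range(3)])
        m = features.build_training_matrix(cases, seed=0)
        tm = model.train(m, "UR", FAST, seed=0)
        assert tm.scenario == "UR"
        assert "cases" in tm.training_fingerprint
        with pytest.raises(ValueError):
            model.train(m, "XX", FAST)

    def test_wrong_width_probe_rejected(self, informative_cases):
        m = features.build_training_matrix(informative_cases, seed=0)
        tm = model.train(m, "SR", FAST, seed=0)
        with pytest.raises(ValueError, match="schema"):
            tm.predict_proba(np.zeros((4, 47), np.float32))


class TestTune:
    def test_single_iteration_returns_sampled_config(self, informative_cases):
        m = features.build_training_matrix(informative_cases[:4], seed=0)
        params, score = model.tune_hyperparameters(m, n_iter=1, seed=5)
        assert set(params) == set(model.SEARCH_SPACE)
        assert 0.0 <= score <= 1.0

    def test_deterministic_under_seed(self, informative_cases):
        m = features.build_training_matrix(informative_cases[:4], seed=0)
        p1, _ = model.tune_hyperparameters(m, n_iter=3, seed=5)
        p2, _ = model.tune_hyperparameters(m, n_iter=3, seed=5)
        assert p1 == p2

    def test_invalid_iterations(self, informative_cases):
        m = features.build_training_matrix(informative_cases[:4], seed=0)
        with pytest.raises(ValueError):
            model.tune_hyperparameters(m, n_iter=0)


class _StubForest:
    """Probability lookup standing in for a fitted forest."""

    def __init__(self, probs):
        self.probs = np.asarray(probs, dtype=float)

    def predict_proba(self, X):
        return np.column_stack([1 - self.probs, self.probs])


class TestPredict:
    def _prediction(self, probs, threshold=0.5):
        n = len(probs)
        cf = features.CaseFeatures(
            case_id="c", scenario="SR",
            X=np.zeros((n, 48), np.float32), labels=None,
            voxels=np.column_stack([np.zeros(n, np.intp),
                                    np.zeros(n, np.intp),
                                    np.arange(n)]),
            window=(0, 6), voxel_volume_mm3=1000.0)
        tm = model.TissueFateModel(
            classifier=_StubForest(probs), scenario="SR",
            schema=features.FEATURE_SCHEMA, hyperparameters={}, seed=0)
        return model.predict_case(tm, cf, (1, 1, n), threshold=threshold)

    def test_probability_exactly_half_counts_as_infarct(self):
        pred = self._prediction([0.49, 0.5, 0.51])
        assert pred.infarct_mask[0, 0].tolist() == [False, True, True]
        assert pred.volume_ml == pytest.approx(2.0)

    def test_volume_monotone_in_threshold(self):
        probs = np.linspace(0, 1, 21)
        vols = [self._prediction(probs, threshold=t).volume_ml
                for t in (0.2, 0.5, 0.8)]
        assert vols[0] >= vols[1] >= vols[2]

    def test_probability_map_placed_at_candidate_voxels(self):
        pred = self._prediction([0.25, 0.75])
        assert pred.probability[0, 0, 0] == pytest.approx(0.25)
        assert pred.probability[0, 0, 1] == pytest.approx(0.75)
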