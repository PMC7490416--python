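"""Nested-CV machinery: recovery of linear ground truth, partitioning,
grid-search equivalence with a brute-force oracle, ensembles, the
training-size sweep and the external-test path."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.model_selection import KFold

from hemopred.dataset import StudyDataset
from hemopred.errors import (
    AlignmentError,
    InvalidParameterError,
    ScenarioError,
    SweepError,
)
from hemopred.regression import (
    CVConfig,
    ModelSpec,
    PRESSURE_FEATURES,
    ScenarioSpec,
    ensemble_average,
    fit_full_and_predict_external,
    hyperparameter_frequency,
    run_nested_cv,
    training_size_sweep,
)


def linear_dataset(n=200, seed=0, noise=0.0) -> StudyDataset:
    """aSBP is an exact (or nearly exact) linear blend of the features."""
    rng = np.random.default_rng(seed)
    table = pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(n)],
        "brSBP_mmHg": rng.normal(134, 25, n),
        "brDBP_mmHg": rng.normal(76, 10, n),
        "HR_bpm": rng.normal(82, 8, n),
        "cfPWV_mps": rng.normal(8.9, 1.6, n),
        "EF_pct": rng.normal(51, 7, n),
        "CO_Lmin": rng.normal(5.9, 1.2, n),
        "Ees_mmHg_per_mL": rng.normal(2.3, 0.4, n),
    })
    table["aSBP_mmHg"] = (
        0.9 * table["brSBP_mmHg"] + 0.1 * table["brDBP_mmHg"]
        - 0.05 * table["HR_bpm"] + rng.normal(0, noise, n)
    )
    return StudyDataset(table=table, provenance={})


SCEN_ASBP = ScenarioSpec(PRESSURE_FEATURES, "aSBP")


class TestSpecs:
    def test_default_grids_are_the_study_grids(self):
        assert ModelSpec("svr").grid == {"C": [1, 10, 100],
                                         "gamma": [0.001, 0.01, 0.1, 1]}
        assert ModelSpec("ridge").grid == {"alpha": [1, 10, 100, 200]}
        assert ModelSpec("random_forest").grid == {
            "max_depth": [5, 10, 20], "n_estimators": [500, 700, 1000]}
        assert ModelSpec("gradient_boosting").grid == {
            "learning_rate": [0.01, 0.05, 1],
            "n_estimators": [100, 500, 1000, 1750]}

    def test_invalid_family_and_grid(self):
        with pytest.raises(InvalidParameterError):
            ModelSpec("nnet")
        with pytest.raises(InvalidParameterError):
            ModelSpec("svr", {"kernel": ["rbf"]})

    def test_scenario_validation(self):
        with pytest.raises(ScenarioError):
            ScenarioSpec((), "aSBP")
        with pytest.raises(ScenarioError):
            ScenarioSpec(("brSBP",), "weight")


class TestNestedCV:
    def test_linear_ground_truth_recovered_by_ridge(self):
        ds = linear_dataset(n=200, noise=0.0)
        run = run_nested_cv(ds, ModelSpec("ridge"), SCEN_ASBP,
                            CVConfig(seed=0))
        r = np.corrcoef(run.y_pred, run.y_true)[0, 1]
        rmse = np.sqrt(np.mean((run.y_pred - run.y_true) ** 2))
        assert r >= 0.999
        assert rmse <= 1e-3 * run.y_true.std()

    def test_outer_folds_partition_rows(self):
        ds = linear_dataset(n=97, noise=1.0)
        run = run_nested_cv(ds, ModelSpec("ridge"), SCEN_ASBP,
                            CVConfig(seed=3))
        assert len(run.y_pred) == 97
        counts = np.bincount(run.fold_ids, minlength=10)
        assert counts.sum() == 97 and counts.min() >= 9
        assert len(run.fold_params) == 10

    def test_missing_column_raises_scenario_error(self):
        ds = linear_dataset(50)
        bad = StudyDataset(ds.table.drop(columns=["cfPWV_mps"]), {})
        with pytest.raises(ScenarioError):
            run_nested_cv(bad, ModelSpec("ridge"), SCEN_ASBP, CVConfig())

    def test_end_to_end_seed_determinism(self):
        ds = linear_dataset(n=120, noise=2.0)
        a = run_nested_cv(ds, ModelSpec("ridge"), SCEN_ASBP, CVConfig(seed=5))
        b = run_nested_cv(ds, ModelSpec("ridge"), SCEN_ASBP, CVConfig(seed=5))
        assert np.array_equal(a.y_pred, b.y_pred)
        assert a.fold_params == b.fold_params

    def test_grid_search_matches_brute_force_oracle(self):
        """On a 60-row toy problem with a 2-point grid, the inner selection
        must equal an explicit fit-every-(point, fold) re-implementation."""
        ds = linear_dataset(n=60, noise=5.0, seed=4)
        model = ModelSpec("ridge", {"alpha": [1, 200]})
        cv = CVConfig(outer_folds=5, inner_folds=4, seed=9)
        run = run_nested_cv(ds, model, SCEN_ASBP, cv)

        X = ds.table[SCEN_ASBP.feature_columns].to_numpy()
        y = ds.table[SCEN_ASBP.target_column].to_numpy()
        outer = KFold(5, shuffle=True, random_state=cv.seed)
        for k, (tr, _) in enumerate(outer.split(X)):
            best, best_mse = None, np.inf
            for alpha in [1, 200]:
                inner = KFold(4, shuffle=True, random_state=cv.seed + 1000 + k)
                mses = []
                for itr, ite in inner.split(X[tr]):
                    est = model.make_estimator({"alpha": alpha})
                    est.fit(X[tr][itr], y[tr][itr])
                    mses.append(np.mean(
                        (est.predict(X[tr][ite]) - y[tr][ite]) ** 2))
                if np.mean(mses) < best_mse:
                    best_mse, best = np.mean(mses), alpha
            assert run.fold_params[k] == {"alpha": best}


class TestEnsemble:
    def test_identical_runs_average_to_themselves(self):
        ds = linear_dataset(n=80, noise=2.0)
        run = run_nested_cv(ds, ModelSpec("ridge"), SCEN_ASBP, CVConfig(seed=1))
        np.testing.assert_allclose(ensemble_average([run, run]), run.y_pred)

    def test_rowwise_mean_oracle(self):
        ds = linear_dataset(n=80, noise=2.0)
        base = run_nested_cv(ds, ModelSpec("ridge"), SCEN_ASBP, CVConfig(seed=1))
        import copy

        runs = []
        for shift in (4.0, 6.0):
            r = copy.deepcopy(base)
            r.y_pred = np.full_like(base.y_pred, shift)
            runs.append(r)
        np.testing.assert_allclose(ensemble_average(runs),
                                   np.full_like(base.y_pred, 5.0))

    def test_misaligned_runs_rejected(self):
        ds = linear_dataset(n=80, noise=2.0)
        a = run_nested_cv(ds, ModelSpec("ridge"), SCEN_ASBP, CVConfig(seed=1))
        b = run_nested_cv(ds, ModelSpec("ridge"), SCEN_ASBP, CVConfig(seed=2))
        with pytest.raises(AlignmentError):
            ensemble_average([a, b])


class TestHyperparameterFrequency:
    def test_percentages(self):
        ds = linear_dataset(n=60, noise=5.0)
        run = run_nested_cv(ds, ModelSpec("ridge"), SCEN_ASBP,
                            CVConfig(outer_folds=10, inner_folds=3, seed=2))
        freq = hyperparameter_frequency(run)
        assert freq.groupby("hyperparameter")["pct_selected"].sum().eq(100).all()
        # every recorded selection is consistent with fold_params
        for value, pct in freq[["value", "pct_selected"]].itertuples(index=False):
            n_sel = sum(p["alpha"] == value for p in run.fold_params)
            assert pct == pytest.approx(100 * n_sel / 10)


class TestSweep:
    def test_point_count_and_determinism(self):
        ds = linear_dataset(n=150, noise=2.0)
        fr = np.round(np.arange(0.95, 0.149, -0.10), 2)
        model = ModelSpec("ridge", {"alpha": [1, 10]})
        a = training_size_sweep(ds, model, SCEN_ASBP, fr, inner_folds=3,
                                seed=4, min_test_rows=5)
        b = training_size_sweep(ds, model, SCEN_ASBP, fr, inner_folds=3,
                                seed=4, min_test_rows=5)
        assert len(a) == 9
        pd.testing.assert_frame_equal(a, b)

    def test_too_small_test_remainder_rejected(self):
        ds = linear_dataset(n=100, noise=2.0)
        with pytest.raises(SweepError):
            training_size_sweep(ds, ModelSpec("ridge"), SCEN_ASBP, [0.95],
                                inner_folds=3, min_test_rows=20)


class TestExternal:
    def test_external_copy_of_training_features_reproduces_in_sample(self):
        ds = linear_dataset(n=100, noise=1.0)
        model = ModelSpec("ridge", {"alpha": [1]})
        pred = fit_full_and_predict_external(ds, model, SCEN_ASBP, ds.table,
                                             inner_folds=3)
        X = ds.table[SCEN_ASBP.feature_columns].to_numpy()
        y = ds.table[SCEN_ASBP.target_column].to_numpy()
        est = model.make_estimator({"alpha": 1})
        est.fit(X, y)
        np.testing.assert_allclose(pred, est.predict(X))

    def test_missing_feature_column_is_named(self):
        ds = linear_dataset(n=100, noise=1.0)
        ext = ds.table.drop(columns=["EF_pct"])
        scen = ScenarioSpec(("brSBP", "brDBP", "HR", "cfPWV", "EF"), "E_es")
        with pytest.raises(ScenarioError, match="EF"):
            fit_full_and_predict_external(ds, ModelSpec("ridge"), scen, ext,
                                          inner_folds=3)

    def test_distributional_generalisation_on_fresh_seed(self):
        train = linear_dataset(n=300, noise=2.0, seed=0)
        test = linear_dataset(n=200, noise=2.0, seed=99)
        model = ModelSpec("ridge", {"alpha": [1, 10]})
        pred = fit_full_and_predict_external(train, model, SCEN_ASBP,
                                             test.table, inner_folds=5)
        truth = test.table["aSBP_mmHg"].to_numpy()
        r_ext = np.corrcoef(pred, truth)[0, 1]
        run = run_nested_cv(train, model, SCEN_ASBP,
                            CVConfig(outer_folds=5, inner_folds=5, seed=1))
        r_cv = np.corrcoef(run.y_pred, run.y_true)[0, 1]
        assert r_ext >= r_cv - 0.02
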