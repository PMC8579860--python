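"""Grouped LOOCV protocol: fold structure, baselines, leakage canaries."""

import numpy as np
import pytest

from vimtarget.evaluation import (
    CohortDataset,
    ConstantMeanRegressor,
    NearestNeighborRegressor,
    compare_models,
    error_statistics,
    grand_mean_distance,
    loocv,
)
from vimtarget.metamodels import RKHSRegressor


def _toy_dataset(rng, n_patients=6):
    pids = np.repeat([f"P{i}" for i in range(n_patients)], 2)
    hemis = np.tile(["L", "R"], n_patients)
    X = rng.normal(size=(2 * n_patients, 54))
    Y = rng.normal(size=(2 * n_patients, 3))
    return CohortDataset(patient_ids=pids, hemispheres=hemis, X=X, Y=Y)


def test_both_hemispheres_share_a_fold(rng):
    ds = _toy_dataset(rng)
    report = loocv(ds, ConstantMeanRegressor)
    per_patient_folds = report.per_sample.groupby("patient_id")["fold"].nunique()
    assert (per_patient_folds == 1).all()
    assert report.per_sample["fold"].nunique() == 6
    assert len(report.per_sample) == ds.n_samples


def test_loocv_requires_two_patients(rng):
    ds = _toy_dataset(rng, n_patients=6)
    one = ds.subset(np.flatnonzero(ds.patient_ids == "P0"))
    with pytest.raises(ValueError):
        loocv(one, ConstantMeanRegressor)


def test_constant_baseline_matches_closed_form(rng):
    ds = _toy_dataset(rng)
    report = loocv(ds, ConstantMeanRegressor)
    # direct recomputation of the fold-wise train-mean predictor
    expected = []
    for pid in sorted(set(ds.patient_ids)):
        test = ds.patient_ids == pid
        center = ds.Y[~test].mean(axis=0)
        expected.extend(np.linalg.norm(ds.Y[test] - center, axis=1))
    assert report.mean_error_mm == pytest.approx(float(np.mean(expected)))
    # and the in-sample grand-mean distance is a lower bound of that error
    assert grand_mean_distance(ds.Y) <= report.mean_error_mm + 1e-12


def test_memorizing_model_on_duplicated_patients_is_a_split_canary(rng):
    base = _toy_dataset(rng, n_patients=4)
    # same anatomy recorded under two different patient ids
    dup = CohortDataset(
        patient_ids=np.concatenate([base.patient_ids,
                                    np.char.add(base.patient_ids.astype(str), "dup")]),
        hemispheres=np.concatenate([base.hemispheres, base.hemispheres]),
        X=np.vstack([base.X, base.X]),
        Y=np.vstack([base.Y, base.Y]),
    )
    report = loocv(dup, NearestNeighborRegressor)
    assert report.mean_error_mm == pytest.approx(0.0, abs=1e-12)


def test_loocv_is_invariant_to_sample_order(rng):
    ds = _toy_dataset(rng)
    perm = rng.permutation(ds.n_samples)
    shuffled = ds.subset(perm)
    factory = lambda: RKHSRegressor(sigma=5.0, ridge_lambda=1e-2)
    r1, r2 = loocv(ds, factory), loocv(shuffled, factory)
    assert r1.mean_error_mm == pytest.approx(r2.mean_error_mm, abs=1e-10)


def test_fold_model_never_sees_the_held_out_patient(rng):
    # the P0-fold predictions must equal a manual fit on everyone but P0:
    # a leaked sample would change the trained model and break the equality
    ds = _toy_dataset(rng)
    factory = lambda: RKHSRegressor(sigma=5.0, ridge_lambda=1e-2)
    report = loocv(ds, factory)
    held = ds.patient_ids == "P0"
    manual = factory().fit(ds.X[~held], ds.Y[~held]).predict(ds.X[held])
    fold_rows = report.per_sample[report.per_sample["patient_id"] == "P0"]
    np.testing.assert_allclose(
        fold_rows[["pred_x", "pred_y", "pred_z"]].to_numpy(), manual, atol=1e-12
    )


def test_compare_models_identical_factories_and_folds(rng):
    ds = _toy_dataset(rng)
    table, reports = compare_models(
        ds, {"a": ConstantMeanRegressor, "b": ConstantMeanRegressor}
    )
    assert table.loc[0, "mean_error_mm"] == table.loc[1, "mean_error_mm"]
    assert reports["a"].per_sample["fold"].equals(reports["b"].per_sample["fold"])


def test_kernel_models_beat_constant_baseline_on_smooth_map(noiseless_cohort):
    ds = noiseless_cohort.clean
    table, _ = compare_models(
        ds,
        {
            "rkhs": lambda: RKHSRegressor(sigma=np.sqrt(54.0), ridge_lambda=1e-3),
            "baseline": ConstantMeanRegressor,
        },
    )
    by_model = table.set_index("model")["mean_error_mm"]
    assert by_model["rkhs"] < by_model["baseline"]


def test_error_statistics_conventions():
    stats = error_statistics([3.0, 4.0, 5.0])
    assert stats["mean"] == pytest.approx(4.0)
    assert stats["sd"] == pytest.approx(1.0)  # ddof=1
    assert stats["median"] == pytest.approx(4.0)
    assert stats["iqr"] == pytest.approx(1.0)
    assert stats["max"] == pytest.approx(5.0)
    single = error_statistics([2.5])
    assert single["sd"] == 0.0 and not single["sd_defined"]
    with pytest.raises(ValueError):
        error_statistics([])


def test_error_statistics_against_reference_formulas(rng):
    for _ in range(10):
        e = rng.exponential(size=17)
        stats = error_statistics(e)
        assert stats["mean"] == pytest.approx(float(np.mean(e)))
        assert stats["sd"] == pytest.approx(float(np.std(e, ddof=1)))
        assert stats["iqr"] == pytest.approx(
            float(np.percentile(e, 75) - np.percentile(e, 25))
        )


def test_nested_grid_search_reoptimizes_inside_each_fold(noiseless_cohort):
    from vimtarget.metamodels import HyperparamGrid, NestedGridSearchRegressor

    ds = noiseless_cohort.clean.subset(np.arange(12))  # 6 patients
    grid = HyperparamGrid(sigma=(np.sqrt(54.0), 2 * np.sqrt(54.0)),
                          ridge_lambda=(1e-3, 1e-1))
    fitted_params = []

    class Spy(NestedGridSearchRegressor):
        def fit(self, X, Y, groups=None):
            out = super().fit(X, Y, groups=groups)
            fitted_params.append(self.best_params_)
            return out

    report = loocv(ds, lambda: Spy(kind="rkhs", grid=grid))
    assert len(fitted_params) == ds.n_patients  # one search per outer fold
    assert all(set(p) == {"sigma", "ridge_lambda"} for p in fitted_params)
    assert np.isfinite(report.mean_error_mm)


def test_nested_regressor_requires_groups(rng):
    from vimtarget.metamodels import NestedGridSearchRegressor

    with pytest.raises(ValueError):
        NestedGridSearchRegressor(kind="rkhs").fit(
            rng.normal(size=(6, 54)), rng.normal(size=(6, 3))
        )


def test_dataset_rejects_duplicate_lead_keys(rng):
    with pytest.raises(ValueError):
        CohortDataset(
            patient_ids=np.array(["P0", "P0"]),
            hemispheres=np.array(["L", "L"]),
            X=rng.normal(size=(2, 54)),
            Y=rng.normal(size=(2, 3)),
        )
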