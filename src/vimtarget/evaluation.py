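"""Grouped leave-one-patient-out cross-validation and error reporting.

The validation unit is the patient, not the hemisphere: when a patient is
held out, both of their hemispheres leave the training set together, so a
model can never be scored on a hemisphere whose mirror image it has seen.
Errors are reported per lead as the 3-D Euclidean distance between the
predicted and the implanted active-contact position, with per-axis absolute
errors alongside; aggregate statistics use the n-1 (sample) SD convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .geometry import Frame, FrameOrigin
from .metamodels import grouped_folds

__all__ = [
    "CohortDataset",
    "CVReport",
    "ConstantMeanRegressor",
    "NearestNeighborRegressor",
    "loocv",
    "compare_models",
    "error_statistics",
    "grand_mean_distance",
]


@dataclass(frozen=True)
class CohortDataset:
    """Per-hemisphere samples: feature vector (54,) paired with a 3-D target."""

    patient_ids: np.ndarray  # (n,) str
    hemispheres: np.ndarray  # (n,) "L"/"R"
    X: np.ndarray  # (n, 54)
    Y: np.ndarray  # (n, 3)
    frame: Frame = field(default_factory=lambda: Frame(FrameOrigin.PC, 26.0))

    def __post_init__(self) -> None:
        object.__setattr__(self, "patient_ids", np.asarray(self.patient_ids, dtype=object))
        object.__setattr__(self, "hemispheres", np.asarray(self.hemispheres, dtype=object))
        object.__setattr__(self, "X", np.asarray(self.X, dtype=float))
        object.__setattr__(self, "Y", np.asarray(self.Y, dtype=float))
        n = len(self.patient_ids)
        if not (len(self.hemispheres) == self.X.shape[0] == self.Y.shape[0] == n):
            raise ValueError("inconsistent sample counts across fields")
        if self.Y.shape[1] != 3:
            raise ValueError("targets must be 3-D points")
        keys = list(zip(self.patient_ids.tolist(), self.hemispheres.tolist()))
        if len(set(keys)) != n:
            raise ValueError("duplicate (patient, hemisphere) pairs")

    @property
    def n_samples(self) -> int:
        return len(self.patient_ids)

    @property
    def n_patients(self) -> int:
        return len(set(self.patient_ids.tolist()))

    def subset(self, idx: np.ndarray) -> "CohortDataset":
        return CohortDataset(
            patient_ids=self.patient_ids[idx],
            hemispheres=self.hemispheres[idx],
            X=self.X[idx],
            Y=self.Y[idx],
            frame=self.frame,
        )


@dataclass(frozen=True)
class CVReport:
    """Per-sample held-out errors plus aggregates from one grouped LOOCV run."""

    per_sample: pd.DataFrame  # patient_id, hemisphere, fold, err_mm, err_x/y/z, pred_*
    model_name: str = ""
    seed: int | None = None

    @property
    def errors_mm(self) -> np.ndarray:
        return self.per_sample["error_mm"].to_numpy()

    @property
    def mean_error_mm(self) -> float:
        return float(self.errors_mm.mean())

    @property
    def sd_error_mm(self) -> float:
        e = self.errors_mm
        return float(e.std(ddof=1)) if e.size > 1 else 0.0

    def axis_summary(self) -> pd.DataFrame:
        rows = []
        for axis in ("x", "y", "z"):
            e = self.per_sample[f"err_{axis}"].to_numpy()
            rows.append({"axis": axis, "mean_mm": float(e.mean()),
                         "sd_mm": float(e.std(ddof=1)) if e.size > 1 else 0.0})
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        stats = error_statistics(self.errors_mm)
        return {
            "model": self.model_name,
            "n_folds": int(self.per_sample["fold"].nunique()),
            "n_samples": int(len(self.per_sample)),
            "mean_error_mm": stats["mean"],
            "sd_error_mm": stats["sd"],
            "median_error_mm": stats["median"],
            "iqr_error_mm": stats["iqr"],
            "max_error_mm": stats["max"],
            "per_axis": {
                r["axis"]: {"mean_mm": r["mean_mm"], "sd_mm": r["sd_mm"]}
                for r in self.axis_summary().to_dict("records")
            },
            "seed": self.seed,
        }


class ConstantMeanRegressor:
    """Baseline: always predict the training grand-mean target."""

    kind = "constant"

    def __init__(self):
        self.center_: np.ndarray | None = None

    def get_params(self) -> dict:
        return {}

    def fit(self, X, Y):
        self.center_ = np.asarray(Y, dtype=float).mean(axis=0)
        return self

    def predict(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.tile(self.center_, (X.shape[0], 1))


class NearestNeighborRegressor:
    """Memorizing 1-NN model; a split-correctness canary for CV plumbing."""

    kind = "1nn"

    def __init__(self):
        self.X_: np.ndarray | None = None
        self.Y_: np.ndarray | None = None

    def get_params(self) -> dict:
        return {}

    def fit(self, X, Y):
        self.X_ = np.atleast_2d(np.asarray(X, dtype=float))
        self.Y_ = np.asarray(Y, dtype=float)
        return self

    def predict(self, X):
        from scipy.spatial.distance import cdist

        X = np.atleast_2d(np.asarray(X, dtype=float))
        nearest = cdist(X, self.X_).argmin(axis=1)
        return self.Y_[nearest]


def loocv(
    dataset: CohortDataset,
    model_factory: Callable[[], object],
    augmentation: Optional["AugmentationConfig"] = None,  # noqa: F821
    seed: int = 0,
    model_name: str = "",
) -> CVReport:
    """Leave-one-patient-out cross-validation (both hemispheres held out).

    For each patient, a fresh model from ``model_factory`` is trained on the
    remaining patients' samples — augmented with observer noise if an
    augmentation config is given; held-out folds are never augmented — and
    its predictions for the held-out hemispheres are scored.  Deterministic
    given ``seed``: fold k's augmentation stream is spawned from
    ``SeedSequence([seed, k])``.
    """
    if dataset.n_patients < 2:
        raise ValueError("grouped LOOCV needs at least 2 patients")
    folds = grouped_folds(dataset.patient_ids, n_splits=None)
    rows: list[dict] = []
    for fold_idx, (train, test) in enumerate(folds):
        assert np.intersect1d(train, test).size == 0, "train/test folds overlap"
        X_train, Y_train = dataset.X[train], dataset.Y[train]
        g_train = dataset.patient_ids[train]
        if augmentation is not None:
            from .augmentation import augment

            rng = np.random.default_rng(np.random.SeedSequence([seed, fold_idx]))
            X_train, Y_train, g_train = augment(X_train, Y_train, augmentation,
                                                rng=rng, groups=g_train)
        model = model_factory()
        try:
            # group-aware models (e.g. nested grid search) get the fold's
            # patient labels so inner CV can stay grouped
            import inspect

            if "groups" in inspect.signature(model.fit).parameters:
                model.fit(X_train, Y_train, groups=g_train)
            else:
                model.fit(X_train, Y_train)
        except Exception as exc:
            held = sorted(set(dataset.patient_ids[test].tolist()))
            raise RuntimeError(f"model fit failed on fold holding out {held}") from exc
        pred = np.atleast_2d(model.predict(dataset.X[test]))
        diff = pred - dataset.Y[test]
        for i, sample_idx in enumerate(test):
            rows.append(
                {
                    "patient_id": dataset.patient_ids[sample_idx],
                    "hemisphere": dataset.hemispheres[sample_idx],
                    "fold": fold_idx,
                    "error_mm": float(np.linalg.norm(diff[i])),
                    "err_x": float(abs(diff[i, 0])),
                    "err_y": float(abs(diff[i, 1])),
                    "err_z": float(abs(diff[i, 2])),
                    "pred_x": float(pred[i, 0]),
                    "pred_y": float(pred[i, 1]),
                    "pred_z": float(pred[i, 2]),
                }
            )
    per_sample = pd.DataFrame(rows)
    assert len(per_sample) == dataset.n_samples, "every sample must be tested exactly once"
    return CVReport(per_sample=per_sample, model_name=model_name, seed=seed)


def compare_models(
    dataset: CohortDataset,
    factories: Mapping[str, Callable[[], object]],
    augmentation: Optional["AugmentationConfig"] = None,  # noqa: F821
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, CVReport]]:
    """Run grouped LOOCV for several model factories on identical folds.

    Returns a comparison table (mean/SD of the 3-D error and of each axis's
    absolute error) plus the full per-model reports.  Fold assignments are a
    pure function of the patient ids, so all models see the same splits;
    this is asserted.
    """
    reports: dict[str, CVReport] = {}
    fold_check: pd.Series | None = None
    rows = []
    for name, factory in factories.items():
        rep = loocv(dataset, factory, augmentation=augmentation, seed=seed,
                    model_name=name)
        assignment = rep.per_sample.set_index(["patient_id", "hemisphere"])["fold"]
        if fold_check is None:
            fold_check = assignment
        elif not assignment.equals(fold_check):
            raise AssertionError("fold assignments differ between models")
        reports[name] = rep
        axis = {f"{r['axis']}_mean_mm": r["mean_mm"] for r in rep.axis_summary().to_dict("records")}
        rows.append({"model": name, "mean_error_mm": rep.mean_error_mm,
                     "sd_error_mm": rep.sd_error_mm, **axis})
    return pd.DataFrame(rows), reports


def error_statistics(errors: Sequence[float]) -> dict:
    """mean, sd (ddof=1), median, IQR and max of a non-empty error list.

    A single value has no sample SD; it is reported as 0.0 with
    ``sd_defined=False``.  Quantiles use linear interpolation.
    """
    e = np.asarray(errors, dtype=float)
    if e.size == 0:
        raise ValueError("error_statistics requires a non-empty list")
    q25, q75 = np.percentile(e, [25, 75])
    return {
        "mean": float(e.mean()),
        "sd": float(e.std(ddof=1)) if e.size > 1 else 0.0,
        "sd_defined": bool(e.size > 1),
        "median": float(np.median(e)),
        "iqr": float(q75 - q25),
        "max": float(e.max()),
        "n": int(e.size),
    }


def grand_mean_distance(Y: Sequence) -> float:
    """Mean distance of targets to their grand mean — the in-sample limit of
    the constant-mean baseline's LOOCV error."""
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    return float(np.linalg.norm(Y - Y.mean(axis=0), axis=1).mean())
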