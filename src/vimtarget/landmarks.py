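"""The 18-landmark patient-specific stereotactic referential.

Eighteen named anatomical points per hemisphere — commissures, thalamic
and putaminal boundary points, the habenular commissure and the
mammillothalamic tract — form a bounding box around the ventro-intermedius
(Vim) region.  The points are not free: they are defined on planes derived
from the commissures and from points A (lateral third-ventricle border at
the mid-commissural level), B (highest thalamic point above A) and C (the
midpoint of [AB]), which gives a set of verifiable consistency constraints.

The regression feature vector is the fixed-order concatenation of the 18
points' (x, y, z) coordinates: 54 values in the canonical PC-origin frame
with laterality stored as a positive magnitude toward the implanted side.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .geometry import as_point

__all__ = [
    "LANDMARK_NAMES",
    "AXES",
    "FEATURE_NAMES",
    "N_FEATURES",
    "LandmarkSet",
    "ConstraintViolation",
    "MissingLandmarkError",
    "ValidationError",
    "InsufficientDataError",
    "ObserverVariabilityModel",
    "validate_landmark_set",
    "assemble_feature_vector",
    "disassemble_feature_vector",
    "canonicalize_hemisphere",
    "estimate_observer_variability",
]

#: Canonical landmark order; feature vectors concatenate (x, y, z) in this order.
LANDMARK_NAMES: tuple[str, ...] = (
    "AC", "A", "B", "C", "D",
    "PA2", "PM2", "PP2", "BAT", "BPT", "CH",
    "PA1", "PM1", "PP1",
    "PA3", "FMT",
    "Pculm", "Plat",
)

AXES: tuple[str, ...] = ("x", "y", "z")
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{name}_{axis}" for name in LANDMARK_NAMES for axis in AXES
)
N_FEATURES: int = len(FEATURE_NAMES)  # 54


class MissingLandmarkError(KeyError):
    """A landmark set lacks one of the 18 required points."""


class ValidationError(ValueError):
    """A landmark set failed its plane-consistency validation."""


class InsufficientDataError(ValueError):
    """Too few repeated segmentations to estimate observer variability."""


@dataclass(frozen=True)
class ConstraintViolation:
    constraint: str
    residual_mm: float

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.constraint} (residual {self.residual_mm:.3f} mm)"


@dataclass(frozen=True)
class LandmarkSet:
    """One hemisphere's 18 landmarks, in the canonical PC-origin frame (mm).

    ``rater_id`` and ``session_id`` identify repeated segmentation campaigns
    and are only needed for observer-variability estimation.
    """

    patient_id: str
    hemisphere: str  # "L" or "R"
    points: Mapping[str, np.ndarray]
    tolerance_tau: float = 1.0
    rater_id: str | None = None
    session_id: str | None = None

    def __post_init__(self) -> None:
        if self.hemisphere not in ("L", "R"):
            raise ValueError(f"hemisphere must be 'L' or 'R', got {self.hemisphere!r}")
        unknown = set(self.points) - set(LANDMARK_NAMES)
        if unknown:
            raise ValueError(f"unknown landmark names: {sorted(unknown)}")
        object.__setattr__(
            self, "points", {k: as_point(v) for k, v in self.points.items()}
        )

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.points[name]
        except KeyError:
            raise MissingLandmarkError(name) from None

    def require_complete(self) -> None:
        missing = [n for n in LANDMARK_NAMES if n not in self.points]
        if missing:
            raise MissingLandmarkError(
                f"landmark set {self.patient_id}/{self.hemisphere} is missing {missing}"
            )


def _plane_constraints(s: LandmarkSet) -> list[tuple[str, float]]:
    """(description, residual) for every plane/midpoint consistency rule."""
    c_z = s["C"][2]
    pairs: list[tuple[str, float]] = [
        ("AC lies in the axial plane z = 0", abs(s["AC"][2])),
        ("A lies in the axial plane z = 0", abs(s["A"][2])),
        ("B lies in the parasagittal plane x = X_A", abs(s["B"][0] - s["A"][0])),
        ("D lies in the parasagittal plane x = X_A", abs(s["D"][0] - s["A"][0])),
        ("C is the midpoint of [AB]",
         float(np.linalg.norm(s["C"] - (s["A"] + s["B"]) / 2.0))),
        ("D lies in the axial plane z = Z_C", abs(s["D"][2] - c_z)),
    ]
    for name in ("PA2", "PM2", "PP2", "BAT", "BPT", "CH"):
        pairs.append((f"{name} lies in the axial plane z = Z_C", abs(s[name][2] - c_z)))
    for name in ("PA1", "PM1", "PP1"):
        pairs.append(
            (f"{name} lies in the axial plane z = Z_C - 5", abs(s[name][2] - (c_z - 5.0)))
        )
    for name in ("PA3", "FMT"):
        pairs.append(
            (f"{name} lies in the axial plane z = Z_C - 10", abs(s[name][2] - (c_z - 10.0)))
        )
    for name in ("Pculm", "Plat"):
        pairs.append(
            (f"{name} lies in the coronal plane y = Y_PM1", abs(s[name][1] - s["PM1"][1]))
        )
    return pairs


def validate_landmark_set(s: LandmarkSet, tolerance_tau: float | None = None) -> list[ConstraintViolation]:
    """Every plane/midpoint constraint violated by more than the tolerance.

    Returns an empty list for a consistent set. Raises
    :class:`MissingLandmarkError` if any of the 18 landmarks is absent.
    """
    s.require_complete()
    tau = s.tolerance_tau if tolerance_tau is None else tolerance_tau
    return [
        ConstraintViolation(desc, res)
        for desc, res in _plane_constraints(s)
        if res > tau
    ]


def canonicalize_hemisphere(s: LandmarkSet) -> LandmarkSet:
    """Map a right-hemisphere set to positive laterality magnitudes (x -> |x|).

    Left-hemisphere sets (already stored with positive laterality) pass
    through unchanged; the operation is idempotent and touches only x.
    """
    if s.hemisphere != "R":
        return s
    points = {k: np.array([abs(v[0]), v[1], v[2]]) for k, v in s.points.items()}
    return replace(s, points=points)


def assemble_feature_vector(s: LandmarkSet, force: bool = False) -> np.ndarray:
    """Concatenate the 18 landmarks' coordinates into the canonical 54-vector.

    Right hemispheres are pooled with left ones via
    :func:`canonicalize_hemisphere` first.  Unless ``force`` is set, the set
    must pass :func:`validate_landmark_set`.
    """
    s.require_complete()
    if not force:
        violations = validate_landmark_set(s)
        if violations:
            raise ValidationError(
                f"landmark set {s.patient_id}/{s.hemisphere} violates "
                f"{len(violations)} constraint(s): {violations[0]}"
            )
    s = canonicalize_hemisphere(s)
    return np.concatenate([s[name] for name in LANDMARK_NAMES])


def disassemble_feature_vector(
    x: Sequence[float], patient_id: str = "", hemisphere: str = "L",
    tolerance_tau: float = 1.0,
) -> LandmarkSet:
    """Inverse of :func:`assemble_feature_vector` (canonical frame assumed)."""
    arr = np.asarray(x, dtype=float)
    if arr.shape != (N_FEATURES,):
        raise ValueError(f"expected a {N_FEATURES}-vector, got shape {arr.shape}")
    points = {
        name: arr[3 * i: 3 * i + 3].copy() for i, name in enumerate(LANDMARK_NAMES)
    }
    return LandmarkSet(patient_id=patient_id, hemisphere=hemisphere,
                       points=points, tolerance_tau=tolerance_tau)


@dataclass(frozen=True)
class ObserverVariabilityModel:
    """Per-(landmark, axis) Gaussian sigmas of segmentation uncertainty (mm).

    ``sigma`` holds the per-measurement standard deviation for each of the 54
    (landmark, axis) positions; ``mean_abs_distance`` the mean absolute
    per-axis difference between paired segmentations; the grand mean/SD
    summarise the 54 mean distances.
    """

    provenance: str  # "intra" or "inter"
    sigma: Mapping[tuple[str, str], float]
    mean_abs_distance: Mapping[tuple[str, str], float] = field(default_factory=dict)
    grand_mean_mm: float = float("nan")
    grand_sd_mm: float = float("nan")
    n_pairs: int = 0

    def __post_init__(self) -> None:
        if self.provenance not in ("intra", "inter"):
            raise ValueError("provenance must be 'intra' or 'inter'")
        bad = [k for k, v in self.sigma.items() if v < 0]
        if bad:
            raise ValueError(f"negative sigma for {bad}")

    @classmethod
    def uniform(cls, sigma_mm: float, provenance: str = "inter") -> "ObserverVariabilityModel":
        """A model with the same sigma at every (landmark, axis)."""
        table = {(n, a): float(sigma_mm) for n in LANDMARK_NAMES for a in AXES}
        return cls(provenance=provenance, sigma=table)

    def sigma_vector(self) -> np.ndarray:
        """Sigmas ordered like the 54-value feature vector."""
        try:
            return np.array(
                [self.sigma[(n, a)] for n in LANDMARK_NAMES for a in AXES]
            )
        except KeyError as exc:
            raise KeyError(f"variability model lacks an entry for {exc.args[0]}") from None

    def scaled(self, factor: float) -> "ObserverVariabilityModel":
        return ObserverVariabilityModel(
            provenance=self.provenance,
            sigma={k: v * factor for k, v in self.sigma.items()},
            mean_abs_distance=dict(self.mean_abs_distance),
            grand_mean_mm=self.grand_mean_mm * factor,
            grand_sd_mm=self.grand_sd_mm * factor,
            n_pairs=self.n_pairs,
        )


def _segmentation_pairs(
    repeats: Iterable[LandmarkSet], provenance: str
) -> list[tuple[LandmarkSet, LandmarkSet]]:
    by_unit: dict[tuple[str, str], list[LandmarkSet]] = {}
    for s in repeats:
        by_unit.setdefault((s.patient_id, s.hemisphere), []).append(s)
    pairs: list[tuple[LandmarkSet, LandmarkSet]] = []
    for sets in by_unit.values():
        for a, b in itertools.combinations(sets, 2):
            same_rater = a.rater_id == b.rater_id
            if provenance == "intra" and same_rater and a.session_id != b.session_id:
                pairs.append((a, b))
            elif provenance == "inter" and not same_rater:
                pairs.append((a, b))
    return pairs


def estimate_observer_variability(
    repeats: Iterable[LandmarkSet], provenance: str = "inter"
) -> ObserverVariabilityModel:
    """Fit the Gaussian observer-uncertainty law from repeated segmentations.

    Pairs segmentations of the same (patient, hemisphere): same rater across
    sessions for ``intra``, different raters for ``inter``.  For each
    (landmark, axis), the per-measurement sigma is the standard deviation of
    the signed paired differences divided by sqrt(2) (each difference carries
    the noise of two measurements), which is the parameter of the additive
    noise law used for augmentation.  Also reports the mean absolute paired
    per-axis distance per landmark and its grand mean +/- SD.
    """
    pairs = _segmentation_pairs(list(repeats), provenance)
    if not pairs:
        raise InsufficientDataError(
            f"no {provenance}-observer segmentation pairs could be formed"
        )
    # diffs[(landmark, axis)] -> all signed paired differences, pooled
    diffs = {(n, a): [] for n in LANDMARK_NAMES for a in AXES}
    for s1, s2 in pairs:
        s1.require_complete()
        s2.require_complete()
        for name in LANDMARK_NAMES:
            delta = s1[name] - s2[name]
            for j, axis in enumerate(AXES):
                diffs[(name, axis)].append(float(delta[j]))

    sigma: dict[tuple[str, str], float] = {}
    mean_abs: dict[tuple[str, str], float] = {}
    for key, values in diffs.items():
        arr = np.asarray(values)
        sd = float(np.std(arr, ddof=1)) if arr.size > 1 else float(np.abs(arr[0]))
        sigma[key] = sd / np.sqrt(2.0)
        mean_abs[key] = float(np.mean(np.abs(arr)))

    all_means = np.array([mean_abs[k] for k in mean_abs])
    return ObserverVariabilityModel(
        provenance=provenance,
        sigma=sigma,
        mean_abs_distance=mean_abs,
        grand_mean_mm=float(all_means.mean()),
        grand_sd_mm=float(all_means.std(ddof=1)),
        n_pairs=len(pairs),
    )
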