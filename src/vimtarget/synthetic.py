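"""Synthetic cohorts with the statistical structure of stereotactic data.

Real patient MRI-derived cohorts for this problem cannot be shared, so
every pipeline stage is exercised on generated data that mimics the
essential structure: a handful of latent anatomical dimensions per
hemisphere (AC-PC length, third-ventricle half-width, thalamic height and
antero-posterior extent, putaminal position and extent) drive both the 18
landmark positions — placed by documented affine rules that satisfy the
referential's plane constraints exactly — and the "true" functional target
through a smooth, mildly nonlinear map.  Implanted active contacts are the
true target plus isotropic Gaussian implantation noise, and repeated
segmentation campaigns add per-landmark Gaussian observer noise at the
magnitudes seen in practice (about 0.5-0.6 mm per axis).

The latent-to-target map is version-pinned ("v1"); it is nonlinear in the
thalamic and putaminal latents so that kernel methods have something to
gain over a per-axis linear rule of a single landmark, which mirrors why
multi-landmark modelling is attempted at all.  Its constants put the
cohort's median target near (x, y, z) = (14, 8, 1) mm in PC-origin
coordinates, the region reported for clinically effective contacts.

Everything is a pure function of (config, seed): all randomness flows from
one master seed through named, documented streams.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .evaluation import CohortDataset
from .geometry import Frame, FrameOrigin
from .landmarks import (
    LANDMARK_NAMES,
    LandmarkSet,
    ObserverVariabilityModel,
    assemble_feature_vector,
)

__all__ = [
    "AnatomyLatents",
    "GeneratorConfig",
    "SyntheticCohort",
    "TARGET_MAP_VERSIONS",
    "sample_latents",
    "latents_to_landmarks",
    "true_target",
    "generate_cohort",
]

# stream tags for SeedSequence spawning (documented, fixed)
_STREAM_LATENTS = 0
_STREAM_OBSERVED = 1
_STREAM_IMPLANT = 2
_STREAM_LEADS = 3
_STREAM_CAMPAIGN = 4


@dataclass(frozen=True)
class AnatomyLatents:
    """Latent anatomical dimensions of one hemisphere (mm).

    ``asymmetry`` records the hemisphere-specific perturbation that was added
    on top of the patient-shared draw; all other fields must be positive.
    """

    acpc_length: float
    v3_halfwidth: float
    thal_height: float
    thal_ap_extent: float
    putamen_lat_offset: float
    putamen_ap_extent: float
    global_scale: float = 1.0
    asymmetry: float = 0.0

    def __post_init__(self) -> None:
        for name in ("acpc_length", "v3_halfwidth", "thal_height",
                     "thal_ap_extent", "putamen_lat_offset",
                     "putamen_ap_extent", "global_scale"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be > 0")


#: Sampling laws: (mean, sd, low, high) for truncated normals.
_LATENT_LAWS: dict[str, tuple[float, float, float, float]] = {
    "acpc_length": (26.0, 1.5, 22.0, 30.0),
    "v3_halfwidth": (3.5, 0.8, 1.5, 6.0),
    "thal_height": (16.0, 1.5, 12.0, 20.0),
    "thal_ap_extent": (28.0, 2.0, 22.0, 34.0),
    "putamen_lat_offset": (22.0, 1.5, 18.0, 26.0),
    "putamen_ap_extent": (30.0, 2.0, 24.0, 36.0),
    "global_scale": (1.0, 0.03, 0.9, 1.1),
}

#: Latents that receive an independent per-hemisphere asymmetry perturbation.
_ASYMMETRIC_LATENTS = ("v3_halfwidth", "thal_height", "putamen_lat_offset")


@dataclass(frozen=True)
class GeneratorConfig:
    """Cohort-generation settings.

    Defaults reproduce the shape of a typical essential-tremor DBS series:
    15 patients, bilateral implants except for ``n_unilateral`` patients
    (one by default), i.e. 29 leads.  ``observer_sigma`` is the
    per-measurement, per-axis segmentation noise (mm); ``implantation_sigma``
    the per-axis scatter of the implanted active contact around the true
    functional target (mm).
    """

    n_patients: int = 15
    hemispheres_per_patient: int = 2
    n_unilateral: int = 1
    seed: int = 0
    observer_sigma: float = 0.6
    implantation_sigma: float = 0.75
    asymmetry_sd: float = 0.4
    nonlinearity_amplitude: float = 1.0
    target_map_version: str = "v1"
    n_segmentation_campaigns: int = 3  # (rater1, s1), (rater1, s2), (rater2, s1)

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if not (0 <= self.n_unilateral <= self.n_patients):
            raise ValueError("n_unilateral out of range")
        for name in ("observer_sigma", "implantation_sigma", "asymmetry_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.target_map_version not in TARGET_MAP_VERSIONS:
            raise ValueError(f"unknown target map version {self.target_map_version!r}")


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      low: float, high: float) -> float:
    """Rejection-sampled truncated normal (the bands are wide; a few tries suffice)."""
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if low <= x <= high:
            return float(x)
    return float(np.clip(x, low, high))  # pragma: no cover - pathological config


def sample_latents(config: GeneratorConfig, patient_index: int) -> dict[str, AnatomyLatents]:
    """Draw one patient's latents; hemispheres share them up to asymmetry.

    Returns ``{"L": ..., "R": ...}``.  The per-hemisphere asymmetry term is
    an independent Gaussian perturbation (sd ``asymmetry_sd``) of the
    third-ventricle, thalamic-height and putaminal-laterality latents.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, _STREAM_LATENTS, patient_index])
    )
    shared = {
        name: _truncated_normal(rng, *law) for name, law in _LATENT_LAWS.items()
    }
    scale = shared.pop("global_scale")
    out: dict[str, AnatomyLatents] = {}
    for hemi in ("L", "R"):
        values = {k: v * scale for k, v in shared.items()}
        asym = 0.0
        for name in _ASYMMETRIC_LATENTS:
            delta = rng.normal(0.0, config.asymmetry_sd)
            values[name] = max(values[name] + delta, 0.5)
            asym += abs(delta)
        out[hemi] = AnatomyLatents(global_scale=scale, asymmetry=asym, **values)
    return out


def latents_to_landmarks(
    latents: AnatomyLatents, patient_id: str = "P", hemisphere: str = "L"
) -> LandmarkSet:
    """Place the 18 landmarks from the latents (PC-origin, laterality positive).

    The construction is deterministic and satisfies every plane/midpoint
    constraint of the referential exactly: AC and A sit on z = 0, B and D on
    the parasagittal plane of A, C is the midpoint of [AB] (so Z_C is half
    the thalamic height), the putaminal/thalamic/habenular points sit on
    their required axial planes relative to Z_C, and Pculm/Plat share PM1's
    coronal plane.
    """
    v3 = latents.v3_halfwidth
    acpc = latents.acpc_length
    y_mcp = acpc / 2.0
    th = latents.thal_height
    z_c = th / 2.0
    t_ap = latents.thal_ap_extent
    p_lat = latents.putamen_lat_offset
    p_ap = latents.putamen_ap_extent

    y_pm1 = y_mcp - 1.0
    points = {
        "AC": (0.0, acpc, 0.0),
        "A": (v3, y_mcp, 0.0),
        "B": (v3, y_mcp, th),
        "C": (v3, y_mcp, z_c),
        "D": (v3, y_mcp + 0.5 * t_ap, z_c),
        "PA2": (p_lat - 1.5, y_mcp + 0.5 * p_ap, z_c),
        "PM2": (p_lat + 1.5, y_mcp, z_c),
        "PP2": (p_lat - 1.0, y_mcp - 0.5 * p_ap, z_c),
        "BAT": (v3 + 4.0, y_mcp + 0.45 * t_ap, z_c),
        "BPT": (v3 + 6.0, y_mcp - 0.55 * t_ap, z_c),
        "CH": (1.2, 1.0 + 0.05 * acpc, z_c),
        "PA1": (p_lat - 2.5, y_mcp + 0.45 * p_ap, z_c - 5.0),
        "PM1": (p_lat + 0.5, y_pm1, z_c - 5.0),
        "PP1": (p_lat - 2.0, y_mcp - 0.45 * p_ap, z_c - 5.0),
        "PA3": (p_lat - 3.5, y_mcp + 0.40 * p_ap, z_c - 10.0),
        "FMT": (v3 + 2.5, y_mcp - 1.5, z_c - 10.0),
        "Pculm": (p_lat - 1.0, y_pm1, z_c + 4.0),
        "Plat": (p_lat + 2.5, y_pm1, z_c - 3.0),
    }
    return LandmarkSet(
        patient_id=patient_id,
        hemisphere=hemisphere,
        points={k: np.array(v) for k, v in points.items()},
        tolerance_tau=1e-6,
    )


def _target_v1(latents: AnatomyLatents, amplitude: float) -> np.ndarray:
    """Pinned map v1: smooth, nonlinear in the thalamic/putaminal latents.

    x rides on the third-ventricle half-width (the classical laterality
    correction), y on the AC-PC length (the classical antero-posterior
    normalisation); the ``amplitude``-scaled terms add smooth nonlinearity.
    """
    x = 11.0 + 0.8 * latents.v3_halfwidth + amplitude * 1.5 * np.sin(latents.thal_height / 5.0)
    y = 0.30 * latents.acpc_length + amplitude * 2.0 * (latents.putamen_ap_extent - 30.0) ** 2 / 50.0
    z = (
        0.7
        + 0.45 * (latents.thal_height - 16.0)
        + amplitude * 0.8 * np.sin(latents.putamen_lat_offset / 4.0)
    )
    return np.array([x, y, z])


TARGET_MAP_VERSIONS: Mapping[str, callable] = {"v1": _target_v1}


def true_target(
    latents: AnatomyLatents,
    nonlinearity_amplitude: float = 1.0,
    version: str = "v1",
) -> np.ndarray:
    """The hemisphere's true functional target (PC-origin, mm)."""
    return TARGET_MAP_VERSIONS[version](latents, nonlinearity_amplitude)


@dataclass(frozen=True)
class SyntheticCohort:
    """Everything one generated cohort provides.

    * ``clean``: exact landmarks paired with exact true targets.
    * ``observed``: observer-noise landmarks paired with implanted active
      contacts (true target + implantation noise) — the realistic dataset.
    * ``clean_sets``: the exact landmark sets (always constraint-consistent).
    * ``replicas``: repeated segmentation campaigns (rater/session tagged)
      for observer-variability estimation.
    * ``leads``: reconstructed lead geometry, one row per implant.
    """

    clean: CohortDataset
    observed: CohortDataset
    clean_sets: tuple[LandmarkSet, ...]
    replicas: tuple[LandmarkSet, ...]
    leads: pd.DataFrame
    acpc_by_patient: Mapping[str, float]
    manifest: dict

    @property
    def n_leads(self) -> int:
        return self.observed.n_samples


def _patient_id(i: int) -> str:
    return f"P{i + 1:03d}"


def generate_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort from one master seed.

    The last ``n_unilateral`` patients contribute a single (left) hemisphere.
    Observer noise is independent Gaussian per landmark coordinate with sd
    ``observer_sigma``; each segmentation campaign is an independent noisy
    reading of the same exact landmarks.  Implanted active contacts scatter
    around the true target with per-axis sd ``implantation_sigma``.  Lead
    trajectories run dorsally along a jittered double-oblique direction with
    the implanted contact placed on the axis at the contact-2 arc distance.
    """
    rng_obs = np.random.default_rng(np.random.SeedSequence([config.seed, _STREAM_OBSERVED]))
    rng_impl = np.random.default_rng(np.random.SeedSequence([config.seed, _STREAM_IMPLANT]))
    rng_lead = np.random.default_rng(np.random.SeedSequence([config.seed, _STREAM_LEADS]))
    rng_campaigns = [
        np.random.default_rng(np.random.SeedSequence([config.seed, _STREAM_CAMPAIGN, c]))
        for c in range(config.n_segmentation_campaigns)
    ]
    campaign_tags = [("R1", "S1"), ("R1", "S2"), ("R2", "S1"), ("R2", "S2")][
        : config.n_segmentation_campaigns
    ]

    patient_ids: list[str] = []
    hemispheres: list[str] = []
    X_clean: list[np.ndarray] = []
    Y_clean: list[np.ndarray] = []
    X_obs: list[np.ndarray] = []
    Y_obs: list[np.ndarray] = []
    clean_sets: list[LandmarkSet] = []
    replicas: list[LandmarkSet] = []
    lead_rows: list[dict] = []
    acpc_by_patient: dict[str, float] = {}

    n_bilateral = config.n_patients - config.n_unilateral
    for i in range(config.n_patients):
        pid = _patient_id(i)
        latents_by_hemi = sample_latents(config, i)
        hemis = ("L", "R")[: config.hemispheres_per_patient]
        if i >= n_bilateral:
            hemis = ("L",)
        acpc_by_patient[pid] = latents_by_hemi["L"].acpc_length
        for hemi in hemis:
            lat = latents_by_hemi[hemi]
            lm = latents_to_landmarks(lat, patient_id=pid, hemisphere=hemi)
            x_exact = assemble_feature_vector(lm)
            y_true = true_target(
                lat, config.nonlinearity_amplitude, config.target_map_version
            )
            # observed reading of the landmarks + implanted contact position
            x_noisy = x_exact + rng_obs.normal(0.0, config.observer_sigma, size=x_exact.shape)
            y_contact = y_true + rng_impl.normal(0.0, config.implantation_sigma, size=3)

            patient_ids.append(pid)
            hemispheres.append(hemi)
            X_clean.append(x_exact)
            Y_clean.append(y_true)
            X_obs.append(x_noisy)
            Y_obs.append(y_contact)
            clean_sets.append(lm)

            for (rater, session), rng_c in zip(campaign_tags, rng_campaigns):
                noisy_points = {
                    name: lm[name] + rng_c.normal(0.0, config.observer_sigma, size=3)
                    for name in LANDMARK_NAMES
                }
                replicas.append(
                    LandmarkSet(
                        patient_id=pid, hemisphere=hemi, points=noisy_points,
                        tolerance_tau=lm.tolerance_tau,
                        rater_id=rater, session_id=session,
                    )
                )

            # lead geometry: contact 2 (0-based index 1) carries the implant
            u = np.array([0.15, 0.35, 0.92]) + rng_lead.normal(0.0, 0.05, size=3)
            u /= np.linalg.norm(u)
            d_active = 1.5 + 1 * (1.5 + 0.5)  # tip_to_first + k * pitch, k = 1
            tip = y_contact - d_active * u
            proximal = tip + 12.0 * u
            lead_rows.append(
                {
                    "patient_id": pid, "hemisphere": hemi,
                    "ax": tip[0], "ay": tip[1], "az": tip[2],
                    "jx": proximal[0], "jy": proximal[1], "jz": proximal[2],
                    "frame": "PC", "acpc_length": lat.acpc_length,
                    "active_contact_index": 1,
                }
            )

    frame = Frame(FrameOrigin.PC, float(np.mean(list(acpc_by_patient.values()))))
    clean = CohortDataset(
        patient_ids=np.array(patient_ids, dtype=object),
        hemispheres=np.array(hemispheres, dtype=object),
        X=np.array(X_clean), Y=np.array(Y_clean), frame=frame,
    )
    observed = CohortDataset(
        patient_ids=np.array(patient_ids, dtype=object),
        hemispheres=np.array(hemispheres, dtype=object),
        X=np.array(X_obs), Y=np.array(Y_obs), frame=frame,
    )
    manifest = {
        "config": dataclasses.asdict(config),
        "target_map_version": config.target_map_version,
        "seed": config.seed,
        "n_leads": observed.n_samples,
        "n_patients": config.n_patients,
    }
    return SyntheticCohort(
        clean=clean,
        observed=observed,
        clean_sets=tuple(clean_sets),
        replicas=tuple(replicas),
        leads=pd.DataFrame(lead_rows),
        acpc_by_patient=acpc_by_patient,
        manifest=manifest,
    )
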