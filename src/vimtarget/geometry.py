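"""Stereotactic coordinate geometry for DBS lead trajectories.

Conventions
-----------
All coordinates live in AC-PC space in millimetres: x is laterality
(positive toward the implanted side), y is positive anterior, z is
positive dorsal.  The canonical storage frame puts the posterior
commissure (PC) at the origin; the mid-commissural point (MCP) frame is
accepted on input and converted, the two differing by a pure
y-translation of half the AC-PC distance.

A DBS lead is reconstructed from its distal tip A and a point J chosen
just proximal to the most proximal contact; any point M on the lead at
arc distance D from the tip is ``M = D * u + A`` where ``u`` is the unit
vector from A toward J.  Placement accuracy is summarised by two
statistics: ``d1``, the Euclidean distance between the (possibly
bipolar-midpoint) active-contact centre and the planned target, and
``d2``, the perpendicular distance between the lead axis and the planned
target, ``d2 = ||(T - L) x u|| / ||u||``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "FrameOrigin",
    "Frame",
    "LeadTrajectory",
    "ContactGeometry",
    "StereotacticAccuracy",
    "DegenerateTrajectoryError",
    "FrameMismatchError",
    "as_point",
    "unit_direction",
    "point_on_lead",
    "contact_centers",
    "bipolar_midpoint",
    "accuracy_d1",
    "accuracy_d2",
    "convert_frame",
    "MEDTRONIC_3389",
]


class DegenerateTrajectoryError(ValueError):
    """Raised when a lead axis cannot be defined (coincident points, zero direction)."""


class FrameMismatchError(ValueError):
    """Raised when two frames that must share an AC-PC length do not."""


class FrameOrigin(str, Enum):
    PC = "PC"
    MCP = "MCP"


def as_point(p: Sequence[float]) -> np.ndarray:
    """Coerce a 3-sequence to a finite float ndarray of shape (3,)."""
    arr = np.asarray(p, dtype=float)
    if arr.shape != (3,):
        raise ValueError(f"expected a 3-D point, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"point has non-finite coordinates: {arr}")
    return arr


@dataclass(frozen=True)
class Frame:
    """A stereotactic frame: origin convention plus the patient's AC-PC length (mm)."""

    origin: FrameOrigin
    acpc_length: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", FrameOrigin(self.origin))
        if not (self.acpc_length > 0):
            raise ValueError(f"acpc_length must be > 0, got {self.acpc_length}")


@dataclass(frozen=True)
class LeadTrajectory:
    """Lead axis reconstructed from the distal tip A and a proximal point J."""

    tip_A: np.ndarray
    proximal_J: np.ndarray
    unit_direction_u: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "tip_A", as_point(self.tip_A))
        object.__setattr__(self, "proximal_J", as_point(self.proximal_J))
        object.__setattr__(
            self, "unit_direction_u", unit_direction(self.tip_A, self.proximal_J)
        )


@dataclass(frozen=True)
class ContactGeometry:
    """Physical contact layout of a lead model.

    ``tip_to_first_contact_center`` is the arc distance from the distal tip to
    the centre of the most distal contact; consecutive contact centres are
    spaced ``contact_length + inter_contact_gap`` apart.
    """

    n_contacts: int = 4
    contact_length: float = 1.5
    inter_contact_gap: float = 0.5
    diameter: float = 1.28
    tip_to_first_contact_center: float = 1.5

    def __post_init__(self) -> None:
        if self.n_contacts < 1:
            raise ValueError("n_contacts must be >= 1")
        for name in ("contact_length", "inter_contact_gap", "diameter",
                     "tip_to_first_contact_center"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be > 0")


#: Medtronic 3389 lead: 1.28 mm diameter, 1.5 mm contacts, 0.5 mm spacing.
MEDTRONIC_3389 = ContactGeometry()


@dataclass(frozen=True)
class StereotacticAccuracy:
    """Accuracy pair: contact-to-target distance d1 and axis-to-target distance d2."""

    d1: float
    d2: float

    def __post_init__(self) -> None:
        if self.d1 < 0 or self.d2 < 0:
            raise ValueError("distances must be non-negative")
        # The nearest axis point is at least as close as any on-axis contact.
        if self.d2 > self.d1 + 1e-9:
            raise ValueError(f"d2 ({self.d2}) must not exceed d1 ({self.d1})")


def unit_direction(tip_A: Sequence[float], proximal_J: Sequence[float]) -> np.ndarray:
    """Unit vector along the lead, from the tip A toward the proximal point J."""
    a, j = as_point(tip_A), as_point(proximal_J)
    d = j - a
    norm = float(np.linalg.norm(d))
    if norm == 0.0:
        raise DegenerateTrajectoryError("tip and proximal point coincide")
    return d / norm


def point_on_lead(tip_A: Sequence[float], u: Sequence[float], distance_D: float) -> np.ndarray:
    """Point M on the lead at arc distance D from the tip: ``M = D*u + A``."""
    a, u = as_point(tip_A), as_point(u)
    if abs(np.linalg.norm(u) - 1.0) > 1e-9:
        raise ValueError(f"u must be a unit vector, got norm {np.linalg.norm(u)!r}")
    if distance_D < 0:
        raise ValueError("distance along the lead must be >= 0")
    return distance_D * u + a


def contact_centers(trajectory: LeadTrajectory, geometry: ContactGeometry = MEDTRONIC_3389) -> list[np.ndarray]:
    """Centres of every contact, most distal first."""
    pitch = geometry.contact_length + geometry.inter_contact_gap
    return [
        point_on_lead(
            trajectory.tip_A,
            trajectory.unit_direction_u,
            geometry.tip_to_first_contact_center + k * pitch,
        )
        for k in range(geometry.n_contacts)
    ]


def bipolar_midpoint(center_a: Sequence[float], center_b: Sequence[float]) -> np.ndarray:
    """Midpoint of two contact centres (the target convention for bipolar stimulation)."""
    return (as_point(center_a) + as_point(center_b)) / 2.0


def accuracy_d1(contact_M: Sequence[float], target_T: Sequence[float]) -> float:
    """Euclidean distance between the active-contact centre M and the planned target T."""
    return float(np.linalg.norm(as_point(target_T) - as_point(contact_M)))


def accuracy_d2(tip_L: Sequence[float], u: Sequence[float], target_T: Sequence[float]) -> float:
    """Minimal distance between the lead axis through L with direction u and target T.

    Computed as ``||(T - L) x u|| / ||u||``; u need not be normalised but must
    be nonzero.
    """
    L, u, T = as_point(tip_L), as_point(u), as_point(target_T)
    norm_u = float(np.linalg.norm(u))
    if norm_u == 0.0:
        raise DegenerateTrajectoryError("direction vector has zero norm")
    return float(np.linalg.norm(np.cross(T - L, u)) / norm_u)


def lead_accuracy(trajectory: LeadTrajectory, contact_M: Sequence[float],
                  target_T: Sequence[float]) -> StereotacticAccuracy:
    """Convenience: the (d1, d2) pair for one lead and one planned target."""
    return StereotacticAccuracy(
        d1=accuracy_d1(contact_M, target_T),
        d2=accuracy_d2(trajectory.tip_A, trajectory.unit_direction_u, target_T),
    )


def convert_frame(p: Sequence[float], from_frame: Frame, to_frame: Frame) -> np.ndarray:
    """Translate a point between PC-origin and MCP-origin conventions.

    MCP sits acpc_length/2 anterior to PC, so y_PC = y_MCP + acpc_length/2;
    x and z are unchanged. Both frames must declare the same AC-PC length.
    """
    if abs(from_frame.acpc_length - to_frame.acpc_length) > 1e-9:
        raise FrameMismatchError(
            f"AC-PC lengths differ: {from_frame.acpc_length} vs {to_frame.acpc_length}"
        )
    point = as_point(p).copy()
    if from_frame.origin == to_frame.origin:
        return point
    half = from_frame.acpc_length / 2.0
    if from_frame.origin == FrameOrigin.MCP:  # MCP -> PC
        point[1] += half
    else:  # PC -> MCP
        point[1] -= half
    return point
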