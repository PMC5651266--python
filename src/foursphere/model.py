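"""Domain types and geometry for the four-sphere volume-conductor head model.

The head is idealized as four concentric spherical layers — brain, cerebrospinal
fluid (CSF), skull, and scalp — each with a homogeneous, isotropic, frequency-
independent conductivity.  A current dipole sits inside the brain layer and the
quasi-static potential it sets up is expanded in Legendre series whose closed
forms assume a canonical frame: the dipole location on the +z axis, the
tangential moment component along +y.  This module provides the validated
parameter containers and the rigid transform into that frame.

All internal quantities are SI (meters, S/m, A·m, volts).  Configuration files
may declare centimeters; conversion happens at the boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "FourSphereError",
    "GeometryError",
    "ParameterError",
    "UndecomposableError",
    "OutsideHeadError",
    "ValidityRegionError",
    "SeriesRangeError",
    "HeadModel",
    "Dipole",
    "EvaluationPoint",
    "CanonicalFrame",
    "make_head_model",
    "default_head_model",
    "canonical_frame",
    "to_spherical",
]


class FourSphereError(Exception):
    """Base class for all errors raised by this package."""


class GeometryError(FourSphereError, ValueError):
    """Shell radii are not strictly increasing and positive."""


class ParameterError(FourSphereError, ValueError):
    """A physical parameter is out of its admissible range."""


class UndecomposableError(FourSphereError, ValueError):
    """Dipole at the sphere center: the radial direction is undefined."""


class OutsideHeadError(FourSphereError, ValueError):
    """Evaluation point lies outside the scalp surface."""


class ValidityRegionError(FourSphereError, ValueError):
    """Evaluation point lies at or below the dipole radius r_z.

    The series expansions are stated only for r > r_z; the interior expansion
    is deliberately not implemented (EEG use cases never need it, and silent
    extrapolation would be wrong).
    """


class SeriesRangeError(FourSphereError, FloatingPointError):
    """Coefficient evaluation left the numerically representable range."""


_LENGTH_UNITS = {"m": 1.0, "cm": 1e-2, "mm": 1e-3}


def _as_float_tuple(values: Sequence[float], n: int, what: str) -> tuple[float, ...]:
    vals = tuple(float(v) for v in values)
    if len(vals) != n:
        raise ParameterError(f"{what}: expected {n} values, got {len(vals)}")
    if not all(math.isfinite(v) for v in vals):
        raise ParameterError(f"{what}: all values must be finite, got {vals}")
    return vals


@dataclass(frozen=True)
class HeadModel:
    """Four concentric shells: radii (m) and conductivities (S/m).

    ``radii[s-1]`` is the outer radius of shell ``s`` (1 brain, 2 CSF, 3 skull,
    4 scalp) and must be strictly increasing; all conductivities are strictly
    positive.
    """

    radii: tuple[float, float, float, float]
    conductivities: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        radii = _as_float_tuple(self.radii, 4, "radii")
        sigmas = _as_float_tuple(self.conductivities, 4, "conductivities")
        if not (0.0 < radii[0] < radii[1] < radii[2] < radii[3]):
            raise GeometryError(
                f"radii must satisfy 0 < r1 < r2 < r3 < r4, got {radii}"
            )
        if any(s <= 0.0 for s in sigmas):
            raise ParameterError(f"conductivities must be positive, got {sigmas}")
        object.__setattr__(self, "radii", radii)
        object.__setattr__(self, "conductivities", sigmas)

    # readable accessors -------------------------------------------------
    @property
    def r1(self) -> float:
        return self.radii[0]

    @property
    def r2(self) -> float:
        return self.radii[1]

    @property
    def r3(self) -> float:
        return self.radii[2]

    @property
    def r4(self) -> float:
        return self.radii[3]

    def radius(self, s: int) -> float:
        """Outer radius of shell ``s`` (1-based)."""
        return self.radii[s - 1]

    def sigma(self, s: int) -> float:
        """Conductivity of shell ``s`` (1-based)."""
        return self.conductivities[s - 1]


#: Brain conductivity used by the standard parameterization (S/m).
SIGMA_BRAIN = 0.33

#: Documented presets for the skull conductivity divisor K (sigma_skull =
#: sigma_brain / K).
SKULL_DIVISOR_PRESETS = (20.0, 40.0, 80.0)


def make_head_model(
    radii: Sequence[float],
    conductivities: Sequence[float],
    units: str = "m",
) -> HeadModel:
    """Build a validated :class:`HeadModel`.

    Parameters
    ----------
    radii
        Four shell radii, strictly increasing, in ``units``.
    conductivities
        Four shell conductivities in S/m.
    units
        Length unit of ``radii``: ``"m"`` (default), ``"cm"`` or ``"mm"``.
    """
    try:
        scale = _LENGTH_UNITS[units]
    except KeyError:
        raise ParameterError(f"unknown length unit {units!r}") from None
    radii_m = tuple(float(r) * scale for r in _as_float_tuple(radii, 4, "radii"))
    return HeadModel(radii=radii_m, conductivities=tuple(conductivities))


def default_head_model(skull_divisor: float = 20.0) -> HeadModel:
    """Standard four-sphere parameterization.

    Radii 7.9 / 8.0 / 8.5 / 9.0 cm; conductivities
    sigma_brain = 0.33 S/m, sigma_CSF = 5 sigma_brain,
    sigma_skull = sigma_brain / ``skull_divisor``, sigma_scalp = sigma_brain.
    ``skull_divisor`` defaults to 20 (40 and 80 are the other documented
    presets).
    """
    if not (math.isfinite(skull_divisor) and skull_divisor > 0):
        raise ParameterError(f"skull_divisor must be positive, got {skull_divisor}")
    return make_head_model(
        radii=(7.9, 8.0, 8.5, 9.0),
        conductivities=(
            SIGMA_BRAIN,
            5.0 * SIGMA_BRAIN,
            SIGMA_BRAIN / skull_divisor,
            SIGMA_BRAIN,
        ),
        units="cm",
    )


@dataclass(frozen=True)
class Dipole:
    """Ideal current dipole: position (m) and moment (A·m), world frame.

    The position must be nonzero (the canonical radial direction is undefined
    at the center; use a small offset instead).  Whether the position lies
    inside the brain shell is checked against a concrete :class:`HeadModel`
    at evaluation time.  A zero moment is allowed and yields zero potential.
    """

    position: tuple[float, float, float]
    moment: tuple[float, float, float]

    def __post_init__(self) -> None:
        pos = _as_float_tuple(self.position, 3, "position")
        mom = _as_float_tuple(self.moment, 3, "moment")
        if pos == (0.0, 0.0, 0.0):
            raise UndecomposableError(
                "dipole exactly at the sphere center has no radial direction; "
                "offset it slightly instead"
            )
        object.__setattr__(self, "position", pos)
        object.__setattr__(self, "moment", mom)

    @property
    def r_z(self) -> float:
        """Radial location of the dipole (m)."""
        return float(np.linalg.norm(self.position))

    @property
    def p(self) -> float:
        """Moment magnitude (A·m)."""
        return float(np.linalg.norm(self.moment))


@dataclass(frozen=True)
class EvaluationPoint:
    """Spherical coordinates of a measurement point in the canonical frame.

    ``theta`` is the polar angle from the dipole position axis, ``phi`` the
    azimuth from the canonical +x axis (the tangential moment lies along +y).
    """

    r: float
    theta: float
    phi: float = 0.0

    def __post_init__(self) -> None:
        r, theta, phi = (float(self.r), float(self.theta), float(self.phi))
        if not (math.isfinite(r) and r > 0):
            raise ParameterError(f"r must be positive and finite, got {r}")
        if not (-1e-12 <= theta <= math.pi + 1e-12):
            raise ParameterError(f"theta must lie in [0, pi], got {theta}")
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "theta", min(max(theta, 0.0), math.pi))
        object.__setattr__(self, "phi", phi)


@dataclass(frozen=True)
class CanonicalFrame:
    """Rigid map from world coordinates into the canonical dipole frame.

    ``rotation`` (3×3, orthogonal, det +1) takes world vectors to the frame in
    which the dipole position lies on +z and the tangential moment component
    along +y; ``p_rad`` is the signed radial moment, ``p_tan ≥ 0`` the
    tangential one, with p_rad² + p_tan² = |moment|².
    """

    rotation: np.ndarray
    p_rad: float
    p_tan: float
    r_z: float


def canonical_frame(dipole: Dipole) -> CanonicalFrame:
    """Decompose a dipole into radial and tangential components.

    Any dipole is a linear combination of a radial and a tangential dipole at
    the same location; this builds the rotation realizing that decomposition.
    """
    pos = np.asarray(dipole.position, dtype=float)
    r_z = float(np.linalg.norm(pos))
    if r_z == 0.0:
        raise UndecomposableError("dipole position has zero magnitude")
    zhat = pos / r_z
    m = np.asarray(dipole.moment, dtype=float)
    p_rad = float(m @ zhat)
    m_tan = m - p_rad * zhat
    p_tan = float(np.linalg.norm(m_tan))
    m_norm = float(np.linalg.norm(m))
    if p_tan > 1e-13 * max(m_norm, 1e-300):
        yhat = m_tan / p_tan
    else:
        # Purely radial moment: any axis perpendicular to zhat will do.
        # Pick deterministically from the world axis least aligned with zhat.
        e = np.zeros(3)
        e[int(np.argmin(np.abs(zhat)))] = 1.0
        yhat = e - (e @ zhat) * zhat
        yhat /= np.linalg.norm(yhat)
        p_tan = 0.0
    xhat = np.cross(yhat, zhat)
    rotation = np.vstack([xhat, yhat, zhat])
    rotation.setflags(write=False)
    return CanonicalFrame(rotation=rotation, p_rad=p_rad, p_tan=p_tan, r_z=r_z)


def to_spherical(
    point: Sequence[float],
    frame: CanonicalFrame,
    model: HeadModel | None = None,
) -> EvaluationPoint:
    """Map a world-frame point to canonical spherical coordinates (r, θ, φ).

    θ is the angle between the point and the dipole position axis; φ is
    measured from the canonical +x axis.  If ``model`` is given, points beyond
    the scalp surface raise :class:`OutsideHeadError`.
    """
    q = frame.rotation @ np.asarray(point, dtype=float)
    r = float(np.linalg.norm(q))
    if model is not None and r > model.r4 * (1.0 + 1e-12):
        raise OutsideHeadError(
            f"point at r={r:.6g} m lies outside the scalp surface r4={model.r4:.6g} m"
        )
    if r == 0.0:
        return EvaluationPoint(r=np.finfo(float).tiny, theta=0.0, phi=0.0)
    theta = float(np.arccos(np.clip(q[2] / r, -1.0, 1.0)))
    phi = float(np.arctan2(q[1], q[0]))
    return EvaluationPoint(r=r, theta=theta, phi=phi)
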