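"""Closed-form control solutions used to validate the four-sphere series.

Two limits of the layered model have elementary solutions:

* a radial dipole inside a homogeneous, insulated single sphere — the
  surface potential has a closed form in f = r_z/r_4 (the summed Legendre
  series Σ (2n+1) f^{n+1} P_n(cosθ) in closed form);
* an ideal current dipole in an unbounded homogeneous medium — the familiar
  inverse-square dipole potential, which the layered model must approach when
  all conductivities are equal and the shell radii are taken to infinity at
  fixed dipole–electrode geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model import Dipole, ParameterError

__all__ = [
    "HomogeneousSphere",
    "potential_single_sphere",
    "potential_infinite_medium",
]


@dataclass(frozen=True)
class HomogeneousSphere:
    """Insulated homogeneous sphere: outer radius (m) and conductivity (S/m)."""

    radius: float
    conductivity: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.radius) and self.radius > 0):
            raise ParameterError(f"radius must be positive, got {self.radius}")
        if not (math.isfinite(self.conductivity) and self.conductivity > 0):
            raise ParameterError(
                f"conductivity must be positive, got {self.conductivity}"
            )


def potential_single_sphere(
    sphere: HomogeneousSphere,
    r_z: float,
    p: float,
    theta: float | Sequence[float] | np.ndarray,
) -> np.ndarray | float:
    """Surface potential of a radial dipole in a homogeneous sphere (V).

    With f = r_z/R and u = cosθ the closed form is

        Φ(R, θ) = p/(4πσR²) · [ 2(u − f)/d³ + (1/f)(1/d − 1) ],
        d = sqrt(1 + f² − 2fu).

    As f → 0 this reduces to the central-dipole formula 3p cosθ/(4πσR²).
    """
    f = float(r_z) / sphere.radius
    if not 0.0 < f < 1.0:
        raise ParameterError(
            f"f = r_z/radius must lie in (0, 1), got {f:.6g}"
        )
    u = np.cos(np.asarray(theta, dtype=float))
    d = np.sqrt(1.0 + f * f - 2.0 * f * u)
    pref = p / (4.0 * np.pi * sphere.conductivity * sphere.radius**2)
    val = pref * (2.0 * (u - f) / d**3 + (1.0 / f) * (1.0 / d - 1.0))
    return val if val.ndim else float(val)


def potential_infinite_medium(
    sigma: float,
    dipole: Dipole,
    point: Sequence[float] | np.ndarray,
) -> np.ndarray | float:
    """Potential of an ideal current dipole in an unbounded homogeneous medium.

    Φ(x) = p · (x − x0) / (4πσ |x − x0|³) — inverse-square in distance, zero
    in the plane perpendicular to the moment through the source.
    """
    if not (math.isfinite(sigma) and sigma > 0):
        raise ParameterError(f"conductivity must be positive, got {sigma}")
    pts = np.atleast_2d(np.asarray(point, dtype=float))
    disp = pts - np.asarray(dipole.position, dtype=float)
    dist = np.linalg.norm(disp, axis=1)
    if np.any(dist == 0.0):
        raise ParameterError("evaluation point coincides with the dipole position")
    vals = (disp @ np.asarray(dipole.moment, dtype=float)) / (
        4.0 * np.pi * sigma * dist**3
    )
    return vals if np.asarray(point).ndim > 1 else float(vals[0])
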