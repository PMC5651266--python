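"""Series evaluation of four-sphere dipole potentials in every shell.

The radial-dipole potential is an axisymmetric Legendre series
Φ ∝ Σ [A_n^s (r/r_s)^n + B_n^s (r_s/r)^{n+1}] n P_n(cosθ); the tangential
solution carries the same coefficients with P_n^1 and a sinφ azimuthal factor
(no extra factor n).  Any dipole is evaluated by superposing the two after the
canonical-frame decomposition.

Conventions: the associated Legendre function is Condon–Shortley free,
P_1^1(cosθ) = sinθ ≥ 0, with a +sinφ prefactor for a tangential moment along
the canonical +y axis — the combination fixed by requiring agreement with the
infinite-homogeneous-medium dipole formula in the large-radius limit.
Evaluation points at an interface radius use the inner shell's expansion
(continuity makes the choice immaterial to tolerance); points with
r ≤ r_z are rejected, since the expansions hold only outside the dipole
radius.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .coefficients import CoefficientTable, SeriesControl, coefficient_table
from .model import (
    Dipole,
    EvaluationPoint,
    HeadModel,
    OutsideHeadError,
    ParameterError,
    ValidityRegionError,
    canonical_frame,
    to_spherical,
)

__all__ = [
    "PotentialSample",
    "shell_of",
    "potential_radial",
    "potential_tangential",
    "potential_dipole",
    "radial_derivative",
]

DipoleKind = Literal["radial", "tangential"]

_R_TOL = 1e-12


@dataclass(frozen=True)
class PotentialSample:
    """One evaluated potential: location, containing shell, value, truncation."""

    point: EvaluationPoint
    shell: int
    value: float
    terms_used: int


def shell_of(model: HeadModel, r: float) -> int:
    """Index (1–4) of the shell containing radius ``r``.

    Interface radii are assigned to the inner shell; by potential continuity
    either assignment gives the same value to series tolerance.
    """
    if r > model.r4 * (1.0 + _R_TOL):
        raise OutsideHeadError(
            f"r={r:.6g} m lies outside the scalp surface r4={model.r4:.6g} m"
        )
    for s in (1, 2, 3):
        if r <= model.radius(s):
            return s
    return 4


def _evaluate(
    model: HeadModel,
    r_z: float,
    p: float,
    r: np.ndarray,
    theta: np.ndarray,
    phi: np.ndarray,
    kind: DipoleKind,
    ctrl: SeriesControl,
    *,
    derivative: bool = False,
    method: str = "closed_form",
    force_terms: int | None = None,
    shell_override: int | None = None,
) -> tuple[np.ndarray, int]:
    """Sum the series for a batch of points lying in a single shell.

    Returns (values, terms_used).  ``force_terms`` disables adaptive
    truncation and sums exactly that many harmonics (used when two pipelines
    must be compared at identical truncation).
    """
    if kind not in ("radial", "tangential"):
        raise ParameterError(f"kind must be 'radial' or 'tangential', got {kind!r}")
    r = np.atleast_1d(np.asarray(r, dtype=float))
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    phi = np.atleast_1d(np.asarray(phi, dtype=float))
    r, theta, phi = np.broadcast_arrays(r, theta, phi)
    if np.any(r <= r_z):
        raise ValidityRegionError(
            f"evaluation requires r > r_z={r_z:.6g} m (interior expansion not "
            "implemented)"
        )
    shells = (
        np.full(r.shape, shell_override, dtype=int)
        if shell_override is not None
        else np.array([shell_of(model, ri) for ri in r.ravel()]).reshape(r.shape)
    )
    r = np.minimum(r, model.r4)  # clamp round-off overshoot at the surface

    n_cap = force_terms if force_terms is not None else ctrl.n_max
    table = coefficient_table(model, r_z, n_cap, method=method)

    sigma1 = model.sigma(1)
    pref = p / (4.0 * np.pi * sigma1 * r_z**2)

    values = np.zeros(r.shape)
    terms_used = 0
    for s in np.unique(shells):
        mask = shells == s
        vals, used = _sum_shell(
            table,
            int(s),
            r[mask],
            theta[mask],
            kind,
            ctrl,
            derivative=derivative,
            force_terms=force_terms,
        )
        values[mask] = vals
        terms_used = max(terms_used, used)
    if kind == "tangential":
        values = values * np.sin(phi)
    return pref * values, terms_used


def _sum_shell(
    table: CoefficientTable,
    s: int,
    r: np.ndarray,
    theta: np.ndarray,
    kind: DipoleKind,
    ctrl: SeriesControl,
    *,
    derivative: bool,
    force_terms: int | None,
) -> tuple[np.ndarray, int]:
    model = table.model
    r_z = table.r_z
    r_s = model.radius(s)
    ratio_a = r / r_s
    if s == 1:
        ratio_b = r_z / r
        A = table.A[1]
        D = np.ones_like(table.A[1])  # shell-1 exterior basis is (r_z/r)^{n+1} itself
    else:
        ratio_b = model.radius(s - 1) / r
        A = table.A[s]
        D = table.B_inner[s]

    x = np.cos(theta)
    pa = ratio_a.copy()  # (r/r_s)^n at n=1
    pb = ratio_b * ratio_b  # inner-scaled (·/r)^{n+1} at n=1
    if kind == "radial":
        ang_prev = np.ones_like(x)  # P_0
        ang = x.copy()  # P_1
    else:
        ang_prev = np.zeros_like(x)  # P_0^1
        ang = np.sin(theta)  # P_1^1, Condon–Shortley free

    n_cap = force_terms if force_terms is not None else ctrl.n_max
    acc = np.zeros_like(x)
    small_run = 0
    floor = np.finfo(float).tiny
    used = n_cap
    for n in range(1, n_cap + 1):
        i = n - 1
        if derivative:
            g = (n * A[i] * pa - (n + 1) * D[i] * pb) / r
        else:
            g = A[i] * pa + D[i] * pb
        term = g * (n * ang) if kind == "radial" else g * ang
        acc += term
        if force_terms is None:
            tmax = float(np.max(np.abs(term)))
            smax = max(float(np.max(np.abs(acc))), floor)
            if tmax <= ctrl.rel_tol * smax:
                small_run += 1
                if small_run >= ctrl.consecutive_small:
                    used = n
                    break
            else:
                small_run = 0
        # advance powers and Legendre recurrences to n+1
        pa *= ratio_a
        pb *= ratio_b
        if kind == "radial":
            ang_prev, ang = ang, ((2 * n + 1) * x * ang - n * ang_prev) / (n + 1)
        else:
            ang_prev, ang = ang, ((2 * n + 1) * x * ang - (n + 1) * ang_prev) / n
    return acc, used


def _as_point(point: EvaluationPoint | Sequence[float]) -> EvaluationPoint:
    if isinstance(point, EvaluationPoint):
        return point
    r, theta, *rest = point
    return EvaluationPoint(r=float(r), theta=float(theta), phi=float(rest[0]) if rest else 0.0)


def potential_radial(
    model: HeadModel,
    r_z: float,
    p: float,
    point: EvaluationPoint | Sequence[float],
    ctrl: SeriesControl | None = None,
    *,
    method: str = "closed_form",
) -> PotentialSample:
    """Potential of a radial dipole of moment ``p`` at canonical (r, θ, φ).

    The value is independent of φ.  Valid for r_z < r ≤ r4.
    """
    ctrl = ctrl or SeriesControl()
    pt = _as_point(point)
    vals, used = _evaluate(
        model, r_z, p, np.array([pt.r]), np.array([pt.theta]), np.array([pt.phi]),
        "radial", ctrl, method=method,
    )
    return PotentialSample(
        point=pt, shell=shell_of(model, pt.r), value=float(vals[0]), terms_used=used
    )


def potential_tangential(
    model: HeadModel,
    r_z: float,
    p: float,
    point: EvaluationPoint | Sequence[float],
    ctrl: SeriesControl | None = None,
    *,
    method: str = "closed_form",
) -> PotentialSample:
    """Potential of a tangential dipole (moment ``p`` along canonical +y).

    Same coefficients as the radial solution; odd in φ, zero on the polar
    axis (P_n^1(±1) = 0).
    """
    ctrl = ctrl or SeriesControl()
    pt = _as_point(point)
    vals, used = _evaluate(
        model, r_z, p, np.array([pt.r]), np.array([pt.theta]), np.array([pt.phi]),
        "tangential", ctrl, method=method,
    )
    return PotentialSample(
        point=pt, shell=shell_of(model, pt.r), value=float(vals[0]), terms_used=used
    )


def potential_dipole(
    model: HeadModel,
    dipole: Dipole,
    points: Sequence[Sequence[float]] | np.ndarray,
    ctrl: SeriesControl | None = None,
    *,
    method: str = "closed_form",
) -> np.ndarray:
    """Potentials (V) of an arbitrarily oriented dipole at world-frame points.

    Decomposes the dipole into radial and tangential components in the
    canonical frame and superposes the two series; one coefficient table is
    shared across all points.
    """
    ctrl = ctrl or SeriesControl()
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[1] != 3:
        raise ParameterError(f"points must be (N, 3), got {pts.shape}")
    frame = canonical_frame(dipole)
    r_z = frame.r_z
    if not r_z < model.r1:
        raise ParameterError(
            f"dipole radius r_z={r_z:.6g} m must lie inside the brain shell "
            f"r1={model.r1:.6g} m"
        )
    sph = [to_spherical(pt, frame, model) for pt in pts]
    r = np.array([q.r for q in sph])
    theta = np.array([q.theta for q in sph])
    phi = np.array([q.phi for q in sph])
    if dipole.p == 0.0:
        return np.zeros(len(pts))
    out = np.zeros(len(pts))
    if frame.p_rad != 0.0:
        vals, _ = _evaluate(
            model, r_z, frame.p_rad, r, theta, phi, "radial", ctrl, method=method
        )
        out += vals
    if frame.p_tan != 0.0:
        vals, _ = _evaluate(
            model, r_z, frame.p_tan, r, theta, phi, "tangential", ctrl, method=method
        )
        out += vals
    return out


def radial_derivative(
    model: HeadModel,
    r_z: float,
    p: float,
    point: EvaluationPoint | Sequence[float],
    kind: DipoleKind = "radial",
    ctrl: SeriesControl | None = None,
    *,
    method: str = "closed_form",
) -> float:
    """∂Φ/∂r (V/m) by term-by-term analytic differentiation of the basis.

    At r = r4 every term cancels identically (the Neumann condition is built
    into B_n^4 = n/(n+1)·A_n^4), so the result there is round-off noise.
    """
    ctrl = ctrl or SeriesControl()
    pt = _as_point(point)
    vals, _ = _evaluate(
        model, r_z, p, np.array([pt.r]), np.array([pt.theta]), np.array([pt.phi]),
        kind, ctrl, derivative=True, method=method,
    )
    return float(vals[0])
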