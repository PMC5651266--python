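"""Per-harmonic expansion coefficients of the four-sphere series solution.

For each harmonic n the potential in shell s is a combination of the interior
basis (r/r_s)^n and the exterior basis (r_s/r)^{n+1}, with coefficients A_n^s
and B_n^s fixed by potential/current continuity at the three inner interfaces
and a zero-current (Neumann) condition at the scalp surface.  Two independent
routes are provided:

* :func:`compute_coefficients` — the closed-form chain through the auxiliaries
  V_n, Y_n, Z_n, evaluated in a numerically stable form (each rational
  expression is divided through by its dominant exponential so no intermediate
  grows like r_43^{n+1}).
* :func:`solve_coefficients_linear` — an oracle that assembles the 7×7 linear
  system expressing the boundary conditions directly and solves it in extended
  precision; it never touches the closed-form algebra.

Both report coefficients in the same shell-normalized basis, so they are
directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .model import HeadModel, ParameterError, SeriesRangeError

__all__ = [
    "SeriesControl",
    "CoefficientSet",
    "CoefficientTable",
    "compute_coefficients",
    "solve_coefficients_linear",
    "coefficient_table",
    "coefficient_residuals",
    "clear_cache",
]


@dataclass(frozen=True)
class SeriesControl:
    """Truncation policy for the infinite Legendre sums.

    ``n_max`` caps the harmonics; adaptive truncation stops once
    ``consecutive_small`` successive terms fall below ``rel_tol`` times the
    magnitude of the running sum.  The defaults resolve boundary-surface
    checks (r_z/r_1 ≈ 0.987) to ~1e-12 tails, which needs O(2000) terms.
    """

    n_max: int = 5000
    rel_tol: float = 1e-12
    consecutive_small: int = 10

    def __post_init__(self) -> None:
        if self.n_max < 1:
            raise ParameterError(f"n_max must be >= 1, got {self.n_max}")
        if not self.rel_tol > 0:
            raise ParameterError(f"rel_tol must be > 0, got {self.rel_tol}")
        if self.consecutive_small < 1:
            raise ParameterError(
                f"consecutive_small must be >= 1, got {self.consecutive_small}"
            )


@dataclass(frozen=True)
class CoefficientSet:
    """Expansion coefficients and auxiliaries for one harmonic n.

    Linkage identities hold by construction: B2 = Y·A2, B3 = V·A3,
    B4 = n/(n+1)·A4.
    """

    n: int
    A1: float
    A2: float
    B2: float
    A3: float
    B3: float
    A4: float
    B4: float
    V: float
    Y: float
    Z: float


class CoefficientTable:
    """Vectorized coefficients for harmonics n = 1..n_max at fixed (model, r_z).

    ``A[s]``/``B[s]`` are the shell-s coefficients; ``B_inner[s]`` stores
    B_s·(r_s/r_{s-1})^{n+1} (the exterior-basis contribution evaluated at the
    shell's inner boundary), which stays representable even when B_s itself
    underflows, and is what field evaluation uses.  ``src`` is the source term
    (r_z/r_1)^{n+1} of the brain-shell expansion.
    """

    def __init__(
        self,
        model: HeadModel,
        r_z: float,
        n: np.ndarray,
        A: dict[int, np.ndarray],
        B: dict[int, np.ndarray],
        B_inner: dict[int, np.ndarray],
        src: np.ndarray,
        V: np.ndarray,
        Y: np.ndarray,
        Z: np.ndarray,
        method: str,
    ) -> None:
        self.model = model
        self.r_z = r_z
        self.n = n
        self.A = A
        self.B = B
        self.B_inner = B_inner
        self.src = src
        self.V = V
        self.Y = Y
        self.Z = Z
        self.method = method

    @property
    def n_max(self) -> int:
        return int(self.n[-1])

    def coefficient_set(self, n: int) -> CoefficientSet:
        """Scalar view of harmonic ``n`` (1-based)."""
        i = n - 1
        if not (1 <= n <= self.n_max):
            raise ParameterError(f"n={n} outside table range 1..{self.n_max}")
        return CoefficientSet(
            n=n,
            A1=float(self.A[1][i]),
            A2=float(self.A[2][i]),
            B2=float(self.B[2][i]),
            A3=float(self.A[3][i]),
            B3=float(self.B[3][i]),
            A4=float(self.A[4][i]),
            B4=float(self.B[4][i]),
            V=float(self.V[i]),
            Y=float(self.Y[i]),
            Z=float(self.Z[i]),
        )


def _validate_rz(model: HeadModel, r_z: float) -> float:
    r_z = float(r_z)
    if not (0.0 < r_z < model.r1):
        raise ParameterError(
            f"dipole radius r_z={r_z:.6g} m must lie strictly inside the brain "
            f"shell (0, {model.r1:.6g}) m"
        )
    return r_z


def _closed_form_table(model: HeadModel, r_z: float, n_max: int) -> CoefficientTable:
    """Closed-form coefficient chain, vectorized over n, in scaled form.

    The auxiliaries V, Y, Z are carried as (numerator, denominator) pairs with
    every exponential ratio reduced to powers of quantities < 1, so nothing
    overflows before the coefficients themselves leave double range.
    """
    r1, r2, r3, r4 = model.radii
    s1, s2, s3, s4 = model.conductivities
    r12, r23, r34 = r1 / r2, r2 / r3, r3 / r4
    s12, s23, s34 = s1 / s2, s2 / s3, s3 / s4

    n = np.arange(1, n_max + 1, dtype=float)
    np1_n = (n + 1.0) / n
    n_np1 = n / (n + 1.0)

    with np.errstate(over="ignore", under="ignore", invalid="ignore", divide="ignore"):
        x34 = r34 ** (2.0 * n + 1.0)
        x23 = r23 ** (2.0 * n + 1.0)
        x12 = r12 ** (2.0 * n + 1.0)

        # T = (r34^n - r43^{n+1}) / ((n+1)/n r34^n + r43^{n+1}), reduced.
        tnum = x34 - 1.0
        tden = np1_n * x34 + 1.0
        # V = (n/(n+1) s34 - T) / (s34 + T) as a pair.
        vnum = n_np1 * s34 * tden - tnum
        vden = s34 * tden + tnum
        # r-const of Y, reduced by r32^{n+1}, as a pair.
        rcnum = n_np1 * x23 * vden - vnum
        rcden = x23 * vden + vnum
        # Y = (n/(n+1) s23 - rc) / (s23 + rc) as a pair.
        ynum = n_np1 * s23 * rcden - rcnum
        yden = s23 * rcden + rcnum
        # Z = (r12^n - (n+1)/n Y r21^{n+1}) / (r12^n + Y r21^{n+1}), reduced.
        znum = x12 * yden - np1_n * ynum
        zden = x12 * yden + ynum

        src = (r_z / r1) ** (n + 1.0)
        # Reduced coefficients (unit source); actual ones carry the factor src.
        a1h = (np1_n * s12 * zden + znum) / (s12 * zden - znum)
        r12n1 = r12 ** (n + 1.0)
        a2h = (a1h + 1.0) * yden * r12n1 / zden
        b2h_inner = (a1h + 1.0) * ynum / zden  # = B2 * r21^{n+1} / src
        b2h = b2h_inner * r12n1
        r23n1 = r23 ** (n + 1.0)
        a3h = (a2h + b2h) * vden * r23n1 / rcden
        b3h_inner = (a2h + b2h) * vnum / rcden
        b3h = b3h_inner * r23n1
        r34n1 = r34 ** (n + 1.0)
        a4h = np1_n * (a3h + b3h) * r34n1 / tden
        b4h_inner = (a3h + b3h) / tden
        b4h = n_np1 * a4h

        V = vnum / vden
        Y = ynum / yden
        Z = znum / zden

    A = {1: a1h * src, 2: a2h * src, 3: a3h * src, 4: a4h * src}
    B = {2: b2h * src, 3: b3h * src, 4: b4h * src}
    B_inner = {2: b2h_inner * src, 3: b3h_inner * src, 4: b4h_inner * src}
    for s in (1, 2, 3, 4):
        if not np.all(np.isfinite(A[s])):
            bad = int(n[~np.isfinite(A[s])][0])
            raise SeriesRangeError(
                f"coefficient A{s} overflowed at harmonic n={bad}"
            )
    for s in (2, 3, 4):
        if not (np.all(np.isfinite(B[s])) and np.all(np.isfinite(B_inner[s]))):
            bad_mask = ~(np.isfinite(B[s]) & np.isfinite(B_inner[s]))
            bad = int(n[bad_mask][0])
            raise SeriesRangeError(
                f"coefficient B{s} overflowed at harmonic n={bad}"
            )
    return CoefficientTable(
        model, r_z, n, A, B, B_inner, src, V, Y, Z, method="closed_form"
    )


def _solve_7x7_longdouble(M: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    """Gaussian elimination with partial pivoting in extended precision.

    numpy's LAPACK bindings are double-only; for a 7×7 system a direct
    elimination in longdouble is cheap and keeps the oracle's accuracy well
    below the comparison tolerances.
    """
    a = np.hstack([M, rhs[:, None]]).astype(np.longdouble)
    m = a.shape[0]
    for k in range(m):
        piv = k + int(np.argmax(np.abs(a[k:, k])))
        if a[piv, k] == 0:
            raise SeriesRangeError("singular boundary-condition system")
        if piv != k:
            a[[k, piv]] = a[[piv, k]]
        a[k + 1 :] -= (a[k + 1 :, k] / a[k, k])[:, None] * a[k]
    x = np.zeros(m, dtype=np.longdouble)
    for k in range(m - 1, -1, -1):
        x[k] = (a[k, m] - a[k, k + 1 : m] @ x[k + 1 :]) / a[k, k]
    return x


def _linear_reduced(model: HeadModel, n: int) -> np.ndarray:
    """Solve the per-harmonic boundary system for a unit source term.

    Unknowns are u = (Â1, Â2, Ĉ2, Â3, Ĉ3, Â4, Ĉ4) where Ĉ_s is the
    exterior-basis contribution of shell s evaluated at its inner boundary
    (column scaling that keeps every matrix entry O(n·σ)).  Rows: potential
    and current continuity at r1, r2, r3, then the scalp Neumann condition.
    """
    r1, r2, r3, r4 = model.radii
    s1, s2, s3, s4 = model.conductivities
    nf = float(n)
    r12n = (r1 / r2) ** nf
    r12n1 = (r1 / r2) ** (nf + 1.0)
    r23n = (r2 / r3) ** nf
    r23n1 = (r2 / r3) ** (nf + 1.0)
    r34n = (r3 / r4) ** nf
    r34n1 = (r3 / r4) ** (nf + 1.0)
    k = nf + 1.0
    M = np.array(
        [
            [1.0, -r12n, -1.0, 0.0, 0.0, 0.0, 0.0],
            [s1 * nf, -s2 * nf * r12n, s2 * k, 0.0, 0.0, 0.0, 0.0],
            [0.0, 1.0, r12n1, -r23n, -1.0, 0.0, 0.0],
            [0.0, s2 * nf, -s2 * k * r12n1, -s3 * nf * r23n, s3 * k, 0.0, 0.0],
            [0.0, 0.0, 0.0, 1.0, r23n1, -r34n, -1.0],
            [0.0, 0.0, 0.0, s3 * nf, -s3 * k * r23n1, -s4 * nf * r34n, s4 * k],
            [0.0, 0.0, 0.0, 0.0, 0.0, nf, -k * r34n1],
        ]
    )
    rhs = np.array([-1.0, s1 * k, 0.0, 0.0, 0.0, 0.0, 0.0])
    return _solve_7x7_longdouble(M, rhs)


def solve_coefficients_linear(model: HeadModel, r_z: float, n: int) -> CoefficientSet:
    """Independent oracle: coefficients from the boundary conditions directly.

    Assembles and solves, per harmonic, the 7×7 linear system expressing
    potential continuity at r1..r3, current continuity at r1..r3, and the
    scalp Neumann condition, with the source term (r_z/r)^{n+1} on the
    right-hand side.  The auxiliaries are recovered from their boundary-value
    meaning (Y = B2/A2, V = B3/A3, Z from the shell-1 matching condition),
    never from the closed-form chain.
    """
    r_z = _validate_rz(model, r_z)
    if n < 1:
        raise ParameterError(f"harmonic index must be >= 1, got {n}")
    u = _linear_reduced(model, n)
    r1, r2, r3, r4 = model.radii
    s1, s2 = model.conductivities[0], model.conductivities[1]
    nf = float(n)
    src = (r_z / r1) ** (nf + 1.0)
    a1h, a2h, c2h, a3h, c3h, a4h, c4h = (np.float64(v) for v in u)
    b2h = c2h * (r1 / r2) ** (nf + 1.0)
    b3h = c3h * (r2 / r3) ** (nf + 1.0)
    b4h = c4h * (r3 / r4) ** (nf + 1.0)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        Y = b2h / a2h
        V = b3h / a3h
        Z = s1 * (nf * a1h - (nf + 1.0)) / (nf * s2 * (a1h + 1.0))
    return CoefficientSet(
        n=n,
        A1=a1h * src,
        A2=a2h * src,
        B2=b2h * src,
        A3=a3h * src,
        B3=b3h * src,
        A4=a4h * src,
        B4=b4h * src,
        V=float(V),
        Y=float(Y),
        Z=float(Z),
    )


def _linear_table(model: HeadModel, r_z: float, n_max: int) -> CoefficientTable:
    n = np.arange(1, n_max + 1, dtype=float)
    r1, r2, r3, r4 = model.radii
    src = (r_z / r1) ** (n + 1.0)
    cols = {key: np.empty(n_max) for key in ("a1", "a2", "c2", "a3", "c3", "a4", "c4")}
    for i, ni in enumerate(range(1, n_max + 1)):
        u = _linear_reduced(model, ni)
        for j, key in enumerate(("a1", "a2", "c2", "a3", "c3", "a4", "c4")):
            cols[key][i] = float(u[j])
    with np.errstate(under="ignore", over="ignore", invalid="ignore", divide="ignore"):
        b2 = cols["c2"] * (r1 / r2) ** (n + 1.0)
        b3 = cols["c3"] * (r2 / r3) ** (n + 1.0)
        b4 = cols["c4"] * (r3 / r4) ** (n + 1.0)
        A = {s: cols[f"a{s}"] * src for s in (1, 2, 3, 4)}
        B = {2: b2 * src, 3: b3 * src, 4: b4 * src}
        B_inner = {2: cols["c2"] * src, 3: cols["c3"] * src, 4: cols["c4"] * src}
        V = b3 / cols["a3"]
        Y = b2 / cols["a2"]
        Z = (
            model.sigma(1)
            * (n * cols["a1"] - (n + 1.0))
            / (n * model.sigma(2) * (cols["a1"] + 1.0))
        )
    return CoefficientTable(model, r_z, n, A, B, B_inner, src, V, Y, Z, method="linear")


def compute_coefficients(model: HeadModel, r_z: float, n: int) -> CoefficientSet:
    """Closed-form coefficients A_n^s, B_n^s and auxiliaries for harmonic n."""
    r_z = _validate_rz(model, r_z)
    if n < 1:
        raise ParameterError(f"harmonic index must be >= 1, got {n}")
    return coefficient_table(model, r_z, n).coefficient_set(n)


# Coefficients depend on (model, r_z) but not on the evaluation point, so one
# table is shared across all electrodes of a computation.
_TABLE_CACHE: dict[tuple, CoefficientTable] = {}
_CACHE_LIMIT = 64


def coefficient_table(
    model: HeadModel, r_z: float, n_max: int, method: str = "closed_form"
) -> CoefficientTable:
    """Cached coefficient table for harmonics 1..n_max."""
    r_z = _validate_rz(model, r_z)
    if method not in ("closed_form", "linear"):
        raise ParameterError(f"unknown coefficient method {method!r}")
    key = (model, r_z, method)
    tab = _TABLE_CACHE.get(key)
    if tab is None or tab.n_max < n_max:
        if len(_TABLE_CACHE) >= _CACHE_LIMIT:
            _TABLE_CACHE.clear()
        builder = _closed_form_table if method == "closed_form" else _linear_table
        tab = builder(model, r_z, n_max)
        _TABLE_CACHE[key] = tab
    return tab


def clear_cache() -> None:
    """Drop all cached coefficient tables."""
    _TABLE_CACHE.clear()


def coefficient_residuals(
    coeffs: CoefficientSet, model: HeadModel, r_z: float
) -> np.ndarray:
    """Normalized residuals of the seven boundary equations for one harmonic.

    Order: potential continuity at r1, current continuity at r1, the same pair
    at r2 and r3, then the scalp Neumann condition.  Each residual is
    |lhs − rhs| normalized by the larger matched side; all are ≤ 1e-10 for a
    correct coefficient set.
    """
    r_z = _validate_rz(model, r_z)
    r1, r2, r3, r4 = model.radii
    s1, s2, s3, s4 = model.conductivities
    n = float(coeffs.n)
    k = n + 1.0
    src = (r_z / r1) ** k
    c = coeffs

    pairs: Iterable[tuple[float, float]] = (
        (c.A1 + src, c.A2 * (r1 / r2) ** n + c.B2 * (r2 / r1) ** k),
        (
            s1 * (n * c.A1 - k * src),
            s2 * (n * c.A2 * (r1 / r2) ** n - k * c.B2 * (r2 / r1) ** k),
        ),
        (c.A2 + c.B2, c.A3 * (r2 / r3) ** n + c.B3 * (r3 / r2) ** k),
        (
            s2 * (n * c.A2 - k * c.B2),
            s3 * (n * c.A3 * (r2 / r3) ** n - k * c.B3 * (r3 / r2) ** k),
        ),
        (c.A3 + c.B3, c.A4 * (r3 / r4) ** n + c.B4 * (r4 / r3) ** k),
        (
            s3 * (n * c.A3 - k * c.B3),
            s4 * (n * c.A4 * (r3 / r4) ** n - k * c.B4 * (r4 / r3) ** k),
        ),
        (n * c.A4, k * c.B4),
    )
    out = np.empty(7)
    for i, (lhs, rhs) in enumerate(pairs):
        scale = max(abs(lhs), abs(rhs))
        out[i] = 0.0 if scale == 0.0 else abs(lhs - rhs) / scale
    return out
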