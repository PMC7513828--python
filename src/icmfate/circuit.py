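"""Lateral-inhibition gene circuit for epiblast/PrE fate choice.

The model tracks a single dimensionless variable ``x`` per cell — the NANOG
level — whose production is repressed by the average NANOG level in the
cell's signaling neighborhood (the mean field ``<x>``, which includes the
cell itself).  Repression is indirect in the biology (NANOG -> FGF4 -> ERK
-| NANOG in neighbors) but enters here as a single Hill term:

    dx_i/dt = alpha * (1 + x_i^n)^m / [ (1 + x_i^n)^m + (<x>_i / K)^(2m) ] - x_i

For intermediate mean-field values the per-cell potential is double-welled,
so uncommitted (DP) cells are transient and relax to a high-NANOG (epiblast)
or low-NANOG (PrE) state.  A perfectly mixed population that splits into two
clusters ``a`` and ``b`` reduces to the planar system analyzed by
:func:`two_cluster_rhs`, :func:`nullclines` and :func:`find_equilibria`.

Time is measured in units of the NANOG protein lifetime; the agent-based
layer identifies one model time unit with one hour.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import fsolve, brentq

__all__ = [
    "CircuitParams",
    "Equilibrium",
    "production",
    "nanog_rhs",
    "two_cluster_rhs",
    "two_cluster_jacobian",
    "nullclines",
    "find_equilibria",
    "diagonal_fixed_point",
    "integrate_population",
    "StepSizeError",
]


class StepSizeError(RuntimeError):
    """Raised when a fixed-step integration leaves the invariant region."""


@dataclass(frozen=True)
class CircuitParams:
    """Constants of the fate-choice circuit.

    alpha
        Maximal (dimensionless) NANOG production rate; also the upper bound
        of any trajectory started in ``[0, alpha]``.
    n
        Hill exponent of NANOG self-activation.
    m
        Cooperativity of the production/repression balance.
    K
        Mean-field level at which repression half-saturates (for ``x = 0``).

    The defaults were fixed by scanning the ``(alpha, K)`` plane at
    ``n = m = 2`` for the regime with two well-separated stable two-cluster
    states (high:low ratio >= 5) and a single unstable symmetric state.
    """

    alpha: float = 5.0
    n: int = 2
    m: int = 2
    K: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.K <= 0:
            raise ValueError("alpha and K must be positive")
        if self.n < 1 or self.m < 1:
            raise ValueError("Hill exponents n, m must be >= 1")


def _check_nonneg(name: str, value) -> None:
    if np.any(np.asarray(value) < 0):
        raise ValueError(f"{name} must be non-negative")


def production(x, field, p: CircuitParams = CircuitParams()):
    """NANOG production rate at level ``x`` under mean field ``field``.

    Returns ``alpha (1+x^n)^m / [(1+x^n)^m + (field/K)^(2m)]``; always in
    ``(0, alpha]``.  Accepts scalars or arrays (broadcast).
    """
    _check_nonneg("x", x)
    _check_nonneg("field", field)
    x = np.asarray(x, dtype=float)
    field = np.asarray(field, dtype=float)
    act = (1.0 + x**p.n) ** p.m
    rep = (field / p.K) ** (2 * p.m)
    out = p.alpha * act / (act + rep)
    return out if out.ndim else float(out)


def nanog_rhs(x, field, p: CircuitParams = CircuitParams()):
    """Full right-hand side: production minus first-order decay."""
    x = np.asarray(x, dtype=float)
    out = production(x, field, p) - x
    return out if np.ndim(out) else float(out)


def two_cluster_rhs(xa, xb, p: CircuitParams = CircuitParams()):
    """RHS of the two-cluster reduction; both clusters share field (xa+xb)/2.

    Symmetric under swapping the cluster labels: ``f(xa, xb) == f(xb, xa)[::-1]``.
    """
    _check_nonneg("xa", xa)
    _check_nonneg("xb", xb)
    shared = (np.asarray(xa, dtype=float) + np.asarray(xb, dtype=float)) / 2.0
    fa = nanog_rhs(xa, shared, p)
    fb = nanog_rhs(xb, shared, p)
    return fa, fb


def two_cluster_jacobian(xa: float, xb: float, p: CircuitParams = CircuitParams(),
                         eps: float = 1e-6) -> np.ndarray:
    """Jacobian of the two-cluster system by central differences."""
    J = np.empty((2, 2))
    point = np.array([xa, xb], dtype=float)
    for j in range(2):
        hi = point.copy()
        lo = point.copy()
        hi[j] += eps
        lo[j] = max(lo[j] - eps, 0.0)
        h = hi[j] - lo[j]
        fhi = two_cluster_rhs(hi[0], hi[1], p)
        flo = two_cluster_rhs(lo[0], lo[1], p)
        J[0, j] = (fhi[0] - flo[0]) / h
        J[1, j] = (fhi[1] - flo[1]) / h
    return J


@dataclass(frozen=True)
class Equilibrium:
    """A fixed point of the two-cluster system with its linear stability."""

    point: tuple[float, float]
    stability: str  # "stable" | "unstable" | "saddle" | "marginal"
    eigenvalues: tuple[complex, complex]

    @property
    def is_stable(self) -> bool:
        return self.stability == "stable"

    @property
    def on_diagonal(self) -> bool:
        return abs(self.point[0] - self.point[1]) < 1e-6


_MARGINAL_TOL = 1e-8


def _classify(eigenvalues: np.ndarray) -> str:
    re = eigenvalues.real
    if np.any(np.abs(re) < _MARGINAL_TOL):
        return "marginal"
    if np.all(re < 0):
        return "stable"
    if np.all(re > 0):
        return "unstable"
    return "saddle"


def find_equilibria(p: CircuitParams = CircuitParams(), grid: int = 200,
                    tol: float = 1e-9) -> list[Equilibrium]:
    """All fixed points of the two-cluster system in ``[0, alpha]^2``.

    Candidate cells are found by a sign-change scan of both RHS components
    on a ``grid x grid`` lattice and polished with a Newton-type solver;
    duplicates are merged.  At the default parameters this returns exactly
    three equilibria: a mirror pair of stable states off the diagonal and a
    saddle on the diagonal.
    """
    g = np.linspace(0.0, p.alpha, grid)
    XA, XB = np.meshgrid(g, g, indexing="ij")
    FA, FB = two_cluster_rhs(XA, XB, p)

    # cells where each component changes sign across either grid direction
    def sign_change(F):
        c = np.zeros((grid - 1, grid - 1), dtype=bool)
        c |= np.signbit(F[:-1, :-1]) != np.signbit(F[1:, :-1])
        c |= np.signbit(F[:-1, :-1]) != np.signbit(F[:-1, 1:])
        c |= np.signbit(F[:-1, :-1]) != np.signbit(F[1:, 1:])
        return c

    cells = np.argwhere(sign_change(FA) & sign_change(FB))

    def F(v):
        v = np.clip(v, 0.0, None)
        fa, fb = two_cluster_rhs(v[0], v[1], p)
        return [fa, fb]

    roots: list[np.ndarray] = []
    for i, j in cells:
        x0 = [(g[i] + g[i + 1]) / 2, (g[j] + g[j + 1]) / 2]
        sol, _info, ier, _msg = fsolve(F, x0, full_output=True, xtol=1e-12)
        if ier != 1:
            continue  # reported per-root: unconverged candidates are dropped
        sol = np.clip(sol, 0.0, None)
        fa, fb = two_cluster_rhs(sol[0], sol[1], p)
        if abs(fa) > max(tol, 1e-9) or abs(fb) > max(tol, 1e-9):
            continue
        if sol.max() > p.alpha * (1 + 1e-9):
            continue
        if not any(np.allclose(sol, r, atol=1e-6) for r in roots):
            roots.append(sol)

    out = []
    for r in sorted(roots, key=lambda v: (v[0], v[1])):
        ev = np.linalg.eigvals(two_cluster_jacobian(r[0], r[1], p))
        out.append(Equilibrium(point=(float(r[0]), float(r[1])),
                               stability=_classify(ev),
                               eigenvalues=(complex(ev[0]), complex(ev[1]))))
    return out


def diagonal_fixed_point(p: CircuitParams = CircuitParams()) -> float:
    """The symmetric fixed point x* with ``nanog_rhs(x*, x*) = 0``.

    Exists for any parameters: the diagonal map is continuous, positive at 0
    and negative at ``alpha``.
    """
    f = lambda x: nanog_rhs(x, x, p)
    return brentq(f, 0.0, p.alpha, xtol=1e-12)


def nullclines(p: CircuitParams = CircuitParams(), grid: Sequence[float] | int = 400
               ) -> tuple[np.ndarray, np.ndarray]:
    """Nullclines of the two-cluster system as ordered polylines.

    For each grid value of one coordinate the other is solved by bracketing
    and bisection (the RHS is monotone in the partner coordinate through the
    shared field).  Returns ``(na, nb)`` arrays of shape (k, 2); ``nb`` is
    the mirror image of ``na`` across the diagonal.
    """
    if isinstance(grid, int):
        if grid < 2:
            raise ValueError("grid must contain at least 2 points")
        gv = np.linspace(0.0, p.alpha, grid)
    else:
        gv = np.asarray(list(grid), dtype=float)
        if gv.size < 2:
            raise ValueError("grid must contain at least 2 points")

    pts = []
    hi = p.alpha * 1.5  # field large enough to kill production
    for xa in gv:
        f = lambda xb: two_cluster_rhs(xa, xb, p)[0]
        f0, f1 = f(0.0), f(hi)
        if f0 == 0.0:
            pts.append((xa, 0.0))
        elif np.sign(f0) != np.sign(f1):
            xb = brentq(f, 0.0, hi, xtol=1e-12)
            pts.append((xa, xb))
    na = np.array(pts)
    nb = na[:, ::-1].copy()  # swap symmetry of the reduction
    return na, nb


def mean_field(x: np.ndarray, adjacency: np.ndarray) -> np.ndarray:
    """Neighborhood average of ``x`` on a graph with self-loops.

    ``adjacency`` is a dense boolean/0-1 matrix; row i selects the
    neighborhood of cell i (which must include i itself).
    """
    A = np.asarray(adjacency, dtype=float)
    deg = A.sum(axis=1)
    if np.any(deg == 0):
        raise ValueError("every cell needs at least its self-loop")
    return (A @ np.asarray(x, dtype=float)) / deg


def integrate_population(x0: Iterable[float], adjacency: np.ndarray,
                         p: CircuitParams = CircuitParams(), dt: float = 0.01,
                         t_end: float = 50.0, record_every: int = 1
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Explicit-Euler integration of the population circuit on a fixed graph.

    Returns ``(times, X)`` with ``X[k]`` the state at ``times[k]``.  Raises
    :class:`StepSizeError` if any level leaves ``[0, 1.05 * alpha]``, which
    at this model's relaxation rate only happens for too-large ``dt``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    x = np.array(list(x0), dtype=float)
    _check_nonneg("x0", x)
    A = np.asarray(adjacency)
    if A.shape != (x.size, x.size):
        raise ValueError("adjacency shape does not match state size")
    if not np.all(np.diagonal(A)):
        raise ValueError("adjacency must include self-loops")
    n_steps = int(round(t_end / dt))
    times = [0.0]
    traj = [x.copy()]
    for k in range(1, n_steps + 1):
        x = x + dt * nanog_rhs(x, mean_field(x, A), p)
        if np.any(x < 0.0) or np.any(x > p.alpha * 1.05):
            raise StepSizeError(f"state left [0, 1.05*alpha] at step {k}; reduce dt")
        if k % record_every == 0 or k == n_steps:
            times.append(k * dt)
            traj.append(x.copy())
    return np.array(times), np.array(traj)
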