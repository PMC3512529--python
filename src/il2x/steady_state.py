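"""Fixed points, stability and the commitment threshold of a single cell.

At steady state the three equations for one cell reduce to a scalar
problem in the bound-receptor count B:

    U(B) = (g(m, B) - a_B*B) / a_U                (receptor balance)
    I(B) = (s_m + ext - a_B*B) / d_I              (IL-2 balance)
    F(B) = k*I(B)*U(B) - B*(k_off + a_B) = 0      (binding balance)

All non-negative roots are located by a sign-change scan on a log-spaced
grid followed by bracketed bisection, then classified by the eigenvalues
of the full 3-D Jacobian.  The commitment threshold m_c is found by
bisection on the long-time integration outcome starting from the naive
initial condition U = g_c/a_U, B = I = 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .model_core import CellParams, MediumParams, receptor_synthesis_rate, secretion_rate
from .simulate import ActivationSchedule, SolverSettings, steady_state_endpoint

__all__ = [
    "FixedPoint",
    "BifurcationScan",
    "single_cell_fixed_points",
    "find_commitment_threshold",
    "bifurcation_scan",
    "CommitmentResult",
]

log = logging.getLogger(__name__)

# eigenvalue real parts within this band of zero are flagged marginal
MARGINAL_EIG_TOL = 1e-10


@dataclass(frozen=True)
class FixedPoint:
    U: float
    B: float
    I: float
    stable: bool
    branch: str  # "low" | "high" | "intermediate"
    marginal: bool = False
    eigenvalues: tuple = ()


@dataclass
class CommitmentResult:
    """Outcome of the threshold search.

    ``m_c`` is None when commitment never occurs on [0, 1] (flag
    ``no_threshold``) or always occurs (flag ``always_committed``).
    """

    m_c: float | None
    no_threshold: bool = False
    always_committed: bool = False


@dataclass
class BifurcationScan:
    m_grid: np.ndarray
    fixed_points: list  # list[list[FixedPoint]] parallel to m_grid
    m_c: float | None
    bistable_range: tuple | None  # (m_low, m_high) or None

    def n_stable(self) -> np.ndarray:
        return np.array(
            [sum(1 for fp in fps if fp.stable) for fps in self.fixed_points]
        )


def _scalar_equation(cell: CellParams, medium: MediumParams):
    k = medium.k_on_eff
    s_m = secretion_rate(cell) + medium.external_source
    a_U, a_B = cell.a_U, cell.a_B
    k_off, d_I = medium.k_off, medium.d_I

    def U_of(B):
        return (receptor_synthesis_rate(cell, B) - a_B * B) / a_U

    def I_of(B):
        return (s_m - a_B * B) / d_I if d_I > 0 else np.inf

    def F(B):
        return k * I_of(B) * U_of(B) - B * (k_off + a_B)

    return F, U_of, I_of, s_m


def _jacobian(cell: CellParams, medium: MediumParams, U, B, I) -> np.ndarray:
    k = medium.k_on_eff
    k_off, d_I = medium.k_off, medium.d_I
    a_U, a_B = cell.a_U, cell.a_B
    eps = max(1e-6, 1e-6 * B)
    gp = (
        receptor_synthesis_rate(cell, B + eps) - receptor_synthesis_rate(cell, max(B - eps, 0.0))
    ) / (eps + min(eps, B))
    return np.array(
        [
            [-a_U - k * I, gp + k_off, -k * U],
            [k * I, -(k_off + a_B), k * U],
            [-k * I, k_off, -d_I - k * U],
        ]
    )


def single_cell_fixed_points(
    cell: CellParams,
    medium: MediumParams,
    n_scan: int = 10_000,
    bracket_safety: float = 10.0,
) -> list:
    """All non-negative fixed points of the one-cell system, classified.

    Roots yielding negative U or I are discarded (logged at DEBUG).
    """
    F, U_of, I_of, s_m = _scalar_equation(cell, medium)
    g_max = cell.g_c + max(cell.feedback.g_f, cell.feedback.g_f_const or 0.0)
    B_max = bracket_safety * g_max / min(cell.a_U, cell.a_B) if cell.a_B > 0 else 1e9
    # supply cap: beyond s_m/a_B the IL-2 balance forces I < 0
    if cell.a_B > 0 and np.isfinite(s_m):
        B_max = min(B_max, s_m / cell.a_B if s_m > 0 else B_max)

    roots: list[float] = []
    if s_m == 0.0:
        roots.append(0.0)  # no IL-2 source: the resting state is exact
    if B_max > 0 and s_m > 0:
        grid = np.concatenate([[0.0], np.logspace(-6, np.log10(B_max), n_scan)])
        vals = np.array([F(b) for b in grid])
        sign = np.sign(vals)
        for i in np.flatnonzero(sign[:-1] * sign[1:] < 0):
            r = brentq(F, grid[i], grid[i + 1], xtol=1e-10, rtol=1e-12)
            roots.append(r)
        for i in np.flatnonzero(vals == 0.0):
            roots.append(float(grid[i]))

    out = []
    seen: list[float] = []
    for B in sorted(roots):
        if any(abs(B - b) <= 1e-6 * max(1.0, b) for b in seen):
            continue
        seen.append(B)
        U, I = float(U_of(B)), float(I_of(B)) if s_m > 0 else 0.0
        if s_m == 0.0 and B == 0.0:
            I = medium.external_source / medium.d_I if medium.d_I > 0 else 0.0
        if U < -1e-9 or I < -1e-9:
            log.debug("discarding root B=%.4g with U=%.4g I=%.4g", B, U, I)
            continue
        J = _jacobian(cell, medium, max(U, 0.0), B, max(I, 0.0))
        eig = np.linalg.eigvals(J)
        re = eig.real
        marginal = bool(np.any(np.abs(re) < MARGINAL_EIG_TOL))
        stable = bool(np.all(re < -MARGINAL_EIG_TOL))
        if marginal:
            log.warning("marginal fixed point at B=%.4g (eigenvalues near zero)", B)
        out.append(
            FixedPoint(
                U=max(U, 0.0),
                B=float(B),
                I=max(I, 0.0),
                stable=stable,
                branch="",
                marginal=marginal,
                eigenvalues=tuple(eig),
            )
        )
    if not out:
        raise RuntimeError(
            "no non-negative fixed point found; this should be impossible for "
            "valid parameters (the resting branch exists at m=0)"
        )
    return _label_branches(out)


def _label_branches(fps: list) -> list:
    stable = [fp for fp in fps if fp.stable]
    out = []
    for fp in fps:
        if not fp.stable:
            branch = "intermediate"
        elif len(stable) == 1:
            branch = "low" if fp.B <= min(s.B for s in stable) else "high"
        else:
            branch = "low" if fp.B == min(s.B for s in stable) else "high"
        out.append(
            FixedPoint(
                U=fp.U,
                B=fp.B,
                I=fp.I,
                stable=fp.stable,
                branch=branch,
                marginal=fp.marginal,
                eigenvalues=fp.eigenvalues,
            )
        )
    return out


def _committed_from_rest(
    cell: CellParams,
    medium: MediumParams,
    threshold: float,
    solver: SolverSettings | None,
) -> bool:
    end = steady_state_endpoint(
        [cell],
        medium,
        ActivationSchedule.simultaneous(1, 5000.0),
        solver=solver,
    )
    return bool(end.B[0] >= threshold)


def find_commitment_threshold(
    cell: CellParams,
    medium: MediumParams,
    threshold: float | None = None,
    tol: float = 1e-3,
    pre_scan: int = 6,
    solver: SolverSettings | None = None,
) -> CommitmentResult:
    """Bisect the TCR strength m_c separating committed from uncommitted
    long-time outcomes, starting each run from U = g_c/a_U, B = I = 0.

    A cell counts as committed when its steady-state B reaches
    ``threshold`` (default: the feedback half-saturation K_f).  Returns a
    no-threshold flag when commitment never (or always) occurs on [0, 1].
    A non-monotone outcome over the coarse pre-scan raises, with the scan
    attached to the exception.
    """
    if threshold is None:
        threshold = cell.feedback.K_f

    def committed(m: float) -> bool:
        return _committed_from_rest(cell.with_m(m), medium, threshold, solver)

    ms = np.linspace(0.0, 1.0, pre_scan)
    outcomes = [committed(m) for m in ms]
    if not any(outcomes):
        return CommitmentResult(m_c=None, no_threshold=True)
    if all(outcomes):
        return CommitmentResult(m_c=None, always_committed=True)
    flips = [i for i in range(len(outcomes) - 1) if outcomes[i] != outcomes[i + 1]]
    if len(flips) != 1 or outcomes[0]:
        raise RuntimeError(
            f"non-monotone commitment over the scan grid: m={ms.tolist()}, "
            f"committed={outcomes}"
        )
    lo, hi = ms[flips[0]], ms[flips[0] + 1]
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if committed(mid):
            hi = mid
        else:
            lo = mid
    return CommitmentResult(m_c=0.5 * (lo + hi))


def bifurcation_scan(
    cell: CellParams,
    medium: MediumParams,
    m_grid: Sequence[float] | None = None,
    threshold: float | None = None,
    find_m_c: bool = True,
) -> BifurcationScan:
    """Fixed-point structure over a grid of TCR strengths."""
    if m_grid is None:
        m_grid = np.linspace(0.0, 1.0, 201)
    m_grid = np.asarray(m_grid, dtype=float)
    fps = [single_cell_fixed_points(cell.with_m(m), medium) for m in m_grid]
    n_stable = np.array([sum(fp.stable for fp in f) for f in fps])
    bist = np.flatnonzero(n_stable >= 2)
    bistable_range = (
        (float(m_grid[bist[0]]), float(m_grid[bist[-1]])) if bist.size else None
    )
    m_c = None
    if find_m_c:
        res = find_commitment_threshold(cell, medium, threshold=threshold)
        m_c = res.m_c
    return BifurcationScan(
        m_grid=m_grid, fixed_points=fps, m_c=m_c, bistable_range=bistable_range
    )
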