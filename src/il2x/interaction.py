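"""Pairwise interaction outcomes: interaction index, phase maps, time windows.

The normalized interaction index of cell i in a pair activated with TCR
strengths (m1, m2) is

    C_i = (B_i^together - B_i^alone) / max(B^alone)

where ``max(B^alone)`` is the single-cell endpoint at m = 1 under the same
parameter set, computed once per map.  C > 0 marks cooperation (the cell
gains bound receptors from its neighbour's IL-2), C < 0 competition, and
|C| below a small band coexistence.  A cell that commits alone but not
together is additionally labelled "excluded".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model_core import CellParams, MediumParams
from .simulate import ActivationSchedule, SolverSettings, steady_state_endpoint

__all__ = [
    "InteractionOutcome",
    "PhaseMap",
    "CriticalWindow",
    "interaction_index",
    "phase_map",
    "critical_window",
    "treg_cell",
    "COEXISTENCE_BAND",
]

log = logging.getLogger(__name__)

# |C| below this fraction of the maximal response counts as coexistence
COEXISTENCE_BAND = 0.05


@dataclass
class InteractionOutcome:
    m1: float
    m2: float
    delay: float
    B_alone: np.ndarray       # per-cell endpoint B when activated alone
    B_together: np.ndarray    # per-cell endpoint B when co-activated
    C: np.ndarray             # per-cell normalized interaction index
    labels: tuple             # per-cell {cooperation, competition, coexistence, excluded}
    committed_alone: np.ndarray
    committed_together: np.ndarray


@dataclass
class PhaseMap:
    m1_grid: np.ndarray
    m2_grid: np.ndarray
    C1: np.ndarray            # shape (len(m2_grid), len(m1_grid)); rows = m2
    C2: np.ndarray
    labels1: np.ndarray
    labels2: np.ndarray
    delay: float
    B_ref: float              # normalization max(B_alone)
    n_failed: int = 0


@dataclass
class CriticalWindow:
    """Result of the Δt_c search for a (m1, m2) pair with m2 > m1."""

    delta_t_c: float | None
    no_window: bool = False       # cell2 cannot exclude cell1 even at Δt = 0
    always_excludes: bool = False  # exclusion persists to the search horizon
    bracket: tuple | None = None


class _AloneCache:
    """Single-cell endpoints keyed by m, shared across a map row/column."""

    def __init__(self, cell: CellParams, medium: MediumParams, solver, t_end):
        self.cell = cell
        self.medium = medium
        self.solver = solver
        self.t_end = t_end
        self._cache: dict[float, float] = {}

    def B_alone(self, m: float) -> float:
        key = round(float(m), 12)
        if key not in self._cache:
            end = steady_state_endpoint(
                [self.cell.with_m(m)],
                self.medium,
                ActivationSchedule.simultaneous(1, self.t_end),
                solver=self.solver,
            )
            self._cache[key] = float(end.B[0])
        return self._cache[key]


def _label(C: float, committed_alone: bool, committed_together: bool, eps: float) -> str:
    if C >= eps:
        return "cooperation"
    if C <= -eps:
        # exclusion refines competition: the cell loses its solo commitment
        if committed_alone and not committed_together:
            return "excluded"
        return "competition"
    return "coexistence"


def interaction_index(
    m1: float,
    m2: float,
    cell: CellParams,
    medium: MediumParams,
    delay: float = 0.0,
    eps: float = COEXISTENCE_BAND,
    t_end: float = 5000.0,
    solver: SolverSettings | None = None,
    B_ref: float | None = None,
    _cache: _AloneCache | None = None,
) -> InteractionOutcome:
    """Interaction outcome of a pair (cell1 at t = 0, cell2 after ``delay``).

    Three simulations are run (each cell alone, the pair together) and the
    per-cell index C_i computed with the m = 1 single-cell endpoint as the
    normalization constant.
    """
    for m in (m1, m2):
        if not 0.0 <= m <= 1.0:
            raise ValueError(f"m must lie in [0, 1], got {m}")
    cache = _cache or _AloneCache(cell, medium, solver, t_end)
    if B_ref is None:
        B_ref = cache.B_alone(1.0)
    B_alone = np.array([cache.B_alone(m1), cache.B_alone(m2)])

    pair = [cell.with_m(m1), cell.with_m(m2)]
    schedule = ActivationSchedule.delayed_pair(delay, max(t_end, delay + t_end))
    end = steady_state_endpoint(pair, medium, schedule, solver=solver)
    B_together = end.B.copy()

    C = (B_together - B_alone) / B_ref
    K_f = cell.feedback.K_f
    committed_alone = B_alone >= K_f
    committed_together = B_together >= K_f
    labels = tuple(
        _label(c, ca, ct, eps)
        for c, ca, ct in zip(C, committed_alone, committed_together)
    )
    return InteractionOutcome(
        m1=m1,
        m2=m2,
        delay=delay,
        B_alone=B_alone,
        B_together=B_together,
        C=C,
        labels=labels,
        committed_alone=committed_alone,
        committed_together=committed_together,
    )


def phase_map(
    cell: CellParams,
    medium: MediumParams,
    resolution: int = 41,
    delay: float = 0.0,
    eps: float = COEXISTENCE_BAND,
    t_end: float = 5000.0,
    solver: SolverSettings | None = None,
) -> PhaseMap:
    """Interaction indices over a (m1, m2) grid on [0, 1]^2.

    Single-cell endpoints are computed once per m value and shared across
    the corresponding row and column.  Deterministic.
    """
    if resolution < 2:
        raise ValueError("resolution must be >= 2 per axis")
    grid = np.linspace(0.0, 1.0, resolution)
    cache = _AloneCache(cell, medium, solver, t_end)
    B_ref = cache.B_alone(1.0)
    C1 = np.empty((resolution, resolution))
    C2 = np.empty_like(C1)
    labels1 = np.empty(C1.shape, dtype=object)
    labels2 = np.empty_like(labels1)
    n_failed = 0
    for j, m2 in enumerate(grid):
        for i, m1 in enumerate(grid):
            try:
                out = interaction_index(
                    m1, m2, cell, medium, delay=delay, eps=eps,
                    t_end=t_end, solver=solver, B_ref=B_ref, _cache=cache,
                )
            except RuntimeError as err:  # non-converged endpoint
                log.warning("phase_map cell (%g, %g) failed: %s", m1, m2, err)
                n_failed += 1
                C1[j, i] = C2[j, i] = np.nan
                labels1[j, i] = labels2[j, i] = "failed"
                continue
            C1[j, i], C2[j, i] = out.C
            labels1[j, i], labels2[j, i] = out.labels
    return PhaseMap(
        m1_grid=grid, m2_grid=grid, C1=C1, C2=C2,
        labels1=labels1, labels2=labels2, delay=delay,
        B_ref=B_ref, n_failed=n_failed,
    )


def critical_window(
    m1: float,
    m2: float,
    cell: CellParams,
    medium: MediumParams,
    tol: float = 10.0,
    horizon: float = 5000.0,
    t_end: float = 5000.0,
    solver: SolverSettings | None = None,
    pre_scan: int = 5,
) -> CriticalWindow:
    """Largest activation delay at which the later, stronger cell2 still
    excludes cell1 (activated at t = 0), located by bisection.

    Requires m2 > m1 and cell1 committed when alone.  Returns a no-window
    flag when Δt = 0 already fails to exclude, and an always-excludes flag
    when exclusion persists to the search ``horizon``.
    """
    if not m2 > m1:
        raise ValueError("critical_window requires m2 > m1")
    K_f = cell.feedback.K_f
    alone = steady_state_endpoint(
        [cell.with_m(m1)],
        medium,
        ActivationSchedule.simultaneous(1, t_end),
        solver=solver,
    )
    if alone.B[0] < K_f:
        raise ValueError(
            f"cell1 (m={m1}) does not commit alone (B={alone.B[0]:.1f} < K_f); "
            "the exclusion window is undefined"
        )

    def excluded(delay: float) -> bool:
        end = steady_state_endpoint(
            [cell.with_m(m1), cell.with_m(m2)],
            medium,
            ActivationSchedule.delayed_pair(delay, delay + t_end),
            solver=solver,
        )
        return bool(end.B[0] < K_f)

    if not excluded(0.0):
        return CriticalWindow(delta_t_c=None, no_window=True)
    if excluded(horizon):
        return CriticalWindow(delta_t_c=None, always_excludes=True)

    # coarse scan to bracket the flip and detect non-monotone outcomes
    scan_ts = np.linspace(0.0, horizon, pre_scan + 1)
    outcomes = [True] + [excluded(t) for t in scan_ts[1:-1]] + [False]
    flips = [i for i in range(len(outcomes) - 1) if outcomes[i] != outcomes[i + 1]]
    if len(flips) != 1:
        raise RuntimeError(
            f"non-monotone exclusion outcome over the delay scan: "
            f"delays={scan_ts.tolist()}, excluded={outcomes}"
        )
    lo, hi = scan_ts[flips[0]], scan_ts[flips[0] + 1]
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if excluded(mid):
            lo = mid
        else:
            hi = mid
    return CriticalWindow(delta_t_c=0.5 * (lo + hi), bracket=(lo, hi))


def treg_cell(cell: CellParams, g_c_factor: float = 20.0) -> CellParams:
    """Regulatory-T-cell preset: no IL-2 secretion, elevated constitutive
    receptor synthesis (default 20x).  Calibration-sensitive; used for
    suppression scenarios, not an acceptance surface.
    """
    from dataclasses import replace

    return replace(
        cell,
        g_c=cell.g_c * g_c_factor,
        secretion=replace(cell.secretion, s=0.0),
    )
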