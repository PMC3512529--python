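"""Event-driven integration of the N-cell system under activation schedules.

Cells enter the shared volume at their activation time in the resting
state (U = g_c/a_U, B = 0), mirroring adoptive-transfer protocols in which
competitor cells are introduced later; an alternative configuration keeps
all cells present from t = 0 with inactive cells unstimulated.  Between
activation events the stiff system is integrated with an implicit
adaptive stepper (BDF).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .model_core import (
    CellParams,
    FeedbackForm,
    MediumParams,
    SecretionMode,
    SystemState,
)

__all__ = [
    "ActivationSchedule",
    "NoiseSpec",
    "Trajectory",
    "SolverSettings",
    "run",
    "run_to_steady_state",
    "steady_state_endpoint",
]

# Relative derivative rate (1/min) below which the system counts as settled.
STEADY_RATE_TOL = 1e-9
# Hard cap on integration time (min) when extending to steady state.
MAX_STEADY_TIME = 1.0e6


@dataclass(frozen=True)
class ActivationSchedule:
    """Per-cell activation times (min) and simulation horizon."""

    t_activate: tuple
    t_end: float

    def __init__(self, t_activate: Sequence[float], t_end: float):
        t_act = tuple(float(t) for t in t_activate)
        if any(not np.isfinite(t) or t < 0 for t in t_act):
            raise ValueError("activation times must be finite and >= 0")
        if not np.isfinite(t_end):
            raise ValueError("t_end must be finite")
        if t_end <= max(t_act, default=0.0):
            raise ValueError("t_end must exceed every activation time")
        object.__setattr__(self, "t_activate", t_act)
        object.__setattr__(self, "t_end", float(t_end))

    @classmethod
    def simultaneous(cls, n_cells: int, t_end: float) -> "ActivationSchedule":
        return cls([0.0] * n_cells, t_end)

    @classmethod
    def delayed_pair(cls, delay: float, t_end: float) -> "ActivationSchedule":
        """Cell 1 at t = 0, cell 2 after ``delay`` minutes."""
        return cls([0.0, float(delay)], t_end)


@dataclass(frozen=True)
class NoiseSpec:
    """Noise on the initial unbound-receptor count of entering cells."""

    distribution: str = "lognormal"
    cv: float = 0.0

    def __post_init__(self):
        if self.distribution not in ("lognormal", "none"):
            raise ValueError(f"unknown noise distribution {self.distribution!r}")
        if self.cv < 0:
            raise ValueError(f"cv must be >= 0, got {self.cv}")

    def sample_initial_U(self, mean_U: float, rng: np.random.Generator) -> float:
        if self.distribution == "none" or self.cv == 0:
            return mean_U
        sigma2 = np.log1p(self.cv**2)
        mu = np.log(mean_U) - sigma2 / 2.0
        return float(rng.lognormal(mean=mu, sigma=np.sqrt(sigma2)))


@dataclass(frozen=True)
class SolverSettings:
    rtol: float = 1e-8
    atol: float = 1e-6
    method: str = "BDF"
    sample_dt: float | None = None  # uniform output grid spacing (min); None = solver steps
    max_steady_time: float = MAX_STEADY_TIME
    steady_rate_tol: float = STEADY_RATE_TOL


@dataclass
class Trajectory:
    """Time course of an N-cell simulation.

    ``states`` rows follow the flat layout [U_1..U_n, B_1..B_n, I]; cells
    not yet activated at a sample time appear at their resting values.
    """

    times: np.ndarray
    states: np.ndarray
    cells: list
    schedule: ActivationSchedule
    medium: MediumParams
    committed_threshold: float
    converged: bool = True

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def endpoint(self) -> SystemState:
        y = self.states[-1]
        n = self.n_cells
        return SystemState(U=y[:n], B=y[n : 2 * n], I=y[-1], t=self.times[-1])

    @property
    def U(self) -> np.ndarray:
        return self.states[:, : self.n_cells]

    @property
    def B(self) -> np.ndarray:
        return self.states[:, self.n_cells : 2 * self.n_cells]

    @property
    def I(self) -> np.ndarray:
        return self.states[:, -1]

    @property
    def committed(self) -> np.ndarray:
        """Per-cell commitment at the endpoint (B >= threshold)."""
        return self.endpoint.B >= self.committed_threshold

    @property
    def total_receptor(self) -> np.ndarray:
        """Per-cell B + U at the endpoint."""
        return self.endpoint.U + self.endpoint.B


def _rhs_factory(
    cells: Sequence[CellParams], medium: MediumParams, active: np.ndarray
) -> Callable[[float, np.ndarray], np.ndarray]:
    """Vectorized right-hand side for the currently present/active cells."""
    n = len(cells)
    m = np.array([c.m if a else 0.0 for c, a in zip(cells, active)])
    g_c = np.array([c.g_c for c in cells])
    a_U = np.array([c.a_U for c in cells])
    a_B = np.array([c.a_B for c in cells])
    g_f = np.array([c.feedback.g_f for c in cells])
    K_f = np.array([max(c.feedback.K_f, 1e-300) for c in cells])
    n_h = np.array([c.feedback.n for c in cells])
    g_fc = np.array([c.feedback.g_f_const for c in cells])
    is_hill = np.array([c.feedback.form is FeedbackForm.HILL for c in cells])
    is_lin = np.array([c.feedback.form is FeedbackForm.LINEAR for c in cells])
    is_none = np.array([c.feedback.form is FeedbackForm.NONE for c in cells])
    sec = sum(
        (c.secretion.s * c.m if c.secretion.mode is SecretionMode.PROPORTIONAL else c.secretion.s)
        for c, a in zip(cells, active)
        if a
    )
    source = sec + medium.external_source
    k = medium.k_on_eff
    k_off = medium.k_off
    d_I = medium.d_I
    Kfn = K_f**n_h

    def rhs(t, y):
        # no clamping here: a smooth RHS keeps the stiff stepper happy, and
        # negativity (beyond integrator tolerance) is checked after each leg
        U = y[:n]
        B = y[n : 2 * n]
        I = y[-1]
        g = g_c.copy()
        if is_hill.any():
            # |B|^n keeps the term defined for the tiny negative excursions
            # an adaptive stepper may probe; n >= 1 so this stays smooth
            Bn = np.abs(B) ** n_h
            g = g + np.where(is_hill, m * g_f * Bn / (Bn + Kfn), 0.0)
        if is_lin.any():
            g = g + np.where(is_lin, m * g_f * B / K_f, 0.0)
        if is_none.any():
            g = g + np.where(is_none, m * g_fc, 0.0)
        bind = k * I * U
        dB = bind - B * (k_off + a_B)
        dU = g - a_U * U - bind + k_off * B
        dI = source - d_I * I - bind.sum() + k_off * B.sum()
        out = np.empty(2 * n + 1)
        out[:n] = dU
        out[n : 2 * n] = dB
        out[-1] = dI
        return out

    def jac(t, y):
        U = y[:n]
        B = y[n : 2 * n]
        I = y[-1]
        # dg/dB for each feedback variant (even extension matches the rhs)
        gp = np.zeros(n)
        if is_hill.any():
            absB = np.abs(B)
            Bn = absB**n_h
            denom = (Bn + Kfn) ** 2
            Bn_over_B = np.divide(Bn, absB, out=np.zeros(n), where=absB > 0)
            gp_hill = m * g_f * n_h * Bn_over_B * Kfn / denom * np.sign(B)
            gp = np.where(is_hill, gp_hill, gp)
        if is_lin.any():
            gp = np.where(is_lin, m * g_f / K_f, gp)
        J = np.zeros((2 * n + 1, 2 * n + 1))
        idx = np.arange(n)
        J[idx, idx] = -a_U - k * I                 # dU_i/dU_i
        J[idx, n + idx] = gp + k_off               # dU_i/dB_i
        J[idx, 2 * n] = -k * U                     # dU_i/dI
        J[n + idx, idx] = k * I                    # dB_i/dU_i
        J[n + idx, n + idx] = -(k_off + a_B)       # dB_i/dB_i
        J[n + idx, 2 * n] = k * U                  # dB_i/dI
        J[2 * n, idx] = -k * I                     # dI/dU_j
        J[2 * n, n + idx] = k_off                  # dI/dB_j
        J[2 * n, 2 * n] = -d_I - k * U.sum()       # dI/dI
        return J

    rhs.jac = jac
    return rhs


def _state_scale(y: np.ndarray, atol: float) -> np.ndarray:
    return np.maximum(np.abs(y), max(atol, 1.0))


def _jac_for(rhs, solver: SolverSettings):
    """Analytic Jacobian for the implicit steppers; None otherwise."""
    if solver.method in ("BDF", "Radau", "LSODA"):
        return getattr(rhs, "jac", None)
    return None


def run(
    cells: Sequence[CellParams],
    medium: MediumParams,
    schedule: ActivationSchedule,
    init_noise: NoiseSpec | None = None,
    seed: int | None = None,
    solver: SolverSettings | None = None,
    committed_threshold: float | None = None,
    extend_to_steady_state: bool = True,
    inactive_present: bool = False,
) -> Trajectory:
    """Integrate the N-cell system under an activation schedule.

    Cells are absent from the volume before their activation time and
    enter in the resting state (optionally with noisy initial U); with
    ``inactive_present=True`` they are instead present from t = 0 with
    constitutive turnover only.  Deterministic for a given ``seed``.
    """
    cells = list(cells)
    n = len(cells)
    if n < 1:
        raise ValueError("at least one cell is required")
    if len(schedule.t_activate) != n:
        raise ValueError("schedule length must match the number of cells")
    solver = solver or SolverSettings()
    rng = np.random.default_rng(seed)
    noise = init_noise or NoiseSpec(distribution="none")

    t_act = np.asarray(schedule.t_activate)
    init_U = np.array(
        [noise.sample_initial_U(c.resting_U, rng) for c in cells]
    )

    # breakpoints: activation events plus the horizon
    events = sorted({0.0, *t_act.tolist(), schedule.t_end})
    events = [t for t in events if t <= schedule.t_end]

    times_out: list[np.ndarray] = []
    states_out: list[np.ndarray] = []
    y = np.concatenate([init_U, np.zeros(n), [0.0]])

    def record(ts, ys, present):
        full = np.empty((ts.size, 2 * n + 1))
        # absent cells are reported at their (noise-free would-be) entry values
        full[:, :n] = init_U
        full[:, n : 2 * n] = 0.0
        idx = np.flatnonzero(present)
        npres = idx.size
        full[:, idx] = ys[:npres].T
        full[:, n + idx] = ys[npres : 2 * npres].T
        full[:, -1] = ys[-1]
        times_out.append(ts)
        states_out.append(full)

    for t0, t1 in zip(events[:-1], events[1:]):
        present = (t_act <= t0) | np.full(n, inactive_present)
        active = t_act <= t0
        idx = np.flatnonzero(present)
        sub_cells = [cells[i] for i in idx]
        sub_active = active[idx]
        y_sub = np.concatenate([y[idx], y[n + idx], [y[-1]]])
        if len(sub_cells) == 0:
            ts = np.array([t0, t1])
            record(ts, np.tile(np.array([y[-1]]), (2, 1)).T, present)
            continue
        rhs = _rhs_factory(sub_cells, medium, sub_active)
        t_eval = None
        if solver.sample_dt:
            t_eval = np.arange(t0, t1, solver.sample_dt)
            t_eval = np.append(t_eval, t1)
        sol = solve_ivp(
            rhs,
            (t0, t1),
            y_sub,
            method=solver.method,
            rtol=solver.rtol,
            atol=solver.atol,
            t_eval=t_eval,
            jac=_jac_for(rhs, solver),
        )
        if not sol.success:
            raise RuntimeError(
                f"solver failed in [{t0}, {t1}]: {sol.message}; "
                f"last state {sol.y[:, -1] if sol.y.size else None}"
            )
        _check_nonnegative(sol.y, solver.atol)
        record(sol.t, sol.y, present)
        m_sub = len(sub_cells)
        y[idx] = sol.y[:m_sub, -1]
        y[n + idx] = sol.y[m_sub : 2 * m_sub, -1]
        y[-1] = sol.y[-1, -1]

    converged = True
    if extend_to_steady_state:
        rhs = _rhs_factory(cells, medium, np.ones(n, dtype=bool))
        t = schedule.t_end
        y, t, converged = _extend_to_steady(rhs, y, t, solver)
        times_out.append(np.array([t]))
        states_out.append(y[np.newaxis, :].copy())

    times = np.concatenate(times_out)
    states = np.vstack(states_out)
    states = np.maximum(states, 0.0)

    if committed_threshold is None:
        committed_threshold = max(c.feedback.K_f for c in cells)
    return Trajectory(
        times=times,
        states=states,
        cells=cells,
        schedule=schedule,
        medium=medium,
        committed_threshold=committed_threshold,
        converged=converged,
    )


def _check_nonnegative(y: np.ndarray, atol: float) -> None:
    scale = np.maximum(np.abs(y).max(axis=1, initial=1.0), 1.0)
    worst = (y.min(axis=1) / scale).min()
    if worst < -1e-6:
        raise RuntimeError(
            f"integrator produced negative state beyond tolerance ({worst:.2e} relative)"
        )


def _extend_to_steady(rhs, y, t, solver: SolverSettings):
    """Continue integrating in chunks until derivatives are negligible."""
    chunk = 2.0e4
    while t < solver.max_steady_time:
        dy = rhs(t, y)
        rate = np.abs(dy) / _state_scale(y, solver.atol)
        if rate.max() < solver.steady_rate_tol:
            return y, t, True
        sol = solve_ivp(
            rhs,
            (t, t + chunk),
            y,
            method=solver.method,
            rtol=solver.rtol,
            atol=solver.atol,
            jac=_jac_for(rhs, solver),
        )
        if not sol.success:
            raise RuntimeError(f"solver failed while relaxing to steady state: {sol.message}")
        y = sol.y[:, -1]
        t = sol.t[-1]
        chunk = min(chunk * 2.0, 2.0e5)
    warnings.warn("steady-state relaxation hit the time cap; endpoint not converged")
    return y, t, False


def run_to_steady_state(
    cells: Sequence[CellParams],
    medium: MediumParams,
    schedule: ActivationSchedule | None = None,
    **kwargs,
) -> Trajectory:
    """Convenience wrapper: simultaneous activation, endpoint at convergence."""
    cells = list(cells)
    if schedule is None:
        schedule = ActivationSchedule.simultaneous(len(cells), 5000.0)
    return run(cells, medium, schedule, extend_to_steady_state=True, **kwargs)


def steady_state_endpoint(
    cells: Sequence[CellParams],
    medium: MediumParams,
    schedule: ActivationSchedule | None = None,
    **kwargs,
) -> SystemState:
    return run_to_steady_state(cells, medium, schedule, **kwargs).endpoint
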