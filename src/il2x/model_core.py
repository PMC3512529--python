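"""Dynamical system for IL-2 extracellular feedback between activated T cells.

The model tracks, for each of N cells sharing one well-mixed volume, the
number of unbound and bound IL-2 receptors on the cell surface (U_i, B_i)
and the amount of free IL-2 in the volume (I):

    dI/dt   = sum_i sec_i  - d_I*I - k*I*sum_i U_i + k_off*sum_i B_i + ext
    dB_i/dt = k*I*U_i - B_i*(k_off + a_B)
    dU_i/dt = g(m_i, B_i) - a_U*U_i - k*I*U_i + k_off*B_i

where k is the per-molecule association rate, sec_i the cell's IL-2
secretion rate, and g(m, B) the receptor synthesis rate closing the
positive feedback loop:

    g(m, B) = g_c + m * g_f * B^n / (B^n + K_f^n)        (Hill feedback)

Two control variants replace the feedback term: a linear form
``m * g_f * B / K_f`` and a feedback-free constant induced rate
``m * g_f_const``.

Units are minutes, molecule counts and cubic microns throughout.  The
association rate ``k_on`` is supplied in 1/(M min) and converted to the
per-molecule rate ``k_on / (N_A * V)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Sequence

import numpy as np

__all__ = [
    "AVOGADRO",
    "FeedbackForm",
    "SecretionMode",
    "FeedbackSpec",
    "SecretionSpec",
    "CellParams",
    "MediumParams",
    "SystemState",
    "kon_per_molecule",
    "receptor_synthesis_rate",
    "secretion_rate",
    "vector_field",
    "pack_state",
    "unpack_state",
    "resting_state",
    "default_cell",
    "default_medium",
    "default_params",
]

AVOGADRO = 6.02214076e23

# litres per cubic micron
_L_PER_UM3 = 1e-15


class FeedbackForm(str, Enum):
    HILL = "hill"
    LINEAR = "linear"
    NONE = "none"


class SecretionMode(str, Enum):
    PROPORTIONAL = "proportional_to_m"
    CONSTANT = "constant"


@dataclass(frozen=True)
class FeedbackSpec:
    """IL-2R synthesis feedback on the bound-receptor count.

    Parameters
    ----------
    form
        ``hill`` for the saturating positive feedback, ``linear`` for the
        control variant ``m*g_f*B/K_f``, ``none`` for a constant induced
        rate ``m*g_f_const`` with no dependence on B.
    g_f
        Maximal induced synthesis rate (molecules/min).
    K_f
        Half-saturation bound-receptor count (molecules); also the scale
        used by the linear variant so that all variants share one
        parameter set.
    n
        Hill coefficient (default 2, the shipped model's value).
    g_f_const
        Induced rate for the ``none`` variant.  Defaults to ``g_f/2``, the
        Hill form's half-saturation output.
    """

    form: FeedbackForm = FeedbackForm.HILL
    g_f: float = 0.0
    K_f: float = 1.0
    n: float = 2.0
    g_f_const: float | None = None

    def __post_init__(self):
        form = FeedbackForm(self.form)
        object.__setattr__(self, "form", form)
        if self.g_f < 0:
            raise ValueError(f"g_f must be >= 0, got {self.g_f}")
        if form is FeedbackForm.HILL and self.K_f <= 0:
            raise ValueError(f"K_f must be > 0 for hill feedback, got {self.K_f}")
        if self.n <= 0:
            raise ValueError(f"Hill coefficient n must be > 0, got {self.n}")
        if self.g_f_const is None:
            object.__setattr__(self, "g_f_const", self.g_f / 2.0)


@dataclass(frozen=True)
class SecretionSpec:
    """IL-2 secretion: ``s*m`` (proportional) or ``s`` (constant) while active."""

    mode: SecretionMode = SecretionMode.PROPORTIONAL
    s: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "mode", SecretionMode(self.mode))
        if self.s < 0:
            raise ValueError(f"secretion rate s must be >= 0, got {self.s}")


@dataclass(frozen=True)
class CellParams:
    """Kinetic parameters and TCR signal strength of one cell."""

    m: float
    g_c: float
    a_U: float
    a_B: float
    feedback: FeedbackSpec
    secretion: SecretionSpec

    def __post_init__(self):
        if not 0.0 <= self.m <= 1.0:
            raise ValueError(f"m must lie in [0, 1], got {self.m}")
        for name in ("g_c", "a_B"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.a_U <= 0:
            raise ValueError(
                f"a_U must be > 0 so the resting state g_c/a_U exists, got {self.a_U}"
            )

    @property
    def resting_U(self) -> float:
        """Receptor count of an unstimulated cell, g_c/a_U."""
        return self.g_c / self.a_U

    def with_m(self, m: float) -> "CellParams":
        return replace(self, m=float(m))


@dataclass(frozen=True)
class MediumParams:
    """Shared-environment parameters of the well-mixed interaction volume."""

    volume: float
    d_I: float
    k_on: float
    k_off: float
    external_source: float = 0.0

    def __post_init__(self):
        if self.volume <= 0:
            raise ValueError(f"volume must be > 0, got {self.volume}")
        for name in ("d_I", "k_on", "k_off", "external_source"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")

    @property
    def k_on_eff(self) -> float:
        """Per-molecule association rate (1/min), k_on/(N_A * V)."""
        return kon_per_molecule(self.k_on, self.volume)

    def scaled_volume(self, factor: float) -> "MediumParams":
        return replace(self, volume=self.volume * factor)


def kon_per_molecule(k_on: float, volume_um3: float) -> float:
    """Convert an association rate from 1/(M min) to a per-molecule rate.

    One molecule in ``volume_um3`` cubic microns corresponds to a
    concentration of ``1/(N_A * V)`` molar, so the pseudo-first-order rate
    seen by a single ligand molecule is ``k_on/(N_A * V)`` per minute per
    receptor molecule.
    """
    return k_on / (AVOGADRO * volume_um3 * _L_PER_UM3)


@dataclass
class SystemState:
    """Molecule counts of the N-cell system at one time point."""

    U: np.ndarray
    B: np.ndarray
    I: float
    t: float = 0.0

    def __post_init__(self):
        self.U = np.atleast_1d(np.asarray(self.U, dtype=float))
        self.B = np.atleast_1d(np.asarray(self.B, dtype=float))
        if self.U.shape != self.B.shape:
            raise ValueError("U and B must have the same length")

    @property
    def n_cells(self) -> int:
        return self.U.size

    @property
    def total_receptor(self) -> np.ndarray:
        """Per-cell total surface receptor, B + U (the Fig.-S19-style readout)."""
        return self.U + self.B


def receptor_synthesis_rate(cell: CellParams, B) -> np.ndarray | float:
    """IL-2R synthesis rate g(m, B) for the cell's feedback variant.

    Accepts a scalar or array of bound-receptor counts.  Negative B is a
    domain error.
    """
    B_arr = np.asarray(B, dtype=float)
    if np.any(B_arr < 0):
        raise ValueError("bound-receptor count B must be >= 0")
    fb = cell.feedback
    if fb.form is FeedbackForm.HILL:
        Bn = B_arr ** fb.n
        with np.errstate(invalid="ignore"):
            hill = np.where(Bn > 0, Bn / (Bn + fb.K_f ** fb.n), 0.0)
        out = cell.g_c + cell.m * fb.g_f * hill
    elif fb.form is FeedbackForm.LINEAR:
        out = cell.g_c + cell.m * fb.g_f * B_arr / fb.K_f
    else:  # constant induced rate, no feedback
        out = cell.g_c + cell.m * fb.g_f_const * np.ones_like(B_arr)
    return out if B_arr.ndim else float(out)


def secretion_rate(cell: CellParams, active: bool = True) -> float:
    """IL-2 secretion rate of one cell (0 when inactive)."""
    if not active:
        return 0.0
    if cell.secretion.mode is SecretionMode.PROPORTIONAL:
        return cell.secretion.s * cell.m
    return cell.secretion.s


def vector_field(
    state: SystemState,
    cells: Sequence[CellParams],
    medium: MediumParams,
    active: Sequence[bool] | None = None,
) -> SystemState:
    """Time derivatives (dU, dB, dI) of the N-cell system.

    ``active`` marks which cells are currently TCR-stimulated; inactive
    cells neither secrete nor receive the m-dependent synthesis terms but
    keep constitutive receptor turnover (the present-but-unstimulated
    configuration; scheduling cells as absent is handled by the simulator).
    """
    n = len(cells)
    if state.n_cells != n:
        raise ValueError(
            f"state holds {state.n_cells} cells but {n} CellParams were given"
        )
    if active is None:
        active = [True] * n
    if len(active) != n:
        raise ValueError("active flags must match the number of cells")

    U, B, I = state.U, state.B, state.I
    k = medium.k_on_eff
    bind = k * I * U
    g = np.array(
        [
            receptor_synthesis_rate(c if a else c.with_m(0.0), b)
            for c, b, a in zip(cells, B, active)
        ]
    )
    a_U = np.array([c.a_U for c in cells])
    a_B = np.array([c.a_B for c in cells])
    sec = sum(secretion_rate(c, a) for c, a in zip(cells, active))

    dB = bind - B * (medium.k_off + a_B)
    dU = g - a_U * U - bind + medium.k_off * B
    dI = (
        sec
        + medium.external_source
        - medium.d_I * I
        - bind.sum()
        + medium.k_off * B.sum()
    )
    return SystemState(U=dU, B=dB, I=dI, t=state.t)


# -- flat-vector layout used by the integrator: y = [U_0..U_{n-1}, B_0.., I] --

def pack_state(state: SystemState) -> np.ndarray:
    return np.concatenate([state.U, state.B, [state.I]])


def unpack_state(y: np.ndarray, t: float = 0.0) -> SystemState:
    n = (y.size - 1) // 2
    return SystemState(U=y[:n].copy(), B=y[n : 2 * n].copy(), I=float(y[-1]), t=t)


def resting_state(cells: Sequence[CellParams], I: float = 0.0) -> SystemState:
    """All cells at the unstimulated fixed point U = g_c/a_U, B = 0."""
    U = np.array([c.resting_U for c in cells])
    return SystemState(U=U, B=np.zeros_like(U), I=I, t=0.0)


# ---------------------------------------------------------------------------
# Default (shipped) parameter set
# ---------------------------------------------------------------------------

def _load_default_dict() -> dict:
    import yaml
    from importlib import resources

    with resources.files("il2x.data").joinpath("default_params.yaml").open() as fh:
        return yaml.safe_load(fh)


def _cell_from_dict(d: dict, m: float | None = None) -> CellParams:
    fb = d["feedback"]
    sec = d["secretion"]
    return CellParams(
        m=float(d["m"] if m is None else m),
        g_c=float(d["g_c"]),
        a_U=float(d["a_U"]),
        a_B=float(d["a_B"]),
        feedback=FeedbackSpec(
            form=fb["form"],
            g_f=float(fb["g_f"]),
            K_f=float(fb["K_f"]),
            n=float(fb.get("n", 2.0)),
            g_f_const=(None if fb.get("g_f_const") is None else float(fb["g_f_const"])),
        ),
        secretion=SecretionSpec(mode=sec["mode"], s=float(sec["s"])),
    )


def _medium_from_dict(d: dict) -> MediumParams:
    return MediumParams(
        volume=float(d["volume"]),
        d_I=float(d["d_I"]),
        k_on=float(d["k_on"]),
        k_off=float(d["k_off"]),
        external_source=float(d.get("external_source", 0.0)),
    )


def default_cell(m: float = 1.0) -> CellParams:
    """A cell with the shipped default kinetics and TCR strength ``m``."""
    return _cell_from_dict(_load_default_dict()["cell"], m=m)


def default_medium() -> MediumParams:
    """The shipped default medium (100 um^3 two-cell interaction volume)."""
    return _medium_from_dict(_load_default_dict()["medium"])


def default_params(m: float = 1.0) -> tuple[CellParams, MediumParams]:
    d = _load_default_dict()
    return _cell_from_dict(d["cell"], m=m), _medium_from_dict(d["medium"])
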