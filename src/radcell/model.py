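"""Core compartment models of a non-dividing cell population under radiation.

The population is split into four compartments:

``x``
    healthy cells, susceptible to radiation hits;
``y``
    hit cells that are currently repairing the damage;
``w``
    adapted (protected) cells that cannot acquire permanent damage;
``z``
    permanently altered cells (death, mutation, aberration -- the model
    does not distinguish the endpoint).

Healthy cells are hit at rate ``alpha``. A hit cell resolves repair at rate
``c``; with probability ``p`` the repair fails and the cell becomes
permanently altered, with probability ``1 - p`` it succeeds. What happens on
success distinguishes the two mechanisms:

* **memory** (``memory=1``): the repaired cell retains an intracellular
  protected state and joins ``w``; protection is lost at rate ``eta``
  (mean duration ``1/eta``).
* **communication** (``memory=0``): the repaired cell returns to ``x``;
  protection can only be induced in healthy cells through mass-action
  contact with repairing cells (rate ``beta0``) or with already adapted
  cells (rate ``beta1``).

The full model has both mechanisms active. Cells do not divide, so
``x + y + w + z`` is conserved and the all-altered state ``z = k`` is the
unique long-term outcome under sustained exposure.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.linalg import eig, expm

__all__ = [
    "ModelParams",
    "CellState",
    "ScheduleSegment",
    "RadiationSchedule",
    "Trajectory",
    "IntegrationError",
    "InvalidStateError",
    "memory_model",
    "communication_model",
    "full_model",
    "rhs",
    "integrate",
    "asymptotic_decline_rate",
    "linear_subsystem_matrix",
    "linear_unaltered_fraction",
]

#: relative tolerance below which a negative compartment is treated as
#: integrator round-off and clipped to zero
NEGATIVE_CLIP_REL = 1e-9


class IntegrationError(RuntimeError):
    """The ODE solver failed or produced an invalid trajectory."""


class InvalidStateError(ValueError):
    """A cell state violates non-negativity beyond round-off tolerance."""


class CellState(NamedTuple):
    """Compartment counts ``(x, y, w, z)``; continuous and non-negative."""

    x: float
    y: float
    w: float
    z: float


@dataclass(frozen=True)
class ModelParams:
    """Rate and probability constants of the radiation-response models.

    Parameters
    ----------
    alpha
        Radiation hit rate per healthy cell per unit time (>= 0).
    p
        Probability that repair fails and the alteration becomes
        permanent, in [0, 1].
    c
        Repair-resolution rate of hit cells per unit time (> 0).
    eta
        Rate of loss of the protected state (>= 0); mean protection
        duration is ``1/eta``.
    beta0, beta1
        Mass-action rates at which repairing / adapted cells induce
        adaptation in healthy cells (>= 0).
    memory
        1 if successful repair sends the cell to the adapted pool
        (intracellular memory), 0 if it returns the cell to the
        susceptible pool.
    """

    alpha: float
    p: float
    c: float = 1.0
    eta: float = 0.0
    beta0: float = 0.0
    beta1: float = 0.0
    memory: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p must be in [0, 1], got {self.p}")
        if self.c <= 0:
            raise ValueError(f"c must be > 0, got {self.c}")
        for name in ("alpha", "eta", "beta0", "beta1"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.memory not in (0, 1):
            raise ValueError(f"memory must be 0 or 1, got {self.memory}")

    @property
    def is_linear(self) -> bool:
        """True when the (x, y, w) subsystem is linear (no communication)."""
        return self.beta0 == 0.0 and self.beta1 == 0.0

    def replace(self, **kwargs) -> "ModelParams":
        return dataclasses.replace(self, **kwargs)


def memory_model(alpha: float, p: float, c: float = 1.0, eta: float = 0.0) -> ModelParams:
    """Pure intracellular-memory model: successful repair protects the cell."""
    return ModelParams(alpha=alpha, p=p, c=c, eta=eta, memory=1)


def communication_model(
    alpha: float, p: float, c: float = 1.0, eta: float = 0.0,
    beta0: float = 0.0, beta1: float = 0.0,
) -> ModelParams:
    """Pure communication model: repaired cells return to the susceptible pool."""
    return ModelParams(alpha=alpha, p=p, c=c, eta=eta,
                       beta0=beta0, beta1=beta1, memory=0)


def full_model(
    alpha: float, p: float, c: float = 1.0, eta: float = 0.0,
    beta0: float = 0.0, beta1: float = 0.0,
) -> ModelParams:
    """Both mechanisms active: memory plus cell-to-cell communication."""
    return ModelParams(alpha=alpha, p=p, c=c, eta=eta,
                       beta0=beta0, beta1=beta1, memory=1)


@dataclass(frozen=True)
class ScheduleSegment:
    """A constant-exposure interval carrying its own hit rate and kill probability."""

    t_start: float
    t_end: float
    alpha: float
    p: float

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise ValueError(f"segment must have t_start < t_end, got {self}")
        if self.alpha < 0:
            raise ValueError(f"segment alpha must be >= 0, got {self.alpha}")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"segment p must be in [0, 1], got {self.p}")


@dataclass(frozen=True)
class RadiationSchedule:
    """Piecewise-constant exposure: ordered, non-overlapping segments.

    Outside the segments the beam is off (``alpha = 0``) and hit cells keep
    resolving repair with the ``p`` of the most recent segment (the severity
    of the damage is set at hit time); before the first segment,
    ``default_p`` applies.
    """

    segments: tuple[ScheduleSegment, ...]
    default_p: float = 0.0

    def __post_init__(self) -> None:
        segs = tuple(self.segments)
        object.__setattr__(self, "segments", segs)
        for a, b in zip(segs, segs[1:]):
            if b.t_start < a.t_end:
                raise ValueError(f"segments overlap or are out of order: {a} then {b}")
        if not 0.0 <= self.default_p <= 1.0:
            raise ValueError(f"default_p must be in [0, 1], got {self.default_p}")

    def pieces(self, t0: float, t1: float) -> list[tuple[float, float, float, float]]:
        """Cover ``[t0, t1]`` with constant-(alpha, p) pieces ``(a, b, alpha, p)``."""
        if t1 <= t0:
            raise ValueError("t1 must exceed t0")
        events = [t0, t1]
        for s in self.segments:
            events += [s.t_start, s.t_end]
        events = sorted({t for t in events if t0 <= t <= t1})
        out = []
        for a, b in zip(events, events[1:]):
            mid = 0.5 * (a + b)
            alpha, p = 0.0, self.default_p
            for s in self.segments:
                if s.t_start <= mid < s.t_end:
                    alpha, p = s.alpha, s.p
                    break
                if s.t_end <= mid:
                    p = s.p  # gap after this segment: damage severity persists
            out.append((a, b, alpha, p))
        return out


@dataclass
class Trajectory:
    """Sampled solution of one of the models.

    ``states`` is an ``(n, 4)`` array with columns ``x, y, w, z`` at the
    strictly increasing ``times``.
    """

    times: np.ndarray
    states: np.ndarray
    params: ModelParams
    schedule: RadiationSchedule | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.shape != (self.times.size, 4):
            raise ValueError("states must be (len(times), 4)")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    x = property(lambda self: self.states[:, 0])
    y = property(lambda self: self.states[:, 1])
    w = property(lambda self: self.states[:, 2])
    z = property(lambda self: self.states[:, 3])

    @property
    def unaltered(self) -> np.ndarray:
        """Surviving (not permanently altered) cells, ``u = x + y + w``."""
        return self.states[:, :3].sum(axis=1)

    @property
    def k(self) -> float:
        """Conserved total population, set by the initial condition."""
        return float(self.states[0].sum())

    @property
    def final_state(self) -> CellState:
        return CellState(*self.states[-1])

    def conservation_error(self) -> float:
        return float(np.max(np.abs(self.states.sum(axis=1) - self.k)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": self.times, "x": self.x, "y": self.y, "w": self.w, "z": self.z}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame,
                   params: ModelParams | None = None) -> "Trajectory":
        missing = {"t", "x", "y", "w", "z"} - set(frame.columns)
        if missing:
            raise ValueError(f"trajectory table lacks columns: {sorted(missing)}")
        states = frame[["x", "y", "w", "z"]].to_numpy(dtype=float)
        params = params or ModelParams(alpha=0.0, p=0.0)
        return cls(times=frame["t"].to_numpy(dtype=float), states=states, params=params)

    @classmethod
    def from_csv(cls, path, params: ModelParams | None = None) -> "Trajectory":
        return cls.from_frame(pd.read_csv(path), params=params)


def rhs(state: Sequence[float], params: ModelParams) -> np.ndarray:
    """Time derivatives ``(dx, dy, dw, dz)`` of the unified model.

    Each mass flow appears exactly once as a source and once as a sink, so
    the component sum cancels term-by-term and the total is conserved by
    construction.
    """
    x, y, w, z = state
    k = abs(x) + abs(y) + abs(w) + abs(z)
    if min(x, y, w, z) < -NEGATIVE_CLIP_REL * max(k, 1.0):
        raise InvalidStateError(f"negative compartment in state {tuple(state)}")
    return _rhs(0.0, np.asarray(state, dtype=float), params)


def _rhs(t: float, s: np.ndarray, pr: ModelParams) -> np.ndarray:
    x, y, w = s[0], s[1], s[2]
    hit = pr.alpha * x
    fail = pr.p * pr.c * y
    succeed = (1.0 - pr.p) * pr.c * y
    induce = (pr.beta0 * y + pr.beta1 * w) * x
    unprotect = pr.eta * w
    if pr.memory:
        dx = -hit - induce + unprotect
        dw = succeed + induce - unprotect
    else:
        dx = -hit - induce + unprotect + succeed
        dw = induce - unprotect
    dy = hit - succeed - fail
    return np.array([dx, dy, dw, fail])


def _jac(t: float, s: np.ndarray, pr: ModelParams) -> np.ndarray:
    x, y, w = s[0], s[1], s[2]
    m = pr.memory
    sy = (1.0 - pr.p) * pr.c
    j = np.zeros((4, 4))
    j[0] = [-pr.alpha - pr.beta0 * y - pr.beta1 * w,
            -pr.beta0 * x + (1 - m) * sy,
            -pr.beta1 * x + pr.eta, 0.0]
    j[1] = [pr.alpha, -pr.c, 0.0, 0.0]
    j[2] = [pr.beta0 * y + pr.beta1 * w,
            pr.beta0 * x + m * sy,
            pr.beta1 * x - pr.eta, 0.0]
    j[3] = [0.0, pr.p * pr.c, 0.0, 0.0]
    return j


def integrate(
    params: ModelParams,
    initial: Sequence[float],
    t_grid: Sequence[float],
    schedule: RadiationSchedule | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate one of the models over ``t_grid`` with a stiff-capable solver.

    ``params`` supplies the model variant and all constants; when a
    ``schedule`` is given, its per-segment ``(alpha, p)`` override those of
    ``params`` piecewise, and each constant piece is integrated to its
    boundary with the end state handed to the next piece (no smoothing
    across the discontinuities).
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing with >= 2 points")
    state = np.asarray(initial, dtype=float)
    if state.shape != (4,):
        raise ValueError("initial state must have 4 components (x, y, w, z)")
    k = float(state.sum())
    if np.min(state) < -NEGATIVE_CLIP_REL * max(k, 1.0):
        raise InvalidStateError(f"negative initial state {initial}")
    state = np.clip(state, 0.0, None)

    t0, t1 = float(t_grid[0]), float(t_grid[-1])
    if schedule is None:
        pieces = [(t0, t1, params.alpha, params.p)]
    else:
        pieces = schedule.pieces(t0, t1)

    out = np.empty((t_grid.size, 4))
    filled = np.zeros(t_grid.size, dtype=bool)
    if t_grid[0] == t0:
        out[0] = state
        filled[0] = True

    for a, b, alpha, p in pieces:
        pr = params.replace(alpha=alpha, p=p)
        inside = (t_grid > a) & (t_grid <= b)
        t_eval = np.unique(np.append(t_grid[inside], b))
        sol = solve_ivp(
            _rhs, (a, b), state, t_eval=t_eval, args=(pr,),
            method="LSODA", jac=_jac, rtol=rtol, atol=atol,
        )
        if not sol.success:
            raise IntegrationError(
                f"solver failed on [{a}, {b}] (alpha={alpha}, p={p}): {sol.message}"
            )
        ys = sol.y.T
        if np.min(ys) < -NEGATIVE_CLIP_REL * max(k, 1.0):
            raise IntegrationError(
                f"trajectory went negative beyond tolerance on [{a}, {b}]"
            )
        ys = np.clip(ys, 0.0, None)
        sel = np.isin(sol.t, t_grid[inside])
        out[inside] = ys[sel]
        filled |= inside
        state = ys[-1]

    if not np.all(filled):  # pragma: no cover - guarded by grid validation
        raise IntegrationError("internal error: grid points left unfilled")
    return Trajectory(times=t_grid, states=out, params=params, schedule=schedule)


def linear_subsystem_matrix(params: ModelParams) -> np.ndarray:
    """Generator of the (x, y, w) subsystem linearized about the all-altered state.

    The communication cross-terms are quadratic in the unaltered densities
    and vanish as ``x -> 0``, so this is also the late-time linearization of
    the communication model.
    """
    m = params.memory
    sy = (1.0 - params.p) * params.c
    return np.array([
        [-params.alpha, (1 - m) * sy, params.eta],
        [params.alpha, -params.c, 0.0],
        [0.0, m * sy, -params.eta],
    ])


def asymptotic_decline_rate(params: ModelParams) -> float:
    """Slowest decay rate of the unaltered population under constant exposure.

    Returns the negative of the dominant (least-negative) eigenvalue of the
    linearized (x, y, w) subsystem; this is the late-phase log-slope of
    ``ln(x + y + w)`` versus time. With ``p = 0`` no cell is ever
    permanently altered and the rate is zero.
    """
    if params.alpha <= 0:
        raise ValueError("asymptotic decline rate requires alpha > 0")
    M = linear_subsystem_matrix(params)
    ev = eig(M, right=False)
    rate = -float(np.max(ev.real))
    if not np.isfinite(rate):  # pragma: no cover
        raise ValueError("degenerate subsystem: undefined decline rate")
    return rate


def linear_unaltered_fraction(params: ModelParams, times) -> np.ndarray:
    """Unaltered fraction ``u(t)/k`` from ``(k, 0, 0, 0)`` for the linear models.

    Valid only when ``beta0 = beta1 = 0`` (the (x, y, w) subsystem is then
    linear and the solution is a matrix exponential). Used as a fast exact
    path by the fitting module; cross-checked against :func:`integrate` in
    the test suite.
    """
    if not params.is_linear:
        raise ValueError("linear fast path requires beta0 = beta1 = 0")
    M = linear_subsystem_matrix(params)
    times = np.atleast_1d(np.asarray(times, dtype=float))
    e0 = np.array([1.0, 0.0, 0.0])
    lam, V = eig(M)
    try:
        coeff = np.linalg.solve(V, e0)
        cond_ok = np.linalg.cond(V) < 1e10
    except np.linalg.LinAlgError:  # pragma: no cover
        cond_ok = False
    if cond_ok:
        proj = V.sum(axis=0) * coeff
        u = (np.exp(np.outer(times, lam)) * proj).sum(axis=1).real
    else:  # defective generator: fall back to expm per time point
        u = np.array([(expm(M * t) @ e0).sum() for t in times])
    return np.clip(u, 0.0, 1.0)
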