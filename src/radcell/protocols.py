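"""Named in-silico radiation experiments.

* continuous exposure at a fixed dose rate (decline-phase structure),
* priming-then-challenge radioadaptation protocols,
* the priming-ratio scan over the fold-increase of the kill probability at
  the challenge dose,
* the persistent-protection equilibrium sustained by adapted-to-healthy
  communication after the beam is switched off.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import phases
from .model import (
    ModelParams,
    RadiationSchedule,
    ScheduleSegment,
    Trajectory,
    integrate,
)

__all__ = [
    "continuous_exposure",
    "priming_schedule",
    "priming_challenge",
    "PrimingResult",
    "priming_ratio",
    "priming_ratio_curve",
    "PrimingRatioCurve",
    "ratio_threshold_bisect",
    "persistent_protection_equilibrium",
    "ProtectionEquilibrium",
]

DEFAULT_K = 100.0
DEFAULT_PRIME_WINDOW = (0.0, 10.0)
DEFAULT_CHALLENGE_WINDOW = (20.0, 25.0)
#: readout time for priming protocols; well past the challenge window, by
#: which point z has plateaued (y has drained and the beam is off)
DEFAULT_READOUT = 200.0


def _log_grid(t_end: float, n_points: int, t_min: float = 1e-3) -> np.ndarray:
    return np.concatenate([[0.0], np.geomspace(min(t_min, t_end / 10), t_end, n_points)])


def continuous_exposure(
    params: ModelParams,
    k: float = DEFAULT_K,
    t_end: float = 1e5,
    n_points: int = 600,
) -> tuple[Trajectory, dict]:
    """Constant-rate exposure from an all-healthy population.

    Returns the trajectory on a logarithmic time grid together with a
    summary: the final altered count, the number of decline phases of the
    unaltered population, and the measured late-phase rate (``None`` when
    the horizon is too short to resolve it).
    """
    traj = integrate(params, (k, 0.0, 0.0, 0.0), _log_grid(t_end, n_points))
    summary: dict = {"final_z": float(traj.z[-1]), "k": k}
    try:
        summary["late_rate"] = phases.late_phase_rate(traj).rate
        summary["n_phases"] = phases.count_phases(traj)
    except phases.InsufficientHorizonError:
        summary["late_rate"] = None
        summary["n_phases"] = 1 if params.alpha == 0 else None
    return traj, summary


def priming_schedule(
    low: tuple[float, float],
    high: tuple[float, float],
    prime_window: tuple[float, float] = DEFAULT_PRIME_WINDOW,
    challenge_window: tuple[float, float] = DEFAULT_CHALLENGE_WINDOW,
    with_priming: bool = True,
) -> RadiationSchedule:
    """Two-pulse schedule; the unprimed arm keeps the priming segment with
    its beam off (``alpha = 0``) so both arms are otherwise identical."""
    (a0, a1), (b0, b1) = prime_window, challenge_window
    if not (a0 < a1 <= b0 < b1):
        raise ValueError(
            f"windows must be ordered and non-overlapping, got "
            f"{prime_window} and {challenge_window}"
        )
    alpha_low, p_low = low
    alpha_high, p_high = high
    return RadiationSchedule(
        segments=(
            ScheduleSegment(a0, a1, alpha_low if with_priming else 0.0, p_low),
            ScheduleSegment(b0, b1, alpha_high, p_high),
        ),
        default_p=p_low,
    )


@dataclass(frozen=True)
class PrimingResult:
    primed: Trajectory
    unprimed: Trajectory
    z_primed: float
    z_unprimed: float

    @property
    def ratio(self) -> float:
        """Altered cells with priming over altered cells without."""
        if self.z_unprimed == 0.0:
            raise ZeroDivisionError("no altered cells in the unprimed arm")
        return self.z_primed / self.z_unprimed


def priming_challenge(
    params: ModelParams,
    low: tuple[float, float],
    high: tuple[float, float],
    prime_window: tuple[float, float] = DEFAULT_PRIME_WINDOW,
    challenge_window: tuple[float, float] = DEFAULT_CHALLENGE_WINDOW,
    t_end: float = DEFAULT_READOUT,
    k: float = DEFAULT_K,
    n_points: int = 201,
) -> PrimingResult:
    """Run the primed and unprimed arms and read z at ``t_end``.

    ``low`` and ``high`` are ``(alpha, p)`` pairs for the priming and
    challenge exposures; ``params`` supplies everything else (model variant,
    c, eta, communication rates).
    """
    grid = np.linspace(0.0, t_end, n_points)
    arms = {}
    for primed in (True, False):
        sched = priming_schedule(low, high, prime_window, challenge_window,
                                 with_priming=primed)
        arms[primed] = integrate(params, (k, 0.0, 0.0, 0.0), grid, schedule=sched)
    return PrimingResult(
        primed=arms[True], unprimed=arms[False],
        z_primed=float(arms[True].z[-1]), z_unprimed=float(arms[False].z[-1]),
    )


def priming_ratio(
    params: ModelParams,
    n: float,
    low: tuple[float, float] = (0.1, 0.05),
    alpha_high: float = 100.0,
    **kwargs,
) -> float:
    """Ratio z_primed / z_unprimed when the challenge kill probability is
    ``n``-fold the priming one (capped at 1 with a warning)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    alpha_low, p_low = low
    p_high = n * p_low
    if p_high > 1.0:
        warnings.warn(
            f"n * p_low = {p_high:.3g} exceeds 1; capping the challenge kill "
            "probability at 1", stacklevel=2,
        )
        p_high = 1.0
    res = priming_challenge(params, (alpha_low, p_low), (alpha_high, p_high), **kwargs)
    return res.ratio


@dataclass(frozen=True)
class PrimingRatioCurve:
    table: pd.DataFrame          # columns n, ratio
    n_star: float | None         # grid-interpolated crossing of ratio = 1

    @property
    def crosses(self) -> bool:
        return self.n_star is not None


def priming_ratio_curve(
    params: ModelParams,
    n_values=tuple(range(1, 21)),
    low: tuple[float, float] = (0.1, 0.05),
    alpha_high: float = 100.0,
    **kwargs,
) -> PrimingRatioCurve:
    """Priming ratio over a grid of fold-increases ``n`` of the kill probability.

    The threshold ``n_star`` where the ratio crosses 1 is located by linear
    interpolation between the bracketing grid points (a grid point landing
    exactly on 1 reports that ``n``).
    """
    n_values = np.asarray(sorted(n_values), dtype=float)
    if n_values.size == 0 or n_values[0] < 1:
        raise ValueError("n_values must be >= 1 and non-empty")
    ratios = np.array([
        priming_ratio(params, n, low=low, alpha_high=alpha_high, **kwargs)
        for n in n_values
    ])
    table = pd.DataFrame({"n": n_values, "ratio": ratios})
    n_star = None
    for i in range(n_values.size):
        if ratios[i] == 1.0:
            n_star = float(n_values[i])
            break
        if i and (ratios[i - 1] - 1.0) * (ratios[i] - 1.0) < 0:
            f0, f1 = ratios[i - 1] - 1.0, ratios[i] - 1.0
            n_star = float(n_values[i - 1] + (n_values[i] - n_values[i - 1]) * f0 / (f0 - f1))
            break
    return PrimingRatioCurve(table=table, n_star=n_star)


def ratio_threshold_bisect(
    params: ModelParams,
    bracket: tuple[float, float],
    low: tuple[float, float] = (0.1, 0.05),
    alpha_high: float = 100.0,
    xtol: float = 1e-3,
    **kwargs,
) -> float:
    """Locate the ratio = 1 threshold by bisection on the same simulator."""
    return float(brentq(
        lambda n: priming_ratio(params, n, low=low, alpha_high=alpha_high, **kwargs) - 1.0,
        *bracket, xtol=xtol,
    ))


@dataclass(frozen=True)
class ProtectionEquilibrium:
    persistent: bool            # protected pool maintained (no decay to 0)
    x_inf: float
    w_inf: float
    predicted_x_inf: float | None  # eta / beta1 at an interior equilibrium
    trajectory: Trajectory


def persistent_protection_equilibrium(
    params: ModelParams,
    prime_window: tuple[float, float] = DEFAULT_PRIME_WINDOW,
    alpha_prime: float = 0.1,
    t_end: float = 2000.0,
    k: float = DEFAULT_K,
    extinction_tol: float = 1e-6,
) -> ProtectionEquilibrium:
    """Post-priming fate of the protected pool.

    With adapted-to-healthy communication (``beta1 > 0``) the protected
    population behaves like an endemic infection once the beam is off: the
    balance of induction (``beta1 * x * w``) and loss (``eta * w``) holds
    ``w`` at an interior equilibrium with ``x_inf = eta / beta1``. With
    ``beta1 = 0`` protection wanes as ``exp(-eta * t)`` and the run reports
    extinction instead.
    """
    sched = RadiationSchedule(
        segments=(ScheduleSegment(*prime_window, alpha_prime, params.p),),
        default_p=params.p,
    )
    grid = np.concatenate([
        np.linspace(0.0, prime_window[1], 51),
        np.geomspace(prime_window[1] * 1.5, t_end, 300),
    ])
    traj = integrate(params, (k, 0.0, 0.0, 0.0), grid, schedule=sched)
    x_inf, w_inf = float(traj.x[-1]), float(traj.w[-1])
    persistent = w_inf > extinction_tol * k
    predicted = params.eta / params.beta1 if (params.beta1 > 0 and persistent) else None
    return ProtectionEquilibrium(
        persistent=persistent, x_inf=x_inf, w_inf=w_inf,
        predicted_x_inf=predicted, trajectory=traj,
    )
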