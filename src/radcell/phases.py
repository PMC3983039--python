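"""Decline-phase detection for the unaltered population ``u = x + y + w``.

Under continuous exposure the memory model shows two phases of decline of
``u`` (a short fast transient, then a slow phase at the dominant eigenvalue
of the linearized subsystem). The communication model can interpose a third,
much slower phase -- the quasi-stationary state (QSS) -- in which the
unaltered population is practically stable before the final decline sets in.

Phases are defined operationally: windowed least-squares slopes of
``ln u(t)``, a final-phase rate measured over the last decade of decline,
and a relative threshold ``theta`` below which a window counts as
quasi-stationary. The thresholds are explicit and configurable because the
phenomena are qualitative.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ModelParams, Trajectory, asymptotic_decline_rate

__all__ = [
    "log_slope_profile",
    "late_phase_rate",
    "qss_metrics",
    "count_phases",
    "QssMetrics",
    "LatePhaseRate",
    "InsufficientHorizonError",
    "phase_report",
]

#: fraction of the initial population below which u is considered numerically
#: extinct and excluded from slope analysis
U_FLOOR_REL = 1e-8

#: slopes of magnitude below this are treated as "no decline"
ZERO_SLOPE = 1e-12


class InsufficientHorizonError(RuntimeError):
    """The trajectory does not reach the requested decline phase."""


def _valid_mask(traj: Trajectory, floor_rel: float = U_FLOOR_REL) -> np.ndarray:
    return traj.unaltered > floor_rel * traj.k


def log_slope_profile(traj: Trajectory, window: int = 5,
                      floor_rel: float = U_FLOOR_REL) -> pd.DataFrame:
    """Sliding-window least-squares slopes of ``ln u`` versus time.

    Windows where ``u`` has reached the numerical floor are truncated.
    Returns a frame with columns ``t`` (window centre) and ``slope``.
    """
    if window < 2:
        raise ValueError("window must span at least 2 points")
    mask = _valid_mask(traj, floor_rel)
    t = traj.times[mask]
    lnu = np.log(traj.unaltered[mask])
    if t.size < window:
        raise InsufficientHorizonError("too few valid points for a slope window")
    centers, slopes = [], []
    for i in range(t.size - window + 1):
        ts, ys = t[i:i + window], lnu[i:i + window]
        slopes.append(np.polyfit(ts, ys, 1)[0])
        centers.append(ts.mean())
    return pd.DataFrame({"t": centers, "slope": slopes})


@dataclass(frozen=True)
class LatePhaseRate:
    rate: float                 # measured decline rate (>= 0)
    t_start: float              # start of the fitted tail window
    t_end: float
    oracle: float | None = None  # spectral rate, when params were supplied
    rel_err: float | None = None


def late_phase_rate(
    traj: Trajectory,
    params: ModelParams | None = None,
    decades: float = 1.0,
    floor_rel: float = U_FLOOR_REL,
) -> LatePhaseRate:
    """Decline rate of ``u`` measured over the final ``decades`` of decline.

    Fits ``ln u`` against ``t`` over the tail of the trajectory where ``u``
    lies within ``decades`` decades of its last valid value. When ``params``
    is given, the measured rate is compared against the spectral oracle
    :func:`radcell.model.asymptotic_decline_rate`.
    """
    mask = _valid_mask(traj, floor_rel)
    t = traj.times[mask]
    u = traj.unaltered[mask]
    if t.size < 3:
        raise InsufficientHorizonError("trajectory too short for a rate estimate")
    lnu = np.log(u)
    total_drop = lnu[0] - lnu[-1]
    span = decades * np.log(10.0)
    if total_drop < span:
        raise InsufficientHorizonError(
            f"final phase spans {total_drop / np.log(10.0):.2f} decades "
            f"< requested {decades}"
        )
    tail = lnu <= lnu[-1] + span
    if tail.sum() < 3:
        tail = np.zeros_like(tail)
        tail[-3:] = True
    slope = np.polyfit(t[tail], lnu[tail], 1)[0]
    rate = max(-slope, 0.0)
    oracle = rel = None
    if params is not None:
        oracle = asymptotic_decline_rate(params)
        rel = abs(rate - oracle) / oracle if oracle > 0 else abs(rate)
    return LatePhaseRate(rate=rate, t_start=float(t[tail][0]),
                         t_end=float(t[tail][-1]), oracle=oracle, rel_err=rel)


@dataclass(frozen=True)
class QssMetrics:
    present: bool
    t_start: float = np.nan
    t_end: float = np.nan
    duration: float = np.nan
    mid_rate: float = np.nan     # median |slope| inside the QSS window
    final_rate: float = np.nan   # reference rate the threshold is relative to


def qss_metrics(traj: Trajectory, theta: float = 0.1, window: int = 5,
                floor_rel: float = U_FLOOR_REL) -> QssMetrics:
    """Locate the quasi-stationary state, if any.

    The QSS is the maximal contiguous interval whose windowed log-slope
    magnitude stays below ``theta`` times the final-phase rate AND whose
    duration exceeds one e-folding time of the final phase -- a "prolonged"
    plateau must outlast the decline timescale it interrupts, which also
    rejects the short radiation-onset transient (where the slope is near
    zero simply because hit cells have not yet accumulated). Absence of a
    QSS is a result, not an error.
    """
    profile = log_slope_profile(traj, window=window, floor_rel=floor_rel)
    try:
        final = late_phase_rate(traj, floor_rel=floor_rel).rate
    except InsufficientHorizonError:
        return QssMetrics(present=False)
    if final <= ZERO_SLOPE:
        return QssMetrics(present=False, final_rate=final)
    slopes = profile["slope"].to_numpy()
    ts = profile["t"].to_numpy()
    slow = np.abs(slopes) <= theta * final
    min_span = 1.0 / final  # one e-folding time of the final decline
    best_span, best = min_span, None
    i = 0
    while i < slow.size:
        if slow[i]:
            j = i
            while j < slow.size and slow[j]:
                j += 1
            span = ts[j - 1] - ts[i]
            if span >= best_span:
                best_span, best = span, (i, j)
            i = j
        else:
            i += 1
    if best is None:
        return QssMetrics(present=False, final_rate=final)
    i, j = best
    mid = float(np.median(np.abs(profile["slope"].to_numpy()[i:j])))
    return QssMetrics(
        present=True, t_start=float(ts[i]), t_end=float(ts[j - 1]),
        duration=float(ts[j - 1] - ts[i]), mid_rate=mid, final_rate=final,
    )


def count_phases(traj: Trajectory, theta: float = 0.1, window: int = 5,
                 floor_rel: float = U_FLOOR_REL) -> int:
    """1 = no decline, 2 = two-phase decline, 3 = decline with a QSS."""
    profile = log_slope_profile(traj, window=window, floor_rel=floor_rel)
    if np.max(np.abs(profile["slope"])) <= ZERO_SLOPE:
        return 1
    return 3 if qss_metrics(traj, theta=theta, window=window,
                            floor_rel=floor_rel).present else 2


def phase_report(traj: Trajectory, theta: float = 0.1, window: int = 5) -> pd.DataFrame:
    """Tabular phase summary (phase_index, t_start, t_end, rate) for the CLI."""
    n = count_phases(traj, theta=theta, window=window)
    profile = log_slope_profile(traj, window=window)
    ts = profile["t"].to_numpy()
    sl = profile["slope"].to_numpy()
    rows = []
    if n == 1:
        rows.append((0, ts[0], ts[-1], float(np.median(-sl))))
    elif n == 2:
        final = late_phase_rate(traj)
        pre = ts < final.t_start
        if pre.any():
            rows.append((0, ts[0], float(ts[pre][-1]), float(np.median(-sl[pre]))))
        rows.append((1, final.t_start, final.t_end, final.rate))
    else:
        q = qss_metrics(traj, theta=theta, window=window)
        early = ts < q.t_start
        late = ts > q.t_end
        rows.append((0, ts[0], q.t_start, float(np.median(-sl[early])) if early.any() else np.nan))
        rows.append((1, q.t_start, q.t_end, q.mid_rate))
        rows.append((2, q.t_end, ts[-1], float(np.median(-sl[late])) if late.any() else q.final_rate))
    return pd.DataFrame(rows, columns=["phase_index", "t_start", "t_end", "rate"])
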