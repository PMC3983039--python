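"""Clonogenic dose-survival curves and HRS/IRR phase classification.

Survival is the unaltered fraction ``S/k = (x + y + w)/k`` read at the end
of the exposure, with the kill probability ``p`` held at its dose-dependent
value throughout. The cumulative dose is proportional to ``alpha * t``; two
exposure modes are supported:

* ``fixed_duration`` -- the exposure time is fixed and the dose sets the
  dose rate ``alpha`` (dose-rate experiments);
* ``fixed_rate`` -- the dose rate is fixed and the dose sets the exposure
  time (the regime of the fitted clonogenic datasets).

With a sufficiently increasing ``p(dose)`` the memory model produces the
experimentally observed three-phase log-survival curve: hyper-radiosensitive
(HRS) steep decline at the lowest doses, a shallow increased-radioresistance
(IRR) region, then a resumed, concave-down decline whose slope stays below
the HRS slope. A constant ``p`` or the communication model produce no such
signature.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import ModelParams, Trajectory, integrate, linear_unaltered_fraction

__all__ = [
    "DoseMapping",
    "p_of_dose",
    "survival_fraction",
    "DoseResponseCurve",
    "dose_response_curve",
    "classify_phases",
    "PhaseClassification",
    "hrs_irr_mapping",
    "DEFAULT_HRS_GRID",
]

#: default dose grid for dose-rate-mode curves; stops while p(d) is still
#: well below 1 -- once the kill probability saturates, survival collapses
#: and the log-slope diverges, outside the regime the phenomena describe
DEFAULT_HRS_GRID = np.geomspace(1e-3, 0.6, 60)


@dataclass(frozen=True)
class DoseMapping:
    """How reported dose translates into exposure (alpha, duration) and p.

    ``p(d)`` is ``min(p0 + p1*d, 1)`` for the linear form and
    ``p1*d/(d + p0)`` for the saturating form (``p1 <= 1``). ``dose_scale``
    links model dose ``alpha*t`` to reported dose units (default 1, the
    model's arbitrary units).
    """

    form: str                      # "linear" | "saturating"
    p0: float
    p1: float
    mode: str                      # "fixed_duration" | "fixed_rate"
    duration: float | None = None  # exposure time, fixed_duration mode
    dose_rate: float | None = None  # alpha, fixed_rate mode
    dose_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.form not in ("linear", "saturating"):
            raise ValueError(f"unknown p(dose) form {self.form!r}")
        if self.mode not in ("fixed_duration", "fixed_rate"):
            raise ValueError(f"unknown exposure mode {self.mode!r}")
        if self.p0 < 0 or self.p1 < 0:
            raise ValueError("p0 and p1 must be >= 0")
        if self.form == "saturating" and self.p1 > 1:
            raise ValueError("saturating form requires p1 <= 1 (its plateau)")
        if self.dose_scale <= 0:
            raise ValueError("dose_scale must be > 0")
        if self.mode == "fixed_duration" and not (self.duration and self.duration > 0):
            raise ValueError("fixed_duration mode requires duration > 0")
        if self.mode == "fixed_rate" and not (self.dose_rate and self.dose_rate > 0):
            raise ValueError("fixed_rate mode requires dose_rate > 0")

    def p_of_dose(self, dose: float) -> float:
        if dose < 0:
            raise ValueError("dose must be >= 0")
        if self.form == "linear":
            return min(self.p0 + self.p1 * dose, 1.0)
        return self.p1 * dose / (dose + self.p0) if dose > 0 else 0.0

    def exposure(self, dose: float) -> tuple[float, float]:
        """(alpha, duration) delivering ``dose`` in this mode."""
        if dose < 0:
            raise ValueError("dose must be >= 0")
        if self.mode == "fixed_duration":
            return dose / (self.duration * self.dose_scale), self.duration
        return self.dose_rate, dose / (self.dose_rate * self.dose_scale)

    def replace(self, **kwargs) -> "DoseMapping":
        import dataclasses
        return dataclasses.replace(self, **kwargs)


def p_of_dose(dose: float, mapping: DoseMapping) -> float:
    """Dose-dependent kill probability (module-level convenience)."""
    return mapping.p_of_dose(dose)


def hrs_irr_mapping(p0: float = 0.4, p1: float = 0.55,
                    duration: float = 150.0) -> DoseMapping:
    """Linear-in-dose-rate kill probability with a fixed exposure time,
    the configuration that produces the HRS/IRR signature."""
    # dose_scale = 1/duration makes the reported dose axis equal alpha,
    # so p(dose) = p0 + p1*alpha
    return DoseMapping(form="linear", p0=p0, p1=p1, mode="fixed_duration",
                       duration=duration, dose_scale=1.0 / duration)


def survival_fraction(
    params: ModelParams,
    mapping: DoseMapping,
    dose: float,
    k: float = 100.0,
    method: str = "ode",
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> tuple[float, float]:
    """Surviving fraction and its log at the end of one exposure.

    ``params`` supplies the model variant and the constants the mapping does
    not control (c, eta, memory, communication rates). ``method="linear"``
    uses the matrix-exponential solution (communication-free models only).
    """
    if dose < 0:
        raise ValueError("dose must be >= 0")
    if dose == 0.0:
        return 1.0, 0.0
    alpha, t_exp = mapping.exposure(dose)
    pr = params.replace(alpha=alpha, p=mapping.p_of_dose(dose))
    if method == "linear":
        frac = float(linear_unaltered_fraction(pr, [t_exp])[0])
    elif method == "ode":
        traj = integrate(pr, (k, 0.0, 0.0, 0.0), np.linspace(0.0, t_exp, 11),
                         rtol=rtol, atol=atol)
        frac = float(traj.unaltered[-1] / k)
    else:
        raise ValueError(f"unknown method {method!r}")
    frac = min(max(frac, 1e-300), 1.0)
    return frac, float(np.log(frac))


@dataclass
class DoseResponseCurve:
    doses: np.ndarray
    surviving_fraction: np.ndarray
    ln_surviving_fraction: np.ndarray
    phase_labels: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame({
            "dose": self.doses,
            "surviving_fraction": self.surviving_fraction,
            "ln_surviving_fraction": self.ln_surviving_fraction,
        })
        if self.phase_labels:
            frame["phase_label"] = self.phase_labels
        return frame


def dose_response_curve(
    params: ModelParams,
    mapping: DoseMapping,
    dose_grid=None,
    k: float = 100.0,
    method: str | None = None,
) -> DoseResponseCurve:
    """Survival curve over a dense dose grid (deterministic given params).

    The grid should be dense enough for slope estimation (>= 50 points,
    log-spaced recommended). The fast linear path is used automatically for
    communication-free models unless ``method`` overrides it.
    """
    doses = DEFAULT_HRS_GRID if dose_grid is None else np.asarray(dose_grid, float)
    if doses.size < 2 or np.any(np.diff(doses) <= 0):
        raise ValueError("dose_grid must be strictly increasing with >= 2 points")
    if method is None:
        method = "linear" if params.is_linear else "ode"
    fracs = np.empty(doses.size)
    for i, d in enumerate(doses):
        fracs[i], _ = survival_fraction(params, mapping, float(d), k=k, method=method)
    return DoseResponseCurve(
        doses=doses, surviving_fraction=fracs,
        ln_surviving_fraction=np.log(fracs),
    )


@dataclass(frozen=True)
class PhaseClassification:
    s_hrs: float        # max-|.| slope in the lowest-dose decile
    s_irr: float        # min-|.| slope between the HRS region and final decile
    s_high: float       # least-squares slope over the final decile
    has_signature: bool  # |s_hrs| > |s_high| > |s_irr| with margin
    d_hrs_end: float    # dose at the end of the HRS decile
    d_irr: float        # dose of the IRR (shallowest) point


def classify_phases(
    curve: DoseResponseCurve,
    window: int = 5,
    margin: float = 1.05,
) -> PhaseClassification:
    """Segment the log-survival curve into HRS / IRR / high-dose slopes.

    Slopes are moving-window least-squares fits of ln S versus dose (the
    windowing doubles as smoothing). The HRS and high-dose regions are the
    first and last deciles of the grid; the IRR slope is the shallowest
    window in between. The signature requires the slope-magnitude ordering
    |s_HRS| > |s_high| > |s_IRR| with a small relative ``margin`` so that a
    straight-line curve (all slopes equal to round-off) does not qualify.
    An ambiguous curve yields ``has_signature=False``, never an exception.
    """
    d = curve.doses
    lnS = curve.ln_surviving_fraction
    n = d.size
    if n < max(2 * window, 10):
        raise ValueError("curve too short to classify; use a denser grid")
    centers = np.empty(n - window + 1)
    slopes = np.empty(n - window + 1)
    for i in range(slopes.size):
        slopes[i] = np.polyfit(d[i:i + window], lnS[i:i + window], 1)[0]
        centers[i] = d[i:i + window].mean()
    dec = max(n // 10, 2)
    lo_end_dose = d[dec - 1]
    hi_start_dose = d[n - dec]
    lo = centers <= lo_end_dose
    hi = centers >= hi_start_dose
    mid = ~lo & ~hi
    if not lo.any():  # window wider than the decile: use the first window
        lo = np.zeros_like(lo)
        lo[0] = True
        mid = ~lo & ~hi
    s_hrs = slopes[lo][np.argmax(np.abs(slopes[lo]))]
    s_high = float(np.polyfit(d[n - dec:], lnS[n - dec:], 1)[0])
    if mid.any():
        i_irr = np.argmin(np.abs(slopes[mid]))
        s_irr = slopes[mid][i_irr]
        d_irr = centers[mid][i_irr]
    else:
        s_irr, d_irr = s_high, float(d[-1])
    signature = abs(s_hrs) > margin * abs(s_high) > margin ** 2 * abs(s_irr)
    labels = []
    for dose in d:
        if dose <= lo_end_dose:
            labels.append("HRS")
        elif dose >= hi_start_dose:
            labels.append("high-dose")
        else:
            labels.append("IRR" if signature else "decline")
    curve.phase_labels = labels
    return PhaseClassification(
        s_hrs=float(s_hrs), s_irr=float(s_irr), s_high=s_high,
        has_signature=bool(signature), d_hrs_end=float(lo_end_dose),
        d_irr=float(d_irr),
    )
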