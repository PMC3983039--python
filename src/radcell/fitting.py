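"""Least-squares fitting of the memory model to dose-survival data.

The fit estimates ``(alpha, eta, p0, p1)`` with the repair-resolution rate
``c`` fixed at 1 (it would otherwise be non-identifiable with alpha's time
scale). Residuals live in ln-survival space, weighted by ``1/se`` when
per-point standard errors are present. The exposure follows the clonogenic
regime: constant dose rate, duration set by the dose (``fixed_rate`` mode),
kill probability from the saturating (or linear) dose mapping.

The objective is multi-modal in (p0, p1), so the optimizer is a best-of-n
multi-start trust-region reflective least squares with log-uniform starts
drawn inside the bounds from a caller-supplied seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .dose_response import DoseMapping
from .model import linear_unaltered_fraction, memory_model

__all__ = [
    "DoseSurvivalDataset",
    "FormatError",
    "read_dose_survival_csv",
    "write_dose_survival_csv",
    "predict_ln_survival",
    "objective",
    "fit_memory_model",
    "FitResult",
    "summarize_estimates",
    "DEFAULT_BOUNDS",
    "PARAM_NAMES",
]

PARAM_NAMES = ("alpha", "eta", "p0", "p1")

DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "alpha": (1e-3, 1e3),
    "eta": (1e-4, 10.0),
    "p0": (1e-3, 1e2),
    "p1": (1e-3, 1.0),
}

#: survival predictions are floored here before taking logs, which acts as a
#: large but finite penalty when a parameter set annihilates the population
SURVIVAL_FLOOR = 1e-12


class FormatError(ValueError):
    """A dose-survival table violates the expected schema."""


@dataclass(frozen=True)
class DoseSurvivalDataset:
    """Observed clonogenic survival: dose (Gy), surviving fraction, optional se."""

    frame: pd.DataFrame
    label: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        f = self.frame
        required = {"dose", "surviving_fraction"}
        missing = required - set(f.columns)
        if missing:
            raise FormatError(f"missing columns: {sorted(missing)}")
        for col in f.columns:
            if col in ("dose", "surviving_fraction", "se"):
                if not np.issubdtype(f[col].dtype, np.number):
                    bad = f[~f[col].apply(lambda v: isinstance(v, (int, float)))].index
                    row = int(bad[0]) if len(bad) else 0
                    raise FormatError(f"non-numeric value in column {col!r} at row {row}")
        for i, rec in f.iterrows():
            if rec["dose"] < 0:
                raise FormatError(f"negative dose at row {i}")
            if not 0.0 < rec["surviving_fraction"] <= 1.0:
                raise FormatError(
                    f"surviving_fraction outside (0, 1] at row {i}: "
                    f"{rec['surviving_fraction']}"
                )
            if "se" in f.columns and rec["se"] <= 0:
                raise FormatError(f"non-positive se at row {i}")
        frame = f.sort_values("dose").reset_index(drop=True)
        if np.any(np.diff(frame["dose"].to_numpy()) <= 0):
            raise FormatError("doses must be strictly increasing after sorting")
        object.__setattr__(self, "frame", frame)

    @property
    def doses(self) -> np.ndarray:
        return self.frame["dose"].to_numpy(dtype=float)

    @property
    def surviving_fraction(self) -> np.ndarray:
        return self.frame["surviving_fraction"].to_numpy(dtype=float)

    @property
    def se(self) -> np.ndarray | None:
        if "se" in self.frame.columns:
            return self.frame["se"].to_numpy(dtype=float)
        return None

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other) -> bool:
        if not isinstance(other, DoseSurvivalDataset):
            return NotImplemented
        return self.label == other.label and self.frame.equals(other.frame)


def read_dose_survival_csv(path) -> DoseSurvivalDataset:
    path = Path(path)
    frame = pd.read_csv(path, float_precision="round_trip")
    try:
        return DoseSurvivalDataset(frame=frame, label=path.stem)
    except FormatError as err:
        raise FormatError(f"{path}: {err}") from None


def write_dose_survival_csv(dataset: DoseSurvivalDataset, path) -> None:
    # %.17g keeps doubles exactly round-trippable through the CSV
    dataset.frame.to_csv(path, index=False, float_format="%.17g")


def _mapping_for(theta: np.ndarray, mapping: DoseMapping) -> DoseMapping:
    alpha, _eta, p0, p1 = theta
    return mapping.replace(p0=float(p0), p1=float(p1), dose_rate=float(alpha))


def predict_ln_survival(
    theta,
    doses,
    mapping: DoseMapping,
    c: float = 1.0,
) -> np.ndarray:
    """Model ln surviving fraction at each dose for theta = (alpha, eta, p0, p1).

    Computed with the exact matrix-exponential solution of the linear memory
    model, which makes the multi-start fit cheap.
    """
    theta = np.asarray(theta, dtype=float)
    alpha, eta = theta[0], theta[1]
    m = _mapping_for(theta, mapping)
    if m.mode != "fixed_rate":
        raise ValueError("fitting assumes fixed_rate exposure (clonogenic regime)")
    out = np.empty(len(doses))
    for i, d in enumerate(doses):
        if d == 0.0:
            out[i] = 0.0
            continue
        _, t_exp = m.exposure(float(d))
        pr = memory_model(alpha=alpha, p=m.p_of_dose(float(d)), c=c, eta=eta)
        u = float(linear_unaltered_fraction(pr, [t_exp])[0])
        out[i] = np.log(max(u, SURVIVAL_FLOOR))
    return out


def _residuals(theta, dataset: DoseSurvivalDataset, mapping: DoseMapping,
               c: float = 1.0) -> np.ndarray:
    pred = predict_ln_survival(theta, dataset.doses, mapping, c=c)
    res = pred - np.log(dataset.surviving_fraction)
    se = dataset.se
    if se is not None:
        res = res / se
    return res


def objective(theta, dataset: DoseSurvivalDataset, mapping: DoseMapping,
              c: float = 1.0) -> float:
    """Sum of squared (weighted) ln-survival residuals."""
    r = _residuals(np.asarray(theta, float), dataset, mapping, c=c)
    return float(r @ r)


@dataclass(frozen=True)
class FitResult:
    params: dict[str, float]
    objective: float
    residuals: np.ndarray
    converged: bool
    best_start: int
    n_starts: int
    seed: int
    fixed: dict[str, float] = field(default_factory=dict)
    trace: np.ndarray | None = None  # running-best objective over evaluations

    def __getitem__(self, name: str) -> float:
        return self.params[name]


def fit_memory_model(
    dataset: DoseSurvivalDataset,
    mapping: DoseMapping,
    bounds: dict[str, tuple[float, float]] | None = None,
    n_starts: int = 10,
    seed: int = 0,
    c: float = 1.0,
    tol: float = 1e-10,
) -> FitResult:
    """Best-of-``n_starts`` bounded local least squares; deterministic given seed.

    Starts are drawn log-uniform within the bounds. Raises if the dataset
    has fewer than 5 records (four free parameters) or if every start fails.
    """
    if len(dataset) < 5:
        raise ValueError(
            f"need >= 5 dose-survival records to fit 4 parameters, got {len(dataset)}"
        )
    bounds = {**DEFAULT_BOUNDS, **(bounds or {})}
    lb = np.log10([bounds[nm][0] for nm in PARAM_NAMES])
    ub = np.log10([bounds[nm][1] for nm in PARAM_NAMES])
    rng = np.random.default_rng(seed)
    starts = rng.uniform(lb, ub, size=(n_starts, 4))

    history: list[float] = []

    def resid_log(u):
        r = _residuals(10.0 ** u, dataset, mapping, c=c)
        history.append(float(r @ r))
        return r

    best = None
    best_idx = -1
    failures = []
    for idx, u0 in enumerate(starts):
        try:
            res = least_squares(resid_log, u0, bounds=(lb, ub),
                                xtol=tol, ftol=tol, gtol=tol)
        except Exception as err:  # singular Jacobian etc.
            failures.append(f"start {idx}: {err}")
            continue
        if best is None or res.cost < best.cost:
            best, best_idx = res, idx
    if best is None:
        raise RuntimeError(
            "all optimization starts failed:\n" + "\n".join(failures)
        )
    theta = 10.0 ** best.x
    return FitResult(
        params=dict(zip(PARAM_NAMES, map(float, theta))),
        objective=float(2.0 * best.cost),  # least_squares cost = 0.5 * sum r^2
        residuals=_residuals(theta, dataset, mapping, c=c),
        converged=bool(best.status > 0),
        best_start=best_idx,
        n_starts=n_starts,
        seed=seed,
        fixed={"c": c},
        trace=np.minimum.accumulate(history),
    )


def summarize_estimates(fit_results) -> pd.DataFrame:
    """Quartile/range/CV summary per parameter across a panel of fits."""
    fit_results = list(fit_results)
    if len(fit_results) < 2:
        raise ValueError("need at least 2 fit results to summarize spread")
    rows = []
    for nm in PARAM_NAMES:
        vals = np.array([fr.params[nm] for fr in fit_results])
        rows.append({
            "parameter": nm,
            "median": np.median(vals),
            "q1": np.quantile(vals, 0.25),
            "q3": np.quantile(vals, 0.75),
            "min": vals.min(),
            "max": vals.max(),
            "cv": vals.std(ddof=1) / vals.mean() if vals.mean() != 0 else np.nan,
        })
    return pd.DataFrame(rows).set_index("parameter")
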