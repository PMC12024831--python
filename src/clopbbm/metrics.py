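"""PK-metric extraction and prediction-validation arithmetic.

Metrics: Cmax/tmax from the sampled maximum, AUC(0-t) by linear trapezoid,
AUC(0-inf) = AUC(0-t) + Clast/lambda_z, with lambda_z either supplied
analytically (terminal disposition eigenvalue) or estimated by log-linear
regression on the terminal descending points (last 3, extended while the
tail R^2 improves).

Validation: fold error = predicted/observed, with the conventional
acceptance window 0.5 <= FE <= 2.0 (bounds inclusive), and percent
improvement 100*(test - reference)/reference for formulation comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "PKMetrics",
    "ValidationRecord",
    "pk_metrics",
    "fold_error",
    "two_fold_validation",
    "percent_improvement",
    "ExtrapolationError",
]


class ExtrapolationError(RuntimeError):
    """No usable terminal phase for AUC extrapolation."""


@dataclass(frozen=True)
class PKMetrics:
    Cmax: float        # ng/mL
    tmax: float        # h
    AUC_0_t: float     # ng*h/mL
    AUC_0_inf: float   # ng*h/mL
    t_half: float      # h

    def __post_init__(self) -> None:
        if self.Cmax < 0 or self.AUC_0_t < 0:
            raise ValueError("negative Cmax/AUC")
        if self.AUC_0_inf + 1e-12 < self.AUC_0_t:
            raise ValueError("AUC_0_inf must be >= AUC_0_t")

    def to_dict(self) -> dict:
        return {
            "Cmax": self.Cmax, "tmax": self.tmax,
            "AUC_0_t": self.AUC_0_t, "AUC_0_inf": self.AUC_0_inf,
            "t_half": self.t_half,
        }


@dataclass(frozen=True)
class ValidationRecord:
    parameter: str
    predicted: float
    observed: float
    fold_error: float
    within_two_fold: bool


def _terminal_lambda_z(times: np.ndarray, conc: np.ndarray) -> float:
    """Log-linear regression on the terminal descending tail.

    Starts from the last 3 positive post-peak points and extends backwards
    while the regression R^2 improves.
    """
    i_max = int(np.argmax(conc))
    t_tail = times[i_max:]
    c_tail = conc[i_max:]
    pos = c_tail > 0
    t_tail, c_tail = t_tail[pos], c_tail[pos]
    if t_tail.size < 3:
        raise ExtrapolationError("fewer than 3 positive points after Cmax")
    logc = np.log(c_tail)

    def fit(k: int) -> tuple[float, float]:
        x, y = t_tail[-k:], logc[-k:]
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
        return slope, r2

    best_slope, best_r2 = fit(3)
    for k in range(4, t_tail.size + 1):
        slope, r2 = fit(k)
        if r2 >= best_r2 - 1e-12:
            best_slope, best_r2 = slope, r2
        else:
            break
    if best_slope >= 0:
        raise ExtrapolationError("no descending terminal phase")
    return -best_slope


def pk_metrics(
    times: Sequence[float],
    conc: Sequence[float],
    lambda_z: Optional[float] = None,
) -> PKMetrics:
    """PK metrics from a concentration-time curve (times h, conc ng/mL).

    ``lambda_z`` may be supplied analytically (the smallest-magnitude
    disposition eigenvalue); otherwise it is regressed from the tail.
    An all-zero profile returns zero metrics with a warning.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(conc, dtype=float)
    if t.size < 3 or t.size != c.size:
        raise ValueError("need matching times/conc with >= 3 points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.any(c < 0):
        raise ValueError("concentrations must be >= 0")
    if np.all(c == 0):
        warnings.warn("all-zero concentration profile; metrics are zero")
        return PKMetrics(0.0, float(t[0]), 0.0, 0.0, float("nan"))
    i_max = int(np.argmax(c))
    auc_t = float(np.trapezoid(c, t))
    lz = float(lambda_z) if lambda_z is not None else _terminal_lambda_z(t, c)
    if lz <= 0:
        raise ExtrapolationError("lambda_z must be > 0")
    auc_inf = auc_t + float(c[-1]) / lz
    return PKMetrics(
        Cmax=float(c[i_max]), tmax=float(t[i_max]),
        AUC_0_t=auc_t, AUC_0_inf=auc_inf, t_half=float(np.log(2) / lz),
    )


def fold_error(predicted: float, observed: float) -> float:
    """Fold error = predicted / observed (observed must be > 0)."""
    if observed <= 0:
        raise ValueError("observed must be > 0")
    if predicted < 0:
        raise ValueError("predicted must be >= 0")
    return predicted / observed


def two_fold_validation(
    records: Iterable[tuple[str, float, float]]
) -> list[ValidationRecord]:
    """Fold error and the inclusive two-fold acceptance flag per record."""
    out = []
    for parameter, predicted, observed in records:
        fe = fold_error(predicted, observed)
        out.append(ValidationRecord(
            parameter=parameter, predicted=predicted, observed=observed,
            fold_error=fe, within_two_fold=bool(0.5 <= fe <= 2.0),
        ))
    return out


def percent_improvement(test: float, reference: float) -> float:
    """100 * (test - reference) / reference.  Ratio-based, not symmetric."""
    if reference <= 0:
        raise ValueError("reference must be > 0")
    return 100.0 * (test - reference) / reference
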