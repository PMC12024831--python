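"""Dissolution-kinetics model fitting for cumulative release profiles.

Five classical release models are supported:

========================  =============================================
zero_order                F(t) = k0 * t
first_order               F(t) = Fmax * (1 - exp(-k1 * t))
higuchi                   F(t) = kH * sqrt(t)
korsmeyer_peppas          F(t) = kKP * t**n
hixson_crowell            W0**(1/3) - Wt**(1/3) = kHC * t  (cube-root law)
========================  =============================================

with F the cumulative percent released and, unless an Fmax is fitted,
F_inf = 100%.  Fits are nonlinear least squares on the untransformed
percent-released values (linearization distorts the error weighting; a
``linearized=True`` switch reproduces the classical log-log
Korsmeyer-Peppas fit for comparison).  Goodness of fit is the coefficient
of determination R^2 = 1 - SSres/SStot on the points used.

The Korsmeyer-Peppas diffusional exponent n classifies the release
mechanism for cylindrical/matrix systems: n <= 0.45 Fickian diffusion,
0.45 < n <= 0.89 anomalous transport, n > 0.89 case-II / erosion
controlled release.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "ReleaseModel",
    "Mechanism",
    "DissolutionProfile",
    "ReleaseModelFit",
    "predict_release",
    "fit_release_model",
    "fit_all_models",
    "classify_mechanism",
]


class FitError(RuntimeError):
    """Model fit could not be computed (too few points, non-convergence)."""


class ReleaseModel(str, Enum):
    # enum order is the deterministic tie-break order for equal R^2
    zero_order = "zero_order"
    first_order = "first_order"
    higuchi = "higuchi"
    korsmeyer_peppas = "korsmeyer_peppas"
    hixson_crowell = "hixson_crowell"


class Mechanism(str, Enum):
    fickian_diffusion = "fickian_diffusion"
    anomalous_transport = "anomalous_transport"
    case_II_or_erosion = "case_II_or_erosion"


#: number of free parameters per model (Fmax fitting adds one)
_N_PARAMS = {
    ReleaseModel.zero_order: 1,
    ReleaseModel.first_order: 1,
    ReleaseModel.higuchi: 1,
    ReleaseModel.korsmeyer_peppas: 2,
    ReleaseModel.hixson_crowell: 1,
}


@dataclass(frozen=True)
class DissolutionProfile:
    """Time-stamped cumulative percent-released profile.

    Times in minutes (strictly increasing, first >= 0); values in percent
    of dose.  Small negatives / overshoot above 100% are tolerated as assay
    noise (within [-2, 105]) but flagged via ``noise_flagged``.
    """

    times: tuple[float, ...]
    released: tuple[float, ...]
    stage_pH: Optional[tuple[float, ...]] = None
    formulation_id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        f = np.asarray(self.released, dtype=float)
        if t.size != f.size or t.size < 3:
            raise ValueError("need matching times/released with >= 3 points")
        if t[0] < 0 or np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing and start >= 0")
        if np.any(f < -2.0) or np.any(f > 105.0):
            raise ValueError("released values outside the tolerated [-2, 105] band")
        if self.stage_pH is not None and len(self.stage_pH) != t.size:
            raise ValueError("stage_pH length must match times")

    @classmethod
    def from_arrays(cls, times, released, stage_pH=None, formulation_id="") -> "DissolutionProfile":
        return cls(
            times=tuple(float(x) for x in times),
            released=tuple(float(x) for x in released),
            stage_pH=None if stage_pH is None else tuple(float(x) for x in stage_pH),
            formulation_id=formulation_id,
        )

    @property
    def t(self) -> np.ndarray:
        return np.asarray(self.times, dtype=float)

    @property
    def f(self) -> np.ndarray:
        return np.asarray(self.released, dtype=float)

    @property
    def noise_flagged(self) -> bool:
        """True if any point is negative or exceeds 100% (assay noise)."""
        f = self.f
        return bool(np.any(f < 0) or np.any(f > 100.0))


@dataclass(frozen=True)
class ReleaseModelFit:
    model: ReleaseModel
    params: dict
    r_squared: float
    n_points_used: int
    converged: bool = True
    message: str = ""

    def __post_init__(self) -> None:
        if self.r_squared > 1.0 + 1e-12:
            raise ValueError("r_squared cannot exceed 1")
        for name, v in self.params.items():
            if name == "n":
                if not (0 < v <= 3.0):
                    raise ValueError(f"KP exponent n={v} outside (0, 3]")
            elif v < 0:
                raise ValueError(f"negative rate constant {name}={v}")


def _eval_model(model: ReleaseModel, params: dict, t: np.ndarray) -> np.ndarray:
    fmax = params.get("Fmax", 100.0)
    if model is ReleaseModel.zero_order:
        return params["k0"] * t
    if model is ReleaseModel.first_order:
        return fmax * (1.0 - np.exp(-params["k1"] * t))
    if model is ReleaseModel.higuchi:
        return params["kH"] * np.sqrt(t)
    if model is ReleaseModel.korsmeyer_peppas:
        with np.errstate(invalid="ignore"):
            out = params["kKP"] * np.power(t, params["n"])
        return np.where(t == 0, 0.0, out)
    if model is ReleaseModel.hixson_crowell:
        w0 = fmax
        root = np.cbrt(w0) - params["kHC"] * t
        return np.where(root > 0, w0 - root**3, w0)
    raise ValueError(model)


def predict_release(fit: ReleaseModelFit, times, clip: bool = False) -> np.ndarray:
    """Evaluate the fitted model's closed form at the given times (min)."""
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be >= 0")
    out = _eval_model(fit.model, fit.params, t)
    if clip:
        out = np.minimum(out, 100.0)
    return out


def _r_squared(obs: np.ndarray, pred: np.ndarray) -> float:
    ss_res = float(np.sum((obs - pred) ** 2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else -np.inf
    return 1.0 - ss_res / ss_tot


def _closed_form_scale(x: np.ndarray, f: np.ndarray) -> float:
    """Least-squares slope through the origin for F = k * x."""
    denom = float(np.dot(x, x))
    if denom == 0:
        raise FitError("degenerate design (all regressors zero)")
    return max(float(np.dot(x, f) / denom), 0.0)


def _fit_nonlinear(residual, x0_grid, bounds) -> tuple[np.ndarray, float, bool, str]:
    """Deterministic multi-start least squares; best final SSE wins."""
    best = None
    for x0 in x0_grid:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = least_squares(
                    residual, x0=np.asarray(x0, float), bounds=bounds,
                    xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=2000,
                )
        except Exception:  # pragma: no cover - defensive
            continue
        sse = float(np.sum(res.fun**2))
        if best is None or sse < best[1] - 1e-15:
            best = (res.x, sse, bool(res.success), res.message)
    if best is None:
        raise FitError("all starts failed")
    return best


def fit_release_model(
    profile: DissolutionProfile,
    model: ReleaseModel | str,
    *,
    fit_fmax: bool = False,
    linearized: bool = False,
    kp_max_fraction: Optional[float] = None,
) -> ReleaseModelFit:
    """Least-squares fit of one release model to a profile.

    Points with t > 0 are used (all of them by default, including plateau
    points).  ``kp_max_fraction`` restricts the Korsmeyer-Peppas fit to the
    points below that fraction of the final release (the classical
    "first 60%" convention when set to 0.6).  ``fit_fmax`` frees the
    plateau F_inf of the first-order and Hixson-Crowell models instead of
    pinning it at 100%.  ``linearized`` reproduces the classical log-log /
    log-linear transformed fits.
    """
    model = ReleaseModel(model)
    mask = profile.t > 0
    t, f = profile.t[mask], profile.f[mask]
    if model is ReleaseModel.korsmeyer_peppas and kp_max_fraction is not None:
        final = f[-1]
        sel = f <= kp_max_fraction * final
        if sel.sum() >= 3:
            t, f = t[sel], f[sel]
    n_par = _N_PARAMS[model] + (1 if fit_fmax and model in
                                (ReleaseModel.first_order, ReleaseModel.hixson_crowell) else 0)
    if t.size < n_par + 1:
        raise FitError(
            f"{model.value}: {t.size} usable points < {n_par + 1} required"
        )

    converged, message = True, ""
    if model is ReleaseModel.zero_order:
        params = {"k0": _closed_form_scale(t, f)}
    elif model is ReleaseModel.higuchi:
        params = {"kH": _closed_form_scale(np.sqrt(t), f)}
    elif model is ReleaseModel.korsmeyer_peppas:
        if linearized:
            pos = f > 0
            if pos.sum() < 3:
                raise FitError("korsmeyer_peppas: too few positive points for log-log fit")
            slope, intercept = np.polyfit(np.log10(t[pos]), np.log10(f[pos]), 1)
            n = float(np.clip(slope, 1e-6, 3.0))
            params = {"kKP": float(10.0**intercept), "n": n}
        else:
            def resid(x):
                return x[0] * np.power(t, x[1]) - f
            k_scale = max(f.max(), 1.0) / max(t.max(), 1.0)
            starts = [(k, n) for n in (0.5, 1.0, 1.5)
                      for k in np.geomspace(k_scale * 1e-2, k_scale * 1e2, 5)]
            x, _, converged, message = _fit_nonlinear(
                resid, starts, ([0.0, 1e-6], [np.inf, 3.0]))
            params = {"kKP": float(x[0]), "n": float(x[1])}
    elif model is ReleaseModel.first_order:
        if linearized:
            # ln(1 - F/Fmax) = -k1 t on points strictly below the plateau
            fmax = 100.0
            sel = f < fmax
            slope = _closed_form_scale(t[sel], -np.log(1.0 - f[sel] / fmax))
            params = {"k1": slope}
        else:
            def resid_k(x):
                return x[-1] * (1.0 - np.exp(-x[0] * t)) - f if fit_fmax \
                    else 100.0 * (1.0 - np.exp(-x[0] * t)) - f
            k_scale = 1.0 / max(t.max(), 1.0)
            k_grid = np.geomspace(k_scale * 1e-2, k_scale * 1e2, 5)
            if fit_fmax:
                starts = [(k, fm) for k in k_grid for fm in (f.max(), 100.0)]
                x, _, converged, message = _fit_nonlinear(
                    resid_k, starts, ([0.0, 1e-6], [np.inf, 105.0]))
                params = {"k1": float(x[0]), "Fmax": float(x[1])}
            else:
                starts = [(k,) for k in k_grid]
                x, _, converged, message = _fit_nonlinear(
                    resid_k, starts, ([0.0], [np.inf]))
                params = {"k1": float(x[0])}
    elif model is ReleaseModel.hixson_crowell:
        def resid_hc(x):
            p = {"kHC": x[0]} | ({"Fmax": x[1]} if fit_fmax else {})
            return _eval_model(model, p, t) - f
        k_scale = np.cbrt(100.0) / max(t.max(), 1.0)
        k_grid = np.geomspace(k_scale * 1e-2, k_scale * 1e2, 5)
        if fit_fmax:
            starts = [(k, fm) for k in k_grid for fm in (max(f.max(), 1.0), 100.0)]
            x, _, converged, message = _fit_nonlinear(
                resid_hc, starts, ([0.0, 1e-6], [np.inf, 105.0]))
            params = {"kHC": float(x[0]), "Fmax": float(x[1])}
        else:
            starts = [(k,) for k in k_grid]
            x, _, converged, message = _fit_nonlinear(
                resid_hc, starts, ([0.0], [np.inf]))
            params = {"kHC": float(x[0])}
    else:  # pragma: no cover
        raise ValueError(model)

    pred = _eval_model(model, params, t)
    return ReleaseModelFit(
        model=model,
        params=params,
        r_squared=min(_r_squared(f, pred), 1.0),
        n_points_used=int(t.size),
        converged=converged,
        message=message,
    )


def fit_all_models(profile: DissolutionProfile, **kwargs) -> list[ReleaseModelFit]:
    """Fit all five models; sort by descending R^2, ties by enum order.

    Per-model failures are recorded as non-converged fits with
    R^2 = -inf and never abort the batch.
    """
    fits = []
    for i, model in enumerate(ReleaseModel):
        try:
            fit = fit_release_model(profile, model, **kwargs)
        except FitError as exc:
            fit = ReleaseModelFit(
                model=model, params={}, r_squared=-np.inf,
                n_points_used=0, converged=False, message=str(exc),
            )
        fits.append((fit, i))
    fits.sort(key=lambda pair: (-pair[0].r_squared, pair[1]))
    return [f for f, _ in fits]


def classify_mechanism(n: float) -> Mechanism:
    """Release mechanism from the Korsmeyer-Peppas diffusional exponent."""
    if n <= 0:
        raise ValueError("diffusional exponent must be > 0")
    if n <= 0.45:
        return Mechanism.fickian_diffusion
    if n <= 0.89:
        return Mechanism.anomalous_transport
    return Mechanism.case_II_or_erosion
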