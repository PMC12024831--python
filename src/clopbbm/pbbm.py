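"""Mechanistic absorption/disposition core.

The oral model is a serial nine-compartment compartmental-absorption-and-
transit (CAT/ACAT-style) description of the fasted human GI tract coupled
to linear three-compartment systemic disposition with hepatic first-pass
extraction:

* every luminal species (unreleased formulation, undissolved particles,
  dissolved drug, precipitate) transits compartment i -> i+1 with first-
  order rate 1/transit_time_i; material leaving the ascending colon is
  unabsorbed loss;
* drug enters solution via the active release source: Noyes-Whitney
  shrinking-particle dissolution of a polydisperse solid against the local
  solubility S(pH_i), or a tabulated ("dispersed") release profile whose
  hazard is applied to unreleased mass wherever it resides;
* dissolved drug above local saturation precipitates with first-order
  rate 1/precipitation_time; precipitate redissolves as 1-um solid;
* absorption flux from compartment i is k_a,i * dissolved amount, with
  k_a,i = 2*Peff/R_i * absorption_scale_i (cylindrical surface-to-volume);
* absorbed drug passes a hepatic extraction step: a fraction FPE is
  removed before reaching the central compartment, so Fb = Fa*(1 - FPE)
  exactly under uniform extraction (a `colon_bypass_fraction` lets distal
  absorption escape part of the extraction for exploration);
* systemic disposition is the three-compartment model (central
  elimination k10 = CL/Vc); a well-stirred liver compartment (1.8 L,
  hepatic blood flow 90 L/h) reports liver concentrations qualitatively
  and is excluded from the luminal mass balance.

Amounts are in mg, times in hours, concentrations in ng/mL at the
reporting boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

from .dissolution_sources import (
    DIFFUSION_LAYER_CAP_UM,
    ReleaseKind,
    ReleaseSource,
    TabulatedRelease,
)
from .metrics import PKMetrics, pk_metrics
from .physiology import COMPARTMENT_NAMES, GIPhysiology, default_fasted_physiology
from .solubility import SolubilityTable, interpolate_solubility

__all__ = [
    "DrugParameters",
    "DispositionParameters",
    "DoseEvent",
    "Route",
    "SimulationResult",
    "SolverSettings",
    "simulate_iv",
    "simulate_oral",
    "regional_absorption_fractions",
    "terminal_half_life",
    "fit_three_compartment",
    "SimulationError",
]

SEC_PER_H = 3600.0

#: well-stirred liver reporter constants
LIVER_VOLUME_L = 1.8
HEPATIC_BLOOD_FLOW_L_H = 90.0


class SimulationError(RuntimeError):
    pass


class FitError(RuntimeError):
    pass


class Route(str, Enum):
    iv_bolus = "iv_bolus"
    iv_infusion = "iv_infusion"
    po = "po"


@dataclass(frozen=True)
class DrugParameters:
    """Drug-specific physicochemical and biopharmaceutic constants."""

    MW: float                      # g/mol
    logD_74: float
    pKa_base: float
    solubility: SolubilityTable
    Peff: float                    # cm/s human effective permeability
    Dw: float                      # cm^2/s aqueous diffusion coefficient
    d50_um: float
    d90_um: float
    fu_plasma: float               # fraction unbound in plasma
    Rbp: float                     # blood/plasma concentration ratio
    FPE: float                     # hepatic first-pass extraction fraction
    precipitation_time_s: float = 900.0
    density_g_mL: float = 1.2      # true density (assumed; not published)

    def __post_init__(self) -> None:
        for name in ("MW", "Peff", "Dw", "d50_um", "d90_um",
                     "precipitation_time_s", "density_g_mL"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("fu_plasma", "FPE"):
            v = getattr(self, name)
            if not (0 < v <= 1.0):
                raise ValueError(f"{name}={v} outside (0, 1]")
        if self.Rbp <= 0:
            raise ValueError("Rbp must be > 0")


@dataclass(frozen=True)
class DispositionParameters:
    """Three-compartment disposition constants (per-kg CL and Vc)."""

    CL: float           # L/h/kg
    Vc: float           # L/kg
    k12: float          # 1/h
    k21: float
    k13: float
    k31: float
    body_weight: float = 70.0  # kg

    def __post_init__(self) -> None:
        for name in ("CL", "Vc", "k12", "k21", "k13", "k31", "body_weight"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def k10(self) -> float:
        """Central elimination rate constant CL/Vc (1/h)."""
        return self.CL / self.Vc

    @property
    def CL_total(self) -> float:
        """Absolute clearance, L/h."""
        return self.CL * self.body_weight

    @property
    def Vc_total(self) -> float:
        """Absolute central volume, L."""
        return self.Vc * self.body_weight

    def rate_matrix(self) -> np.ndarray:
        """3x3 disposition rate matrix acting on central/peripheral amounts."""
        k10, k12, k21, k13, k31 = self.k10, self.k12, self.k21, self.k13, self.k31
        return np.array([
            [-(k10 + k12 + k13), k21, k31],
            [k12, -k21, 0.0],
            [k13, 0.0, -k31],
        ])


@dataclass(frozen=True)
class DoseEvent:
    route: Route
    dose: float                        # mg
    infusion_duration: Optional[float] = None  # h, infusions only
    coadministered_water_mL: float = 200.0     # p.o. only

    def __post_init__(self) -> None:
        if self.dose <= 0:
            raise ValueError("dose must be > 0")
        route = Route(self.route)
        if route is Route.iv_infusion and (
            self.infusion_duration is None or self.infusion_duration <= 0
        ):
            raise ValueError("iv_infusion requires infusion_duration > 0")
        if self.coadministered_water_mL < 0:
            raise ValueError("coadministered water cannot be negative")


@dataclass(frozen=True)
class SolverSettings:
    rtol: float = 1e-9
    atol_rel: float = 1e-12   # absolute tolerance = atol_rel * dose
    dt_out: float = 0.01      # output grid, h
    method: str = "LSODA"
    n_bins: int = 10          # PSD discretization for solid sources


@dataclass
class SimulationResult:
    """Full time courses plus derived absorption/PK summaries.

    Per-compartment arrays have shape (9, n_times), ordered as
    :data:`~clopbbm.physiology.COMPARTMENT_NAMES`.  The luminal mass
    balance holds at every output time:
    undissolved + dissolved + precipitated + absorbed + exited == dose.
    """

    times: np.ndarray                 # h
    plasma_conc: np.ndarray           # ng/mL
    liver_conc: Optional[np.ndarray]  # ng/mL (reporter; None for i.v.)
    lumen_undissolved: Optional[np.ndarray]
    lumen_dissolved: Optional[np.ndarray]
    lumen_precipitated: Optional[np.ndarray]
    absorbed_cumulative: Optional[np.ndarray]
    exited: Optional[np.ndarray]
    dose: float = 0.0
    Fa: float = float("nan")          # % of dose absorbed into enterocytes
    Fb: float = float("nan")          # % of dose reaching systemic circulation
    regional_absorbed: Optional[dict] = None  # compartment -> % of absorbed
    metrics: Optional[PKMetrics] = None
    mass_balance_max_error: float = 0.0  # max |balance - dose| / dose


def terminal_half_life(disp: DispositionParameters) -> float:
    """ln2 over the smallest-magnitude eigenvalue of the disposition matrix.

    All eigenvalues of the three-compartment rate matrix are real and
    negative for positive rate constants; the slowest one is the terminal
    log-linear slope of any i.v. profile.
    """
    A = disp.rate_matrix()
    lam, V = np.linalg.eig(A)
    # residues of the central-compartment impulse response: modes that a
    # central dose cannot excite (unreachable peripheral compartments in
    # the k12 -> 0 limits) do not shape the observable terminal phase
    coef = V[0, :] * np.linalg.solve(V, np.array([1.0, 0.0, 0.0]))
    weight = np.abs(coef)
    mask = weight > 1e-9 * weight.sum()
    rates = np.abs(lam.real[mask])
    lam_z = rates.min()
    if lam_z <= 0:
        raise ValueError("degenerate disposition matrix")
    return float(np.log(2) / lam_z)


def _linear_disposition_solution(
    A: np.ndarray, a0: np.ndarray, u: np.ndarray, times: np.ndarray
) -> np.ndarray:
    """Analytic solution of a' = A a + u on a grid (u constant)."""
    lam, V = np.linalg.eig(A)
    Vinv = np.linalg.inv(V)
    if np.all(u == 0):
        a_part = np.zeros(3)
    else:
        a_part = -np.linalg.solve(A, u)
    c = Vinv @ (a0 - a_part)
    # amounts(t) = V @ (c * exp(lam t)) + a_part
    expt = np.exp(np.outer(lam, times))  # (3, T)
    out = (V @ (expt * c[:, None])) + a_part[:, None]
    return np.real(out)


def simulate_iv(
    drug: DrugParameters,
    disp: DispositionParameters,
    dose_event: DoseEvent,
    t_end: float = 24.0,
    solver: SolverSettings = SolverSettings(),
) -> SimulationResult:
    """Simulate i.v. bolus or constant-rate infusion (no GI involvement)."""
    route = Route(dose_event.route)
    if route not in (Route.iv_bolus, Route.iv_infusion):
        raise ValueError("simulate_iv requires an i.v. route")
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    # the solution is analytic, so evaluate on a grid fine enough that
    # trapezoidal AUC is exact to ~1e-4 even through the fast distribution
    # phase, then subsample to the requested output step
    refine = max(int(round(solver.dt_out / 0.002)), 1)
    dt = solver.dt_out / refine
    times = np.arange(0.0, t_end + dt / 2, dt)
    A = disp.rate_matrix()
    if route is Route.iv_bolus:
        amounts = _linear_disposition_solution(
            A, np.array([dose_event.dose, 0.0, 0.0]), np.zeros(3), times)
    else:
        dur = float(dose_event.infusion_duration)
        u = np.array([dose_event.dose / dur, 0.0, 0.0])
        t1 = times[times <= dur]
        t2 = times[times > dur]
        seg1 = _linear_disposition_solution(A, np.zeros(3), u, t1)
        a_dur = _linear_disposition_solution(
            A, np.zeros(3), u, np.array([dur]))[:, 0]
        seg2 = _linear_disposition_solution(A, a_dur, np.zeros(3), t2 - dur)
        amounts = np.concatenate([seg1, seg2], axis=1)
    plasma = np.maximum(amounts[0], 0.0) / disp.Vc_total * 1000.0  # ng/mL
    lam_z = np.log(2) / terminal_half_life(disp)
    metrics = pk_metrics(times, plasma, lambda_z=lam_z)
    times, plasma = times[::refine], plasma[::refine]
    return SimulationResult(
        times=times, plasma_conc=plasma, liver_conc=None,
        lumen_undissolved=None, lumen_dissolved=None, lumen_precipitated=None,
        absorbed_cumulative=None, exited=None, dose=dose_event.dose,
        metrics=metrics,
    )


def _gi_arrays(physiology: GIPhysiology, drug: DrugParameters,
               water_mL: float) -> dict:
    comps = physiology.compartments
    kt = np.array([1.0 / c.transit_time for c in comps])
    ka = np.array([
        2.0 * drug.Peff * SEC_PER_H / c.radius * c.absorption_scale
        for c in comps
    ])
    S = np.array([
        float(interpolate_solubility(drug.solubility, c.pH)) for c in comps
    ])
    Vf = np.array([c.fluid_volume for c in comps])
    Vf[0] += water_mL  # coadministered water stays with gastric fluid
    return {"kt": kt, "ka": ka, "S": S, "Vf": Vf}


def simulate_oral(
    drug: DrugParameters,
    disp: DispositionParameters,
    physiology: Optional[GIPhysiology],
    source: ReleaseSource,
    dose_event: DoseEvent,
    t_end: float = 24.0,
    solver: SolverSettings = SolverSettings(),
    colon_bypass_fraction: float = 0.0,
    precipitation: bool = True,
) -> SimulationResult:
    """Simulate oral administration through the nine-compartment GI model.

    ``precipitation=False`` (or an effectively infinite precipitation
    time) disables luminal precipitation, emulating polymer precipitation
    inhibition by the solid-dispersion carriers.
    """
    if Route(dose_event.route) is not Route.po:
        raise ValueError("simulate_oral requires route='po'")
    if not (0.0 <= colon_bypass_fraction <= 1.0):
        raise ValueError("colon_bypass_fraction must be in [0, 1]")
    physiology = physiology or default_fasted_physiology()
    dose = dose_event.dose
    gi = _gi_arrays(physiology, drug, dose_event.coadministered_water_mL)
    kt, ka, S, Vf = gi["kt"], gi["ka"], gi["S"], gi["Vf"]
    n = 9
    rho = drug.density_g_mL * 1000.0  # mg/cm^3
    kp = SEC_PER_H / drug.precipitation_time_s if precipitation else 0.0
    # precipitate redissolves as nominal 1-um solid
    r_pre = 1e-4  # cm
    coef_pre = SEC_PER_H * 3.0 * drug.Dw / (rho * r_pre * r_pre)
    # systemic availability per compartment (colon may bypass extraction)
    bypass = np.zeros(n)
    bypass[7:] = colon_bypass_fraction
    favail = 1.0 - drug.FPE * (1.0 - bypass)
    Qh, Vliv = HEPATIC_BLOOD_FLOW_L_H, LIVER_VOLUME_L
    A3 = disp.rate_matrix()
    k10 = disp.k10

    solid = ReleaseKind(source.kind) is ReleaseKind.solid_particles
    if solid:
        psd = source.psd
        nb = psd.n_bins
        r0 = psd.radii_um * 1e-4  # cm
        m0 = dose * psd.mass_fractions
        n0 = m0 / ((4.0 / 3.0) * np.pi * rho * r0**3)
        h_cap = DIFFUSION_LAYER_CAP_UM * 1e-4
        i_M = slice(0, n * nb)
        i_N = slice(n * nb, 2 * n * nb)
        base = 2 * n * nb
    else:
        rel = TabulatedRelease(
            source.profile, extension=source.profile_extension,
            lag_min=source.lag_min,
        )
        stomach_only = source.release_site == "stomach_only"
        i_U = slice(0, n)
        base = n

    i_D = slice(base, base + n)
    i_P = slice(base + n, base + 2 * n)
    i_A = slice(base + 2 * n, base + 3 * n)
    i_X = base + 3 * n        # exited unabsorbed
    i_B = i_X + 1             # cumulative systemic (bioavailable) input
    i_E = i_B + 1             # cumulative first-pass eliminated
    i_C = slice(i_E + 1, i_E + 4)  # disposition amounts
    i_CLR = i_E + 4           # cumulative systemically cleared
    i_L = i_E + 5             # liver reporter amount
    n_state = i_L + 1

    y0 = np.zeros(n_state)
    if solid:
        M0 = np.zeros((n, nb)); M0[0] = m0
        N0 = np.zeros((n, nb)); N0[0] = n0
        y0[i_M] = M0.ravel()
        y0[i_N] = N0.ravel()
    else:
        y0[0] = dose  # all unreleased formulation starts in the stomach

    def rhs(t, y):
        dy = np.zeros_like(y)
        D = np.maximum(y[i_D], 0.0)
        P = np.maximum(y[i_P], 0.0)
        C = D / Vf  # mg/mL luminal concentration
        # --- release / dissolution into the dissolved pool
        if solid:
            M = np.maximum(y[i_M].reshape(n, nb), 0.0)
            N = np.maximum(y[i_N].reshape(n, nb), 1e-300)
            r = np.cbrt(3.0 * M / (4.0 * np.pi * rho * N))
            r = np.maximum(r, 1e-7)
            h = np.minimum(r, h_cap)
            kdiss = SEC_PER_H * 3.0 * drug.Dw / (rho * h * r)  # 1/h per (mg/mL)
            grad = np.maximum(S - C, 0.0)[:, None]
            diss = np.minimum(kdiss * grad, 1e4) * M  # mg/h per (comp, bin)
            diss_tot = diss.sum(axis=1)
            # transit of particles (mass and number move together)
            tM = -kt[:, None] * M
            tM[1:] += kt[:-1, None] * M[:-1]
            tN = -kt[:, None] * N
            tN[1:] += kt[:-1, None] * N[:-1]
            dy[i_M] = (tM - diss).ravel()
            dy[i_N] = tN.ravel()
            exit_solid = kt[-1] * M[-1].sum()
        else:
            U = np.maximum(y[i_U], 0.0)
            haz = rel.hazard_per_h(t * 60.0)
            release = np.zeros(n)
            if haz > 0:
                if stomach_only:
                    release[0] = haz * U[0]
                else:
                    release = haz * U
            tU = -kt * U
            tU[1:] += kt[:-1] * U[:-1]
            dy[i_U] = tU - release
            diss_tot = release
            exit_solid = kt[-1] * U[-1]
        # --- precipitation and redissolution
        if kp > 0:
            excess = np.maximum(D - S * Vf, 0.0)
            precip = kp * excess
        else:
            precip = np.zeros(n)
        if kp > 0:
            # Noyes-Whitney first-order coefficient of the 1-um precipitate,
            # capped at 1e4/h for stiffness control
            redis = np.minimum(coef_pre * np.maximum(S - C, 0.0), 1e4) * P
        else:
            redis = np.zeros(n)
        absorbed = ka * D
        tD = -kt * D
        tD[1:] += kt[:-1] * D[:-1]
        tP = -kt * P
        tP[1:] += kt[:-1] * P[:-1]
        dy[i_D] = tD + diss_tot + redis - precip - absorbed
        dy[i_P] = tP + precip - redis
        dy[i_A] = absorbed
        dy[i_X] = exit_solid + kt[-1] * (D[-1] + P[-1])
        sys_in = float(np.dot(favail, absorbed))
        dy[i_B] = sys_in
        dy[i_E] = float(np.dot(1.0 - favail, absorbed))
        c = y[i_C]
        dc = A3 @ c
        dc[0] += sys_in
        dy[i_C] = dc
        dy[i_CLR] = k10 * c[0]
        # liver reporter: portal inflow + systemic blood flow, well stirred
        Cb = c[0] / disp.Vc_total * drug.Rbp  # mg/L blood
        dy[i_L] = absorbed.sum() + Qh * Cb - (Qh / Vliv) * y[i_L]
        return dy

    times = np.arange(0.0, t_end + solver.dt_out / 2, solver.dt_out)
    sol = solve_ivp(
        rhs, (0.0, t_end), y0, method=solver.method, t_eval=times,
        rtol=solver.rtol, atol=solver.atol_rel * dose,
    )
    if not sol.success:
        raise SimulationError(f"ODE solver failed: {sol.message}")
    Y = sol.y
    if solid:
        und = Y[i_M].reshape(n, -1, Y.shape[1]).sum(axis=1)
    else:
        und = Y[i_U]
    Dts = Y[i_D]
    Pts = Y[i_P]
    Ats = Y[i_A]
    Xts = Y[i_X]
    balance = und.sum(axis=0) + Dts.sum(axis=0) + Pts.sum(axis=0) \
        + Ats.sum(axis=0) + Xts
    mb_err = float(np.max(np.abs(balance - dose)) / dose)
    plasma = np.maximum(Y[i_C][0], 0.0) / disp.Vc_total * 1000.0
    liver = np.maximum(Y[i_L], 0.0) / Vliv * 1000.0
    total_abs = Ats[:, -1].sum()
    Fa = 100.0 * total_abs / dose
    Fb = 100.0 * Y[i_B][-1] / dose
    regional = None
    if total_abs > 0:
        shares = 100.0 * Ats[:, -1] / total_abs
        regional = dict(zip(COMPARTMENT_NAMES, shares.tolist()))
    lam_z = np.log(2) / terminal_half_life(disp)
    metrics = pk_metrics(times, plasma, lambda_z=lam_z) if plasma.max() > 0 else None
    return SimulationResult(
        times=times, plasma_conc=plasma, liver_conc=liver,
        lumen_undissolved=und, lumen_dissolved=Dts, lumen_precipitated=Pts,
        absorbed_cumulative=Ats, exited=Xts, dose=dose,
        Fa=Fa, Fb=Fb, regional_absorbed=regional, metrics=metrics,
        mass_balance_max_error=mb_err,
    )


def regional_absorption_fractions(result: SimulationResult) -> dict:
    """Per-compartment share (%) of the total absorbed amount; sums to 100."""
    if result.absorbed_cumulative is None:
        raise ValueError("result has no GI absorption record")
    final = result.absorbed_cumulative[:, -1]
    total = final.sum()
    if total <= 0:
        raise ValueError("Fa = 0: regional distribution undefined")
    return dict(zip(COMPARTMENT_NAMES, (100.0 * final / total).tolist()))


def _iv_bolus_conc(
    x: np.ndarray, times: np.ndarray, dose: float, body_weight: float
) -> np.ndarray:
    CL, Vc, k12, k21, k13, k31 = x
    disp = DispositionParameters(CL=CL, Vc=Vc, k12=k12, k21=k21,
                                 k13=k13, k31=k31, body_weight=body_weight)
    amounts = _linear_disposition_solution(
        disp.rate_matrix(), np.array([dose, 0.0, 0.0]), np.zeros(3), times)
    return np.maximum(amounts[0], 0.0) / disp.Vc_total * 1000.0


def fit_three_compartment(
    times: Sequence[float],
    conc: Sequence[float],
    dose: float,
    route: Route | str = Route.iv_bolus,
    body_weight: float = 70.0,
) -> DispositionParameters:
    """Weighted nonlinear least-squares fit of the tri-exponential i.v.
    bolus solution (1/yhat^2 weighting, deterministic multi-start).

    Returns per-kg CL and Vc plus the four distribution rate constants.
    """
    if Route(route) is not Route.iv_bolus:
        raise FitError("only iv_bolus data fitting is supported")
    t = np.asarray(times, dtype=float)
    c = np.asarray(conc, dtype=float)
    if t.size < 8:
        raise FitError("need at least 8 concentration points")
    if np.any(c <= 0):
        keep = c > 0
        t, c = t[keep], c[keep]
        if t.size < 8:
            raise FitError("need at least 8 positive concentrations")
    # data-driven scale estimates for the multi-start grid
    auc = np.trapezoid(c, t) / 1000.0  # mg*h/L
    CL0 = dose / auc / body_weight if auc > 0 else 1.0
    Vc0 = dose / (c[0] / 1000.0) / body_weight if c[0] > 0 else 0.1

    def resid(logx):
        x = np.exp(logx)
        pred = _iv_bolus_conc(x, t, dose, body_weight)
        return (pred - c) / np.maximum(pred, 1e-9)

    rate_grid = [
        (5.0, 1.0, 1.0, 0.1),
        (1.0, 0.5, 0.2, 0.05),
        (10.0, 2.0, 1.0, 0.2),
        (2.0, 2.0, 0.5, 0.5),
    ]
    lb = np.log([1e-4, 1e-4, 1e-6, 1e-6, 1e-6, 1e-6])
    ub = np.log([1e3, 1e3, 1e3, 1e3, 1e3, 1e3])
    best = None
    for rates in rate_grid:
        x0 = np.log(np.clip([CL0, Vc0, *rates], np.exp(lb), np.exp(ub)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = least_squares(resid, x0, bounds=(lb, ub),
                                xtol=1e-15, ftol=1e-15, gtol=1e-15,
                                max_nfev=5000)
        sse = float(np.sum(res.fun**2))
        if best is None or sse < best[0]:
            best = (sse, res)
    sse, res = best
    x = np.exp(res.x)
    if not np.all(np.isfinite(x)):
        raise FitError(f"fit diverged: {res.message}")
    return DispositionParameters(
        CL=float(x[0]), Vc=float(x[1]), k12=float(x[2]), k21=float(x[3]),
        k13=float(x[4]), k31=float(x[5]), body_weight=body_weight,
    )
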