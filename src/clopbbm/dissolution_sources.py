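"""In-simulation drug release: polydisperse particle dissolution and
tabulated ("dispersed") release profiles.

Two release mechanisms feed the GI simulator:

* **solid_particles** - an immediate-release solid described by a
  log-normal particle size distribution (median D50, 90th percentile D90)
  discretized into equal-mass bins.  Each bin dissolves by the
  Noyes-Whitney / Johnson shrinking-particle law

      dM/dt = -3 * Dw * M / (rho * h * r) * (Cs - C)

  with diffusion-layer thickness h = min(r, 30 um), the standard
  diffusion-layer convention (the commercial "Johnson equation" internals
  are proprietary; this is the published form it derives from).

* **dispersed_profile** - a tabulated cumulative release profile (the
  in vitro pH-media-change curve) drives release of drug from the
  formulation wherever it currently resides in the GI tract; released drug
  joins the local dissolved pool.  Beyond the last measured time point the
  default behaviour continues release at the final segment's rate until
  the dose is exhausted (``extension='hold_rate'``): an eroding matrix
  does not stop releasing because the in vitro test ended.
  ``extension='stop'`` freezes release at the last measured value.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np
from scipy.stats import norm

from .release_kinetics import DissolutionProfile

__all__ = [
    "ParticleSizeDistribution",
    "ReleaseSource",
    "ReleaseKind",
    "build_psd",
    "particle_dissolution_rate",
    "tabulated_release_rate",
    "TabulatedRelease",
    "DIFFUSION_LAYER_CAP_UM",
    "MIN_PER_H",
]

#: conventional maximum diffusion-layer thickness (um)
DIFFUSION_LAYER_CAP_UM = 30.0
#: in vitro profiles are recorded in minutes; the simulator runs in hours
MIN_PER_H = 60.0
#: z-score of the 90th percentile, ties D90/D50 to the log-normal sigma
_Z90 = norm.ppf(0.90)


class ReleaseKind(str, Enum):
    solid_particles = "solid_particles"
    dispersed_profile = "dispersed_profile"


@dataclass(frozen=True)
class ParticleSizeDistribution:
    """Discretized log-normal PSD: bins of (radius um, number_fraction)."""

    D50: float
    D90: float
    bins: tuple[tuple[float, float], ...]  # (radius_um, number_fraction)

    def __post_init__(self) -> None:
        if not (self.D90 > self.D50 > 0):
            raise ValueError("require D90 > D50 > 0")
        total = sum(fr for _, fr in self.bins)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"number fractions sum to {total}, not 1")

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def radii_um(self) -> np.ndarray:
        return np.array([r for r, _ in self.bins])

    @property
    def diameters_um(self) -> np.ndarray:
        return 2.0 * self.radii_um

    @property
    def number_fractions(self) -> np.ndarray:
        return np.array([fr for _, fr in self.bins])

    @property
    def mass_fractions(self) -> np.ndarray:
        """Mass fraction per bin, proportional to number_fraction * r^3."""
        w = self.number_fractions * self.radii_um**3
        return w / w.sum()


def build_psd(D50: float, D90: float, n_bins: int = 10) -> ParticleSizeDistribution:
    """Log-normal PSD with median D50 and 90th percentile D90 (um).

    sigma = ln(D90/D50) / z_0.90 (z = 1.2816).  The distribution is split
    into ``n_bins`` equal-probability (equal-mass) bins represented by
    their median diameters; number fractions follow from mass / r^3.
    A single bin collapses to the median (D50).
    """
    if not (D90 > D50 > 0):
        raise ValueError("require D90 > D50 > 0")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    sigma = math.log(D90 / D50) / _Z90
    q = (np.arange(n_bins) + 0.5) / n_bins
    diameters = D50 * np.exp(sigma * norm.ppf(q))
    radii = diameters / 2.0
    mass_frac = np.full(n_bins, 1.0 / n_bins)
    number_w = mass_frac / radii**3
    number_frac = number_w / number_w.sum()
    # remove accumulated round-off so the invariant holds exactly
    number_frac[-1] += 1.0 - number_frac.sum()
    return ParticleSizeDistribution(
        D50=D50, D90=D90, bins=tuple(zip(radii.tolist(), number_frac.tolist()))
    )


def particle_dissolution_rate(
    M_mg: float,
    radius_um: float,
    Cs: float,
    Clumen: float,
    Dw: float,
    density: float,
    h_cap_um: float = DIFFUSION_LAYER_CAP_UM,
    allow_growth: bool = False,
) -> float:
    """Shrinking-particle dissolution rate of one bin, in mg/min.

    ``M_mg`` remaining solid mass, ``radius_um`` current particle radius,
    ``Cs``/``Clumen`` saturation and bulk concentrations (mg/mL),
    ``Dw`` diffusion coefficient (cm^2/s), ``density`` true density (g/mL).
    The rate is 0 for an exhausted bin; an undersaturated gradient
    (Clumen > Cs) yields growth only when ``allow_growth`` is set,
    otherwise the rate clamps to 0.
    """
    if Cs <= 0:
        raise ValueError("Cs must be > 0")
    if Clumen < 0:
        raise ValueError("concentrations must be >= 0")
    if M_mg <= 0 or radius_um <= 0:
        return 0.0
    r_cm = radius_um * 1e-4
    h_cm = min(r_cm, h_cap_um * 1e-4)
    rho = density * 1000.0  # mg/cm^3
    rate = 60.0 * 3.0 * Dw * M_mg * (Cs - Clumen) / (rho * h_cm * r_cm)
    if rate < 0 and not allow_growth:
        return 0.0
    return rate


class TabulatedRelease:
    """Monotone piecewise-linear interpolant of a cumulative release profile.

    Holds cumulative *fraction of dose* vs time in minutes.  A
    non-monotone input profile is corrected by running maximum (with a
    warning), never rejected.  ``extension`` controls behaviour beyond the
    last point: 'stop' (rate 0) or 'hold_rate' (keep releasing at the
    profile's terminal rate until the cumulative fraction reaches 1).
    The terminal rate is the least-squares slope over the final dissolution
    stage (the points sharing the last pH label, or the last quarter of
    the test when no stage labels are present): a two-point end segment is
    far too noise-sensitive to extrapolate hours of in vivo release from.
    """

    def __init__(
        self,
        profile: DissolutionProfile,
        extension: str = "stop",
        lag_min: float = 0.0,
    ):
        if extension not in ("stop", "hold_rate"):
            raise ValueError(f"unknown extension {extension!r}")
        t = profile.t + lag_min
        f = np.clip(profile.f, 0.0, None) / 100.0
        mono = np.maximum.accumulate(f)
        if np.any(mono > f + 1e-12):
            warnings.warn(
                f"non-monotone cumulative profile {profile.formulation_id!r} "
                "corrected by running maximum"
            )
        f = np.minimum(mono, 1.0)
        self._terminal_slope = self._fit_terminal_slope(t, f, profile.stage_pH)
        if t[0] > 0:
            t = np.concatenate([[0.0], t])
            f = np.concatenate([[0.0], f])
        self.t_min = t
        self.frac = f
        self.extension = extension
        if extension == "hold_rate" and self._terminal_slope > 1e-12 and f[-1] < 1.0:
            t_complete = t[-1] + (1.0 - f[-1]) / self._terminal_slope
            self.t_min = np.concatenate([t, [t_complete]])
            self.frac = np.concatenate([f, [1.0]])

    @staticmethod
    def _fit_terminal_slope(t: np.ndarray, f: np.ndarray, stage_ph) -> float:
        """Regression slope (fraction/min) of the terminal release stage."""
        if len(t) < 2:
            return 0.0
        mask = None
        if stage_ph is not None:
            ph = np.asarray(stage_ph, dtype=float)
            mask = ph == ph[-1]
            if mask.sum() < 3:
                mask = None
        if mask is None:
            mask = t >= t[-1] - 0.25 * (t[-1] - t[0])
        if mask.sum() < 2:
            mask = np.zeros(len(t), dtype=bool)
            mask[-2:] = True
        slope = np.polyfit(t[mask], f[mask], 1)[0]
        return float(max(slope, 0.0))

    def cumulative(self, t_min) -> np.ndarray:
        """Cumulative released fraction at time(s) t (min)."""
        return np.interp(np.asarray(t_min, dtype=float), self.t_min, self.frac,
                         left=0.0, right=float(self.frac[-1]))

    def rate(self, t_min) -> np.ndarray:
        """Release rate, fraction of dose per minute."""
        t = np.atleast_1d(np.asarray(t_min, dtype=float))
        idx = np.searchsorted(self.t_min, t, side="right") - 1
        out = np.zeros_like(t)
        inside = (idx >= 0) & (idx < len(self.t_min) - 1) & (t >= 0)
        i = idx[inside]
        dt = self.t_min[i + 1] - self.t_min[i]
        out[inside] = (self.frac[i + 1] - self.frac[i]) / dt
        return out if np.ndim(t_min) else float(out[0])

    def hazard_per_h(self, t_min: float, cap: float = 1000.0) -> float:
        """Release rate per unit *unreleased* fraction, in 1/h.

        This is the rate constant applied to unreleased formulation mass
        wherever it resides in the GI tract; with it, total release tracks
        the cumulative profile exactly even while the mass transits.
        """
        r = float(self.rate(t_min))
        if r <= 0:
            return 0.0
        remaining = 1.0 - float(self.cumulative(t_min))
        if remaining <= 1e-12:
            return cap
        return min(r / remaining * MIN_PER_H, cap)


def tabulated_release_rate(profile: DissolutionProfile, t) -> np.ndarray | float:
    """Release rate (fraction of dose per minute) at time(s) t.

    Derivative of the monotone piecewise-linear interpolant of the
    cumulative fraction; 0 before t = 0 and beyond the last time point.
    """
    return TabulatedRelease(profile, extension="stop").rate(t)


@dataclass(frozen=True)
class ReleaseSource:
    """Formulation release mechanism handed to the oral simulator."""

    kind: ReleaseKind
    psd: Optional[ParticleSizeDistribution] = None
    profile: Optional[DissolutionProfile] = None
    density: float = 1.2  # g/mL, typical organic salt (true density unpublished)
    profile_extension: str = "hold_rate"
    release_site: str = "all"  # or "stomach_only"
    lag_min: float = 0.0       # capsule disintegration lag

    def __post_init__(self) -> None:
        kind = ReleaseKind(self.kind)
        if kind is ReleaseKind.solid_particles:
            if self.psd is None or self.profile is not None:
                raise ValueError("solid_particles requires psd and no profile")
        else:
            if self.profile is None or self.psd is not None:
                raise ValueError("dispersed_profile requires profile and no psd")
        if self.density <= 0:
            raise ValueError("density must be > 0")
        if self.release_site not in ("all", "stomach_only"):
            raise ValueError(f"unknown release_site {self.release_site!r}")

    @classmethod
    def from_psd(cls, d50_um: float, d90_um: float, n_bins: int = 10,
                 density: float = 1.2) -> "ReleaseSource":
        return cls(kind=ReleaseKind.solid_particles,
                   psd=build_psd(d50_um, d90_um, n_bins), density=density)

    @classmethod
    def from_profile(cls, profile: DissolutionProfile, *,
                     extension: str = "hold_rate", release_site: str = "all",
                     lag_min: float = 0.0) -> "ReleaseSource":
        return cls(kind=ReleaseKind.dispersed_profile, profile=profile,
                   profile_extension=extension, release_site=release_site,
                   lag_min=lag_min)
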