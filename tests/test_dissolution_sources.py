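import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import clopbbm as cb
from clopbbm.dissolution_sources import (
    ReleaseKind,
    ReleaseSource,
    TabulatedRelease,
    build_psd,
    particle_dissolution_rate,
    tabulated_release_rate,
)
from clopbbm.release_kinetics import DissolutionProfile


# -------------------------------------------------------------------- PSD

def test_single_bin_collapses_to_median():
    psd = build_psd(150, 250, n_bins=1)
    assert psd.n_bins == 1
    assert psd.diameters_um[0] == pytest.approx(150.0, rel=1e-12)
    assert psd.number_fractions[0] == 1.0


def test_lognormal_quantile_discretization():
    psd = build_psd(150, 250, n_bins=10)
    sigma = np.log(250 / 150) / 1.2815515655446004
    assert sigma == pytest.approx(0.3986, abs=1e-4)
    d = psd.diameters_um
    assert np.all(np.diff(d) > 0)
    # median diameter of the middle of the distribution stays near D50
    assert np.sqrt(d[4] * d[5]) == pytest.approx(150.0, rel=1e-6)
    # 90th percentile bin edges bracket D90
    assert d[8] < 250 < d[9]


def test_near_monodisperse_limit():
    psd = build_psd(150, 150.0001, n_bins=10)
    assert np.all(np.abs(psd.diameters_um - 150.0) < 0.01)


def test_equal_mass_binning():
    psd = build_psd(150, 250, n_bins=7)
    assert psd.mass_fractions == pytest.approx(np.full(7, 1 / 7), rel=1e-9)


@settings(derandomize=True, max_examples=30, deadline=None)
@given(d50=st.floats(1.0, 500.0), ratio=st.floats(1.01, 5.0),
       n=st.integers(1, 40))
def test_psd_fractions_always_sum_to_one(d50, ratio, n):
    psd = build_psd(d50, d50 * ratio, n_bins=n)
    assert psd.number_fractions.sum() == pytest.approx(1.0, abs=1e-9)


def test_psd_rejects_bad_sizes():
    with pytest.raises(ValueError):
        build_psd(250, 150, 5)
    with pytest.raises(ValueError):
        build_psd(150, 250, 0)


# ----------------------------------------------------- Noyes-Whitney rate

def test_exhausted_bin_rate_is_zero():
    assert particle_dissolution_rate(0.0, 75, 0.05, 0.0, 7e-6, 1.2) == 0.0


def test_equilibrium_rate_is_zero():
    assert particle_dissolution_rate(1.0, 75, 0.05, 0.05, 7e-6, 1.2) == 0.0


def test_no_growth_without_flag():
    assert particle_dissolution_rate(1.0, 75, 0.05, 0.10, 7e-6, 1.2) == 0.0
    grown = particle_dissolution_rate(1.0, 75, 0.05, 0.10, 7e-6, 1.2,
                                      allow_growth=True)
    assert grown < 0


def test_negative_concentration_rejected():
    with pytest.raises(ValueError):
        particle_dissolution_rate(1.0, 75, 0.05, -0.01, 7e-6, 1.2)
    with pytest.raises(ValueError):
        particle_dissolution_rate(1.0, 75, -0.05, 0.0, 7e-6, 1.2)


def test_rate_matches_shrinking_sphere_oracle():
    """One 150-um-diameter bin under sink conditions: the closed-form rate
    matches explicit finite-difference integration of the shrinking sphere
    (dr/dt = -Dw*Cs/(rho*h)) to within 0.1% over one 1e-3 min step."""
    Dw, Cs, density = 0.7397e-5, 0.0246, 1.2
    rho = density * 1000.0          # mg/cm^3
    r0 = 75e-4                      # cm
    M0 = 1.0                        # mg
    dt_min = 1e-3
    # oracle: integrate radius with explicit sub-steps, convert to mass loss
    n_sub = 1000
    dt_s = dt_min * 60.0 / n_sub
    r = r0
    for _ in range(n_sub):
        h = min(r, 30e-4)
        r -= Dw * Cs / (rho * h) * dt_s
    mass_lost_oracle = M0 * (1.0 - (r / r0) ** 3)
    rate = particle_dissolution_rate(M0, 75.0, Cs, 0.0, Dw, density)
    assert rate * dt_min == pytest.approx(mass_lost_oracle, rel=1e-3)


def test_dissolution_time_monotone_in_cs_and_radius():
    """Time to complete dissolution of a single bin falls with higher
    solubility and with smaller starting radius (sink conditions)."""
    Dw, density = 0.7397e-5, 1.2
    rho = density * 1000.0

    def time_to_dissolve(r0_um, Cs):
        r, t, dt = r0_um * 1e-4, 0.0, 0.05
        while r > 1e-6 and t < 1e7:
            h = min(r, 30e-4)
            r -= Dw * Cs / (rho * h) * dt
            t += dt
        return t

    times_cs = [time_to_dissolve(75, cs) for cs in (0.01, 0.02, 0.04)]
    assert times_cs[0] > times_cs[1] > times_cs[2]
    times_r = [time_to_dissolve(r, 0.02) for r in (150, 100, 50)]
    assert times_r[0] > times_r[1] > times_r[2]


# ------------------------------------------------------ tabulated release

def _linear_profile():
    t = np.linspace(0.0, 100.0, 11)
    return DissolutionProfile.from_arrays(t, t)  # 0 -> 100% over 100 min


def test_linear_profile_rate():
    prof = _linear_profile()
    assert tabulated_release_rate(prof, 50.0) == pytest.approx(0.01)
    assert tabulated_release_rate(prof, 150.0) == 0.0
    assert tabulated_release_rate(prof, -5.0) == 0.0


def test_rate_integrates_to_final_fraction():
    spec = cb.formulation_presets()["P9"]
    prof = cb.generate_profile(spec)
    rel = TabulatedRelease(prof, extension="stop")
    # the rate is piecewise constant: integrate it exactly over its
    # own segments (plus a tail segment where it must vanish)
    edges = np.concatenate([rel.t_min, [rel.t_min[-1] + 100.0]])
    mids = 0.5 * (edges[1:] + edges[:-1])
    integral = float(np.sum(rel.rate(mids) * np.diff(edges)))
    assert integral == pytest.approx(prof.f[-1] / 100.0, abs=1e-9)


def test_non_monotone_profile_corrected_with_warning():
    prof = DissolutionProfile.from_arrays([0, 10, 20, 30], [0, 50, 45, 60])
    with pytest.warns(UserWarning, match="non-monotone"):
        rel = TabulatedRelease(prof)
    assert np.all(np.diff(rel.frac) >= 0)


def test_hold_rate_extension_reaches_complete_release():
    # steady 0.1%/min tail keeps releasing linearly until 100%
    t = np.arange(0.0, 301.0, 10.0)
    f = np.minimum(0.1 * t + 20.0, 100.0)
    f[0] = 0.0
    prof = DissolutionProfile.from_arrays(t, f)
    rel = TabulatedRelease(prof, extension="hold_rate")
    assert rel.cumulative(rel.t_min[-1]) == pytest.approx(1.0)
    assert rel.cumulative(1e6) == pytest.approx(1.0)
    stop = TabulatedRelease(prof, extension="stop")
    assert stop.cumulative(1e6) == pytest.approx(f[-1] / 100.0)


def test_plateaued_profile_gets_no_meaningful_extension():
    spec = cb.formulation_presets()["C5"]
    prof = cb.generate_profile(spec)
    rel = TabulatedRelease(prof, extension="hold_rate")
    # terminal stage is flat: release within the simulation window stays
    # at the measured plateau
    assert rel.cumulative(24 * 60.0) <= (prof.f[-1] + 0.5) / 100.0


def test_release_source_validation():
    prof = _linear_profile()
    with pytest.raises(ValueError):
        ReleaseSource(kind=ReleaseKind.solid_particles, profile=prof)
    with pytest.raises(ValueError):
        ReleaseSource(kind=ReleaseKind.dispersed_profile, psd=build_psd(150, 250, 2))
    src = ReleaseSource.from_profile(prof)
    assert src.kind is ReleaseKind.dispersed_profile
    src2 = ReleaseSource.from_psd(150, 250, 5)
    assert src2.psd.n_bins == 5
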