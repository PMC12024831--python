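import numpy as np
import pytest

import clopbbm as cb
from clopbbm.release_kinetics import (
    DissolutionProfile,
    FitError,
    Mechanism,
    ReleaseModel,
    ReleaseModelFit,
    fit_release_model,
)

TIMES = np.arange(10.0, 121.0, 10.0)


def _profile(f, t=TIMES):
    return DissolutionProfile.from_arrays(t, f)


# ---------------------------------------------------------------- predict

def test_predict_closed_forms():
    zero = ReleaseModelFit(ReleaseModel.zero_order, {"k0": 0.5}, 1.0, 5)
    assert cb.predict_release(zero, [60.0])[0] == pytest.approx(30.0)
    kp = ReleaseModelFit(ReleaseModel.korsmeyer_peppas, {"kKP": 1.0, "n": 0.5}, 1.0, 5)
    assert cb.predict_release(kp, [100.0])[0] == pytest.approx(10.0)
    first = ReleaseModelFit(ReleaseModel.first_order, {"k1": 1e-15}, 1.0, 5)
    assert cb.predict_release(first, [1e6])[0] == pytest.approx(0.0, abs=1e-6)


def test_predict_clipping_and_domain():
    zero = ReleaseModelFit(ReleaseModel.zero_order, {"k0": 2.0}, 1.0, 5)
    assert cb.predict_release(zero, [100.0], clip=True)[0] == 100.0
    with pytest.raises(ValueError):
        cb.predict_release(zero, [-1.0])


# ---------------------------------------------------------------- fitting

RECOVERY_CASES = [
    (ReleaseModel.zero_order, {"k0": 0.5}),
    (ReleaseModel.first_order, {"k1": 0.02}),
    (ReleaseModel.higuchi, {"kH": 5.0}),
    (ReleaseModel.korsmeyer_peppas, {"kKP": 0.01, "n": 1.83}),
    (ReleaseModel.hixson_crowell, {"kHC": 0.02}),
]


@pytest.mark.parametrize("model,params", RECOVERY_CASES,
                         ids=[m.value for m, _ in RECOVERY_CASES])
def test_noise_free_parameter_recovery(model, params):
    """Each model refits its own noise-free data exactly (R^2 = 1)."""
    truth = ReleaseModelFit(model, params, 1.0, len(TIMES))
    profile = _profile(cb.predict_release(truth, TIMES))
    fit = fit_release_model(profile, model)
    for name, value in params.items():
        assert fit.params[name] == pytest.approx(value, rel=1e-6)
    assert fit.r_squared == pytest.approx(1.0, abs=1e-12)


def test_higuchi_data_refit_with_kp_gives_half():
    profile = _profile(5.0 * np.sqrt(TIMES))
    fit = fit_release_model(profile, ReleaseModel.korsmeyer_peppas)
    assert fit.params["n"] == pytest.approx(0.5, abs=1e-8)


def test_zero_order_tie_broken_by_enum_order():
    """KP nests zero-order at n = 1: both reach R^2 = 1, zero-order first."""
    fits = cb.fit_all_models(_profile(0.5 * TIMES))
    assert fits[0].model is ReleaseModel.zero_order
    assert fits[0].r_squared == pytest.approx(1.0, abs=1e-12)
    assert fits[1].model is ReleaseModel.korsmeyer_peppas
    assert fits[1].r_squared == pytest.approx(1.0, abs=1e-9)


def test_generating_model_ranks_first_on_own_data():
    truth = ReleaseModelFit(ReleaseModel.higuchi, {"kH": 6.0}, 1.0, len(TIMES))
    fits = cb.fit_all_models(_profile(cb.predict_release(truth, TIMES)))
    assert fits[0].r_squared == pytest.approx(1.0, abs=1e-12)
    assert fits[0].model in (ReleaseModel.higuchi, ReleaseModel.korsmeyer_peppas)
    by_model = {f.model: f for f in fits}
    # non-nesting rivals cannot beat the generating model
    for rival in (ReleaseModel.zero_order, ReleaseModel.first_order,
                  ReleaseModel.hixson_crowell):
        assert by_model[rival].r_squared < 1.0 - 1e-6


def test_fit_fmax_handles_plateau_below_100():
    f = 60.0 * (1.0 - np.exp(-0.05 * TIMES))
    fit = fit_release_model(_profile(f), ReleaseModel.first_order, fit_fmax=True)
    assert fit.params["Fmax"] == pytest.approx(60.0, rel=1e-6)
    assert fit.params["k1"] == pytest.approx(0.05, rel=1e-6)


def test_linearized_kp_matches_log_log_regression():
    f = 0.2 * TIMES**0.8
    fit = fit_release_model(_profile(f), ReleaseModel.korsmeyer_peppas,
                            linearized=True)
    assert fit.params["n"] == pytest.approx(0.8, rel=1e-9)


def test_kp_max_fraction_restricts_points():
    f = 0.2 * TIMES**0.8
    fit = fit_release_model(_profile(f), ReleaseModel.korsmeyer_peppas,
                            kp_max_fraction=0.6)
    assert fit.n_points_used < len(TIMES)
    assert fit.params["n"] == pytest.approx(0.8, rel=1e-6)


def test_too_few_points_raises_fit_error():
    profile = DissolutionProfile.from_arrays([5.0, 10.0, 20.0], [5.0, 9.0, 16.0])
    with pytest.raises(FitError):
        fit_release_model(
            DissolutionProfile.from_arrays([0.0, 10.0, 20.0], [0.0, 9.0, 16.0]),
            ReleaseModel.korsmeyer_peppas)
    # 3 positive-time points are enough for 1-parameter models
    assert fit_release_model(profile, ReleaseModel.zero_order).n_points_used == 3


def test_fit_all_models_never_aborts():
    profile = DissolutionProfile.from_arrays([0.0, 10.0, 20.0], [0.0, 9.0, 16.0])
    fits = cb.fit_all_models(profile)
    assert len(fits) == 5
    failed = [f for f in fits if not f.converged]
    assert all(f.r_squared == -np.inf for f in failed)


# ---------------------------------------------------------------- profiles

def test_profile_validation():
    with pytest.raises(ValueError):
        DissolutionProfile.from_arrays([0, 10], [0, 50])          # too short
    with pytest.raises(ValueError):
        DissolutionProfile.from_arrays([0, 10, 5], [0, 50, 60])   # non-increasing
    with pytest.raises(ValueError):
        DissolutionProfile.from_arrays([0, 10, 20], [0, 50, 120])  # > 105
    noisy = DissolutionProfile.from_arrays([0, 10, 20], [-1.0, 50, 101.0])
    assert noisy.noise_flagged
    clean = DissolutionProfile.from_arrays([0, 10, 20], [0.0, 50, 99.0])
    assert not clean.noise_flagged


# ---------------------------------------------------------------- mechanism

@pytest.mark.parametrize("n,expected", [
    (1.83, Mechanism.case_II_or_erosion),
    (0.45, Mechanism.fickian_diffusion),   # boundary convention
    (0.7, Mechanism.anomalous_transport),
    (0.89, Mechanism.anomalous_transport),
    (0.891, Mechanism.case_II_or_erosion),
])
def test_mechanism_classification(n, expected):
    assert cb.classify_mechanism(n) is expected


def test_mechanism_rejects_nonpositive():
    with pytest.raises(ValueError):
        cb.classify_mechanism(0.0)


# ------------------------------------------------- noisy-recovery coverage

@pytest.mark.parametrize("model,param,truth", [
    (ReleaseModel.zero_order, "k0", 0.5),
    (ReleaseModel.higuchi, "kH", 5.0),
])
def test_bootstrap_coverage_under_noise(model, param, truth):
    """With 2% Gaussian assay noise on a 5-min sampling grid, the true
    rate constant falls inside the parametric-bootstrap 95% interval in
    >= 90% of seeded replicates."""
    rng = np.random.default_rng(20250925)
    t = np.arange(5.0, 121.0, 5.0)
    clean = cb.predict_release(
        ReleaseModelFit(model, {param: truth}, 1.0, t.size), t)
    n_rep, n_boot, covered = 200, 400, 0
    for _ in range(n_rep):
        noisy = np.clip(clean + rng.normal(0, 2.0, clean.shape), -2, 105)
        fit = fit_release_model(_profile(noisy, t), model)
        pred = cb.predict_release(fit, t)
        sigma = np.sqrt(np.sum((noisy - pred) ** 2) / (t.size - 1))
        boots = [
            fit_release_model(
                _profile(np.clip(pred + rng.normal(0, sigma, t.size), -2, 105), t),
                model).params[param]
            for _ in range(n_boot)
        ]
        lo, hi = np.percentile(boots, [2.5, 97.5])
        covered += lo <= truth <= hi
    assert covered / n_rep >= 0.90
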