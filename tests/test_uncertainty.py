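"""Near-optimal subsets, Pearson correlations, Wilcoxon significance, KDE."""

import itertools

import numpy as np
import pandas as pd
import pytest

from mokin.fitting import FitResult, JointParams, MultistartEnsemble, build_param_spec
from mokin.uncertainty import (
    CorrelationReport,
    correlation_matrix,
    near_optimal_set,
    pair_density_grid,
    plot_correlation_heatmap,
    plot_pair_density,
    significance_across_subjects,
)

SPEC = build_param_spec()


def make_result(chi2, **overrides):
    rng = np.random.default_rng(0)
    x = 0.5 * (SPEC.lower + SPEC.upper)
    jp = JointParams.from_vector(SPEC, x)
    jp.values.update(overrides)
    return FitResult(
        params=jp, chi2_nu=chi2, per_organ_chi2={}, converged=True,
        n_obs=165, n_free=22,
    )


def make_ensemble(results):
    best = min(results, key=lambda r: r.chi2_nu)
    return MultistartEnsemble(results, best, best.params, 0)


def test_near_optimal_threshold_arithmetic():
    ens = make_ensemble([make_result(c) for c in (1.0, 1.5, 2.0, 2.5)])
    subset = near_optimal_set(ens)
    assert [r.chi2_nu for r in subset] == [1.0, 1.5, 2.0]


def test_near_optimal_full_set_when_identical():
    ens = make_ensemble([make_result(2.0) for _ in range(5)])
    assert len(near_optimal_set(ens)) == 5


def test_near_optimal_independent_of_mode_choice():
    """The set depends only on chi2 values, not which member is the mode."""
    results = [make_result(c) for c in (1.0, 1.2, 3.0)]
    a = MultistartEnsemble(results, results[0], results[0].params, 0)
    b = MultistartEnsemble(results, results[0], results[1].params, 1)
    assert near_optimal_set(a) == near_optimal_set(b)


def test_correlation_requires_three_points():
    with pytest.raises(ValueError, match="< 3"):
        correlation_matrix([make_result(1.0), make_result(1.0)], "liver")


def test_exact_collinearity_gives_unit_correlation():
    rng = np.random.default_rng(4)
    subset = []
    for _ in range(20):
        k1 = rng.uniform(0.5, 3.0)
        subset.append(make_result(1.0, K1_kidneys=k1, k2_kidneys=2.5 * k1))
    rep = correlation_matrix(subset, "kidneys")
    assert rep.r.loc["K1_kidneys", "k2_kidneys"] == pytest.approx(1.0, abs=1e-12)
    assert rep.n_points == 20


def test_zero_variance_reported_missing_not_zero():
    rng = np.random.default_rng(8)
    subset = [
        make_result(1.0, K1_kidneys=rng.uniform(1, 2)) for _ in range(10)
    ]  # every other kidney parameter is constant across the subset
    rep = correlation_matrix(subset, "kidneys")
    assert np.isnan(rep.r.loc["K1_kidneys", "k2_kidneys"])
    assert np.isnan(rep.r.loc["k2_kidneys", "k2_kidneys"])


def test_correlation_matches_two_pass_formula():
    rng = np.random.default_rng(12)
    subset = [
        make_result(
            1.0,
            K1_kidneys=rng.uniform(1, 3),
            k2_kidneys=rng.uniform(0, 4),
            gamma=rng.uniform(0.5, 1.5),
        )
        for _ in range(15)
    ]
    rep = correlation_matrix(subset, "kidneys")
    for a, b in (("K1_kidneys", "k2_kidneys"), ("gamma", "K1_kidneys")):
        xs = np.array([r.params[a] for r in subset])
        ys = np.array([r.params[b] for r in subset])
        mx, my = xs.mean(), ys.mean()
        oracle = np.sum((xs - mx) * (ys - my)) / np.sqrt(
            np.sum((xs - mx) ** 2) * np.sum((ys - my) ** 2)
        )
        assert rep.r.loc[a, b] == pytest.approx(oracle, rel=1e-12)
    # symmetry; unit diagonal for the varying parameters
    np.testing.assert_allclose(rep.r.to_numpy(), rep.r.to_numpy().T)
    for name in ("gamma", "K1_kidneys", "k2_kidneys"):
        assert rep.r.loc[name, name] == 1.0


def report_from_r(val):
    cols = ["gamma", "tau", "K1_kidneys", "k2_kidneys"]
    mat = pd.DataFrame(np.eye(4), index=cols, columns=cols)
    mat.loc["K1_kidneys", "k2_kidneys"] = mat.loc["k2_kidneys", "K1_kidneys"] = val
    return CorrelationReport("kidneys", mat, 10)


def exact_wilcoxon_p(values):
    """Brute-force enumeration of all sign assignments (two-sided)."""
    values = [v for v in values if v != 0]
    ranks = np.argsort(np.argsort(np.abs(values))) + 1.0
    w_obs = sum(r for v, r in zip(values, ranks) if v > 0)
    total = ranks.sum()
    stat_obs = min(w_obs, total - w_obs)
    count = 0
    n = len(values)
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        if min(w, total - w) <= stat_obs:
            count += 1
    return count / 2**n


def test_wilcoxon_all_same_sign_significant():
    rs = (0.9, 0.8, 0.95, 0.85, 0.9, 0.92)
    reports = [report_from_r(v) for v in rs]
    sig, p = significance_across_subjects(reports, ("K1_kidneys", "k2_kidneys"))
    assert sig
    assert p == pytest.approx(2 / 64)
    assert p == pytest.approx(exact_wilcoxon_p(rs))


def test_wilcoxon_alternating_signs_not_significant():
    rs = (0.9, -0.9, 0.9, -0.9, 0.9, -0.9)
    reports = [report_from_r(v) for v in rs]
    sig, p = significance_across_subjects(reports, ("K1_kidneys", "k2_kidneys"))
    assert not sig
    assert p > 0.5


def test_wilcoxon_agrees_with_enumeration_oracle():
    rs = (0.9, 0.8, 0.85, 0.7, 0.95, -0.1)  # smallest magnitude is negative
    reports = [report_from_r(v) for v in rs]
    _, p = significance_across_subjects(reports, ("K1_kidneys", "k2_kidneys"))
    assert p == pytest.approx(exact_wilcoxon_p(rs), rel=1e-12)


def test_wilcoxon_requires_enough_subjects():
    reports = [report_from_r(0.9) for _ in range(4)]
    with pytest.raises(ValueError, match="5 subjects"):
        significance_across_subjects(reports, ("K1_kidneys", "k2_kidneys"))


def test_wilcoxon_undefined_correlation_excluded():
    reports = [report_from_r(0.9) for _ in range(6)]
    reports[2].r.loc["K1_kidneys", "k2_kidneys"] = np.nan
    with pytest.raises(ValueError, match="undefined"):
        significance_across_subjects(reports, ("K1_kidneys", "k2_kidneys"))


def test_pair_density_integrates_to_one():
    rng = np.random.default_rng(3)
    subset = [
        make_result(
            1.0, K1_kidneys=rng.normal(2, 0.3), k2_kidneys=rng.normal(2.5, 0.8)
        )
        for _ in range(40)
    ]
    x, y, dens = pair_density_grid(subset, ("K1_kidneys", "k2_kidneys"))
    mass = np.trapezoid(np.trapezoid(dens, x, axis=1), y)
    assert mass == pytest.approx(1.0, abs=0.01)


def test_plots_render(tmp_path):
    import matplotlib

    matplotlib.use("Agg")
    rng = np.random.default_rng(5)
    subset = [
        make_result(
            1.0, K1_kidneys=rng.normal(2, 0.3), k2_kidneys=rng.normal(2.5, 0.8),
            gamma=rng.normal(0.8, 0.05), tau=rng.normal(0.2, 0.02),
            k3_kidneys=rng.normal(2, 0.2), k4_kidneys=rng.normal(1, 0.1),
            vb_kidneys=rng.normal(0.2, 0.02), delay_kidneys=rng.normal(0.3, 0.05),
        )
        for _ in range(30)
    ]
    rep = correlation_matrix(subset, "kidneys")
    ax = plot_correlation_heatmap(rep)
    ax.figure.savefig(tmp_path / "heatmap.png")
    ax2 = plot_pair_density(subset, ("K1_kidneys", "k2_kidneys"))
    ax2.figure.savefig(tmp_path / "pair.png")
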