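"""Breakpoint design matrices, WLS fits, profiling, GAM and model selection."""

import numpy as np
import pytest

import socthresh as st
from socthresh.models import (
    BreakpointDomainError,
    SingularFitError,
    ThresholdFit,
    breakpoint_grid,
    detect_threshold,
    n_params,
)
from socthresh.simulate import CurveSpec


def test_step_indicator_column():
    X = st.design_matrix("step", np.array([1.0, 2.0, 3.0]), 2.5)
    assert np.allclose(X[:, 1], [0.0, 0.0, 1.0])


def test_segmented_prediction_continuous_at_breakpoint():
    # hinge term is zero exactly at the breakpoint from the left
    e = 2.0
    x = np.array([e - 1e-9, e, e + 1e-9])
    X = st.design_matrix("segmented", x, e)
    beta = np.array([1.0, 0.5, 2.0])
    pred = X @ beta
    assert pred[1] == pytest.approx(pred[0], abs=1e-6)
    assert pred[2] == pytest.approx(pred[1], abs=1e-6)


def test_stegmented_rows_example():
    X = st.design_matrix("stegmented", np.array([10.0, 20.0]), 15.0)
    assert np.allclose(X, [[1, 10, 0, 0], [1, 20, 1, 5]])


def test_hinge_shapes_and_domain_error():
    x = np.linspace(0, 10, 20)
    assert st.design_matrix("hinge12", x, 5.0).shape == (20, 4)
    assert st.design_matrix("hinge22", x, 5.0).shape == (20, 5)
    with pytest.raises(BreakpointDomainError):
        st.design_matrix("segmented", x, 11.0)


def test_wls_matches_normal_equations(rng):
    """Weighted fits agree with an explicit normal-equations solve."""
    fams = ["linear", "quadratic", "step", "segmented", "stegmented", "hinge12", "hinge22"]
    for i in range(100):
        n = 12
        x = np.sort(rng.uniform(0, 10, n))
        y = rng.normal(0, 1, n)
        w = rng.uniform(0.1, 5.0, n)
        fam = fams[i % len(fams)]
        e = 5.0 if fam not in ("linear", "quadratic") else None
        fit = st.fit_at_breakpoint(x, y, w, fam, e, min_side=1)
        X = st.design_matrix(fam, x, e)
        beta = np.linalg.solve(X.T @ (X * w[:, None]), X.T @ (w * y))
        assert np.allclose(fit.coefficients, beta, atol=1e-10)


def test_noiseless_step_recovery():
    x = np.linspace(0, 10, 40)
    y = np.where(x > 6.0, 2.5, 1.0)
    fit = st.fit_at_breakpoint(x, y, None, "step", 6.0)
    assert fit.rss == pytest.approx(0.0, abs=1e-18)
    assert np.allclose(fit.coefficients, [1.0, 1.5], atol=1e-10)
    assert np.isfinite(fit.aic) and np.isfinite(fit.bic)


def test_constant_y_gives_weighted_mean_intercept(rng):
    x = np.linspace(0, 10, 30)
    w = rng.uniform(0.5, 2.0, 30)
    y = np.full(30, 3.7)
    fit = st.fit_at_breakpoint(x, y, w, "segmented", 5.0)
    assert fit.coefficients[0] == pytest.approx(3.7, abs=1e-9)
    assert np.allclose(fit.coefficients[1:], 0.0, atol=1e-9)


def test_rank_deficient_basis_raises():
    x = np.full(12, 3.0)
    with pytest.raises((SingularFitError, BreakpointDomainError)):
        st.fit_at_breakpoint(x, np.ones(12), None, "linear")


def test_profile_matches_exhaustive_scan(rng):
    """Profiled breakpoint minimizes RSS over the whole admissible grid."""
    x = np.sort(rng.uniform(0, 30, 80))
    y = 0.1 + 0.02 * x - 0.05 * np.maximum(x - 14, 0) + rng.normal(0, 0.1, 80)
    w = rng.uniform(0.5, 2.0, 80)
    fit = st.profile_breakpoint(x, y, w, "segmented")
    grid = breakpoint_grid(x)
    rss = [st.fit_at_breakpoint(x, y, w, "segmented", float(e)).rss for e in grid]
    assert fit.rss == pytest.approx(min(rss), rel=1e-12)
    assert fit.breakpoint == pytest.approx(grid[int(np.argmin(rss))])


def test_profile_noiseless_stegmented_recovers_planted_breakpoint():
    x = np.round(np.linspace(5.0, 25.0, 201), 1)  # includes 15.0 on the grid
    curve = CurveSpec(theta=15.0)
    y = curve(x)
    fit = st.profile_breakpoint(x, y, None, "stegmented", refine=True)
    assert fit.breakpoint == pytest.approx(15.0, abs=1e-9)
    assert fit.rss == pytest.approx(0.0, abs=1e-15)


def test_monotone_data_gives_equal_segment_slopes(rng):
    x = np.sort(rng.uniform(0, 30, 300))
    y = 0.05 + 0.02 * x + rng.normal(0, 0.02, 300)
    fit = st.profile_breakpoint(x, y, None, "segmented")
    slope_change = fit.coefficients[2]
    assert abs(slope_change) < 0.01  # below the noise scale of the slope


def test_nested_families_rss_ordering(rng):
    x = np.sort(rng.uniform(0, 30, 100))
    y = rng.normal(0, 1, 100)
    w = rng.uniform(0.2, 3.0, 100)
    e = 15.0
    rss = {
        fam: st.fit_at_breakpoint(x, y, w, fam, e).rss
        for fam in ("linear", "segmented", "stegmented")
    }
    assert rss["stegmented"] <= rss["segmented"] + 1e-9
    assert rss["segmented"] <= rss["linear"] + 1e-9


def test_breakpoint_invariant_to_row_order_and_weight_scale(rng):
    x = np.sort(rng.uniform(0, 30, 120))
    y = 0.1 + 0.03 * x - 0.06 * np.maximum(x - 16, 0) + rng.normal(0, 0.08, 120)
    w = rng.uniform(0.5, 2.0, 120)
    ref = st.profile_breakpoint(x, y, w, "segmented")
    perm = rng.permutation(120)
    shuffled = st.profile_breakpoint(x[perm], y[perm], w[perm], "segmented")
    rescaled = st.profile_breakpoint(x, y, 7.3 * w, "segmented")
    assert shuffled.breakpoint == pytest.approx(ref.breakpoint)
    assert rescaled.breakpoint == pytest.approx(ref.breakpoint)


def test_gam_reproduces_exact_linear_trend(rng):
    x = np.sort(rng.uniform(0, 30, 100))
    y = 0.5 + 0.03 * x
    fit = st.fit_gam(x, y)
    assert np.allclose(fit.fitted, y, atol=1e-6)


def test_quadratic_fit_recovers_parabola():
    x = np.linspace(-3, 3, 30)
    fits = st.fit_linear_quadratic(x, x**2)
    quad = next(f for f in fits if f.family == "quadratic")
    assert np.allclose(quad.coefficients, [0.0, 0.0, 1.0], atol=1e-9)


def test_gam_penalized_orthogonality_identity(rng):
    """<fitted, resid>_W equals lambda * ||D beta||^2 (exact WLS algebra)."""
    x = np.sort(rng.uniform(0, 30, 150))
    y = np.sin(x / 4.0) + rng.normal(0, 0.1, 150)
    w = rng.uniform(0.5, 2.0, 150)
    fit = st.fit_gam(x, y, w)
    resid = y - fit.fitted
    lhs = float((w * fit.fitted) @ resid)
    D = np.diff(np.eye(len(fit.coefficients)), n=2, axis=0)
    rhs = fit.extra["lambda"] * float(np.sum((D @ fit.coefficients) ** 2))
    assert lhs == pytest.approx(rhs, rel=1e-8, abs=1e-10)


def test_gam_fallback_with_few_points():
    x = np.linspace(0, 10, 8)
    with pytest.warns(UserWarning, match="quadratic"):
        fit = st.fit_gam(x, x**2)
    assert fit.extra.get("fallback") == "quadratic"


def test_select_model_prefers_low_bic_and_flags_disagreement():
    def mk(fam, aic, bic, e=None):
        k = 2.0 if fam == "gam" else n_params(fam)
        return ThresholdFit(family=fam, coefficients=np.zeros(2), rss=1.0,
                            k=k, aic=aic, bic=bic,
                            fitted=np.zeros(3), breakpoint=e, n=3)

    comp = st.select_model([mk("linear", 10.0, 12.0), mk("segmented", 11.0, 11.0, 8.0)])
    assert comp.best == "segmented"
    assert comp.aic_bic_disagree is True
    assert comp.threshold == pytest.approx(8.0)
    assert all(row["delta_bic"] >= 0 for row in comp.selection_table)

    # identical criteria: deterministic tie-break by the fixed family order
    tie = st.select_model([mk("stegmented", 5.0, 5.0, 9.0), mk("step", 5.0, 5.0, 9.0)])
    assert tie.best == "step"

    smooth = st.select_model([mk("gam", 3.0, 3.0), mk("segmented", 9.0, 9.0, 8.0)])
    assert smooth.threshold is None


def test_breakpoint_family_wins_on_strong_break(rng):
    x = np.sort(rng.uniform(0, 30, 200))
    y = np.where(x > 15, 1.0, 0.0) + rng.normal(0, 0.05, 200)
    comp = st.compare_families(x, y)
    assert comp.best in ("step", "stegmented")
    assert comp.threshold is not None


def test_selection_power_on_stegmented_truth():
    """With a planted discontinuous slope change (n=300, low noise), a
    piecewise-linear family is selected in at least 80% of seeds."""
    curve = CurveSpec(theta=15.0)
    wins = 0
    n_seeds = 50
    for seed in range(n_seeds):
        rng = np.random.default_rng(1000 + seed)
        x = np.sort(rng.uniform(0.79, 46.1, 300))
        y = curve(x) + rng.normal(0, 0.05, 300)
        comp = st.compare_families(x, y)
        wins += comp.best in ("stegmented", "segmented")
    assert wins >= 0.8 * n_seeds


def test_detect_threshold_gates_on_linear_prefit(rng):
    x = np.sort(rng.uniform(0, 30, 200))
    y = 0.1 + 0.01 * x + rng.normal(0, 0.001, 200)
    prefit, comparison, threshold = detect_threshold(x, y)
    assert prefit.best == "linear"
    assert threshold is None
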