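"""Mann-Whitney U, side-contrast bootstrap and subgroup heterogeneity."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

import socthresh as st
from socthresh.inference import (
    DegenerateGroupingError,
    UnstableBootstrapError,
    mann_whitney_u,
)

from conftest import make_effects


def brute_force_mw_p(a, b):
    """Exact two-sided p by enumerating every assignment of pooled values."""
    a, b = list(a), list(b)
    m = len(a)
    pooled = a + b

    def u_stat(sample_a, sample_b):
        u = 0.0
        for x in sample_a:
            for y in sample_b:
                u += 1.0 if x > y else 0.5 if x == y else 0.0
        return u

    u_obs = u_stat(a, b)
    mn = m * len(b)
    u_min_obs = min(u_obs, mn - u_obs)
    count = total = 0
    for comb in itertools.combinations(range(len(pooled)), m):
        sa = [pooled[i] for i in comb]
        sb = [pooled[i] for i in range(len(pooled)) if i not in comb]
        u = u_stat(sa, sb)
        if min(u, mn - u) <= u_min_obs + 1e-12:
            count += 1
        total += 1
    return u_obs, count / total


def test_identical_samples_give_half_mn():
    u, p = mann_whitney_u([1, 2, 3], [1, 2, 3])
    assert u == pytest.approx(4.5)
    assert p == pytest.approx(1.0)


def test_separated_samples_exact_p():
    u, p = mann_whitney_u([1, 2], [3, 4])
    assert u == 0.0
    assert p == pytest.approx(2.0 / 6.0, abs=1e-12)


@settings(max_examples=100, deadline=None)
@given(
    a=hst.lists(hst.floats(min_value=-5, max_value=5), min_size=1, max_size=8),
    b=hst.lists(hst.floats(min_value=-5, max_value=5), min_size=1, max_size=8),
)
def test_u_complement_identity(a, b):
    ua, _ = mann_whitney_u(a, b)
    ub, _ = mann_whitney_u(b, a)
    assert ua + ub == pytest.approx(len(a) * len(b), abs=1e-9)


def test_exact_p_matches_enumeration(rng):
    """Exact path agrees with brute-force enumeration on tiny samples."""
    for _ in range(25):
        m, n = int(rng.integers(2, 5)), int(rng.integers(2, 5))
        a = rng.normal(0, 1, m).round(2)
        b = rng.normal(0.3, 1, n).round(2)
        if np.unique(np.concatenate([a, b])).size < m + n:
            continue  # exact path handles the untied case
        u, p = mann_whitney_u(a, b)
        u_ref, p_ref = brute_force_mw_p(a, b)
        assert u == pytest.approx(u_ref)
        assert p == pytest.approx(p_ref, abs=1e-12)


def test_asymptotic_p_matches_scipy(rng):
    from scipy.stats import mannwhitneyu as scipy_mw

    a = rng.normal(0, 1, 60)
    b = rng.normal(0.4, 1, 55)
    u, p = mann_whitney_u(a, b)
    ref = scipy_mw(a, b, alternative="two-sided", method="asymptotic",
                   use_continuity=False)
    assert u == pytest.approx(float(ref.statistic))
    assert p == pytest.approx(float(ref.pvalue), rel=1e-9)


def _sided_data(seed, n_side=80, slope_l=0.0, slope_r=0.0, noise=0.1, jump=0.0):
    rng = np.random.default_rng(seed)
    xl = rng.uniform(5, 15, n_side)
    xr = rng.uniform(15, 25, n_side)
    yl = slope_l * (xl - 15) + rng.normal(0, noise, n_side)
    yr = jump + slope_r * (xr - 15) + rng.normal(0, noise, n_side)
    return np.concatenate([xl, xr]), np.concatenate([yl, yr])


def test_side_contrast_deterministic():
    x, y = _sided_data(3, slope_l=0.05, slope_r=-0.05)
    a = st.bootstrap_side_slopes(x, y, threshold=15.0, seed=99)
    b = st.bootstrap_side_slopes(x, y, threshold=15.0, seed=99)
    assert np.array_equal(a.slopes_left, b.slopes_left)
    assert np.array_equal(a.values_right, b.values_right)
    assert (a.mw_u, a.mw_p) == (b.mw_u, b.mw_p)


def test_side_contrast_null_mirrored_sides():
    """With the same data pattern on both sides the slope distributions are
    exchangeable, so significant contrasts are rare (seeded null run)."""
    nonsig = 0
    n_seeds = 40
    for seed in range(n_seeds):
        rng = np.random.default_rng(5000 + seed)
        xl = rng.uniform(5, 15, 60)
        yl = rng.normal(0, 0.1, 60)
        x = np.concatenate([xl, xl + 10.0])  # identical pattern, shifted right
        y = np.concatenate([yl, yl])
        sc = st.bootstrap_side_slopes(x, y, threshold=15.0, seed=seed, n_boot=299)
        nonsig += sc.mw_p > 0.05
    assert nonsig >= 0.9 * n_seeds


def test_side_contrast_power_on_opposite_slopes():
    x, y = _sided_data(11, n_side=150, slope_l=0.05, slope_r=-0.05, noise=0.1)
    sc = st.bootstrap_side_slopes(x, y, threshold=15.0, seed=7)
    assert sc.mw_p < 0.001
    assert np.median(sc.slopes_left) > np.median(sc.slopes_right)


def test_side_contrast_sign_ordering_under_planted_break():
    """Planted rise-then-decline: left slopes exceed right slopes in at
    least 90% of seeds."""
    ok = 0
    n_seeds = 20
    for seed in range(1, n_seeds + 1):
        ds = st.generate_meta_dataset(st.poc_scenario(seed=seed))
        es = st.effect_sizes(ds)
        x = np.array([e.initial_soc for e in es])
        y = np.array([e.lnrr for e in es])
        w = np.array([e.weight for e in es])
        sc = st.bootstrap_side_slopes(x, y, w, threshold=15.0, seed=seed, n_boot=299)
        ok += np.median(sc.slopes_left) > np.median(sc.slopes_right)
    assert ok >= 0.9 * n_seeds


def test_side_contrast_degenerate_side_errors():
    x = np.concatenate([np.full(6, 10.0), np.linspace(16, 25, 20)])
    y = np.zeros_like(x)
    with pytest.raises(UnstableBootstrapError):
        st.bootstrap_side_slopes(x, y, threshold=15.0, seed=1, n_boot=99)
    with pytest.raises(DegenerateGroupingError):
        st.bootstrap_side_slopes(x[:8], y[:8], threshold=15.0, seed=1)


def test_qm_identical_group_means_is_zero():
    effects = make_effects([0.3, 0.3, 0.3, 0.3], [0.1, 0.1, 0.2, 0.2])
    res = st.subgroup_qm(effects, ["a", "a", "b", "b"])
    assert res.qm == pytest.approx(0.0, abs=1e-12)
    assert res.p == pytest.approx(1.0)


def test_qm_hand_computed_two_singletons():
    effects = make_effects([0.0, 1.0], [1.0, 1.0])
    res = st.subgroup_qm(effects, ["a", "b"])
    assert res.qm == pytest.approx(0.5, abs=1e-12)
    assert res.df == 1


def test_qm_equals_total_minus_within(rng):
    """Q_M = Q_total - Q_within (weighted sums-of-squares decomposition)."""
    for _ in range(20):
        n = int(rng.integers(6, 30))
        y = rng.normal(0, 1, n)
        v = rng.uniform(0.05, 1.0, n)
        labels = rng.choice(["a", "b", "c"], n).tolist()
        if len(set(labels)) < 2:
            continue
        effects = make_effects(y, v)
        res = st.subgroup_qm(effects, labels)
        w = 1.0 / v
        mu = (w * y).sum() / w.sum()
        q_total = float((w * (y - mu) ** 2).sum())
        q_within = 0.0
        for g in set(labels):
            mask = np.array(labels) == g
            mug = (w[mask] * y[mask]).sum() / w[mask].sum()
            q_within += float((w[mask] * (y[mask] - mug) ** 2).sum())
        assert res.qm == pytest.approx(q_total - q_within, abs=1e-10)
        assert res.qm >= -1e-12


def test_qm_p_invariant_to_relabeling(rng):
    y = rng.normal(0, 1, 20)
    v = rng.uniform(0.05, 1.0, 20)
    labels = (["a"] * 10) + (["b"] * 10)
    effects = make_effects(y, v)
    p1 = st.subgroup_qm(effects, labels).p
    p2 = st.subgroup_qm(effects, ["x" if l == "b" else "y" for l in labels]).p
    assert p1 == pytest.approx(p2, rel=1e-12)


def test_qm_single_group_errors():
    effects = make_effects([0.1, 0.2], [0.1, 0.1])
    with pytest.raises(DegenerateGroupingError):
        st.subgroup_qm(effects, ["a", "a"])


def test_threshold_qm_closed_left_convention():
    effects = make_effects([0.1, 0.2, 0.5, 0.6], [0.1] * 4, socs=[10, 15.0, 15.1, 20])
    res = st.threshold_qm(effects, 15.0)
    # the observation at exactly 15.0 joins the 'below' group
    assert res.group_effects["below"] == pytest.approx((0.1 + 0.2) / 2)
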