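"""Evidence that effect-size behaviour differs either side of a threshold.

Two complementary checks run once a breakpoint has been estimated:

* a side-contrast bootstrap — linear regressions are refitted on ``n_boot``
  observation-level resamples of each side of the threshold, the slope and
  the predicted lnRR at the threshold are collected per replicate, and the
  left/right distributions are compared with a Mann-Whitney U test;
* a between-group heterogeneity test — fixed-effect subgroup means on either
  side and the Q_M statistic, chi-square distributed (df = groups - 1) under
  homogeneity.

Observations exactly at the threshold belong to the left side.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.stats import chi2, norm, rankdata

from .meta import EffectSize, SocthreshError


class DegenerateGroupingError(SocthreshError):
    pass


class UnstableBootstrapError(SocthreshError):
    pass


@dataclass
class SideContrast:
    threshold: float
    slopes_left: np.ndarray
    slopes_right: np.ndarray
    values_left: np.ndarray
    values_right: np.ndarray
    mw_u: float
    mw_p: float
    value_mw_u: float
    value_mw_p: float
    n_boot: int
    seed: int
    n_left: int = 0
    n_right: int = 0
    discarded_left: int = 0
    discarded_right: int = 0

    def summary(self) -> dict:
        def stats(v):
            return {
                "median": float(np.median(v)),
                "q025": float(np.percentile(v, 2.5)),
                "q975": float(np.percentile(v, 97.5)),
            }

        return {
            "threshold": self.threshold,
            "slope_left": stats(self.slopes_left),
            "slope_right": stats(self.slopes_right),
            "value_left": stats(self.values_left),
            "value_right": stats(self.values_right),
            "slope_mw_u": self.mw_u,
            "slope_mw_p": self.mw_p,
            "value_mw_u": self.value_mw_u,
            "value_mw_p": self.value_mw_p,
            "n_boot": self.n_boot,
            "seed": self.seed,
            "n_left": self.n_left,
            "n_right": self.n_right,
            "discarded_left": self.discarded_left,
            "discarded_right": self.discarded_right,
        }


@dataclass
class SubgroupHeterogeneity:
    qm: float
    df: int
    p: float
    group_effects: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Mann-Whitney U


@lru_cache(maxsize=None)
def _u_counts(m: int, n: int) -> tuple:
    """Null distribution of U for sample sizes (m, n) without ties.

    Classic counting recurrence N(u; m, n) = N(u - n; m-1, n) + N(u; m, n-1):
    the number of arrangements of m 'a'-ranks among m+n with U statistic u.
    """
    if m == 0 or n == 0:
        return (1,)
    a = _u_counts(m - 1, n)  # last element from sample b contributes n to U? (shifted)
    b = _u_counts(m, n - 1)
    size = m * n + 1
    out = [0] * size
    for u, c in enumerate(a):
        out[u + n] += c
    for u, c in enumerate(b):
        out[u] += c
    return tuple(out)


def mann_whitney_u(a, b, exact_limit: int = 400) -> tuple[float, float]:
    """Mann-Whitney U (midrank ties) with a two-sided p-value.

    The exact null distribution (counting recurrence) is used when
    ``len(a)*len(b) <= exact_limit`` and there are no ties; otherwise the
    tie-corrected normal approximation.  Returns ``(U_a, p)`` where ``U_a``
    counts, over all pairs, b-values beaten by a (ties count one half).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    m, n = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    r_a = ranks[:m].sum()
    u_a = r_a - m * (m + 1) / 2.0

    has_ties = np.unique(pooled).size < pooled.size
    if not has_ties and m * n <= exact_limit:
        counts = _u_counts(m, n)
        total = sum(counts)
        u_int = int(round(u_a))
        u_min = min(u_int, m * n - u_int)
        p = 2.0 * sum(counts[: u_min + 1]) / total
        return float(u_a), min(1.0, p)

    # normal approximation with tie correction
    mu = m * n / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / ((m + n) * (m + n - 1.0))
    sigma2 = m * n / 12.0 * ((m + n + 1.0) - tie_term)
    if sigma2 <= 0:
        return float(u_a), 1.0  # all values identical
    z = (u_a - mu) / math.sqrt(sigma2)
    p = 2.0 * norm.sf(abs(z))
    return float(u_a), min(1.0, float(p))


# ---------------------------------------------------------------------------
# side-contrast bootstrap


def _boot_lines(
    x: np.ndarray, y: np.ndarray, w: np.ndarray, x0: float,
    n_boot: int, rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Vectorized weighted straight-line fits on observation resamples.

    Returns (slopes, predictions at x0, number of discarded replicates);
    replicates whose resampled x-values are all identical (zero weighted
    variance) cannot support a slope and are discarded.
    """
    n = x.size
    idx = rng.integers(0, n, size=(n_boot, n))
    xb, yb, wb = x[idx], y[idx], w[idx]
    sw = wb.sum(axis=1)
    xbar = (wb * xb).sum(axis=1) / sw
    ybar = (wb * yb).sum(axis=1) / sw
    sxx = (wb * (xb - xbar[:, None]) ** 2).sum(axis=1)
    sxy = (wb * (xb - xbar[:, None]) * (yb - ybar[:, None])).sum(axis=1)
    ok = sxx > 1e-12 * np.maximum(1.0, xbar**2) * sw
    slopes = np.where(ok, sxy / np.where(ok, sxx, 1.0), np.nan)
    values = ybar + slopes * (x0 - xbar)
    return slopes[ok], values[ok], int((~ok).sum())


def bootstrap_side_slopes(
    x, y, w=None, threshold: float = 0.0,
    n_boot: int = 999, seed: int | None = None,
    min_side: int = 5, max_discard_frac: float = 0.2,
) -> SideContrast:
    """Bootstrap linear regressions on each side of ``threshold``.

    Each side is resampled at the observation level ``n_boot`` times; per
    replicate a weighted straight line gives the slope and the predicted
    lnRR at the threshold.  The left/right slope (and value) distributions
    are compared with a Mann-Whitney U test.  Points at the threshold go to
    the left side.
    """
    if seed is None:
        raise ValueError("seed is required for the side-contrast bootstrap")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.ones_like(x) if w is None else np.asarray(w, dtype=float)
    left = x <= threshold
    n_left, n_right = int(left.sum()), int((~left).sum())
    if min(n_left, n_right) < min_side:
        raise DegenerateGroupingError(
            f"fewer than {min_side} observations on one side of {threshold}"
        )
    rng = np.random.default_rng(seed)
    sl, vl, dl = _boot_lines(x[left], y[left], w[left], threshold, n_boot, rng)
    sr, vr, dr = _boot_lines(x[~left], y[~left], w[~left], threshold, n_boot, rng)
    if dl > max_discard_frac * n_boot or dr > max_discard_frac * n_boot:
        raise UnstableBootstrapError(
            f"discarded {dl}/{dr} of {n_boot} replicates (left/right)"
        )
    mw_u, mw_p = mann_whitney_u(sl, sr)
    vu, vp = mann_whitney_u(vl, vr)
    return SideContrast(
        threshold=float(threshold),
        slopes_left=sl, slopes_right=sr, values_left=vl, values_right=vr,
        mw_u=mw_u, mw_p=mw_p, value_mw_u=vu, value_mw_p=vp,
        n_boot=n_boot, seed=seed, n_left=n_left, n_right=n_right,
        discarded_left=dl, discarded_right=dr,
    )


# ---------------------------------------------------------------------------
# subgroup heterogeneity


def subgroup_qm(effects: list[EffectSize], labels) -> SubgroupHeterogeneity:
    """Between-group heterogeneity Q_M of fixed-effect subgroup means.

    Q_M = sum_g W_g (mu_g - mu)^2 with W_g the summed weights of group g and
    mu the overall fixed-effect mean; p from chi-square with df = G - 1.
    """
    labels = list(labels)
    if len(labels) != len(effects):
        raise ValueError("labels must match effects one-to-one")
    y = np.array([es.lnrr for es in effects])
    w = np.array([es.weight for es in effects])
    groups = sorted(set(labels), key=str)
    if len(groups) < 2:
        raise DegenerateGroupingError("need >= 2 groups for Q_M")
    lab_arr = np.asarray(labels, dtype=object)
    mu = (w * y).sum() / w.sum()
    qm = 0.0
    group_effects = {}
    for g in groups:
        mask = lab_arr == g
        wg = w[mask].sum()
        mug = (w[mask] * y[mask]).sum() / wg
        qm += wg * (mug - mu) ** 2
        group_effects[str(g)] = float(mug)
    df = len(groups) - 1
    p = float(chi2.sf(qm, df))
    return SubgroupHeterogeneity(qm=float(qm), df=df, p=p, group_effects=group_effects)


def threshold_qm(effects: list[EffectSize], threshold: float) -> SubgroupHeterogeneity:
    """Q_M between observations below/at versus above the SOC threshold."""
    labels = ["below" if es.initial_soc <= threshold else "above" for es in effects]
    return subgroup_qm(effects, labels)
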