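"""Breakpoint regression families for effect size versus initial SOC.

The effect-size curve lnRR(x), with x the initial soil organic carbon content
(g C/kg), is fitted by weighted least squares under eight families:

==========  ==============================================================
linear      a + b x
quadratic   a + b x + c x^2
step        two intercepts: a + d I(x > e)
segmented   continuous slope change: a + b x + g (x - e)_+
stegmented  slope *and* intercept change: a + b x + d I(x > e) + g (x - e)_+
hinge12     linear left, quadratic right (continuous): a + b x + g (x-e)_+ + h (x-e)_+^2
hinge22     quadratic both sides (continuous): a + b x + c x^2 + g (x-e)_+ + h (x-e)_+^2
gam         penalized cubic B-spline smoother (P-spline, GCV)
==========  ==============================================================

(x - e)_+ denotes max(x - e, 0).  The breakpoint e is profiled over the
observed SOC values between the 10th and 90th percentiles (optionally refined
to a 0.1 g/kg lattice) and the candidate minimizing the weighted RSS wins.
Families are compared on a common Gaussian-likelihood scale,

    AIC = n ln(RSS/n) + 2k,   BIC = n ln(RSS/n) + k ln n,

where k counts the regression coefficients plus one for a profiled
breakpoint (GAM uses its effective degrees of freedom).  The lowest BIC
selects the family; a threshold is only reported when the winner actually
has a breakpoint.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

from .meta import SocthreshError

BREAKPOINT_FAMILIES = ("step", "segmented", "stegmented", "hinge12", "hinge22")
SMOOTH_FAMILIES = ("linear", "quadratic", "gam")
ALL_FAMILIES = BREAKPOINT_FAMILIES + SMOOTH_FAMILIES

#: deterministic tie-break order for model selection
TIE_ORDER = ("step", "hinge12", "hinge22", "segmented", "stegmented", "gam",
             "linear", "quadratic")


class SingularFitError(SocthreshError):
    pass


class BreakpointDomainError(SocthreshError):
    pass


class InsufficientSpanError(SocthreshError):
    pass


@dataclass
class ThresholdFit:
    family: str
    coefficients: np.ndarray
    rss: float
    k: float
    aic: float
    bic: float
    fitted: np.ndarray
    breakpoint: float | None = None
    n: int = 0
    extra: dict = field(default_factory=dict)

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.family == "gam":
            dm = BSpline.design_matrix(
                np.clip(x, self.extra["x_min"], self.extra["x_max"]),
                self.extra["knots"], 3
            ).toarray()
            return dm @ self.coefficients
        X = design_matrix(self.family, x, self.breakpoint)
        return X @ self.coefficients


@dataclass
class ModelComparison:
    fits: list
    best: str
    selection_table: list
    aic_bic_disagree: bool
    threshold: float | None

    @property
    def best_fit(self) -> ThresholdFit:
        return next(f for f in self.fits if f.family == self.best)


# ---------------------------------------------------------------------------
# design matrices and WLS


def design_matrix(family: str, x, e: float | None = None) -> np.ndarray:
    """Regression basis for one family at breakpoint ``e`` (where applicable)."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("x must be nonempty")
    one = np.ones_like(x)
    if family == "linear":
        return np.column_stack([one, x])
    if family == "quadratic":
        return np.column_stack([one, x, x**2])
    if family not in BREAKPOINT_FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    if e is None:
        raise ValueError(f"family {family!r} requires a breakpoint")
    if not (x.min() < e < x.max()):
        raise BreakpointDomainError(
            f"breakpoint {e} outside data range ({x.min()}, {x.max()})"
        )
    ind = (x > e).astype(float)
    hinge = np.maximum(x - e, 0.0)
    if family == "step":
        return np.column_stack([one, ind])
    if family == "segmented":
        return np.column_stack([one, x, hinge])
    if family == "stegmented":
        return np.column_stack([one, x, ind, hinge])
    if family == "hinge12":
        return np.column_stack([one, x, hinge, hinge**2])
    # hinge22
    return np.column_stack([one, x, x**2, hinge, hinge**2])


def n_params(family: str) -> int:
    """Parameter count on the common AIC/BIC scale (breakpoint counts as one)."""
    base = {"linear": 2, "quadratic": 3, "step": 2, "segmented": 3,
            "stegmented": 4, "hinge12": 4, "hinge22": 5}[family]
    return base + (1 if family in BREAKPOINT_FAMILIES else 0)


def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, float]:
    """Weighted least squares via the scaled lstsq system; returns (beta, wrss)."""
    sw = np.sqrt(w)
    Xs = X * sw[:, None]
    ys = y * sw
    beta, _, rank, _ = np.linalg.lstsq(Xs, ys, rcond=None)
    if rank < X.shape[1]:
        raise SingularFitError(f"rank-deficient basis (rank {rank} < {X.shape[1]})")
    resid = y - X @ beta
    return beta, float(w @ resid**2)


def _ic(rss: float, n: int, k: float) -> tuple[float, float]:
    # floor keeps AIC/BIC finite on exact (noiseless) fits
    rss = max(rss, 1e-300)
    base = n * math.log(rss / n)
    return base + 2 * k, base + k * math.log(n)


def fit_at_breakpoint(
    x, y, w=None, family: str = "stegmented", e: float | None = None,
    min_side: int = 5,
) -> ThresholdFit:
    """WLS fit of one family at a fixed breakpoint ``e``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.ones_like(x) if w is None else np.asarray(w, dtype=float)
    if family in BREAKPOINT_FAMILIES:
        n_left = int((x <= e).sum())
        n_right = x.size - n_left
        if min(n_left, n_right) < min_side:
            raise BreakpointDomainError(
                f"fewer than {min_side} observations on one side of e={e}"
            )
    X = design_matrix(family, x, e)
    beta, rss = _wls(X, y, w)
    k = n_params(family)
    aic, bic = _ic(rss, x.size, k)
    return ThresholdFit(
        family=family, coefficients=beta, rss=rss, k=k, aic=aic, bic=bic,
        fitted=X @ beta, breakpoint=e if family in BREAKPOINT_FAMILIES else None,
        n=x.size,
    )


# ---------------------------------------------------------------------------
# breakpoint profiling


def breakpoint_grid(
    x, min_side: int = 5, lo_q: float = 0.10, hi_q: float = 0.90,
    refine: bool = False, step: float = 0.1,
) -> np.ndarray:
    """Candidate breakpoints: observed SOC values between the 10th/90th
    percentiles with at least ``min_side`` observations strictly on each side;
    ``refine`` snaps to a uniform ``step`` g/kg lattice over the same span."""
    x = np.asarray(x, dtype=float)
    lo, hi = np.quantile(x, [lo_q, hi_q])
    if refine:
        # snap to exact lattice values so a planted on-grid breakpoint is hit
        cand = np.round(np.arange(math.ceil(lo / step) * step, hi + step / 2, step), 6)
    else:
        cand = np.unique(x[(x >= lo) & (x <= hi)])
    xs = np.sort(x)
    keep = []
    for e in cand:
        n_left = int(np.searchsorted(xs, e, side="right"))
        if n_left >= min_side and (x.size - n_left) >= min_side and xs[0] < e < xs[-1]:
            keep.append(e)
    if not keep:
        raise InsufficientSpanError("no admissible breakpoint candidates")
    return np.asarray(keep)


def profile_breakpoint(
    x, y, w=None, family: str = "stegmented", grid=None,
    min_side: int = 5, refine: bool = False,
) -> ThresholdFit:
    """Scan candidate breakpoints, return the minimum-weighted-RSS fit.

    Ties in RSS break toward the smaller breakpoint.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.ones_like(x) if w is None else np.asarray(w, dtype=float)
    if grid is None:
        grid = breakpoint_grid(x, min_side=min_side, refine=refine)
    best = None
    for e in np.sort(np.asarray(grid, dtype=float)):
        try:
            fit = fit_at_breakpoint(x, y, w, family, float(e), min_side=min_side)
        except (SingularFitError, BreakpointDomainError):
            continue
        if best is None or fit.rss < best.rss - 1e-12 * max(1.0, best.rss):
            best = fit
    if best is None:
        raise InsufficientSpanError(f"no admissible fit for family {family!r}")
    return best


# ---------------------------------------------------------------------------
# smooth families


def fit_linear_quadratic(x, y, w=None) -> list[ThresholdFit]:
    """WLS polynomial fits used in the linear-vs-nonlinear prefit."""
    return [fit_at_breakpoint(x, y, w, fam) for fam in ("linear", "quadratic")]


def fit_gam(
    x, y, w=None, n_basis: int = 10,
    lambdas: np.ndarray | None = None,
) -> ThresholdFit:
    """Penalized cubic B-spline smoother (P-spline) selected by GCV.

    Uniform knots spanning the data (extended beyond the range so linear
    trends lie in the penalty's null space), second-difference coefficient
    penalty, smoothing parameter chosen by generalized cross-validation.
    Effective degrees of freedom = trace of the hat matrix, used as k in
    AIC/BIC.  With fewer observations than basis functions the fit falls
    back to a quadratic with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.ones_like(x) if w is None else np.asarray(w, dtype=float)
    n = x.size
    if n < n_basis:
        warnings.warn("too few observations for the spline basis; using quadratic")
        fit = fit_at_breakpoint(x, y, w, "quadratic")
        fit.extra["fallback"] = "quadratic"
        return fit
    if lambdas is None:
        lambdas = np.logspace(-4, 8, 61)

    deg = 3
    nseg = n_basis - deg
    lo, hi = float(x.min()), float(x.max())
    h = (hi - lo) / nseg
    # endpoints must be exact so boundary observations stay in the basis span
    knots = np.concatenate(
        [lo - h * np.arange(deg, 0, -1), np.linspace(lo, hi, nseg + 1),
         hi + h * np.arange(1, deg + 1)]
    )
    B = BSpline.design_matrix(x, knots, deg).toarray()
    D = np.diff(np.eye(n_basis), n=2, axis=0)
    P = D.T @ D

    BtWB = B.T @ (B * w[:, None])
    BtWy = B.T @ (w * y)
    best = None
    for lam in lambdas:
        A = BtWB + lam * P
        try:
            beta = np.linalg.solve(A, BtWy)
            edf = float(np.trace(np.linalg.solve(A, BtWB)))
        except np.linalg.LinAlgError:
            continue
        resid = y - B @ beta
        wrss = float(w @ resid**2)
        denom = max(n - edf, 1e-8)
        gcv = n * wrss / denom**2
        if best is None or gcv < best[0]:
            best = (gcv, lam, beta, edf, wrss)
    if best is None:
        raise SingularFitError("GAM smoothing failed at all lambda values")
    _, lam, beta, edf, wrss = best
    aic, bic = _ic(wrss, n, edf)
    return ThresholdFit(
        family="gam", coefficients=beta, rss=wrss, k=edf, aic=aic, bic=bic,
        fitted=B @ beta, n=n,
        extra={"lambda": float(lam), "knots": knots, "x_min": lo, "x_max": hi},
    )


# ---------------------------------------------------------------------------
# model selection


def select_model(fits: list[ThresholdFit]) -> ModelComparison:
    """Pick the family with the lowest BIC (ties by fixed family order).

    A disagreement flag is set when AIC and BIC favour different families.
    The threshold is reported only when the winning family has a breakpoint.
    """
    if len(fits) < 2:
        raise ValueError("need >= 2 fits to compare")
    order = {fam: i for i, fam in enumerate(TIE_ORDER)}

    def key(criterion):
        return lambda f: (round(getattr(f, criterion), 10), order.get(f.family, 99))

    best_bic = min(fits, key=key("bic"))
    best_aic = min(fits, key=key("aic"))
    min_aic = min(f.aic for f in fits)
    min_bic = min(f.bic for f in fits)
    table = [
        {
            "family": f.family,
            "aic": f.aic,
            "bic": f.bic,
            "delta_aic": f.aic - min_aic,
            "delta_bic": f.bic - min_bic,
            "breakpoint": f.breakpoint,
        }
        for f in sorted(fits, key=key("bic"))
    ]
    threshold = best_bic.breakpoint if best_bic.family in BREAKPOINT_FAMILIES else None
    return ModelComparison(
        fits=fits,
        best=best_bic.family,
        selection_table=table,
        aic_bic_disagree=best_aic.family != best_bic.family,
        threshold=threshold,
    )


def compare_families(
    x, y, w=None,
    families: tuple = BREAKPOINT_FAMILIES + ("gam",),
    min_side: int = 5, refine: bool = False,
) -> ModelComparison:
    """Profile every breakpoint family plus the GAM and select by BIC."""
    fits = []
    for fam in families:
        if fam in BREAKPOINT_FAMILIES:
            fits.append(profile_breakpoint(x, y, w, fam, min_side=min_side, refine=refine))
        elif fam == "gam":
            fits.append(fit_gam(x, y, w))
        else:
            fits.append(fit_at_breakpoint(x, y, w, fam))
    return select_model(fits)


def detect_threshold(
    x, y, w=None, min_side: int = 5, refine: bool = False,
) -> tuple[ModelComparison, ModelComparison, float | None]:
    """The full two-stage threshold detection procedure.

    Stage one is the linear-vs-nonlinear prefit (linear, quadratic, GAM);
    stage two is the breakpoint-family comparison.  A threshold is reported
    only when the prefit prefers a nonlinear shape and stage two picks a
    family that has a breakpoint.  Returns (prefit, comparison, threshold).
    """
    prefit = select_model(fit_linear_quadratic(x, y, w) + [fit_gam(x, y, w)])
    comparison = compare_families(x, y, w, min_side=min_side, refine=refine)
    threshold = comparison.threshold if prefit.best != "linear" else None
    return prefit, comparison, threshold
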