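"""Publication-bias and robustness battery for the meta-dataset.

* Egger's regression — the standard normal deviate lnRR/SE regressed on the
  precision 1/SE; a nonzero intercept indicates funnel asymmetry.
* Rosenthal fail-safe number — how many null studies would be needed to wash
  out the combined evidence; judged against the classic 5n + 10 criterion.
* Jackknife — leave-one-study-out pooled estimates (analytic CIs, so the
  table is deterministic) with a robustness flag: every leave-one-out
  estimate shares the full-data estimate's sign and significance.
* Temporal trend — weighted meta-regression of lnRR on publication year.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy.stats import norm

from .meta import Z95, EffectSize, SocthreshError, _re_estimate


class IllConditionedError(SocthreshError):
    pass


class InsufficientStudiesError(SocthreshError):
    pass


@dataclass
class BiasReport:
    egger_intercept: float
    egger_p: float
    failsafe_n: int
    failsafe_criterion: int
    failsafe_pass: bool
    jackknife: list
    jackknife_robust: bool
    temporal_beta: float | None
    temporal_p: float | None
    notes: dict = field(default_factory=dict)


def eggers_test(effects: list[EffectSize]) -> tuple[float, float]:
    """Egger's funnel-asymmetry test.

    OLS of z_i = lnRR_i / SE_i on precision 1/SE_i; returns the intercept
    and its two-sided t-test p-value.
    """
    usable = [es for es in effects if es.v > 0]
    if len(usable) < 3:
        raise SocthreshError("Egger's test needs >= 3 observations with v > 0")
    se = np.array([math.sqrt(es.v) for es in usable])
    z = np.array([es.lnrr for es in usable]) / se
    prec = 1.0 / se
    if np.ptp(prec) < 1e-12 * max(1.0, float(np.abs(prec).max())):
        raise IllConditionedError("constant precision; Egger regression ill-conditioned")
    X = sm.add_constant(prec)
    res = sm.OLS(z, X).fit()
    return float(res.params[0]), float(res.pvalues[0])


def failsafe_n(effects: list[EffectSize], alpha: float = 0.05) -> dict:
    """Rosenthal fail-safe number with the 5n + 10 robustness criterion.

    N_fs = floor[(sum z_i)^2 / z_alpha^2 - n] clipped at zero, with
    z_i = lnRR_i / SE_i and z_alpha the one-tailed normal quantile.
    """
    if not effects:
        raise SocthreshError("failsafe_n needs >= 1 observation")
    z = np.array([es.lnrr / math.sqrt(es.v) for es in effects if es.v > 0])
    n = len(effects)
    z_alpha = float(norm.ppf(1.0 - alpha))
    nfs = max(0, math.floor((z.sum()) ** 2 / z_alpha**2 - n))
    criterion = 5 * n + 10
    return {
        "failsafe_n": int(nfs),
        "criterion": int(criterion),
        "passes": bool(nfs > criterion),
        "n_obs": n,
    }


def jackknife(effects: list[EffectSize], method: str = "random") -> dict:
    """Leave-one-study-out pooled estimates with analytic 95% CIs.

    Each row removes every observation of one study and re-pools the rest.
    The robustness flag is true when all leave-one-out estimates agree with
    the full-data estimate in sign and in significance (CI excluding zero
    or not).
    """
    studies = sorted({es.study_id for es in effects})
    if len(studies) < 3:
        raise InsufficientStudiesError("jackknife needs >= 3 studies")
    y = np.array([es.lnrr for es in effects])
    w = np.array([es.weight for es in effects])
    sid = np.array([es.study_id for es in effects])

    def pooled(mask):
        mu, tau2, se = _re_estimate(y[mask], w[mask], method)
        return mu, mu - Z95 * se, mu + Z95 * se

    full_mu, full_lo, full_hi = pooled(np.ones(len(effects), dtype=bool))
    full_sig = full_lo > 0 or full_hi < 0
    rows, robust = [], True
    for s in studies:
        mask = sid != s
        mu, lo, hi = pooled(mask)
        sig = lo > 0 or hi < 0
        rows.append({"study_id": s, "estimate": mu, "ci_low": lo, "ci_high": hi,
                     "n_obs": int(mask.sum())})
        if (mu > 0) != (full_mu > 0) or sig != full_sig:
            robust = False
    return {
        "full": {"estimate": full_mu, "ci_low": full_lo, "ci_high": full_hi},
        "rows": rows,
        "robust": robust,
    }


def temporal_trend(effects: list[EffectSize], year_key: str = "pub_year") -> tuple[float, float]:
    """Weighted meta-regression of lnRR on publication year (slope per year)."""
    pairs = [
        (es.lnrr, es.weight, float(es.moderators[year_key]))
        for es in effects
        if year_key in es.moderators
    ]
    if len(pairs) < 3:
        raise SocthreshError("temporal trend needs >= 3 observations with a year")
    y, w, yr = (np.array(col) for col in zip(*pairs))
    if np.unique(yr).size < 2:
        raise IllConditionedError("single publication year; trend undefined")
    if np.unique(yr).size < 3:
        raise SocthreshError("temporal trend needs >= 3 distinct years")
    X = sm.add_constant(yr)
    res = sm.WLS(y, X, weights=w).fit()
    return float(res.params[1]), float(res.pvalues[1])


def effect_histogram(effects: list[EffectSize], n_bins: int = 30) -> dict:
    """Binned lnRR counts for distribution inspection (plot-ready CSV data)."""
    y = np.array([es.lnrr for es in effects])
    counts, edges = np.histogram(y, bins=n_bins)
    return {"bin_edges": edges.tolist(), "counts": counts.tolist()}


def bias_battery(effects: list[EffectSize], method: str = "random") -> BiasReport:
    """Run the full diagnostics battery, tolerating absent moderators."""
    egger_i, egger_p = eggers_test(effects)
    fs = failsafe_n(effects)
    jk = jackknife(effects, method=method)
    try:
        beta, p = temporal_trend(effects)
    except SocthreshError:
        beta, p = None, None
    return BiasReport(
        egger_intercept=egger_i,
        egger_p=egger_p,
        failsafe_n=fs["failsafe_n"],
        failsafe_criterion=fs["criterion"],
        failsafe_pass=fs["passes"],
        jackknife=jk["rows"],
        jackknife_robust=jk["robust"],
        temporal_beta=beta,
        temporal_p=p,
        notes={"histogram": effect_histogram(effects)},
    )
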