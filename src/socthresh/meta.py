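"""Effect sizes, pooling and dataset I/O for the multi-study observation table.

The meta-analytic unit is a treatment/control pair of soil-carbon-fraction
measurements (POC, MAOC or bulk SOC, g C/kg).  The effect size is the natural
log response ratio

    lnRR = ln(mean_trt / mean_ctl)

with sampling variance, from the delta method applied to the two sample means,

    v = sd_trt^2 / (n_trt * mean_trt^2) + sd_ctl^2 / (n_ctl * mean_ctl^2)

Observations are weighted by 1/v.  Pooling is a random-effects
inverse-variance average with a DerSimonian-Laird between-study variance
(fixed-effect mode available), and confidence intervals come from a
percentile bootstrap that resamples whole studies with replacement so that
within-study dependence is respected.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

Z95 = 1.959963984540054  # two-sided 95% normal quantile

FRACTIONS = ("POC", "MAOC", "SOC")
ECOZONES = ("tropical", "subtropical", "temperate", "boreal")

#: mandatory columns of the observation CSV schema
REQUIRED_COLUMNS = (
    "study_id",
    "obs_id",
    "fraction",
    "mean_trt",
    "sd_trt",
    "n_trt",
    "mean_ctl",
    "sd_ctl",
    "n_ctl",
    "initial_soc",
)

#: recognised optional moderator columns (anything else is kept as a moderator too)
KNOWN_MODERATORS = (
    "ph",
    "tn",
    "clay_silt",
    "mat",
    "map",
    "n_rate",
    "duration",
    "pub_year",
    "ecozone",
)


class SocthreshError(Exception):
    """Base class for package errors."""


class InvalidObservationError(SocthreshError):
    pass


class SchemaError(SocthreshError):
    pass


class DegenerateWeightsError(SocthreshError):
    pass


class CannotImputeError(SocthreshError):
    pass


@dataclass
class StudyObservation:
    """One treatment/control pair with its moderators.

    Means and SDs are fraction contents in g C/kg; ``initial_soc`` is the
    pre-experiment soil organic carbon content in g C/kg.
    """

    study_id: str
    obs_id: str
    fraction: str
    mean_trt: float
    mean_ctl: float
    n_trt: int
    n_ctl: int
    initial_soc: float
    sd_trt: float | None = None
    sd_ctl: float | None = None
    moderators: dict = field(default_factory=dict)
    sd_imputed: bool = False

    def validate(self) -> None:
        if self.fraction not in FRACTIONS:
            raise InvalidObservationError(
                f"{self.obs_id}: fraction must be one of {FRACTIONS}, got {self.fraction!r}"
            )
        if not (self.mean_trt > 0 and self.mean_ctl > 0):
            raise InvalidObservationError(
                f"{self.obs_id}: nonpositive mean (lnRR undefined)"
            )
        if self.n_trt < 1 or self.n_ctl < 1:
            raise InvalidObservationError(f"{self.obs_id}: replicate counts must be >= 1")
        if not self.initial_soc > 0:
            raise InvalidObservationError(f"{self.obs_id}: initial_soc must be > 0")
        for name, s in (("sd_trt", self.sd_trt), ("sd_ctl", self.sd_ctl)):
            if s is not None and s < 0:
                raise InvalidObservationError(f"{self.obs_id}: {name} must be >= 0")


@dataclass
class EffectSize:
    """lnRR with its sampling variance, weight and CI-based response class."""

    study_id: str
    obs_id: str
    lnrr: float
    v: float
    weight: float
    ci_low: float
    ci_high: float
    response_class: str
    initial_soc: float = float("nan")
    moderators: dict = field(default_factory=dict)
    weight_capped: bool = False
    sd_imputed: bool = False


@dataclass
class PooledResult:
    """Random- (or fixed-) effects pooled lnRR with bootstrap CI."""

    estimate: float
    ci_low: float
    ci_high: float
    tau2: float
    n_obs: int
    n_studies: int
    class_counts: dict
    pvalue: float
    method: str = "random"
    n_boot: int = 999
    seed: int | None = None


# ---------------------------------------------------------------------------
# elementary effect-size operations


def compute_lnrr(obs: StudyObservation) -> float:
    """Natural log response ratio ln(mean_trt / mean_ctl)."""
    if not (obs.mean_trt > 0 and obs.mean_ctl > 0):
        raise InvalidObservationError(f"{obs.obs_id}: nonpositive mean (lnRR undefined)")
    return math.log(obs.mean_trt / obs.mean_ctl)


def compute_variance(obs: StudyObservation) -> float:
    """Sampling variance of lnRR from replicate SDs, means and counts."""
    if obs.sd_trt is None or obs.sd_ctl is None:
        raise InvalidObservationError(f"{obs.obs_id}: missing SD; impute or exclude first")
    if obs.sd_trt < 0 or obs.sd_ctl < 0:
        raise InvalidObservationError(f"{obs.obs_id}: negative SD")
    if obs.n_trt < 1 or obs.n_ctl < 1:
        raise InvalidObservationError(f"{obs.obs_id}: replicate counts must be >= 1")
    if not (obs.mean_trt > 0 and obs.mean_ctl > 0):
        raise InvalidObservationError(f"{obs.obs_id}: nonpositive mean")
    return obs.sd_trt**2 / (obs.n_trt * obs.mean_trt**2) + obs.sd_ctl**2 / (
        obs.n_ctl * obs.mean_ctl**2
    )


def classify_response(lnrr, v: float | None = None) -> str:
    """Classify one observation by the sign of its 95% CI.

    ``positive`` if the lower bound exceeds zero, ``negative`` if the upper
    bound is below zero, ``neutral`` otherwise (CI spans zero).  Accepts
    either an ``EffectSize`` or an (lnrr, v) pair.
    """
    if isinstance(lnrr, EffectSize):
        lnrr, v = lnrr.lnrr, lnrr.v
    if v < 0:
        raise InvalidObservationError("variance must be >= 0")
    half = Z95 * math.sqrt(v)
    if lnrr - half > 0:
        return "positive"
    if lnrr + half < 0:
        return "negative"
    return "neutral"


# ---------------------------------------------------------------------------
# missing-SD imputation and effect-size table construction


def impute_missing_sd(observations: list[StudyObservation]) -> list[StudyObservation]:
    """Fill missing SDs by the mean coefficient of variation of complete cases.

    The mean CV is computed within each carbon fraction over observations with
    both SDs present (treatment and control CVs both contribute); a missing SD
    is replaced by that CV times the observation's own mean.  Imputed rows are
    flagged via ``sd_imputed``.
    """
    by_fraction: dict[str, list[float]] = {}
    for obs in observations:
        if obs.sd_trt is not None and obs.sd_ctl is not None:
            by_fraction.setdefault(obs.fraction, []).extend(
                [obs.sd_trt / obs.mean_trt, obs.sd_ctl / obs.mean_ctl]
            )
    out = []
    for obs in observations:
        if obs.sd_trt is not None and obs.sd_ctl is not None:
            out.append(obs)
            continue
        cvs = by_fraction.get(obs.fraction)
        if not cvs:
            raise CannotImputeError(
                f"no complete-SD observations for fraction {obs.fraction}; cannot impute"
            )
        cv = float(np.mean(cvs))
        new = replace(obs, sd_imputed=True)
        if new.sd_trt is None:
            new.sd_trt = cv * new.mean_trt
        if new.sd_ctl is None:
            new.sd_ctl = cv * new.mean_ctl
        out.append(new)
    return out


def effect_sizes(
    observations: list[StudyObservation],
    sd_policy: str = "impute",
    weight_cap_quantile: float = 0.99,
) -> list[EffectSize]:
    """Compute per-observation effect sizes with weights.

    ``sd_policy`` is ``"impute"`` (mean-CV fill of missing SDs) or
    ``"exclude"`` (drop observations lacking an SD).  Zero-variance
    observations (both SDs zero) get their infinite weight capped at the
    ``weight_cap_quantile`` quantile of the finite weights so that a single
    exact observation cannot dominate the pooled estimate; such rows are
    flagged ``weight_capped``.
    """
    if sd_policy not in ("impute", "exclude"):
        raise ValueError(f"unknown sd_policy {sd_policy!r}")
    if sd_policy == "impute" and any(
        o.sd_trt is None or o.sd_ctl is None for o in observations
    ):
        observations = impute_missing_sd(observations)
    elif sd_policy == "exclude":
        observations = [
            o for o in observations if o.sd_trt is not None and o.sd_ctl is not None
        ]

    lnrrs, vs = [], []
    for obs in observations:
        obs.validate()
        lnrrs.append(compute_lnrr(obs))
        vs.append(compute_variance(obs))
    v_arr = np.asarray(vs, dtype=float)
    with np.errstate(divide="ignore"):
        w_arr = 1.0 / v_arr
    finite = np.isfinite(w_arr)
    if finite.any() and not finite.all():
        cap = float(np.quantile(w_arr[finite], weight_cap_quantile))
        capped = ~finite
        w_arr = np.where(capped, cap, w_arr)
    else:
        capped = np.zeros(len(w_arr), dtype=bool)

    out = []
    for obs, y, v, w, flagged in zip(observations, lnrrs, vs, w_arr, capped):
        half = Z95 * math.sqrt(v)
        out.append(
            EffectSize(
                study_id=obs.study_id,
                obs_id=obs.obs_id,
                lnrr=y,
                v=v,
                weight=float(w),
                ci_low=y - half,
                ci_high=y + half,
                response_class=classify_response(y, v),
                initial_soc=obs.initial_soc,
                moderators=dict(obs.moderators),
                weight_capped=bool(flagged),
                sd_imputed=obs.sd_imputed,
            )
        )
    return out


def class_percentages(effects: list[EffectSize]) -> dict:
    """Percentage of negative / neutral / positive observations (sums to 100)."""
    n = len(effects)
    counts = {"negative": 0, "neutral": 0, "positive": 0}
    for es in effects:
        counts[es.response_class] += 1
    return {k: 100.0 * c / n if n else 0.0 for k, c in counts.items()}


# ---------------------------------------------------------------------------
# pooling


def _re_estimate(y: np.ndarray, w: np.ndarray, method: str) -> tuple[float, float, float]:
    """Pooled mean, tau^2 and SE for one (sub)sample.

    Fixed-effect: inverse-variance weighted mean.  Random-effects: the
    DerSimonian-Laird moment estimator of the between-study variance tau^2,
    then weights 1/(v_i + tau^2) where v_i is recovered as 1/w_i.
    """
    sw = w.sum()
    mu_fe = float((w * y).sum() / sw)
    if method == "fixed":
        return mu_fe, 0.0, math.sqrt(1.0 / sw)
    q = float((w * (y - mu_fe) ** 2).sum())
    k = len(y)
    c = sw - (w**2).sum() / sw
    tau2 = max(0.0, (q - (k - 1)) / c) if c > 0 else 0.0
    w_star = 1.0 / (1.0 / w + tau2)
    mu = float((w_star * y).sum() / w_star.sum())
    return mu, tau2, math.sqrt(1.0 / w_star.sum())


def pool_effects(
    effects: list[EffectSize],
    n_boot: int = 999,
    seed: int | None = None,
    method: str = "random",
) -> PooledResult:
    """Pool effect sizes with a study-resampling percentile bootstrap CI.

    Studies (not observations) are resampled with replacement ``n_boot``
    times; each replicate recomputes the full pooled estimate (including
    tau^2 in random-effects mode) and the CI is the 2.5/97.5 percentile of
    the replicate estimates.  ``seed`` is required when ``n_boot > 0``.
    """
    if len(effects) < 2:
        raise DegenerateWeightsError("need >= 2 observations to pool")
    if method not in ("random", "fixed"):
        raise ValueError(f"unknown pooling method {method!r}")
    y = np.array([es.lnrr for es in effects])
    w = np.array([es.weight for es in effects])
    if not np.isfinite(w).all() or (w <= 0).all():
        raise DegenerateWeightsError("weights are degenerate (non-finite or all zero)")

    mu, tau2, se = _re_estimate(y, w, method)
    z = mu / se if se > 0 else math.inf
    pvalue = 2.0 * (1.0 - _norm_cdf(abs(z)))

    studies = sorted({es.study_id for es in effects})
    idx_by_study = {s: [] for s in studies}
    for i, es in enumerate(effects):
        idx_by_study[es.study_id].append(i)
    study_idx = [np.array(idx_by_study[s]) for s in studies]

    ci_low = ci_high = mu
    if n_boot > 0:
        if seed is None:
            raise ValueError("seed is required for the bootstrap CI")
        rng = np.random.default_rng(seed)
        boots = np.empty(n_boot)
        n_s = len(studies)
        picks = rng.integers(0, n_s, size=(n_boot, n_s))
        for b in range(n_boot):
            idx = np.concatenate([study_idx[j] for j in picks[b]])
            boots[b] = _re_estimate(y[idx], w[idx], method)[0]
        ci_low, ci_high = (float(q) for q in np.percentile(boots, [2.5, 97.5]))
        # percentile interval can exclude the point estimate on skewed
        # resamples; widen to contain it so the interval is always usable
        ci_low = min(ci_low, mu)
        ci_high = max(ci_high, mu)

    return PooledResult(
        estimate=mu,
        ci_low=ci_low,
        ci_high=ci_high,
        tau2=tau2,
        n_obs=len(effects),
        n_studies=len(studies),
        class_counts=class_percentages(effects),
        pvalue=pvalue,
        method=method,
        n_boot=n_boot,
        seed=seed,
    )


def _norm_cdf(x: float) -> float:
    return 0.5 * (1.0 + math.erf(x / math.sqrt(2.0)))


# ---------------------------------------------------------------------------
# I/O


def read_observations(path) -> list[StudyObservation]:
    """Read the observation CSV into validated ``StudyObservation`` records.

    Unknown columns are preserved in ``moderators``.  Missing SDs become
    ``None`` (handled later by the configured SD policy).
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory columns: {missing}")
    extra = [c for c in df.columns if c not in REQUIRED_COLUMNS]
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        moderators = {}
        for c in extra:
            val = d[c]
            if isinstance(val, float) and math.isnan(val):
                continue
            moderators[c] = val
        obs = StudyObservation(
            study_id=str(d["study_id"]),
            obs_id=str(d["obs_id"]),
            fraction=str(d["fraction"]),
            mean_trt=float(d["mean_trt"]),
            mean_ctl=float(d["mean_ctl"]),
            n_trt=int(d["n_trt"]),
            n_ctl=int(d["n_ctl"]),
            initial_soc=float(d["initial_soc"]),
            sd_trt=None if pd.isna(d["sd_trt"]) else float(d["sd_trt"]),
            sd_ctl=None if pd.isna(d["sd_ctl"]) else float(d["sd_ctl"]),
            moderators=moderators,
        )
        obs.validate()
        out.append(obs)
    return out


def observations_to_frame(observations: list[StudyObservation]) -> pd.DataFrame:
    rows = []
    for obs in observations:
        row = {
            "study_id": obs.study_id,
            "obs_id": obs.obs_id,
            "fraction": obs.fraction,
            "mean_trt": obs.mean_trt,
            "sd_trt": obs.sd_trt,
            "n_trt": obs.n_trt,
            "mean_ctl": obs.mean_ctl,
            "sd_ctl": obs.sd_ctl,
            "n_ctl": obs.n_ctl,
            "initial_soc": obs.initial_soc,
        }
        row.update(obs.moderators)
        rows.append(row)
    return pd.DataFrame(rows)


def write_observations(observations: list[StudyObservation], path) -> None:
    observations_to_frame(observations).to_csv(path, index=False)


def effects_to_frame(effects: list[EffectSize]) -> pd.DataFrame:
    rows = []
    for es in effects:
        rows.append(
            {
                "study_id": es.study_id,
                "obs_id": es.obs_id,
                "lnrr": es.lnrr,
                "v": es.v,
                "weight": es.weight,
                "ci_low": es.ci_low,
                "ci_high": es.ci_high,
                "response_class": es.response_class,
                "initial_soc": es.initial_soc,
                "weight_capped": es.weight_capped,
                "sd_imputed": es.sd_imputed,
            }
        )
    return pd.DataFrame(rows)


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_report(report: dict, path) -> None:
    """Serialize an analysis report as indented, key-stable JSON."""
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.bool_):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
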