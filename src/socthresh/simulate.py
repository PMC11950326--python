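"""Synthetic meta-analytic and site-level datasets.

The meta-dataset generator emulates the statistical structure of a global
nitrogen-fertilization dataset for soil carbon fractions: studies contribute
a handful of treatment/control observations each; initial SOC spans the
0.79-46.1 g/kg range; the true effect-size curve is piecewise in initial SOC
(a discontinuous slope-and-intercept change at a planted threshold by
default); reported means carry sampling noise consistent with the delta-
method lnRR variance (replicate SDs = CV x mean, 3-6 replicates); studies
add a shared normal deviation.  Everything is driven by one explicit seed.

The site-level generator emulates a pair of long-term field experiments in
carbon-poor versus carbon-rich soils: under N fertilization, POC and
aggregate stability rise in C-poor soils, while MAOC, microbial necromass
and NMR stability indices rise (and qCO2 falls) in C-rich soils.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .meta import ECOZONES, StudyObservation


@dataclass
class CurveSpec:
    """True effect-size curve lnRR(soc), piecewise at a threshold theta.

    ``family`` is one of step/segmented/stegmented/linear.  Left of theta the
    curve is ``left_intercept + left_slope * soc``; right of theta it is
    ``right_level + right_slope * (soc - theta)`` for stegmented/step, while
    the segmented family forces continuity at theta and linear ignores theta.
    """

    family: str = "stegmented"
    theta: float = 15.0
    left_intercept: float = -0.10
    left_slope: float = 0.04
    right_level: float = 0.22
    right_slope: float = -0.004

    def __call__(self, soc):
        soc = np.asarray(soc, dtype=float)
        left = self.left_intercept + self.left_slope * soc
        if self.family == "linear":
            return left
        if self.family == "step":
            left = np.full_like(soc, self.left_intercept)
            right = np.full_like(soc, self.right_level)
        elif self.family == "segmented":
            at = self.left_intercept + self.left_slope * self.theta
            right = at + self.right_slope * (soc - self.theta)
        elif self.family == "stegmented":
            right = self.right_level + self.right_slope * (soc - self.theta)
        else:
            raise ValueError(f"unknown curve family {self.family!r}")
        return np.where(soc <= self.theta, left, right)


#: curve resembling the particulate-organic-carbon response: a rise with
#: initial SOC up to ~15 g/kg, then a small drop and a slight decline
POC_CURVE = CurveSpec()

#: curve resembling the mineral-associated response: an abrupt decline at low
#: initial SOC, then a weakly declining plateau past ~13 g/kg
MAOC_CURVE = CurveSpec(
    theta=13.2, left_intercept=0.55, left_slope=-0.045,
    right_level=0.10, right_slope=-0.002,
)


@dataclass
class ScenarioConfig:
    """Study conditions for one synthetic meta-dataset."""

    n_studies: int = 120
    obs_per_study: tuple = (2, 6)
    soc_range: tuple = (0.79, 46.1)
    true_curve: CurveSpec = field(default_factory=CurveSpec)
    cv_range: tuple = (0.05, 0.30)
    n_reps: tuple = (3, 6)
    study_sd: float = 0.08
    fraction: str = "POC"
    seed: int | None = None

    def validate(self) -> None:
        lo, hi = self.soc_range
        if not (lo > 0 and hi > lo):
            raise ValueError("soc_range must be positive and increasing")
        if self.true_curve.family != "linear" and not (lo < self.true_curve.theta < hi):
            raise ValueError("theta must lie inside soc_range")
        if not (0 <= self.cv_range[0] <= self.cv_range[1]):
            raise ValueError("cv_range must be nonnegative and ordered")
        if self.seed is None:
            raise ValueError("an explicit seed is mandatory")
        if self.n_studies < 1 or self.obs_per_study[0] < 1:
            raise ValueError("need at least one study and one observation per study")


def generate_meta_dataset(cfg: ScenarioConfig) -> list[StudyObservation]:
    """Draw a multi-study observation table under ``cfg``.

    Initial SOC ~ Uniform(soc_range); the true lnRR is the planted curve
    plus a study-level N(0, study_sd) deviation; control means are lognormal;
    the reported group means carry sampling noise with variance cv^2/n
    (the delta-method variance of a log sample mean), so the computed lnRR
    scatters around the truth exactly as its reported variance claims.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    out = []
    for s in range(cfg.n_studies):
        n_obs = int(rng.integers(cfg.obs_per_study[0], cfg.obs_per_study[1] + 1))
        study_dev = rng.normal(0.0, cfg.study_sd) if cfg.study_sd > 0 else 0.0
        pub_year = int(rng.integers(2005, 2025))
        ecozone = str(rng.choice(ECOZONES))
        for i in range(n_obs):
            soc = float(rng.uniform(*cfg.soc_range))
            true_lnrr = float(cfg.true_curve(soc)) + study_dev
            n_t = int(rng.integers(cfg.n_reps[0], cfg.n_reps[1] + 1))
            n_c = int(rng.integers(cfg.n_reps[0], cfg.n_reps[1] + 1))
            cv_t = float(rng.uniform(*cfg.cv_range))
            cv_c = float(rng.uniform(*cfg.cv_range))
            ctl_expected = float(rng.lognormal(mean=np.log(8.0), sigma=0.6))
            # sampling noise of the reported group means (delta method on a
            # log-scale sample mean): sd of ln(mean) ~ cv / sqrt(n)
            eps_c = rng.normal(0.0, cv_c / np.sqrt(n_c)) if cv_c > 0 else 0.0
            eps_t = rng.normal(0.0, cv_t / np.sqrt(n_t)) if cv_t > 0 else 0.0
            mean_ctl = ctl_expected * np.exp(eps_c)
            mean_trt = ctl_expected * np.exp(true_lnrr + eps_t)
            out.append(
                StudyObservation(
                    study_id=f"S{s:03d}",
                    obs_id=f"S{s:03d}_O{i:02d}",
                    fraction=cfg.fraction,
                    mean_trt=float(mean_trt),
                    mean_ctl=float(mean_ctl),
                    sd_trt=cv_t * float(mean_trt),
                    sd_ctl=cv_c * float(mean_ctl),
                    n_trt=n_t,
                    n_ctl=n_c,
                    initial_soc=soc,
                    moderators={
                        "ph": float(rng.uniform(4.5, 8.5)),
                        "tn": float(rng.uniform(0.5, 3.0)),
                        "clay_silt": float(rng.uniform(10.0, 90.0)),
                        "mat": float(rng.uniform(0.0, 25.0)),
                        "map": float(rng.uniform(200.0, 2000.0)),
                        "n_rate": float(rng.uniform(50.0, 350.0)),
                        "duration": float(rng.integers(3, 40)),
                        "pub_year": pub_year,
                        "ecozone": ecozone,
                    },
                )
            )
    return out


def poc_scenario(seed: int, **kw) -> ScenarioConfig:
    """Particulate-fraction study conditions (threshold planted at 15 g/kg)."""
    return ScenarioConfig(true_curve=replace(POC_CURVE), fraction="POC", seed=seed, **kw)


def maoc_scenario(seed: int, **kw) -> ScenarioConfig:
    """Mineral-associated-fraction study conditions (threshold at 13.2 g/kg)."""
    return ScenarioConfig(true_curve=replace(MAOC_CURVE), fraction="MAOC", seed=seed, **kw)


# ---------------------------------------------------------------------------
# site-level generator

#: multiplicative N-fertilization effects planted per carbon class; values
#: chosen to mirror the qualitative field contrasts this pipeline screens
#: for (POC and aggregates up in C-poor soil; MAOC, necromass and chemical
#: stability up, qCO2 down, in C-rich soil)
SITE_EFFECTS = {
    "poor": {
        "poc": 2.05, "maoc": 1.02, "root_biomass": 2.48, "necromass": 0.88,
        "mwd_shift": 1.21, "qco2": 1.10, "oxidase": 0.90, "nmr_shift": 1.00,
    },
    "rich": {
        "poc": 1.05, "maoc": 1.15, "root_biomass": 2.15, "necromass": 1.10,
        "mwd_shift": 0.95, "qco2": 0.864, "oxidase": 0.74, "nmr_shift": 1.07,
    },
}

#: mean diameters (mm) of the four wet-sieved aggregate classes
AGG_DIAMETERS = (5.0, 1.125, 0.1515, 0.0265)


def generate_site_dataset(
    c_class: str, n_plots: int = 4, seed: int | None = None,
    effects: dict | None = None, noise_cv: float = 0.08,
) -> pd.DataFrame:
    """Plot-level site table for one carbon class with paired N0/N treatments.

    Each of ``n_plots`` replicate plots appears under both treatments; the N
    rows apply the class-specific multipliers of ``SITE_EFFECTS`` before
    multiplicative lognormal noise.  All values are positive by construction;
    aggregate mass proportions sum to one (Dirichlet draw).
    """
    if c_class not in SITE_EFFECTS:
        raise ValueError(f"c_class must be 'poor' or 'rich', got {c_class!r}")
    if n_plots < 4:
        raise ValueError("need n_plots >= 4")
    if seed is None:
        raise ValueError("an explicit seed is mandatory")
    eff = effects or SITE_EFFECTS[c_class]
    rng = np.random.default_rng(seed)
    rich = c_class == "rich"

    base = {
        "soc": 16.8 if rich else 9.5, "tn": 1.5 if rich else 0.9,
        "mbc": 320.0 if rich else 180.0, "mbn": 40.0 if rich else 21.0,
        "poc": 4.2 if rich else 2.0, "maoc": 11.0 if rich else 6.5,
        "root_biomass": 1.1, "respiration": 0.55 if rich else 0.45,
        "bg": 120.0, "cbh": 40.0, "nag": 60.0, "lap": 30.0, "pase": 150.0,
        "ppo": 18.0, "pod": 25.0,
        "glucosamine": 0.030 if rich else 0.020, "muramic_acid": 0.004,
        "alkyl": 24.0, "o_alkyl": 44.0, "aromatic": 18.0, "carboxyl": 14.0,
    }
    alpha = np.array([3.0, 5.0, 3.0, 2.0]) if rich else np.array([2.0, 4.0, 4.0, 3.0])

    rows = []
    for treatment in ("N0", "N"):
        fert = treatment == "N"
        for plot in range(1, n_plots + 1):
            noisy = {
                k: v * rng.lognormal(0.0, noise_cv) for k, v in base.items()
            }
            if fert:
                noisy["poc"] *= eff["poc"]
                noisy["maoc"] *= eff["maoc"]
                noisy["root_biomass"] *= eff["root_biomass"]
                noisy["glucosamine"] *= eff["necromass"]
                noisy["muramic_acid"] *= eff["necromass"]
                noisy["respiration"] *= eff["qco2"]
                noisy["ppo"] *= eff["oxidase"]
                noisy["pod"] *= eff["oxidase"]
                noisy["alkyl"] *= eff["nmr_shift"]
                noisy["aromatic"] *= eff["nmr_shift"]
            a = alpha * (eff["mwd_shift"] if fert else 1.0) ** np.array([1, 1, -1, -1])
            props = rng.dirichlet(a * 10.0)
            row = {"c_class": c_class, "treatment": treatment, "plot": plot}
            row.update(noisy)
            for i, (d, p) in enumerate(zip(AGG_DIAMETERS, props), start=1):
                row[f"agg_diam_{i}"] = d
                row[f"agg_prop_{i}"] = float(p)
            rows.append(row)
    return pd.DataFrame(rows)
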