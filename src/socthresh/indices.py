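"""Site-level soil functional-carbon indices and driver screening.

Closed-form indices computed from already-integrated laboratory measurements:

* enzymatic vector length VL = sqrt(x^2 + y^2), with x and y the relative
  C:P and C:N acquiring-enzyme proportions — larger VL means stronger
  microbial carbon limitation;
* resource limitation (SOC:TN) / (MBC:MBN), the resource C:N normalized by
  microbial biomass stoichiometry;
* bacterial necromass C = muramic acid x 45 and fungal necromass C =
  (glucosamine - 2 x muramic acid) x 179.17 x 9, amino sugars taken as
  molar amounts so the molecular-weight product is dimensionally coherent
  (a conventional mass-input variant is available behind ``molar=False``);
* mean weight diameter MWD = sum X_i W_i of water-stable aggregate classes;
* 13C-NMR aliphaticity alkyl/O-alkyl and recalcitrance
  (alkyl + aromatic)/(O-alkyl + carboxyl);
* metabolic quotient qCO2 = respiration rate / MBC.

Driver screening uses zero-order Pearson correlations and partial
correlations of residuals after regressing out control variables.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .meta import SocthreshError


class DomainError(SocthreshError):
    pass


@dataclass
class EnzymeProfile:
    """Hydrolase and oxidase activities, nmol g^-1 h^-1.

    ``pase`` is the phosphatase relevant at the site's pH (acid or alkaline).
    """

    bg: float
    cbh: float
    nag: float
    lap: float
    pase: float
    ppo: float = 0.0
    pod: float = 0.0

    def validate(self) -> None:
        for name in ("bg", "cbh", "nag", "lap", "pase", "ppo", "pod"):
            if getattr(self, name) < 0:
                raise DomainError(f"enzyme activity {name} must be >= 0")


@dataclass
class IndexRecord:
    vl: float
    resource_limitation: float
    qco2: float
    bacterial_nec: float
    fungal_nec: float
    total_nec: float
    mwd: float
    aliphaticity: float
    recalcitrance: float


def enzyme_ratios(profile: EnzymeProfile) -> tuple[float, float]:
    """Relative C:P and C:N acquiring-enzyme proportions (x, y).

    x = C/(C+P), y = C/(C+N) with C = BG+CBH, N = NAG+LAP, P = phosphatase.
    """
    profile.validate()
    c = profile.bg + profile.cbh
    n = profile.nag + profile.lap
    p = profile.pase
    if c + p == 0 or c + n == 0:
        raise DomainError("all-zero enzyme activities; ratios undefined")
    return c / (c + p), c / (c + n)


def vector_length(x: float, y: float) -> float:
    """Enzymatic-stoichiometry vector length sqrt(x^2 + y^2)."""
    if not (math.isfinite(x) and math.isfinite(y)):
        raise DomainError("ratios must be finite")
    return math.hypot(x, y)


def resource_limitation(soc: float, tn: float, mbc: float, mbn: float) -> float:
    """(SOC/TN) / (MBC/MBN): resource C:N over microbial biomass C:N."""
    if tn <= 0 or mbn <= 0 or mbc <= 0:
        raise DomainError("tn, mbc and mbn must be > 0")
    return (soc / tn) / (mbc / mbn)


def bacterial_necromass(muramic_acid: float) -> float:
    """Bacterial necromass C from muramic acid (conversion factor 45)."""
    if muramic_acid < 0:
        raise DomainError("muramic acid must be >= 0")
    return muramic_acid * 45.0


def fungal_necromass(glucosamine: float, muramic_acid: float, molar: bool = True) -> float:
    """Fungal necromass C from glucosamine corrected for bacterial glucosamine.

    Molar mode (default): (GluN - 2 MurA) x 179.17 x 9 with molar amino-sugar
    amounts.  Mass mode applies the conventional mass-based formula
    (GluN/179.17 - 2 MurA/251.23) x 179.17 x 9 instead.  A negative net
    fungal glucosamine is clipped to zero with a warning.
    """
    if glucosamine < 0 or muramic_acid < 0:
        raise DomainError("amino sugar amounts must be >= 0")
    if molar:
        net = glucosamine - 2.0 * muramic_acid
    else:
        net = (glucosamine / 179.17 - 2.0 * muramic_acid / 251.23) * 179.17
    if net < 0:
        warnings.warn("net fungal glucosamine negative; clipped to zero")
        net = 0.0
    return net * 179.17 * 9.0 if molar else net * 9.0


def total_necromass(glucosamine: float, muramic_acid: float, molar: bool = True) -> float:
    return bacterial_necromass(muramic_acid) + fungal_necromass(
        glucosamine, muramic_acid, molar=molar
    )


def mwd(fractions) -> float:
    """Mean weight diameter sum(X_i W_i) of aggregate size classes.

    ``fractions`` is a sequence of (mean diameter mm, mass proportion) pairs;
    proportions must sum to 1 within [0.98, 1.02] and are renormalized with a
    warning if they do not sum exactly to 1.
    """
    xs = np.array([f[0] for f in fractions], dtype=float)
    ws = np.array([f[1] for f in fractions], dtype=float)
    if (ws < 0).any():
        raise DomainError("mass proportions must be >= 0")
    total = ws.sum()
    if not (0.98 <= total <= 1.02):
        raise DomainError(f"mass proportions sum to {total:.4f}, outside [0.98, 1.02]")
    if abs(total - 1.0) > 1e-12:
        warnings.warn(f"mass proportions sum to {total:.4f}; renormalizing")
        ws = ws / total
    return float((xs * ws).sum())


def aliphaticity(alkyl: float, o_alkyl: float) -> float:
    """NMR alkyl-C / O-alkyl-C ratio (chemical stability of SOC)."""
    if alkyl < 0 or o_alkyl < 0:
        raise DomainError("NMR region integrals must be >= 0")
    if o_alkyl == 0:
        raise DomainError("O-alkyl integral is zero; aliphaticity undefined")
    return alkyl / o_alkyl


def recalcitrance(alkyl: float, o_alkyl: float, aromatic: float, carboxyl: float) -> float:
    """NMR (alkyl + aromatic) / (O-alkyl + carboxyl) ratio."""
    for v in (alkyl, o_alkyl, aromatic, carboxyl):
        if v < 0:
            raise DomainError("NMR region integrals must be >= 0")
    if o_alkyl + carboxyl == 0:
        raise DomainError("zero denominator; recalcitrance undefined")
    return (alkyl + aromatic) / (o_alkyl + carboxyl)


def qco2(respiration_rate: float, mbc: float) -> float:
    """Metabolic quotient: respiration (ug CO2-C g^-1 h^-1) per ug MBC g^-1."""
    if mbc <= 0:
        raise DomainError("mbc must be > 0")
    return respiration_rate / mbc


# ---------------------------------------------------------------------------
# driver screening


def partial_correlation(target, predictor, controls=None) -> tuple[float, float]:
    """Zero-order and partial Pearson correlation of target with predictor.

    The partial correlation is the Pearson correlation of the OLS residuals
    of target and predictor after regressing each on the control matrix
    (with intercept).  Collinear controls trigger a rank warning and a
    pseudo-inverse solve.
    """
    t = np.asarray(target, dtype=float)
    p = np.asarray(predictor, dtype=float)
    if t.shape != p.shape or t.ndim != 1:
        raise ValueError("target and predictor must be equal-length vectors")
    r0 = float(np.corrcoef(t, p)[0, 1])
    if controls is None or (hasattr(controls, "size") and np.asarray(controls).size == 0):
        return r0, r0
    C = np.asarray(controls, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    n, k = C.shape
    if n != t.size:
        raise ValueError("controls must have one row per observation")
    if n <= k + 2:
        raise ValueError("need n > number of controls + 2")
    X = np.column_stack([np.ones(n), C])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        warnings.warn("collinear controls; using pseudo-inverse")
    proj = X @ np.linalg.pinv(X)
    rt = t - proj @ t
    rp = p - proj @ p
    denom = math.sqrt(float(rt @ rt) * float(rp @ rp))
    if denom < 1e-15 * max(1.0, float(np.abs(t).max()) * float(np.abs(p).max())):
        return r0, 0.0  # a residual is (numerically) zero: predictor in span of controls
    return r0, float(rt @ rp) / denom


def partial_correlation_matrix(df, target: str, predictors, control_groups: dict):
    """Zero-order and per-control-group partial correlations, as a DataFrame.

    ``control_groups`` maps a group name to the list of columns to control
    for; each predictor is screened against the target with every group of
    controls removed in turn (columns overlapping the predictor are dropped
    from the controls).
    """
    import pandas as pd

    rows = []
    t = df[target].to_numpy(dtype=float)
    for pred in predictors:
        p = df[pred].to_numpy(dtype=float)
        r0, _ = partial_correlation(t, p)
        row = {"predictor": pred, "zero_order": r0}
        for gname, cols in control_groups.items():
            use = [c for c in cols if c != pred]
            if not use:
                row[gname] = r0
                continue
            C = df[use].to_numpy(dtype=float)
            _, rp = partial_correlation(t, p, C)
            row[gname] = rp
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# site-table convenience


def site_indices(df, molar: bool = True):
    """Compute an ``IndexRecord`` row per plot from a site table.

    Expected columns: bg, cbh, nag, lap, pase, soc, tn, mbc, mbn,
    respiration, muramic_acid, glucosamine, alkyl, o_alkyl, aromatic,
    carboxyl, and agg_diam_i / agg_prop_i pairs (i = 1..4) for the aggregate
    size classes.
    """
    import pandas as pd

    agg_cols = sorted(c for c in df.columns if c.startswith("agg_diam_"))
    out = []
    for _, row in df.iterrows():
        prof = EnzymeProfile(
            bg=row["bg"], cbh=row["cbh"], nag=row["nag"], lap=row["lap"],
            pase=row["pase"], ppo=row.get("ppo", 0.0), pod=row.get("pod", 0.0),
        )
        x, y = enzyme_ratios(prof)
        fracs = [
            (row[c], row[c.replace("agg_diam_", "agg_prop_")]) for c in agg_cols
        ]
        bn = bacterial_necromass(row["muramic_acid"])
        fn = fungal_necromass(row["glucosamine"], row["muramic_acid"], molar=molar)
        rec = IndexRecord(
            vl=vector_length(x, y),
            resource_limitation=resource_limitation(
                row["soc"], row["tn"], row["mbc"], row["mbn"]
            ),
            qco2=qco2(row["respiration"], row["mbc"]),
            bacterial_nec=bn,
            fungal_nec=fn,
            total_nec=bn + fn,
            mwd=mwd(fracs),
            aliphaticity=aliphaticity(row["alkyl"], row["o_alkyl"]),
            recalcitrance=recalcitrance(
                row["alkyl"], row["o_alkyl"], row["aromatic"], row["carboxyl"]
            ),
        )
        out.append(vars(rec))
    res = pd.DataFrame(out)
    carry = [c for c in ("site", "plot", "treatment", "c_class") if c in df.columns]
    if carry:
        res = pd.concat([df[carry].reset_index(drop=True), res], axis=1)
    return res
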