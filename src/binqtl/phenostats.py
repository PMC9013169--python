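"""Phenotype statistics: trait summaries, generation comparisons,
heterosis and photosynthetic-pigment quantification.

Conventions follow common crop-genetics reporting: sample SD (n-1),
adjusted Fisher-Pearson skewness G1 and excess kurtosis G2 (the SPSS
convention, identical to pandas ``skew``/``kurt``), CV% = 100*sd/mean,
mid-parent heterosis MH = 100*(F1 - MP)/MP with MP the parental
midpoint, and over-parent (better-parent) heterosis against the larger
parental mean.

Pigment concentrations (mg/L) from 95%-ethanol extract absorbances:

    Ca   = 13.95*D665 - 6.88*D649          (chlorophyll a)
    Cb   = 24.96*D649 - 7.32*D665          (chlorophyll b)
    Cx.c = (1000*D470 - 2.05*Ca - 144.8*Cb) / 245   (carotenoids)

and leaf content (mg/g) = C * V / (1000 * W) for extract volume V (ml)
and fresh weight W (g).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

GENERATIONS = ("P1", "P2", "F1", "F2")


@dataclass
class TraitStats:
    n: int
    mean: float
    se_mean: float
    min: float
    max: float
    sd: float
    variance: float
    skewness: float
    kurtosis: float  # excess, normal = 0
    cv_percent: float


def trait_summary(values) -> TraitStats:
    """Descriptive statistics of one trait over individuals."""
    x = pd.Series(np.asarray(values, dtype=float)).dropna()
    if len(x) < 2:
        raise ValueError("need at least 2 non-missing values")
    sd = float(x.std(ddof=1))
    mean = float(x.mean())
    cv = 100.0 * sd / mean if mean != 0 else np.nan
    if mean == 0:
        warnings.warn("mean is 0: CV undefined")
    return TraitStats(
        n=int(len(x)), mean=mean, se_mean=sd / np.sqrt(len(x)),
        min=float(x.min()), max=float(x.max()), sd=sd, variance=sd ** 2,
        skewness=float(x.skew()) if sd > 0 else np.nan,
        kurtosis=float(x.kurt()) if sd > 0 and len(x) > 3 else np.nan,
        cv_percent=cv)


def heterosis(f1_mean: float, p1_mean: float, p2_mean: float) -> tuple[float, float]:
    """(mid-parent %, over-parent %) heterosis of the F1.

    MH = 100*(F1-MP)/MP with MP = (P1+P2)/2; OH compares against the
    better (larger-mean) parent.
    """
    mp = 0.5 * (p1_mean + p2_mean)
    if mp == 0:
        raise ValueError("mid-parent value is 0: heterosis undefined")
    bp = max(p1_mean, p2_mean)
    mh = 100.0 * (f1_mean - mp) / mp
    oh = 100.0 * (f1_mean - bp) / bp if bp != 0 else np.nan
    return mh, oh


@dataclass
class PigmentResult:
    ca_mg_l: float
    cb_mg_l: float
    cxc_mg_l: float
    content_a_mg_g: float
    content_b_mg_g: float
    content_car_mg_g: float
    chl_ab_ratio: float
    total_chl_mg_g: float
    negative_flag: bool


def pigment_quantification(d665: float, d649: float, d470: float,
                           v_ml: float, w_g: float) -> PigmentResult:
    """Chlorophyll a/b and carotenoid concentrations and leaf contents."""
    if v_ml <= 0 or w_g <= 0:
        raise ValueError("extract volume and fresh weight must be positive")
    if min(d665, d649, d470) < 0:
        raise ValueError("absorbances must be >= 0")
    ca = 13.95 * d665 - 6.88 * d649
    cb = 24.96 * d649 - 7.32 * d665
    cxc = (1000.0 * d470 - 2.05 * ca - 144.8 * cb) / 245.0
    negative = min(ca, cb, cxc) < 0
    if negative:
        warnings.warn("negative pigment concentration: physically impossible reading")
    scale = v_ml / (1000.0 * w_g)
    content_a, content_b, content_car = ca * scale, cb * scale, cxc * scale
    return PigmentResult(
        ca_mg_l=ca, cb_mg_l=cb, cxc_mg_l=cxc,
        content_a_mg_g=content_a, content_b_mg_g=content_b,
        content_car_mg_g=content_car,
        chl_ab_ratio=content_a / content_b if content_b != 0 else np.nan,
        total_chl_mg_g=content_a + content_b,
        negative_flag=bool(negative))


def average_replicates(table: pd.DataFrame, id_cols: tuple[str, ...] =
                       ("individual", "generation")) -> pd.DataFrame:
    """Average repeated measurements per individual before population stats."""
    traits = [c for c in table.columns if c not in id_cols and c != "replicate"]
    return table.groupby(list(id_cols), as_index=False, sort=False)[traits].mean()


def generation_comparison(table: pd.DataFrame, trait: str,
                          parent1: str = "P1", parent2: str = "P2") -> dict:
    """ANOVA across generations + pairwise Welch t-tests + F2 correlations.

    Returns a dict with ``anova`` (F, p), ``pairwise`` {(g1, g2): (t, p)}
    for parent1-parent2, parent1-F1 and parent2-F1, and ``correlations``,
    the Pearson matrix over all trait columns on pairwise-complete F2
    records.
    """
    groups = {g: table.loc[table["generation"] == g, trait].dropna().to_numpy()
              for g in table["generation"].unique()}
    valid = [v for v in groups.values() if len(v) >= 2]
    if len(valid) < 2:
        raise ValueError("need >= 2 generations with >= 2 observations")
    f_stat, p = stats.f_oneway(*valid)
    pairwise = {}
    for g1, g2 in ((parent1, parent2), (parent1, "F1"), (parent2, "F1")):
        a, b = groups.get(g1, []), groups.get(g2, [])
        if len(a) >= 2 and len(b) >= 2:
            t, pt = stats.ttest_ind(a, b, equal_var=False)
            pairwise[(g1, g2)] = (float(t), float(pt))
    f2 = table[table["generation"] == "F2"]
    traits = [c for c in table.columns
              if c not in ("individual", "generation", "replicate")]
    corr = f2[traits].corr(method="pearson")
    return {"anova": (float(f_stat), float(p)), "pairwise": pairwise,
            "correlations": corr}


def summarize_generations(table: pd.DataFrame, traits: list[str] | None = None
                          ) -> pd.DataFrame:
    """Per-trait descriptive statistics of the F2 plus heterosis from the
    parental and F1 generation means."""
    traits = traits or [c for c in table.columns
                        if c not in ("individual", "generation", "replicate")]
    rows = []
    for t in traits:
        f2 = table.loc[table["generation"] == "F2", t].dropna()
        s = trait_summary(f2)
        row = {"trait": t, **vars(s)}
        means = {g: table.loc[table["generation"] == g, t].dropna().mean()
                 for g in ("P1", "P2", "F1")}
        if all(np.isfinite(list(means.values()))) and (means["P1"] + means["P2"]) != 0:
            mh, oh = heterosis(means["F1"], means["P1"], means["P2"])
            row["mh_percent"], row["oh_percent"] = mh, oh
        else:
            row["mh_percent"] = row["oh_percent"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
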