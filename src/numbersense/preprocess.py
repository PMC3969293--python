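"""Phenotype transformation, standardization, screening and descriptives.

Accuracy scores are squared and Weber fractions square-root transformed,
scores are standardized and residualized on age and sex, observations
beyond +/-3 SD are excluded, and a descriptives table (per-group moments,
skewness/kurtosis with SEs, two-way ANOVA by sex and zygosity) is built
on one randomly chosen twin per pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .twin_models import TwinPairDataset

__all__ = [
    "DescriptiveReport",
    "transform_scores",
    "standardize_and_residualize",
    "exclude_outliers",
    "descriptives",
    "prepare_dataset",
]

REPORT_GROUPS = ("All", "MZ", "DZ", "Female", "Male", "MZm", "DZm", "MZf",
                 "DZf", "DZo", "DZss")


@dataclass
class DescriptiveReport:
    groups: dict               # group -> dict(n, mean, sd); absent groups omitted
    skewness: float
    skewness_se: float
    kurtosis: float
    kurtosis_se: float
    anova: dict                # effect -> dict(p, eta2)
    r2: float
    n: int
    flags: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [(g, v["n"], v["mean"], v["sd"]) for g, v in self.groups.items()]
        return pd.DataFrame(rows, columns=["group", "N", "mean", "sd"])


def transform_scores(accuracy, weber):
    """(accuracy^2, sqrt(weber)); arrays pass through elementwise."""
    accuracy = np.asarray(accuracy, float)
    weber = np.asarray(weber, float)
    if np.any(weber[~np.isnan(weber)] < 0):
        raise ValueError("weber scores must be non-negative")
    acc_t = accuracy**2
    web_t = np.sqrt(weber)
    if acc_t.ndim == 0:
        return float(acc_t), float(web_t)
    return acc_t, web_t


def standardize_and_residualize(values, age, sex) -> np.ndarray:
    """Z-score, regress out age and sex (OLS with intercept), return
    residuals restandardized to mean 0 / SD 1. NaNs propagate."""
    values = np.asarray(values, float)
    age = np.asarray(age, float)
    sex_codes = pd.Categorical(pd.Series(sex)).codes.astype(float)
    if len(values) != len(age) or len(values) != len(sex_codes):
        raise ValueError("values, age and sex must have equal length")
    ok = ~np.isnan(values) & ~np.isnan(age)
    if ok.sum() < 3:
        raise ValueError("need at least 3 non-missing values")
    v = values[ok]
    if np.std(v, ddof=1) == 0:
        raise ValueError("constant input: zero variance")
    z = (values - v.mean()) / v.std(ddof=1)
    x = sm.add_constant(np.column_stack([age[ok], sex_codes[ok]]))
    fit = sm.OLS(z[ok], x).fit()
    resid = np.full_like(values, np.nan)
    resid[ok] = fit.resid
    sd = np.nanstd(resid, ddof=1)
    if sd < 1e-8:
        # (near-)perfect fit: residuals are numerically zero; do not blow
        # them up by restandardizing
        return resid
    resid = (resid - np.nanmean(resid)) / sd
    return resid


def exclude_outliers(values, k: float = 3.0) -> np.ndarray:
    """Keep mask: |value| <= k on already-standardized scores (closed
    interval, single pass). NaNs are marked not-kept."""
    values = np.asarray(values, float)
    with np.errstate(invalid="ignore"):
        return np.abs(values) <= k


def _group_mask(df: pd.DataFrame, group: str) -> np.ndarray:
    zyg, sex = df["zygosity"], df["sex"]
    os_fam = df["_is_os"]
    return {
        "All": np.ones(len(df), bool),
        "MZ": (zyg == "MZ").to_numpy(),
        "DZ": (zyg == "DZ").to_numpy(),
        "Female": (sex == "F").to_numpy(),
        "Male": (sex == "M").to_numpy(),
        "MZm": ((zyg == "MZ") & (sex == "M")).to_numpy(),
        "DZm": ((zyg == "DZ") & (sex == "M") & ~os_fam).to_numpy(),
        "MZf": ((zyg == "MZ") & (sex == "F")).to_numpy(),
        "DZf": ((zyg == "DZ") & (sex == "F") & ~os_fam).to_numpy(),
        "DZo": ((zyg == "DZ") & os_fam).to_numpy(),
        "DZss": ((zyg == "DZ") & ~os_fam).to_numpy(),
    }[group]


def descriptives(
    dataset: TwinPairDataset,
    pheno: str | None = None,
    one_per_pair: bool = True,
    seed: int = 0,
) -> DescriptiveReport:
    """Table-style descriptives with a two-way (sex x zygosity) ANOVA.

    With ``one_per_pair`` a single twin per family is chosen by a seeded
    draw. Empty groups are omitted from the report rather than zeroed.
    """
    pheno = pheno or dataset.pheno
    df = dataset.df.dropna(subset=[pheno]).copy()
    if df.empty:
        raise ValueError("dataset is empty")
    fam_group = dataset.group_of_family()
    df["_is_os"] = df["family_id"].map(fam_group) == "DZos"
    if one_per_pair:
        rng = np.random.default_rng(seed)
        df = df.sample(frac=1.0, random_state=rng.integers(0, 2**31 - 1))
        df = df.groupby("family_id", sort=True).head(1).sort_index()
    flags = []
    groups = {}
    for g in REPORT_GROUPS:
        mask = _group_mask(df, g)
        vals = df.loc[mask, pheno].to_numpy(float)
        if len(vals) == 0:
            continue
        groups[g] = dict(n=int(len(vals)), mean=float(vals.mean()),
                         sd=float(vals.std(ddof=1)) if len(vals) > 1 else 0.0)
    allv = df[pheno].to_numpy(float)
    n = len(allv)
    skew = float(stats.skew(allv, bias=False)) if np.std(allv) > 0 else float("nan")
    kurt = float(stats.kurtosis(allv, bias=False)) if np.std(allv) > 0 else float("nan")
    anova: dict[str, dict] = {}
    r2 = float("nan")
    if np.std(allv) == 0:
        flags.append("constant phenotype: ANOVA undefined")
    elif df["sex"].nunique() < 2 or df["zygosity"].nunique() < 2:
        flags.append("sex or zygosity has a single level: ANOVA skipped")
    else:
        d = df.rename(columns={pheno: "y"})[["y", "sex", "zygosity"]]
        model = smf.ols("y ~ C(sex) * C(zygosity)", data=d).fit()
        tab = sm.stats.anova_lm(model, typ=2)
        ss_total = float(tab["sum_sq"].sum())
        name_map = {"C(sex)": "sex", "C(zygosity)": "zygosity",
                    "C(sex):C(zygosity)": "interaction"}
        for raw, name in name_map.items():
            anova[name] = dict(
                p=float(tab.loc[raw, "PR(>F)"]),
                eta2=float(tab.loc[raw, "sum_sq"] / ss_total),
            )
        r2 = float(model.rsquared)
    return DescriptiveReport(
        groups=groups, skewness=skew, skewness_se=math.sqrt(6.0 / n),
        kurtosis=kurt, kurtosis_se=math.sqrt(24.0 / n),
        anova=anova, r2=r2, n=n, flags=flags,
    )


def prepare_dataset(
    dataset: TwinPairDataset,
    pheno: str | None = None,
    out_col: str | None = None,
    k: float = 3.0,
) -> TwinPairDataset:
    """Standardize, residualize on age/sex, then drop +/-k SD outliers.

    Returns a new dataset whose ``out_col`` (default ``<pheno>_resid``)
    holds the screened residuals; excluded scores become missing.
    """
    pheno = pheno or dataset.pheno
    out_col = out_col or f"{pheno}_resid"
    df = dataset.df.copy()
    resid = standardize_and_residualize(df[pheno], df["age"], df["sex"])
    keep = exclude_outliers(resid, k=k)
    resid[~keep] = np.nan
    df[out_col] = resid
    return TwinPairDataset(df, pheno=out_col)
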