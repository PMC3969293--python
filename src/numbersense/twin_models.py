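"""Classical twin variance-component models.

Intraclass correlations, maximum-likelihood fitting of the saturated,
ACE, AE and E models on twin-pair phenotypes (full-information: complete
pairs contribute a bivariate normal, singletons a univariate normal),
likelihood-ratio / AIC / BIC model comparison, and profile-likelihood
confidence intervals for standardized variance components.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "TwinPairDataset",
    "IccResult",
    "VarianceComponents",
    "ModelFit",
    "ModelComparison",
    "intraclass_correlation",
    "fit_twin_model",
    "profile_ci",
    "compare_models",
    "select_best",
]

GROUP_LABELS = ("MZm", "MZf", "DZm", "DZf", "DZos")

_LOG2PI = math.log(2.0 * math.pi)
_BIG = 1e12


# ---------------------------------------------------------------------------
# dataset container
# ---------------------------------------------------------------------------


class TwinPairDataset:
    """Twin phenotypes stored long (one row per individual).

    Required columns: ``family_id``, ``twin`` (1 or 2), ``zygosity``
    ('MZ'|'DZ'), ``sex`` ('M'|'F'), ``age`` and at least one phenotype
    column. Families have at most two members; MZ pairs must be same-sex.
    """

    REQUIRED = ("family_id", "twin", "zygosity", "sex", "age")

    def __init__(self, df: pd.DataFrame, pheno: str = "pheno"):
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"missing required columns: {missing}")
        if pheno not in df.columns:
            raise ValueError(f"phenotype column {pheno!r} not present")
        df = df.copy()
        counts = df.groupby("family_id")["twin"].count()
        if (counts > 2).any():
            bad = counts[counts > 2].index[0]
            raise ValueError(f"family {bad!r} has more than two twins")
        zyg = df.groupby("family_id")["zygosity"].nunique()
        if (zyg > 1).any():
            raise ValueError("zygosity not constant within a family")
        mz = df[df["zygosity"] == "MZ"]
        mz_sex = mz.groupby("family_id")["sex"].nunique()
        if (mz_sex > 1).any():
            raise ValueError("MZ pair with discordant sex")
        self.df = df
        self.pheno = pheno

    # -- grouping ----------------------------------------------------------

    def group_of_family(self) -> pd.Series:
        """Map family_id -> one of MZm/MZf/DZm/DZf/DZos."""

        g = self.df.groupby("family_id").agg(
            zyg=("zygosity", "first"),
            n_sex=("sex", "nunique"),
            sex=("sex", "first"),
        )
        out = np.where(
            g["zyg"] == "MZ",
            np.where(g["sex"] == "M", "MZm", "MZf"),
            np.where(g["n_sex"] == 2, "DZos",
                     np.where(g["sex"] == "M", "DZm", "DZf")),
        )
        return pd.Series(out, index=g.index)

    def complete_pairs(
        self, groups: Sequence[str] | None = None, pheno: str | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """Return co-twin phenotype arrays (x1, x2) for complete pairs.

        For DZos pairs twin 1 is the male co-twin (ordering convention of
        the five-group models); otherwise the stored twin index is used.
        """
        pheno = pheno or self.pheno
        fam_group = self.group_of_family()
        keep = fam_group.index if groups is None else fam_group[fam_group.isin(groups)].index
        sub = self.df[self.df["family_id"].isin(keep)].dropna(subset=[pheno])
        counts = sub.groupby("family_id")["twin"].count()
        complete = counts[counts == 2].index
        sub = sub[sub["family_id"].isin(complete)]
        is_os = sub["family_id"].map(fam_group) == "DZos"
        # male-first ordering for opposite-sex pairs
        order_key = np.where(is_os, np.where(sub["sex"] == "M", 1, 2), sub["twin"])
        sub = sub.assign(_ord=order_key).sort_values(["family_id", "_ord"])
        vals = sub[pheno].to_numpy(float)
        return vals[0::2], vals[1::2]

    def singletons(
        self, groups: Sequence[str] | None = None, pheno: str | None = None
    ) -> np.ndarray:
        pheno = pheno or self.pheno
        fam_group = self.group_of_family()
        keep = fam_group.index if groups is None else fam_group[fam_group.isin(groups)].index
        sub = self.df[self.df["family_id"].isin(keep)].dropna(subset=[pheno])
        counts = sub.groupby("family_id")["twin"].count()
        single = counts[counts == 1].index
        return sub[sub["family_id"].isin(single)][pheno].to_numpy(float)

    def n_observations(self, pheno: str | None = None) -> int:
        pheno = pheno or self.pheno
        return int(self.df[pheno].notna().sum())

    def group_counts(self) -> dict[str, int]:
        g = self.group_of_family()
        return {lab: int((g == lab).sum()) for lab in GROUP_LABELS}


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------


@dataclass
class IccResult:
    r: float
    n_pairs: int
    ci_low: float
    ci_high: float


@dataclass
class VarianceComponents:
    a2: float
    c2: float
    e2: float
    sex: str = "All"
    ci: dict = field(default_factory=dict)


@dataclass
class ModelFit:
    model: str
    minus2ll: float
    df: int
    n_params: int
    n_obs: int
    aic: float
    aic_mx: float
    bic: float
    estimates: VarianceComponents | None
    mu: float | None
    paths: tuple | None
    converged: bool
    saturated_moments: dict | None = None
    # handle kept so profile_ci can refit under constraints
    _dataset: TwinPairDataset | None = field(default=None, repr=False)
    flags: list = field(default_factory=list)


@dataclass
class ModelComparison:
    delta_minus2ll: float
    delta_params: int
    p_value: float
    flagged: bool = False


# ---------------------------------------------------------------------------
# intraclass correlation
# ---------------------------------------------------------------------------


def intraclass_correlation(
    x1: Iterable[float], x2: Iterable[float], level: float = 0.95
) -> IccResult:
    """Double-entry intraclass correlation with a Fisher-z interval.

    The Fisher-z standard error uses the number of *pairs* as effective n,
    not the doubled sample.
    """
    x1 = np.asarray(list(x1), float)
    x2 = np.asarray(list(x2), float)
    if x1.shape != x2.shape:
        raise ValueError("co-twin vectors must have equal length")
    n = len(x1)
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    u = np.concatenate([x1, x2])
    v = np.concatenate([x2, x1])
    if np.std(u) == 0:
        raise ValueError("zero variance in phenotype")
    r = float(np.corrcoef(u, v)[0, 1])
    z = math.atanh(min(max(r, -0.999999), 0.999999))
    se = 1.0 / math.sqrt(n - 3)
    zc = stats.norm.ppf(0.5 + level / 2.0)
    return IccResult(r, n, math.tanh(z - zc * se), math.tanh(z + zc * se))


# ---------------------------------------------------------------------------
# sufficient statistics for the normal likelihoods
# ---------------------------------------------------------------------------


@dataclass
class PairStats:
    """Sufficient statistics of exchangeable co-twin pairs."""

    n: int
    s1: float  # sum(x1 + x2)
    s2: float  # sum(x1^2 + x2^2)
    s12: float  # sum(x1 * x2)

    @classmethod
    def from_pairs(cls, x1: np.ndarray, x2: np.ndarray) -> "PairStats":
        return cls(
            n=len(x1),
            s1=float(np.sum(x1) + np.sum(x2)),
            s2=float(np.sum(x1**2) + np.sum(x2**2)),
            s12=float(np.sum(x1 * x2)),
        )


@dataclass
class SingleStats:
    n: int
    sx: float
    sxx: float

    @classmethod
    def from_values(cls, x: np.ndarray) -> "SingleStats":
        return cls(len(x), float(np.sum(x)), float(np.sum(x**2)))


def m2ll_pairs(st: PairStats, mu: float, v: float, gam: float) -> float:
    """-2 log L of n exchangeable bivariate-normal pairs (common mean/var)."""
    if st.n == 0:
        return 0.0
    det = v * v - gam * gam
    if det <= 0 or v <= 0:
        return _BIG
    q_diag = st.s2 - 2 * mu * st.s1 + 2 * st.n * mu * mu
    q_off = st.s12 - mu * st.s1 + st.n * mu * mu
    return st.n * (2 * _LOG2PI + math.log(det)) + (v * q_diag - 2 * gam * q_off) / det


def m2ll_pairs_hetero(
    n: int,
    sx1: float,
    sx2: float,
    s11: float,
    s22: float,
    s12: float,
    mu1: float,
    mu2: float,
    v1: float,
    v2: float,
    gam: float,
) -> float:
    """-2 log L of n ordered bivariate-normal pairs with distinct margins."""
    if n == 0:
        return 0.0
    det = v1 * v2 - gam * gam
    if det <= 0 or v1 <= 0 or v2 <= 0:
        return _BIG
    q1 = s11 - 2 * mu1 * sx1 + n * mu1 * mu1
    q2 = s22 - 2 * mu2 * sx2 + n * mu2 * mu2
    q12 = s12 - mu1 * sx2 - mu2 * sx1 + n * mu1 * mu2
    return n * (2 * _LOG2PI + math.log(det)) + (v2 * q1 + v1 * q2 - 2 * gam * q12) / det


def m2ll_singles(st: SingleStats, mu: float, v: float) -> float:
    if st.n == 0:
        return 0.0
    if v <= 0:
        return _BIG
    q = st.sxx - 2 * mu * st.sx + st.n * mu * mu
    return st.n * (_LOG2PI + math.log(v)) + q / v


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------

_MODEL_PARAMS = {"saturated": 10, "ACE": 4, "AE": 3, "E": 1}


def _collect_stats(dataset: TwinPairDataset, pheno: str | None):
    mz1, mz2 = dataset.complete_pairs(["MZm", "MZf"], pheno)
    dz1, dz2 = dataset.complete_pairs(["DZm", "DZf", "DZos"], pheno)
    mz_pairs = PairStats.from_pairs(mz1, mz2)
    dz_pairs = PairStats.from_pairs(dz1, dz2)
    mz_single = SingleStats.from_values(dataset.singletons(["MZm", "MZf"], pheno))
    dz_single = SingleStats.from_values(dataset.singletons(["DZm", "DZf", "DZos"], pheno))
    return mz_pairs, dz_pairs, mz_single, dz_single, (mz1, mz2, dz1, dz2)


def _moment_start(mz_pairs, dz_pairs, raw):
    mz1, mz2, dz1, dz2 = raw
    allv = np.concatenate([mz1, mz2, dz1, dz2])
    v0 = float(np.var(allv)) if len(allv) > 2 else 1.0
    v0 = max(v0, 1e-3)
    mu0 = float(np.mean(allv)) if len(allv) else 0.0

    def de_corr(x1, x2):
        if len(x1) < 3:
            return 0.0
        u = np.concatenate([x1, x2])
        v = np.concatenate([x2, x1])
        if np.std(u) == 0:
            return 0.0
        return float(np.corrcoef(u, v)[0, 1])

    rmz, rdz = de_corr(mz1, mz2), de_corr(dz1, dz2)
    a2 = min(max(2 * (rmz - rdz), 0.02), 0.95)
    c2 = min(max(2 * rdz - rmz, 0.01), 0.9)
    e2 = max(1.0 - a2 - c2, 0.02)
    s = a2 + c2 + e2
    return v0, mu0, a2 / s, c2 / s, e2 / s


def _fit_biometric(dataset: TwinPairDataset, model: str, pheno: str | None) -> ModelFit:
    mzp, dzp, mzs, dzs, raw = _collect_stats(dataset, pheno)
    if mzp.n + mzs.n == 0 or dzp.n + dzs.n == 0:
        raise ValueError("both zygosity groups must be represented")
    v0, mu0, a2s, c2s, e2s = _moment_start(mzp, dzp, raw)

    def total_m2ll(a, c, e, mu):
        v = a * a + c * c + e * e
        out = m2ll_pairs(mzp, mu, v, a * a + c * c)
        out += m2ll_pairs(dzp, mu, v, 0.5 * a * a + c * c)
        out += m2ll_singles(mzs, mu, v)
        out += m2ll_singles(dzs, mu, v)
        return out

    if model == "E":
        # mean fixed at 0 on residualized data; e is the single parameter
        n = 2 * (mzp.n + dzp.n) + mzs.n + dzs.n
        ssq = mzp.s2 + dzp.s2 + mzs.sxx + dzs.sxx
        e2hat = ssq / n
        m2ll = n * (_LOG2PI + math.log(e2hat)) + n
        paths = (0.0, 0.0, math.sqrt(e2hat))
        est = VarianceComponents(0.0, 0.0, 1.0)
        best = (m2ll, paths, 0.0)
        converged = True
    else:
        if model == "ACE":
            def obj(x):
                return total_m2ll(x[0], x[1], x[2], x[3])
            start = [math.sqrt(a2s * v0), math.sqrt(c2s * v0), math.sqrt(e2s * v0), mu0]
            bounds = [(0, None)] * 3 + [(None, None)]
        elif model == "AE":
            def obj(x):
                return total_m2ll(x[0], 0.0, x[1], x[2])
            a2f = min(max(a2s + c2s, 0.02), 0.98)
            start = [math.sqrt(a2f * v0), math.sqrt((1 - a2f) * v0), mu0]
            bounds = [(0, None)] * 2 + [(None, None)]
        else:
            raise ValueError(f"unknown model {model!r}")

        best = None
        rng = np.random.default_rng(12345)
        starts = [np.asarray(start, float)]
        for _ in range(4):
            jit = np.asarray(start, float) * rng.uniform(0.5, 1.5, len(start))
            jit[-1] = start[-1] + rng.normal(0, 0.1)
            starts.append(jit)
        converged = False
        for s0 in starts:
            res = optimize.minimize(obj, s0, method="L-BFGS-B", bounds=bounds)
            if best is None or res.fun < best[0]:
                if model == "ACE":
                    paths = (abs(res.x[0]), abs(res.x[1]), abs(res.x[2]))
                    mu = res.x[3]
                else:
                    paths = (abs(res.x[0]), 0.0, abs(res.x[1]))
                    mu = res.x[2]
                best = (float(res.fun), paths, float(mu))
                converged = converged or res.success
        if best is None or not math.isfinite(best[0]):
            raise RuntimeError(f"{model} fit failed to converge")
        a, c, e = best[1]
        v = a * a + c * c + e * e
        if v <= 0:
            raise RuntimeError(f"{model} fit degenerate (zero total variance)")
        est = VarianceComponents(a * a / v, c * c / v, e * e / v)

    m2ll, paths, mu = best
    p = _MODEL_PARAMS[model]
    n_obs = dataset.n_observations(pheno)
    return _make_fit(model, m2ll, p, n_obs, est, mu, paths, converged, dataset)


def _make_fit(model, m2ll, p, n_obs, est, mu, paths, converged, dataset, moments=None):
    df = n_obs - p
    return ModelFit(
        model=model,
        minus2ll=m2ll,
        df=df,
        n_params=p,
        n_obs=n_obs,
        aic=m2ll + 2 * p,
        aic_mx=m2ll - 2 * df,
        bic=m2ll + p * math.log(max(n_obs, 1)),
        estimates=est,
        mu=mu,
        paths=paths,
        converged=converged,
        saturated_moments=moments,
        _dataset=dataset,
    )


def _fit_saturated(dataset: TwinPairDataset, pheno: str | None) -> ModelFit:
    """Per-zygosity saturated model: 2 means, 2 variances, 1 covariance each."""
    pheno = pheno or dataset.pheno
    total = 0.0
    moments: dict[str, dict] = {}
    converged = True
    for zyg, groups in (("MZ", ["MZm", "MZf"]), ("DZ", ["DZm", "DZf", "DZos"])):
        x1, x2 = dataset.complete_pairs(groups, pheno)
        n = len(x1)
        if n < 3:
            raise ValueError(f"too few complete {zyg} pairs for the saturated model")
        stats_ = dict(
            n=n,
            sx1=float(x1.sum()),
            sx2=float(x2.sum()),
            s11=float((x1**2).sum()),
            s22=float((x2**2).sum()),
            s12=float((x1 * x2).sum()),
        )
        # singletons keep their stored twin index
        fam_group = dataset.group_of_family()
        keep = fam_group[fam_group.isin(groups)].index
        sub = dataset.df[dataset.df["family_id"].isin(keep)].dropna(subset=[pheno])
        cnt = sub.groupby("family_id")["twin"].count()
        singles = sub[sub["family_id"].isin(cnt[cnt == 1].index)]
        sg1 = SingleStats.from_values(singles[singles["twin"] == 1][pheno].to_numpy(float))
        sg2 = SingleStats.from_values(singles[singles["twin"] == 2][pheno].to_numpy(float))

        def obj(x, st=stats_, sg1=sg1, sg2=sg2):
            mu1, mu2, lv1, lv2, zr = x
            v1, v2 = math.exp(lv1), math.exp(lv2)
            r = math.tanh(zr)
            gam = r * math.sqrt(v1 * v2)
            out = m2ll_pairs_hetero(
                st["n"], st["sx1"], st["sx2"], st["s11"], st["s22"], st["s12"],
                mu1, mu2, v1, v2, gam,
            )
            out += m2ll_singles(sg1, mu1, v1) + m2ll_singles(sg2, mu2, v2)
            return out

        m1, m2 = float(x1.mean()), float(x2.mean())
        v1_0, v2_0 = max(float(x1.var()), 1e-4), max(float(x2.var()), 1e-4)
        r0 = float(np.corrcoef(x1, x2)[0, 1]) if n > 2 else 0.0
        r0 = min(max(r0, -0.95), 0.95)
        start = [m1, m2, math.log(v1_0), math.log(v2_0), math.atanh(r0)]
        res = optimize.minimize(obj, start, method="L-BFGS-B")
        converged = converged and res.success
        total += float(res.fun)
        mu1, mu2, lv1, lv2, zr = res.x
        moments[zyg] = dict(
            mu1=mu1, mu2=mu2, v1=math.exp(lv1), v2=math.exp(lv2),
            r=math.tanh(zr),
        )
    n_obs = dataset.n_observations(pheno)
    return _make_fit("saturated", total, 10, n_obs, None, None, None, converged,
                     dataset, moments=moments)


def fit_twin_model(
    dataset: TwinPairDataset, model: str, pheno: str | None = None
) -> ModelFit:
    """Fit one of {saturated, ACE, AE, E} by (full-information) ML."""
    if model == "saturated":
        return _fit_saturated(dataset, pheno)
    if model not in _MODEL_PARAMS:
        raise ValueError(f"unknown model {model!r}")
    return _fit_biometric(dataset, model, pheno)


# ---------------------------------------------------------------------------
# profile confidence intervals
# ---------------------------------------------------------------------------


def _profiled_m2ll(dataset, model, component, t, pheno=None):
    """Min -2LL subject to component/V == t (paths otherwise free)."""
    mzp, dzp, mzs, dzs, raw = _collect_stats(dataset, pheno)
    v0, mu0, a2s, c2s, e2s = _moment_start(mzp, dzp, raw)
    t = min(max(t, 1e-9), 1 - 1e-9)
    ratio = t / (1.0 - t)

    def total(a, c, e, mu):
        v = a * a + c * c + e * e
        out = m2ll_pairs(mzp, mu, v, a * a + c * c)
        out += m2ll_pairs(dzp, mu, v, 0.5 * a * a + c * c)
        out += m2ll_singles(mzs, mu, v)
        out += m2ll_singles(dzs, mu, v)
        return out

    if model == "ACE":
        free0 = {
            "a2": [math.sqrt(max(c2s, 1e-3) * v0), math.sqrt(max(e2s, 1e-3) * v0), mu0],
            "c2": [math.sqrt(max(a2s, 1e-3) * v0), math.sqrt(max(e2s, 1e-3) * v0), mu0],
            "e2": [math.sqrt(max(a2s, 1e-3) * v0), math.sqrt(max(c2s, 1e-3) * v0), mu0],
        }[component]

        def obj(x):
            p, q, mu = abs(x[0]), abs(x[1]), x[2]
            fixed = math.sqrt(ratio * (p * p + q * q))
            if component == "a2":
                return total(fixed, p, q, mu)
            if component == "c2":
                return total(p, fixed, q, mu)
            return total(p, q, fixed, mu)

    elif model == "AE":
        if component == "c2":
            raise ValueError("AE model has no c2 component")
        free0 = [math.sqrt(0.5 * v0), mu0]

        def obj(x):
            p, mu = abs(x[0]), x[1]
            fixed = math.sqrt(ratio) * p
            if component == "a2":
                return total(fixed, 0.0, p, mu)
            return total(p, 0.0, fixed, mu)

    else:
        raise ValueError(f"profile CI unsupported for model {model!r}")

    best = math.inf
    rng = np.random.default_rng(7)
    for i in range(3):
        s0 = np.asarray(free0, float)
        if i:
            s0 = s0 * rng.uniform(0.6, 1.4, len(s0))
        res = optimize.minimize(obj, s0, method="Nelder-Mead",
                                options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 2000})
        best = min(best, float(res.fun))
    return best


def profile_ci(
    fit: ModelFit, component: str, level: float = 0.95
) -> tuple[float, float]:
    """Profile-likelihood interval for a standardized variance component.

    Bounds are where -2LL rises by the chi-square(1) critical value above
    the fitted minimum, truncated to [0, 1]; a component pinned at a
    boundary yields a one-sided interval (flag recorded on the fit).
    """
    if fit._dataset is None:
        raise ValueError("fit does not carry its dataset; cannot profile")
    if fit.estimates is None:
        raise ValueError("saturated fits have no variance components")
    crit = stats.chi2.ppf(level, 1)
    target = fit.minus2ll + crit
    that = getattr(fit.estimates, component)
    ds, model = fit._dataset, fit.model

    def g(t):
        return _profiled_m2ll(ds, model, component, t) - target

    eps = 1e-6
    # lower bound
    if that <= eps or g(eps) < 0:
        lo = 0.0
        if that <= eps:
            fit.flags.append(f"{component} lower bound pinned at 0")
    else:
        lo = float(optimize.brentq(g, eps, max(that, 2 * eps), xtol=1e-5))
    # upper bound
    if that >= 1 - eps or g(1 - eps) < 0:
        hi = 1.0
        if that >= 1 - eps:
            fit.flags.append(f"{component} upper bound pinned at 1")
    else:
        hi = float(optimize.brentq(g, min(that, 1 - 2 * eps), 1 - eps, xtol=1e-5))
    return lo, hi


# ---------------------------------------------------------------------------
# model comparison / selection
# ---------------------------------------------------------------------------


def compare_models(full: ModelFit, nested: ModelFit) -> ModelComparison:
    if nested.n_params == full.n_params and abs(nested.minus2ll - full.minus2ll) < 1e-9:
        # degenerate comparison of a model with itself
        return ModelComparison(0.0, 0, 1.0)
    if nested.n_params >= full.n_params:
        raise ValueError("nested model must have fewer parameters")
    delta = nested.minus2ll - full.minus2ll
    dp = full.n_params - nested.n_params
    flagged = delta < -1e-6
    p = float(stats.chi2.sf(max(delta, 0.0), dp)) if delta > 0 else 1.0
    return ModelComparison(delta, dp, p, flagged)


def select_best(fits: Sequence[ModelFit], alpha: float = 0.05) -> dict:
    """Rank fits by AIC and BIC and apply the LRT-against-ACE rule.

    The LRT choice is the most reduced model (fewest parameters) whose
    fit is not significantly worse than ACE; BIC breaks disagreements.
    """
    fits = list(fits)
    if len(fits) == 1:
        return {"selected": fits[0].model, "by_aic": fits[0].model,
                "by_bic": fits[0].model, "by_lrt": fits[0].model,
                "agreement": True}
    by_aic = min(fits, key=lambda f: (f.aic, f.n_params)).model
    by_bic = min(fits, key=lambda f: (f.bic, f.n_params)).model
    ace = next((f for f in fits if f.model == "ACE"), None)
    by_lrt = None
    if ace is not None:
        candidates = sorted(
            [f for f in fits if f.n_params < ace.n_params],
            key=lambda f: f.n_params,
        )
        for f in candidates:
            if compare_models(ace, f).p_value >= alpha:
                by_lrt = f.model
                break
        if by_lrt is None:
            by_lrt = ace.model
    agreement = by_aic == by_bic and (by_lrt in (None, by_aic))
    return {
        "selected": by_bic,
        "by_aic": by_aic,
        "by_bic": by_bic,
        "by_lrt": by_lrt,
        "agreement": agreement,
    }
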