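"""Five-group sex-limitation twin models.

Full (per-sex ACE + free opposite-sex genetic correlation), Common
Effects (rg fixed at 0.5), Scalar (shared standardized components, a
variance scalar on female paths) and Null (identical variance parameters
for the sexes). Means are estimated per sex in every model; the Null
model equates only the variance parameters, which is what the printed
degrees of freedom of the source analyses imply.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .twin_models import (
    GROUP_LABELS,
    ModelFit,
    PairStats,
    SingleStats,
    TwinPairDataset,
    VarianceComponents,
    m2ll_pairs,
    m2ll_pairs_hetero,
    m2ll_singles,
)

__all__ = ["SexLimFit", "fit_sexlim", "sexlim_decision", "SEXLIM_MODELS"]

SEXLIM_MODELS = ("full", "common", "scalar", "null")
_N_PARAMS = {"full": 9, "common": 8, "scalar": 6, "null": 5}


@dataclass
class SexLimFit:
    model: str
    male: VarianceComponents
    female: VarianceComponents
    rg_os: float
    scalar_k: float | None
    fit: ModelFit
    paths_m: tuple = ()
    paths_f: tuple = ()
    mu_m: float = 0.0
    mu_f: float = 0.0


@dataclass
class _FiveGroupStats:
    pairs: dict            # label -> PairStats for same-sex groups
    singles_m: SingleStats
    singles_f: SingleStats
    dzos: dict             # ordered male-first pair stats
    n_obs: int


def _collect(dataset: TwinPairDataset, pheno: str | None) -> _FiveGroupStats:
    counts = dataset.group_counts()
    for lab in GROUP_LABELS:
        if counts[lab] == 0:
            raise ValueError(f"group {lab} is empty; five-group model needs all groups")
    pairs = {}
    for lab in ("MZm", "MZf", "DZm", "DZf"):
        x1, x2 = dataset.complete_pairs([lab], pheno)
        pairs[lab] = PairStats.from_pairs(x1, x2)
    xm, xf = dataset.complete_pairs(["DZos"], pheno)  # male first
    dzos = dict(
        n=len(xm), sx1=float(xm.sum()), sx2=float(xf.sum()),
        s11=float((xm**2).sum()), s22=float((xf**2).sum()),
        s12=float((xm * xf).sum()),
    )
    # singletons pooled by own sex (their likelihood depends only on sex)
    pheno_col = pheno or dataset.pheno
    fam_group = dataset.group_of_family()
    sub = dataset.df.dropna(subset=[pheno_col])
    cnt = sub.groupby("family_id")["twin"].count()
    singles = sub[sub["family_id"].isin(cnt[cnt == 1].index)]
    sm = SingleStats.from_values(singles[singles["sex"] == "M"][pheno_col].to_numpy(float))
    sf = SingleStats.from_values(singles[singles["sex"] == "F"][pheno_col].to_numpy(float))
    return _FiveGroupStats(pairs, sm, sf, dzos, dataset.n_observations(pheno_col))


def _m2ll_sexlim(st: _FiveGroupStats, pm, pf, mu_m, mu_f, rg):
    am, cm, em = pm
    af, cf, ef = pf
    vm = am * am + cm * cm + em * em
    vf = af * af + cf * cf + ef * ef
    out = m2ll_pairs(st.pairs["MZm"], mu_m, vm, am * am + cm * cm)
    out += m2ll_pairs(st.pairs["MZf"], mu_f, vf, af * af + cf * cf)
    out += m2ll_pairs(st.pairs["DZm"], mu_m, vm, 0.5 * am * am + cm * cm)
    out += m2ll_pairs(st.pairs["DZf"], mu_f, vf, 0.5 * af * af + cf * cf)
    gam = rg * am * af + cm * cf
    d = st.dzos
    out += m2ll_pairs_hetero(d["n"], d["sx1"], d["sx2"], d["s11"], d["s22"],
                             d["s12"], mu_m, mu_f, vm, vf, gam)
    out += m2ll_singles(st.singles_m, mu_m, vm)
    out += m2ll_singles(st.singles_f, mu_f, vf)
    return out


def _start_values(st: _FiveGroupStats):
    tot_n = 2 * sum(p.n for p in st.pairs.values()) + 2 * st.dzos["n"]
    tot_s = sum(p.s1 for p in st.pairs.values()) + st.dzos["sx1"] + st.dzos["sx2"]
    tot_ss = sum(p.s2 for p in st.pairs.values()) + st.dzos["s11"] + st.dzos["s22"]
    mu0 = tot_s / tot_n
    v0 = max(tot_ss / tot_n - mu0 * mu0, 1e-3)
    return mu0, v0


def fit_sexlim(
    dataset: TwinPairDataset, model: str, pheno: str | None = None
) -> SexLimFit:
    """ML fit of one five-group sex-limitation model."""
    if model not in SEXLIM_MODELS:
        raise ValueError(f"unknown sex-limitation model {model!r}")
    st = _collect(dataset, pheno)
    mu0, v0 = _start_values(st)
    p0 = math.sqrt(v0 / 3.0)

    if model == "full":
        x0 = [p0, p0 / 2, p0, p0, p0 / 2, p0, mu0, mu0, 0.5]
        bounds = [(0, None)] * 6 + [(None, None)] * 2 + [(0.0, 1.0)]

        def unpack(x):
            return (x[0], x[1], x[2]), (x[3], x[4], x[5]), x[6], x[7], x[8]

    elif model == "common":
        x0 = [p0, p0 / 2, p0, p0, p0 / 2, p0, mu0, mu0]
        bounds = [(0, None)] * 6 + [(None, None)] * 2

        def unpack(x):
            return (x[0], x[1], x[2]), (x[3], x[4], x[5]), x[6], x[7], 0.5

    elif model == "scalar":
        x0 = [p0, p0 / 2, p0, 1.0, mu0, mu0]
        bounds = [(0, None)] * 3 + [(1e-6, None)] + [(None, None)] * 2

        def unpack(x):
            pm = (x[0], x[1], x[2])
            k = x[3]
            return pm, (k * x[0], k * x[1], k * x[2]), x[4], x[5], 0.5

    else:  # null
        x0 = [p0, p0 / 2, p0, mu0, mu0]
        bounds = [(0, None)] * 3 + [(None, None)] * 2

        def unpack(x):
            pm = (x[0], x[1], x[2])
            return pm, pm, x[3], x[4], 0.5

    def obj(x):
        pm, pf, mu_m, mu_f, rg = unpack(x)
        return _m2ll_sexlim(st, pm, pf, mu_m, mu_f, rg)

    best = None
    rng = np.random.default_rng(2024)
    starts = [np.asarray(x0, float)]
    for _ in range(4):
        jit = np.asarray(x0, float) * rng.uniform(0.5, 1.5, len(x0))
        starts.append(np.clip(jit, [b[0] if b[0] is not None else -np.inf for b in bounds],
                              [b[1] if b[1] is not None else np.inf for b in bounds]))
    converged = False
    for s0 in starts:
        res = optimize.minimize(obj, s0, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
            converged = converged or res.success
    if best is None or not math.isfinite(best.fun):
        raise RuntimeError(f"sex-limitation {model} fit did not converge")

    pm, pf, mu_m, mu_f, rg = unpack(best.x)
    pm = tuple(abs(v) for v in pm)
    pf = tuple(abs(v) for v in pf)

    def comps(p, sex):
        v = sum(q * q for q in p)
        if v <= 0:
            raise RuntimeError("degenerate variance in sex-limitation fit")
        return VarianceComponents(p[0] ** 2 / v, p[1] ** 2 / v, p[2] ** 2 / v, sex=sex)

    npar = _N_PARAMS[model]
    m2ll = float(best.fun)
    df = st.n_obs - npar
    fitstats = ModelFit(
        model=f"sexlim-{model}", minus2ll=m2ll, df=df, n_params=npar,
        n_obs=st.n_obs, aic=m2ll + 2 * npar, aic_mx=m2ll - 2 * df,
        bic=m2ll + npar * math.log(max(st.n_obs, 1)),
        estimates=None, mu=None, paths=None, converged=converged,
        _dataset=dataset,
    )
    return SexLimFit(
        model=model, male=comps(pm, "M"), female=comps(pf, "F"),
        rg_os=float(rg) if model == "full" else 0.5,
        scalar_k=float(best.x[3]) if model == "scalar" else None,
        fit=fitstats, paths_m=pm, paths_f=pf,
        mu_m=float(mu_m), mu_f=float(mu_f),
    )


def _profile_sexlim_component(dataset, pheno, sex, component, fullfit, level=0.95):
    """Profile CI of one per-sex standardized component in the full model."""
    st = _collect(dataset, pheno)
    crit = stats.chi2.ppf(level, 1)
    target = fullfit.fit.minus2ll + crit
    comp_idx = {"a2": 0, "c2": 1, "e2": 2}[component]
    that = getattr(fullfit.male if sex == "M" else fullfit.female, component)

    def profiled(t):
        t = min(max(t, 1e-9), 1 - 1e-9)
        ratio = math.sqrt(t / (1.0 - t))
        # free: 2 remaining paths of the profiled sex, 3 of the other sex,
        # two means and rg
        x0 = list(fullfit.paths_m) + list(fullfit.paths_f) + [
            fullfit.mu_m, fullfit.mu_f, fullfit.rg_os]
        del x0[(0 if sex == "M" else 3) + comp_idx]

        def obj(x):
            xs = list(x)
            rg = min(max(xs[-1], 0.0), 1.0)
            mu_m, mu_f = xs[-3], xs[-2]
            free = [abs(v) for v in xs[:-3]]
            if sex == "M":
                rest = free[:2]
                other = tuple(free[2:5])
            else:
                other = tuple(free[:3])
                rest = free[3:5]
            fixed = ratio * math.sqrt(rest[0] ** 2 + rest[1] ** 2)
            p = rest[:comp_idx] + [fixed] + rest[comp_idx:]
            pm, pf = (tuple(p), other) if sex == "M" else (other, tuple(p))
            return _m2ll_sexlim(st, pm, pf, mu_m, mu_f, rg)

        res = optimize.minimize(obj, x0, method="Nelder-Mead",
                                options={"xatol": 1e-6, "fatol": 1e-8,
                                         "maxiter": 4000})
        return float(res.fun)

    def g(t):
        return profiled(t) - target

    eps = 1e-6
    lo = 0.0 if (that <= eps or g(eps) < 0) else float(
        optimize.brentq(g, eps, max(that, 2 * eps), xtol=1e-4))
    hi = 1.0 if (that >= 1 - eps or g(1 - eps) < 0) else float(
        optimize.brentq(g, min(that, 1 - 2 * eps), 1 - eps, xtol=1e-4))
    return lo, hi


def sexlim_decision(
    dataset: TwinPairDataset,
    pheno: str | None = None,
    alpha: float = 0.05,
    cis: bool | tuple = False,
) -> dict:
    """Fit all four models and pick one.

    Returns the comparison table (-2LL, df, delta vs full, p, AIC, BIC),
    the BIC-selected model, a plain-language verdict and the per-sex
    estimates from the full model (with profile CIs when ``cis``).
    """
    fits = {m: fit_sexlim(dataset, m, pheno) for m in SEXLIM_MODELS}
    full = fits["full"]
    table = []
    for m in SEXLIM_MODELS:
        f = fits[m]
        delta = f.fit.minus2ll - full.fit.minus2ll
        dp = full.fit.n_params - f.fit.n_params
        p = float(stats.chi2.sf(max(delta, 0.0), dp)) if dp > 0 else float("nan")
        table.append(dict(model=m, minus2ll=f.fit.minus2ll, df=f.fit.df,
                          delta_minus2ll=delta, p_value=p, aic=f.fit.aic,
                          bic=f.fit.bic))
    selected = min(SEXLIM_MODELS, key=lambda m: (fits[m].fit.bic, fits[m].fit.n_params))
    verdict = {
        "null": "no qualitative or quantitative sex differences",
        "scalar": "variance differences only (scalar)",
        "common": "quantitative sex differences",
        "full": "qualitative sex differences",
    }[selected]
    estimates = {
        "M": fits["full"].male,
        "F": fits["full"].female,
        "rg_os": fits["full"].rg_os,
    }
    if cis:
        names = ("a2", "c2", "e2") if cis is True else tuple(cis)
        for sex in ("M", "F"):
            comp = estimates[sex]
            for name in names:
                comp.ci[name] = _profile_sexlim_component(
                    dataset, pheno, sex, name, full)
    return {"fits": fits, "table": table, "selected": selected,
            "verdict": verdict, "estimates": estimates}
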