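"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators: ACE-structured twin phenotypes over the five
zygosity-by-sex groups, trial-level dot-comparison sessions driven by a
per-subject Weber fraction, and unrelated-individual biallelic SNP panels
with a chosen SNP heritability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .numerosity import TrialRecord, predict_percent_correct, trials_to_frame
from .twin_models import GROUP_LABELS, TwinPairDataset

__all__ = [
    "TwinSimSpec",
    "TaskSimSpec",
    "SnpSimSpec",
    "simulate_twin_dataset",
    "simulate_session",
    "simulate_population_sessions",
    "simulate_snp_panel",
    "draw_weber_population",
    "default_ratio_schedule",
    "truncated_lognormal_params",
    "write_twin_tsv",
    "read_twin_tsv",
    "write_trials_csv",
]


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------


@dataclass
class TwinSimSpec:
    """Generative ACE model, per sex, plus group sizes.

    Variance proportions must sum to 1 within each sex. ``rg_os`` is the
    additive-genetic correlation of opposite-sex pairs (0.5 = the same
    genes act in both sexes).
    """

    a2_m: float = 0.32
    c2_m: float = 0.0
    e2_m: float = 0.68
    a2_f: float = 0.32
    c2_f: float = 0.0
    e2_f: float = 0.68
    rg_os: float = 0.5
    n_pairs_by_group: dict = field(
        default_factory=lambda: {"MZm": 317, "MZf": 519, "DZm": 335,
                                 "DZf": 398, "DZos": 689}
    )
    missing_rate: float = 0.0
    age_range: tuple = (16.0, 17.2)
    seed: int = 0

    def validate(self) -> None:
        for sex in ("m", "f"):
            a2, c2, e2 = (getattr(self, f"{k}2_{sex}") for k in "ace")
            for name in (f"a2_{sex}", f"c2_{sex}", f"e2_{sex}"):
                v = getattr(self, name)
                if not (0.0 <= v <= 1.0):
                    raise ValueError(f"{name} must lie in [0, 1], got {v}")
            if abs(a2 + c2 + e2 - 1.0) > 1e-9:
                raise ValueError(
                    f"a2_{sex}+c2_{sex}+e2_{sex} must sum to 1, got {a2 + c2 + e2}"
                )
        if not (0.0 <= self.rg_os <= 1.0):
            raise ValueError(f"rg_os must lie in [0, 1], got {self.rg_os}")
        for g, n in self.n_pairs_by_group.items():
            if g not in GROUP_LABELS:
                raise ValueError(f"unknown group label {g!r}")
            if n < 0:
                raise ValueError(f"n_pairs_by_group[{g!r}] must be >= 0")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError(f"missing_rate must lie in [0, 1), got {self.missing_rate}")


@dataclass
class TaskSimSpec:
    w_mean: float = 0.28
    w_sd: float = 0.13
    n_trials: int = 150
    ratio_schedule: list = field(default_factory=lambda: default_ratio_schedule())
    rt_location_ms: float = 800.0
    rt_scale_ms: float = 200.0
    outlier_rate: float = 0.03
    outlier_factor: float = 4.0
    w_range: tuple = (0.10, 0.99)
    seed: int = 0

    def validate(self) -> None:
        if self.w_mean <= 0:
            raise ValueError(f"w_mean must be positive, got {self.w_mean}")
        if self.w_sd <= 0:
            raise ValueError(f"w_sd must be positive, got {self.w_sd}")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        for n1, n2 in self.ratio_schedule:
            if n1 < 1 or n2 < 1:
                raise ValueError("all dot counts must be >= 1")
        if not (0.0 <= self.outlier_rate <= 1.0):
            raise ValueError("outlier_rate must lie in [0, 1]")


@dataclass
class SnpSimSpec:
    n_individuals: int = 1000
    n_snps: int = 5000
    maf_range: tuple = (0.05, 0.5)
    h2_snp: float = 0.3
    n_causal: int = 1000
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must satisfy 0 < lo <= hi <= 0.5, got {self.maf_range}")
        if not (0.0 <= self.h2_snp <= 1.0):
            raise ValueError(f"h2_snp must lie in [0, 1], got {self.h2_snp}")
        if self.n_causal > self.n_snps:
            raise ValueError("n_causal must not exceed n_snps")
        if self.n_individuals < 1 or self.n_snps < 1:
            raise ValueError("n_individuals and n_snps must be >= 1")


# ---------------------------------------------------------------------------
# twin phenotypes
# ---------------------------------------------------------------------------

_GROUP_SEXES = {"MZm": ("M", "M"), "MZf": ("F", "F"), "DZm": ("M", "M"),
                "DZf": ("F", "F"), "DZos": ("M", "F")}
_GROUP_RHO_A = {"MZm": 1.0, "MZf": 1.0, "DZm": 0.5, "DZf": 0.5}


def simulate_twin_dataset(spec: TwinSimSpec, pheno: str = "pheno") -> TwinPairDataset:
    """Draw phenotype = a*A + c*C + e*E per twin with ACE latent structure.

    A is shared (r=1) for MZ, r=0.5 for same-sex DZ and r=rg_os for
    opposite-sex DZ; C is fully shared within pair; E is independent.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    paths = {
        "M": tuple(math.sqrt(v) for v in (spec.a2_m, spec.c2_m, spec.e2_m)),
        "F": tuple(math.sqrt(v) for v in (spec.a2_f, spec.c2_f, spec.e2_f)),
    }
    rows = []
    fam = 0
    for group in GROUP_LABELS:
        n = int(spec.n_pairs_by_group.get(group, 0))
        if n == 0:
            continue
        rho = _GROUP_RHO_A.get(group, spec.rg_os)
        z0 = rng.standard_normal(n)
        z1 = rng.standard_normal(n)
        z2 = rng.standard_normal(n)
        a1 = math.sqrt(rho) * z0 + math.sqrt(1 - rho) * z1
        a2_ = math.sqrt(rho) * z0 + math.sqrt(1 - rho) * z2
        c = rng.standard_normal(n)
        e1 = rng.standard_normal(n)
        e2_ = rng.standard_normal(n)
        ages = rng.uniform(spec.age_range[0], spec.age_range[1], n)
        sex1, sex2 = _GROUP_SEXES[group]
        pa1, pa2 = paths[sex1], paths[sex2]
        y1 = pa1[0] * a1 + pa1[1] * c + pa1[2] * e1
        y2 = pa2[0] * a2_ + pa2[1] * c + pa2[2] * e2_
        zyg = "MZ" if group.startswith("MZ") else "DZ"
        drop = rng.random(n) < spec.missing_rate
        which = rng.integers(1, 3, n)  # which twin goes missing
        for i in range(n):
            fam += 1
            fid = f"F{fam:06d}"
            if not (drop[i] and which[i] == 1):
                rows.append((fid, 1, zyg, sex1, ages[i], y1[i]))
            if not (drop[i] and which[i] == 2):
                rows.append((fid, 2, zyg, sex2, ages[i], y2[i]))
    df = pd.DataFrame(rows, columns=["family_id", "twin", "zygosity", "sex",
                                     "age", pheno])
    return TwinPairDataset(df, pheno=pheno)


# ---------------------------------------------------------------------------
# task sessions
# ---------------------------------------------------------------------------


def default_ratio_schedule(
    min_dots: int = 5, max_dots: int = 21
) -> list[tuple[int, int]]:
    """All integer multiples of the ratio bins 1:2 .. 9:10 within the
    dot-count range, as (n_small, n_large) pairs."""
    bins = [(1, 2), (2, 3), (3, 4), (4, 5), (5, 6), (6, 7), (7, 8), (8, 9), (9, 10)]
    out = []
    for a, b in bins:
        k = 1
        while k * b <= max_dots:
            if k * a >= min_dots:
                out.append((k * a, k * b))
            k += 1
    return out


def simulate_session(
    w_true: float,
    spec: TaskSimSpec,
    rng: np.random.Generator | None = None,
    subject_id: str = "S1",
) -> list[TrialRecord]:
    """One session: correctness Bernoulli under the psychometric curve,
    lognormal RTs with a share of inflated outliers."""
    if w_true <= 0:
        raise ValueError("w_true must be positive")
    spec.validate()
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    schedule = spec.ratio_schedule
    idx = rng.integers(0, len(schedule), spec.n_trials)
    swap = rng.random(spec.n_trials) < 0.5
    sigma = spec.rt_scale_ms / spec.rt_location_ms
    trials = []
    for t in range(spec.n_trials):
        n_small, n_large = schedule[idx[t]]
        ny, nb = (n_large, n_small) if swap[t] else (n_small, n_large)
        rt = float(spec.rt_location_ms * math.exp(sigma * rng.standard_normal()))
        if rng.random() < spec.outlier_rate:
            rt *= spec.outlier_factor
        if ny == nb:
            correct = bool(rng.random() < 0.5)
            response = "yellow" if rng.random() < 0.5 else "blue"
        else:
            p = predict_percent_correct(ny, nb, w_true)
            correct = bool(rng.random() < p)
            larger = "yellow" if ny > nb else "blue"
            smaller = "blue" if larger == "yellow" else "yellow"
            response = larger if correct else smaller
        trials.append(TrialRecord(subject_id, int(ny), int(nb), response,
                                  correct, rt))
    return trials


def truncated_lognormal_params(
    mean: float, sd: float, lo: float, hi: float
) -> tuple[float, float]:
    """Underlying (mu, sigma) of a lognormal whose truncation to [lo, hi]
    has the requested mean and SD. Raises if no solution exists."""
    if not (lo < hi):
        raise ValueError("need lo < hi")
    if not (lo < mean < hi):
        raise ValueError("target mean must lie inside the truncation interval")

    def trunc_moment(mu, sigma, k):
        alpha = (math.log(lo) - mu) / sigma
        beta = (math.log(hi) - mu) / sigma
        z = stats.norm.cdf(beta) - stats.norm.cdf(alpha)
        if z <= 0:
            return np.nan
        num = stats.norm.cdf(beta - k * sigma) - stats.norm.cdf(alpha - k * sigma)
        arg = k * mu + 0.5 * k * k * sigma * sigma
        if arg > 700:  # overflow guard; signals an infeasible parameter probe
            return np.nan
        return math.exp(arg) * num / z

    def eqs(x):
        mu, lsig = x
        sigma = math.exp(lsig)
        m1 = trunc_moment(mu, sigma, 1)
        m2 = trunc_moment(mu, sigma, 2)
        if not (np.isfinite(m1) and np.isfinite(m2)):
            return [1e6, 1e6]
        return [m1 - mean, (m2 - m1 * m1) - sd * sd]

    s0 = math.sqrt(math.log(1 + (sd / mean) ** 2))
    x0 = [math.log(mean) - 0.5 * s0 * s0, math.log(s0)]
    sol = optimize.root(eqs, x0, method="hybr")
    resid = np.abs(eqs(sol.x)).max()
    if not sol.success or resid > 1e-8:
        raise ValueError(
            f"moments (mean={mean}, sd={sd}) incompatible with truncation "
            f"to [{lo}, {hi}]"
        )
    return float(sol.x[0]), float(math.exp(sol.x[1]))


def draw_weber_population(
    spec: TaskSimSpec, n_subjects: int, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Per-subject true Weber fractions: truncated lognormal matched to
    (w_mean, w_sd) on w_range, drawn by inverse CDF."""
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    lo, hi = spec.w_range
    mu, sigma = truncated_lognormal_params(spec.w_mean, spec.w_sd, lo, hi)
    a = stats.norm.cdf((math.log(lo) - mu) / sigma)
    b = stats.norm.cdf((math.log(hi) - mu) / sigma)
    u = rng.uniform(a, b, n_subjects)
    return np.exp(mu + sigma * stats.norm.ppf(u))


def simulate_population_sessions(
    spec: TaskSimSpec, n_subjects: int
) -> dict[str, list[TrialRecord]]:
    """Sessions for a population of subjects with heterogeneous w."""
    if n_subjects < 0:
        raise ValueError("n_subjects must be >= 0")
    if n_subjects == 0:
        return {}
    rng = np.random.default_rng(spec.seed)
    ws = draw_weber_population(spec, n_subjects, rng)
    out = {}
    for i, w in enumerate(ws, start=1):
        sid = f"S{i:05d}"
        out[sid] = simulate_session(float(w), spec, rng=rng, subject_id=sid)
    return out


# ---------------------------------------------------------------------------
# SNP panels
# ---------------------------------------------------------------------------


def simulate_snp_panel(spec: SnpSimSpec, standardize: bool = True):
    """Independent biallelic SNPs plus an additive phenotype.

    Returns (GenotypeMatrix, phenotype, effects): genotypes are binomial
    allele counts at frequencies uniform on maf_range; the phenotype is
    the sum of standardized-dosage effects at n_causal loci scaled to
    explain exactly h2_snp of the (unit, when standardized) variance.
    """
    from .gcta_greml import GenotypeMatrix  # local import avoids a cycle

    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_individuals, spec.n_snps
    p = rng.uniform(spec.maf_range[0], spec.maf_range[1], m)
    x = rng.binomial(2, p[None, :], size=(n, m)).astype(np.int8)
    causal = rng.choice(m, size=spec.n_causal, replace=False)
    beta = np.zeros(m)
    beta[causal] = rng.standard_normal(spec.n_causal)

    xc = x[:, causal].astype(float)
    mean = xc.mean(axis=0)
    sd = xc.std(axis=0)
    sd[sd == 0] = 1.0
    g = (xc - mean) / sd @ beta[causal]
    g_sd = g.std()
    if g_sd > 0:
        g = g / g_sd
    noise = rng.standard_normal(n)
    noise_sd = noise.std()
    if noise_sd > 0:
        noise = noise / noise_sd
    y = math.sqrt(spec.h2_snp) * g + math.sqrt(1.0 - spec.h2_snp) * noise
    if not standardize:
        y = y * 1.0  # already on the unit scale; kept for interface clarity

    scale = np.zeros(m)
    if g_sd > 0:
        scale[causal] = math.sqrt(spec.h2_snp) / g_sd
    effects = beta * scale

    ids = [f"I{i:06d}" for i in range(1, n + 1)]
    snp_ids = [f"snp{j:06d}" for j in range(1, m + 1)]
    geno = GenotypeMatrix(ids=ids, snp_ids=snp_ids, dosages=x)
    return geno, y, effects


# ---------------------------------------------------------------------------
# writers / readers
# ---------------------------------------------------------------------------

TWIN_COLUMNS = ["family_id", "twin", "zygosity", "sex", "age",
                "pheno_accuracy", "pheno_weber"]


def write_twin_tsv(dataset: TwinPairDataset, path) -> None:
    df = dataset.df.copy()
    for col in ("pheno_accuracy", "pheno_weber"):
        if col not in df.columns:
            df[col] = df[dataset.pheno] if dataset.pheno in df.columns else np.nan
    df[TWIN_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_twin_tsv(path, pheno: str = "pheno_weber") -> TwinPairDataset:
    df = pd.read_csv(path, sep="\t")
    return TwinPairDataset(df, pheno=pheno)


def write_trials_csv(trials_by_subject: dict[str, list[TrialRecord]], path) -> None:
    trials_to_frame(trials_by_subject).to_csv(path, index=False,
                                              float_format="%.6f")
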