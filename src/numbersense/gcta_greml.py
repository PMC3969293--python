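"""SNP heritability for unrelated individuals.

Genetic relationship matrix from standardized dosages, greedy pruning of
related pairs above a cutoff, and average-information REML (one EM step
first) for the variance explained by genotyped SNPs, with a delta-method
standard error on h2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "GRM",
    "GremlResult",
    "compute_grm",
    "prune_related",
    "reml_h2",
    "read_plink",
    "write_plink",
    "write_gcta_grm",
    "read_gcta_grm",
]

MISSING = -1  # dosage code for a missing genotype


@dataclass
class GenotypeMatrix:
    """N x M allele-count matrix (0/1/2, MISSING for absent calls)."""

    ids: list
    snp_ids: list
    dosages: np.ndarray  # int8, N x M

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        n, m = self.dosages.shape
        if n != len(self.ids) or m != len(self.snp_ids):
            raise ValueError("dosage dimensions inconsistent with id lists")
        if ((self.dosages > 2) | ((self.dosages < 0) & (self.dosages != MISSING))).any():
            raise ValueError("dosages must be 0, 1, 2 or missing")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        x = self.dosages.astype(float)
        x[self.dosages == MISSING] = np.nan
        with np.errstate(invalid="ignore"):
            return np.nanmean(x, axis=0) / 2.0


@dataclass
class GRM:
    values: np.ndarray  # N x N symmetric
    ids: list
    n_snps_used: np.ndarray  # N x N counts

    def __post_init__(self):
        v = np.asarray(self.values, float)
        if v.shape[0] != v.shape[1] or v.shape[0] != len(self.ids):
            raise ValueError("GRM must be square and match the id list")
        if not np.allclose(v, v.T, atol=1e-8):
            raise ValueError("GRM must be symmetric")
        self.values = v

    def subset(self, keep_ids) -> "GRM":
        pos = {i: k for k, i in enumerate(self.ids)}
        idx = np.array([pos[i] for i in keep_ids])
        return GRM(self.values[np.ix_(idx, idx)], list(keep_ids),
                   self.n_snps_used[np.ix_(idx, idx)])


@dataclass
class GremlResult:
    h2_snp: float
    se: float
    sigma_g2: float
    sigma_e2: float
    loglik: float
    n_iterations: int
    converged: bool
    n_individuals: int = 0
    flags: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# GRM
# ---------------------------------------------------------------------------


def compute_grm(genotypes: GenotypeMatrix, mean_impute: bool = False) -> GRM:
    """A_jk = mean over shared SNPs of (x_j - 2p)(x_k - 2p) / (2p(1-p)).

    Monomorphic SNPs are dropped. Missing genotypes are handled by
    restricting each pair to jointly observed SNPs (M_jk), or by mean
    imputation when ``mean_impute`` is set.
    """
    if genotypes.n_snps < 2:
        raise ValueError("need at least 2 SNPs")
    x = genotypes.dosages.astype(float)
    miss = genotypes.dosages == MISSING
    x[miss] = np.nan
    p = np.nanmean(x, axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all SNPs are monomorphic")
    x = x[:, poly]
    p = p[poly]
    miss = miss[:, poly]
    denom = np.sqrt(2.0 * p * (1.0 - p))
    z = (x - 2.0 * p) / denom
    n = genotypes.n_individuals
    if not miss.any() or mean_impute:
        z = np.nan_to_num(z, nan=0.0)  # mean imputation == zero after centring
        m_used = np.full((n, n), z.shape[1], dtype=float)
        a = (z @ z.T) / z.shape[1]
    else:
        obs = (~miss).astype(float)
        zf = np.nan_to_num(z, nan=0.0)
        m_used = obs @ obs.T
        if (m_used == 0).any():
            raise ValueError("a pair of individuals shares no observed SNPs")
        a = (zf @ zf.T) / m_used
    a = (a + a.T) / 2.0
    return GRM(a, list(genotypes.ids), m_used)


def prune_related(grm: GRM, cutoff: float = 0.025) -> list:
    """Greedy removal of one member per offending pair until no
    off-diagonal exceeds |cutoff|; ties broken by id order."""
    a = np.abs(grm.values.copy())
    np.fill_diagonal(a, 0.0)
    active = np.ones(len(grm.ids), bool)
    adj = a > cutoff
    while True:
        deg = (adj & active[None, :] & active[:, None]).sum(axis=1)
        deg[~active] = 0
        if deg.max() == 0:
            break
        worst = int(np.argmax(deg))  # argmax -> lowest index on ties
        active[worst] = False
    return [i for i, keep in zip(grm.ids, active) if keep]


# ---------------------------------------------------------------------------
# REML
# ---------------------------------------------------------------------------


def _reml_pieces(lam, yt, xt, sg, se):
    """Quantities of the REML log-likelihood in the GRM eigenbasis."""
    d = sg * lam + se
    if (d <= 0).any():
        return None
    di = 1.0 / d
    xtd = xt * di[:, None]
    xtvx = xt.T @ xtd
    sign, logdet_x = np.linalg.slogdet(xtvx)
    if sign <= 0:
        return None
    xtvx_inv = np.linalg.inv(xtvx)
    vy = yt * di
    beta = xtvx_inv @ (xt.T @ vy)
    py = vy - xtd @ beta

    def papply(v):
        vv = v * di
        return vv - xtd @ (xtvx_inv @ (xt.T @ vv))

    ypy = float(yt @ py)
    logdet_v = float(np.sum(np.log(d)))
    ll = -0.5 * (logdet_v + logdet_x + ypy)
    # traces of P*A and P: tr(V^-1 A) - tr((X'V^-1X)^-1 X'V^-1 A V^-1 X)
    tr_va = float(np.sum(lam * di))
    tr_v = float(np.sum(di))
    xa = xtd * lam[:, None]
    tr_corr_a = float(np.trace(xtvx_inv @ (xtd.T @ xa)))
    tr_corr_i = float(np.trace(xtvx_inv @ (xtd.T @ xtd)))
    return dict(ll=ll, py=py, papply=papply, ypy=ypy,
                tr_pa=tr_va - tr_corr_a, tr_p=tr_v - tr_corr_i)


def reml_h2(
    grm: GRM,
    phenotype: np.ndarray,
    covariates: np.ndarray | None = None,
    constrain: bool = True,
    max_iter: int = 100,
    tol: float = 1e-8,
    method: str = "ai",
) -> GremlResult:
    """Average-information REML for y = Xb + g + e, cov(g) = sg2 * A.

    With ``method="ai"`` (default) the first update is an EM step (stable
    far from the optimum) and the rest are AI steps; ``method="em"`` runs
    pure EM throughout (slow, used as a cross-check). Variance components
    are clamped non-negative unless ``constrain`` is False. SE of h2 by
    the delta method from the inverse AI matrix at convergence.
    """
    if method not in ("ai", "em"):
        raise ValueError("method must be 'ai' or 'em'")
    if method == "em" and max_iter == 100:
        max_iter = 5000  # EM converges linearly
    y = np.asarray(phenotype, float)
    n = len(y)
    if n != len(grm.ids):
        raise ValueError("phenotype length does not match the GRM")
    if n < 50:
        raise ValueError("GREML refused below N=50: estimate would be meaningless")
    vp = float(np.var(y, ddof=1))
    if vp <= 0:
        raise ValueError("phenotype has zero variance")
    x = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), np.asarray(covariates, float)]
    )
    lam, u = np.linalg.eigh(grm.values)
    yt = u.T @ y
    xt = u.T @ x

    floor = 1e-6 * vp if constrain else -np.inf
    sg, se = vp / 2.0, vp / 2.0
    ll_prev = None
    ai = np.eye(2)
    n_iter = 0
    converged = False
    trace = []
    for it in range(max_iter):
        n_iter = it + 1
        pieces = _reml_pieces(lam, yt, xt, sg, se)
        if pieces is None:
            raise RuntimeError(f"REML likelihood undefined at iteration {it}: {trace}")
        py = pieces["py"]
        papply = pieces["papply"]
        apy = lam * py
        ypapy = float(py @ apy)
        ypy2 = float(py @ py)
        score_g = -0.5 * (pieces["tr_pa"] - ypapy)
        score_e = -0.5 * (pieces["tr_p"] - ypy2)
        if it == 0 or method == "em":
            # EM step
            sg_new = sg + sg * sg * (ypapy - pieces["tr_pa"]) / n
            se_new = se + se * se * (ypy2 - pieces["tr_p"]) / n
        else:
            pay = papply(apy)
            ppy = papply(py)
            ai = 0.5 * np.array(
                [[float(apy @ pay), float(apy @ ppy)],
                 [float(apy @ ppy), float(py @ ppy)]]
            )
            try:
                step = np.linalg.solve(ai, np.array([score_g, score_e]))
            except np.linalg.LinAlgError:
                step = np.array([score_g, score_e]) * vp / n
            sg_new, se_new = sg + step[0], se + step[1]
        sg = max(sg_new, floor) if constrain else sg_new
        se = max(se_new, floor) if constrain else se_new
        trace.append((sg, se, pieces["ll"]))
        if ll_prev is not None and abs(pieces["ll"] - ll_prev) < tol:
            converged = True
            break
        ll_prev = pieces["ll"]
    if not converged:
        raise RuntimeError(
            f"AI-REML did not converge in {max_iter} iterations; trace tail: "
            f"{trace[-3:]}"
        )
    pieces = _reml_pieces(lam, yt, xt, sg, se)
    # AI at the optimum for the sampling covariance
    py = pieces["py"]
    apy = lam * py
    pay = pieces["papply"](apy)
    ppy = pieces["papply"](py)
    ai = 0.5 * np.array(
        [[float(apy @ pay), float(apy @ ppy)],
         [float(apy @ ppy), float(py @ ppy)]]
    )
    try:
        cov = np.linalg.inv(ai)
    except np.linalg.LinAlgError:
        cov = np.full((2, 2), np.nan)
    total = sg + se
    h2 = sg / total
    grad = np.array([se, -sg]) / total**2
    var_h2 = float(grad @ cov @ grad)
    se_h2 = math.sqrt(var_h2) if var_h2 > 0 else float("nan")
    flags = []
    if constrain and (sg <= floor * 1.01 or se <= floor * 1.01):
        flags.append("variance component at boundary")
    return GremlResult(
        h2_snp=float(h2), se=se_h2, sigma_g2=float(sg), sigma_e2=float(se),
        loglik=float(pieces["ll"]), n_iterations=n_iter, converged=converged,
        n_individuals=n, flags=flags,
    )


# ---------------------------------------------------------------------------
# PLINK bed/bim/fam IO (SNP-major; dosage = count of the A1 allele)
# ---------------------------------------------------------------------------

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit codes: 00 hom A1 (2), 01 missing, 10 het (1), 11 hom A2 (0)
_CODE_TO_DOSE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSE_TO_CODE = {2: 0b00, 1: 0b10, 0: 0b11, MISSING: 0b01}


def write_plink(genotypes: GenotypeMatrix, prefix: str) -> None:
    n, m = genotypes.n_individuals, genotypes.n_snps
    with open(f"{prefix}.fam", "w") as fh:
        for i in genotypes.ids:
            fh.write(f"{i} {i} 0 0 0 -9\n")
    with open(f"{prefix}.bim", "w") as fh:
        for j, s in enumerate(genotypes.snp_ids, start=1):
            fh.write(f"1\t{s}\t0\t{j}\tA\tG\n")
    nbytes = (n + 3) // 4
    # dosage -> 2-bit code, vectorized (missing = -1 -> 01)
    dose_to_code = np.zeros(4, dtype=np.uint8)
    for d, c in _DOSE_TO_CODE.items():
        dose_to_code[d] = c  # index -1 wraps to the last slot
    codes = dose_to_code[genotypes.dosages.T]  # m x n
    pad = nbytes * 4 - n
    if pad:
        codes = np.pad(codes, ((0, 0), (0, pad)), constant_values=0)
    codes = codes.reshape(m, nbytes, 4)
    packed = (codes[:, :, 0] | (codes[:, :, 1] << 2)
              | (codes[:, :, 2] << 4) | (codes[:, :, 3] << 6)).astype(np.uint8)
    with open(f"{prefix}.bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


def read_plink(prefix: str) -> GenotypeMatrix:
    fam = pd.read_csv(f"{prefix}.fam", sep=r"\s+", header=None)
    bim = pd.read_csv(f"{prefix}.bim", sep=r"\s+", header=None)
    ids = fam[1].astype(str).tolist()
    snp_ids = bim[1].astype(str).tolist()
    n, m = len(ids), len(snp_ids)
    nbytes = (n + 3) // 4
    with open(f"{prefix}.bed", "rb") as fh:
        magic = fh.read(3)
        if magic != _BED_MAGIC:
            raise ValueError("not a SNP-major PLINK .bed file")
        raw = np.frombuffer(fh.read(), dtype=np.uint8)
    if raw.size != m * nbytes:
        raise ValueError(".bed size inconsistent with .fam/.bim")
    raw = raw.reshape(m, nbytes)
    shifts = np.arange(4, dtype=np.uint8) * 2
    codes = (raw[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(m, nbytes * 4)[:, :n]
    dosages = _CODE_TO_DOSE[codes].T.copy()
    return GenotypeMatrix(ids=ids, snp_ids=snp_ids, dosages=dosages)


# ---------------------------------------------------------------------------
# GCTA binary GRM IO
# ---------------------------------------------------------------------------


def write_gcta_grm(grm: GRM, prefix: str) -> None:
    """grm.bin / grm.N.bin: float32 lower triangle row by row; grm.id text."""
    n = len(grm.ids)
    tri = np.tril_indices(n)
    grm.values[tri].astype("<f4").tofile(f"{prefix}.grm.bin")
    grm.n_snps_used[tri].astype("<f4").tofile(f"{prefix}.grm.N.bin")
    with open(f"{prefix}.grm.id", "w") as fh:
        for i in grm.ids:
            fh.write(f"{i}\t{i}\n")


def read_gcta_grm(prefix: str) -> GRM:
    ids = [line.split()[1] for line in open(f"{prefix}.grm.id")]
    n = len(ids)
    tri = np.tril_indices(n)
    vals = np.fromfile(f"{prefix}.grm.bin", dtype="<f4").astype(float)
    a = np.zeros((n, n))
    a[tri] = vals
    a = a + np.tril(a, -1).T
    counts = np.fromfile(f"{prefix}.grm.N.bin", dtype="<f4").astype(float)
    m = np.zeros((n, n))
    m[tri] = counts
    m = m + np.tril(m, -1).T
    return GRM(a, ids, m)
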