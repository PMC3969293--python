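import itertools

import numpy as np
import pytest

from numbersense.gcta_greml import (
    GRM,
    MISSING,
    GenotypeMatrix,
    compute_grm,
    prune_related,
    read_gcta_grm,
    read_plink,
    reml_h2,
    write_gcta_grm,
    write_plink,
)
from numbersense.synthetic_data import SnpSimSpec, simulate_snp_panel


def small_panel(n=200, m=500, h2=0.3, seed=0, n_causal=100):
    spec = SnpSimSpec(n_individuals=n, n_snps=m, h2_snp=h2,
                      n_causal=n_causal, seed=seed)
    return simulate_snp_panel(spec)


class TestGrm:
    def test_identical_profiles(self):
        geno, _, _ = small_panel(n=50, m=2000, seed=1)
        dos = geno.dosages.copy()
        dos[1] = dos[0]  # duplicate individual 0 as 1
        dup = GenotypeMatrix(geno.ids, geno.snp_ids, dos)
        grm = compute_grm(dup)
        assert grm.values[0, 1] == pytest.approx(
            0.5 * (grm.values[0, 0] + grm.values[1, 1]), abs=1e-9)
        assert grm.values[0, 0] == pytest.approx(1.0, abs=0.1)

    def test_offdiagonal_sampling_theory(self):
        geno, _, _ = small_panel(n=200, m=10_000, h2=0.0, n_causal=1, seed=2)
        grm = compute_grm(geno)
        off = grm.values[np.triu_indices(200, 1)]
        # sample-frequency centring biases the off-diagonal mean by ~ -1/(N-1)
        assert abs(off.mean()) < 2.0 / 199
        assert off.std() == pytest.approx(1 / np.sqrt(grm.n_snps_used[0, 1]),
                                          rel=0.15)
        assert grm.values.diagonal().mean() == pytest.approx(1.0, abs=0.02)

    def test_hand_evaluated_two_snps(self):
        # dosages {0,2} at p=0.5: (x-2p)(x'-2p)/(2p(1-p)) = +/-2 per SNP
        dos = np.array([[0, 0], [0, 0], [2, 2], [2, 2]], dtype=np.int8)
        geno = GenotypeMatrix(["a", "b", "c", "d"], ["s1", "s2"], dos)
        grm = compute_grm(geno)
        assert grm.values[0, 1] == pytest.approx(2.0)
        assert grm.values[0, 2] == pytest.approx(-2.0)
        assert grm.values[0, 0] == pytest.approx(2.0)

    def test_monomorphic_excluded(self):
        dos = np.array([[0, 1], [0, 2], [0, 0], [0, 1]], dtype=np.int8)
        geno = GenotypeMatrix(list("abcd"), ["s1", "s2"], dos)
        grm = compute_grm(geno)  # s1 monomorphic, dropped
        assert grm.n_snps_used[0, 1] == 1

    def test_all_monomorphic_rejected(self):
        dos = np.zeros((4, 3), dtype=np.int8)
        geno = GenotypeMatrix(list("abcd"), ["s1", "s2", "s3"], dos)
        with pytest.raises(ValueError, match="monomorphic"):
            compute_grm(geno)

    def test_missing_pairwise_intersection(self):
        geno, _, _ = small_panel(n=60, m=400, seed=3)
        dos = geno.dosages.copy()
        dos[0, :200] = MISSING
        miss = GenotypeMatrix(geno.ids, geno.snp_ids, dos)
        grm = compute_grm(miss)
        assert grm.n_snps_used[0, 1] < grm.n_snps_used[2, 3]

    def test_permutation_invariance(self):
        geno, _, _ = small_panel(n=40, m=300, seed=4)
        grm = compute_grm(geno)
        perm = np.random.default_rng(0).permutation(40)
        geno_p = GenotypeMatrix([geno.ids[i] for i in perm], geno.snp_ids,
                                geno.dosages[perm])
        grm_p = compute_grm(geno_p)
        assert np.allclose(grm_p.values, grm.values[np.ix_(perm, perm)])


def brute_force_min_cover(values, cutoff):
    """Smallest set of individuals whose removal clears all offending pairs."""
    n = len(values)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)
             if abs(values[i, j]) > cutoff]
    if not pairs:
        return 0
    for k in range(1, n + 1):
        for combo in itertools.combinations(range(n), k):
            s = set(combo)
            if all(i in s or j in s for i, j in pairs):
                return k
    return n


class TestPrune:
    def test_nothing_to_remove(self):
        n = 50
        rng = np.random.default_rng(5)
        off = rng.normal(0, 0.006, (n, n))
        a = (off + off.T) / 2
        np.fill_diagonal(a, 1.0)
        assert np.abs(a[np.triu_indices(n, 1)]).max() <= 0.025
        grm = GRM(a, [f"i{k}" for k in range(n)], np.full((n, n), 100.0))
        assert len(prune_related(grm)) == n

    def test_duplicate_removes_one(self):
        n = 30
        a = np.eye(n)
        a[0, 1] = a[1, 0] = 0.98
        grm = GRM(a, [f"i{k}" for k in range(n)], np.full((n, n), 100.0))
        kept = prune_related(grm)
        assert len(kept) == n - 1
        assert ("i0" in kept) != ("i1" in kept)

    def test_planted_trio_matches_min_cover(self):
        n = 20
        a = np.eye(n)
        for i, j in [(2, 5), (2, 9), (5, 9)]:  # mutual relatives at 0.5
            a[i, j] = a[j, i] = 0.5
        grm = GRM(a, [f"i{k}" for k in range(n)], np.full((n, n), 100.0))
        kept = prune_related(grm)
        removed = n - len(kept)
        assert removed == brute_force_min_cover(a, 0.025) == 2

    def test_chain_greedy_equals_cover(self):
        n = 10
        a = np.eye(n)
        for i, j in [(0, 1), (1, 2), (3, 4)]:
            a[i, j] = a[j, i] = 0.3
        grm = GRM(a, [f"i{k}" for k in range(n)], np.full((n, n), 100.0))
        removed = n - len(prune_related(grm))
        assert removed == brute_force_min_cover(a, 0.025) == 2


def reml_loglik_oracle(a, y, h2, x=None):
    """REML log-likelihood at heritability ratio h2, total variance profiled
    out analytically; plain dense linear algebra, no shared code."""
    n = len(y)
    x = np.ones((n, 1)) if x is None else x
    k = x.shape[1]
    r = h2 * a + (1 - h2) * np.eye(n)
    ri = np.linalg.inv(r)
    xrx = x.T @ ri @ x
    p = ri - ri @ x @ np.linalg.inv(xrx) @ x.T @ ri
    ypy = float(y @ p @ y)
    vp = ypy / (n - k)
    sign, logdet_r = np.linalg.slogdet(r)
    _, logdet_x = np.linalg.slogdet(xrx)
    return -0.5 * (logdet_r + (n - k) * np.log(vp) + logdet_x + (n - k))


def grid_oracle_h2(a, y, step=0.005):
    grid = np.arange(0.0, 1.0 + step / 2, step)
    grid[0], grid[-1] = 1e-4, 1 - 1e-4
    lls = [reml_loglik_oracle(a, y, h) for h in grid]
    return float(grid[int(np.argmax(lls))])


class TestReml:
    def test_matches_grid_oracle(self):
        geno, y, _ = small_panel(n=500, m=2000, h2=0.3, n_causal=500, seed=6)
        grm = compute_grm(geno)
        res = reml_h2(grm, y)
        oracle = grid_oracle_h2(grm.values, y)
        assert res.h2_snp == pytest.approx(oracle, abs=0.005)

    def test_recovery_mean(self):
        # one panel's GRM, fresh causal draws per replicate
        spec = SnpSimSpec(n_individuals=1000, n_snps=4000, h2_snp=0.3,
                          n_causal=1000, seed=7)
        geno, _, _ = simulate_snp_panel(spec)
        grm = compute_grm(geno)
        rng = np.random.default_rng(7)
        z = (geno.dosages - geno.dosages.mean(0)) / geno.dosages.std(0)
        vals = []
        for _ in range(12):
            beta = rng.standard_normal(1000)
            g = z[:, rng.choice(4000, 1000, replace=False)] @ beta
            g /= g.std()
            y = np.sqrt(0.3) * g + np.sqrt(0.7) * rng.standard_normal(1000)
            vals.append(reml_h2(grm, y).h2_snp)
        assert np.mean(vals) == pytest.approx(0.3, abs=0.06)

    def test_exact_genetic_value(self):
        geno, y, _ = small_panel(n=300, m=300, h2=1.0, n_causal=300, seed=8)
        grm = compute_grm(geno)
        res = reml_h2(grm, y)
        assert res.h2_snp > 0.95

    def test_scale_invariance(self):
        geno, y, _ = small_panel(n=300, m=1000, seed=9)
        grm = compute_grm(geno)
        a = reml_h2(grm, y)
        b = reml_h2(grm, 5.0 * y)
        assert a.h2_snp == pytest.approx(b.h2_snp, abs=1e-6)
        assert b.sigma_g2 == pytest.approx(25 * a.sigma_g2, rel=1e-4)

    def test_se_decreases_with_n(self):
        ses = []
        for n in (500, 1000, 2000):
            geno, y, _ = small_panel(n=n, m=2000, seed=10)
            grm = compute_grm(geno)
            ses.append(reml_h2(grm, y).se)
        assert ses[0] > ses[1] > ses[2]

    def test_em_equals_ai(self):
        geno, y, _ = small_panel(n=300, m=1000, seed=11)
        grm = compute_grm(geno)
        ai = reml_h2(grm, y, method="ai")
        em = reml_h2(grm, y, method="em", tol=1e-12)
        assert em.h2_snp == pytest.approx(ai.h2_snp, abs=1e-4)

    def test_small_n_refused(self):
        geno, y, _ = small_panel(n=60, m=200, seed=12)
        grm = compute_grm(geno)
        with pytest.raises(ValueError, match="N=50"):
            reml_h2(grm.subset(grm.ids[:40]), y[:40])

    def test_covariates_accepted(self):
        geno, y, _ = small_panel(n=300, m=1000, seed=13)
        grm = compute_grm(geno)
        rng = np.random.default_rng(13)
        cov = rng.standard_normal((300, 2))
        y2 = y + cov @ np.array([1.5, -1.0])
        base = reml_h2(grm, y, covariates=cov)
        adjusted = reml_h2(grm, y2, covariates=cov)
        unadjusted = reml_h2(grm, y2)
        # REML is invariant to mean shifts within the covariate span;
        # ignoring the covariates dilutes h2 toward zero
        assert adjusted.h2_snp == pytest.approx(base.h2_snp, abs=1e-5)
        assert unadjusted.h2_snp < 0.5 * base.h2_snp


class TestIo:
    def test_plink_round_trip(self, tmp_path):
        geno, _, _ = small_panel(n=37, m=101, seed=14)  # n % 4 != 0 on purpose
        dos = geno.dosages.copy()
        dos[3, 7] = MISSING
        geno = GenotypeMatrix(geno.ids, geno.snp_ids, dos)
        write_plink(geno, str(tmp_path / "p"))
        back = read_plink(str(tmp_path / "p"))
        assert back.ids == geno.ids
        assert back.snp_ids == geno.snp_ids
        assert np.array_equal(back.dosages, geno.dosages)

    def test_bed_magic_checked(self, tmp_path):
        (tmp_path / "x.bed").write_bytes(b"nope")
        (tmp_path / "x.fam").write_text("a a 0 0 0 -9\n")
        (tmp_path / "x.bim").write_text("1\ts1\t0\t1\tA\tG\n")
        with pytest.raises(ValueError, match="bed"):
            read_plink(str(tmp_path / "x"))

    def test_gcta_grm_round_trip(self, tmp_path):
        geno, _, _ = small_panel(n=25, m=200, seed=15)
        grm = compute_grm(geno)
        write_gcta_grm(grm, str(tmp_path / "g"))
        back = read_gcta_grm(str(tmp_path / "g"))
        assert back.ids == [str(i) for i in grm.ids]
        assert np.allclose(back.values, grm.values, atol=1e-6)
        assert np.allclose(back.n_snps_used, grm.n_snps_used)
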