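import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from numbersense.synthetic_data import TwinSimSpec, simulate_twin_dataset
from numbersense.twin_models import (
    TwinPairDataset,
    compare_models,
    fit_twin_model,
    intraclass_correlation,
    profile_ci,
    select_best,
)

from conftest import ae_spec


def make_dataset(x1, x2, zygosity="MZ", sex=("M", "M")):
    rows = []
    for i, (a, b) in enumerate(zip(x1, x2)):
        rows.append((f"F{i}", 1, zygosity, sex[0], 16.5, a))
        rows.append((f"F{i}", 2, zygosity, sex[1], 16.5, b))
    return TwinPairDataset(
        pd.DataFrame(rows, columns=["family_id", "twin", "zygosity", "sex",
                                    "age", "pheno"])
    )


class TestDatasetValidation:
    def test_three_twins_rejected(self):
        df = pd.DataFrame({
            "family_id": ["F1"] * 3, "twin": [1, 2, 2],
            "zygosity": ["MZ"] * 3, "sex": ["M"] * 3,
            "age": [16.0] * 3, "pheno": [0.0] * 3,
        })
        with pytest.raises(ValueError, match="more than two"):
            TwinPairDataset(df)

    def test_mz_discordant_sex_rejected(self):
        df = pd.DataFrame({
            "family_id": ["F1", "F1"], "twin": [1, 2],
            "zygosity": ["MZ", "MZ"], "sex": ["M", "F"],
            "age": [16.0, 16.0], "pheno": [0.0, 1.0],
        })
        with pytest.raises(ValueError, match="discordant"):
            TwinPairDataset(df)

    def test_group_counts(self, ae_dataset):
        counts = ae_dataset.group_counts()
        assert counts["MZm"] + counts["MZf"] == 700
        assert counts["DZm"] + counts["DZf"] + counts["DZos"] == 1140


class TestIcc:
    def test_identical_pairs(self):
        x = np.random.default_rng(0).normal(0, 1, 100)
        res = intraclass_correlation(x, x)
        assert res.r == pytest.approx(1.0, abs=1e-9)

    def test_independent_null(self):
        rng = np.random.default_rng(3)
        res = intraclass_correlation(rng.normal(0, 1, 10_000),
                                     rng.normal(0, 1, 10_000))
        assert abs(res.r) < 0.03

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            intraclass_correlation([1.0, 2.0], [1.0, 2.0])

    def test_zero_variance(self):
        with pytest.raises(ValueError):
            intraclass_correlation([1.0] * 10, [1.0] * 10)

    def test_calibration_rho_035(self):
        # bivariate-normal pairs at rho=.35, n=730: mean r and CI coverage
        rng = np.random.default_rng(42)
        rho, n, reps = 0.35, 730, 500
        cov = [[1, rho], [rho, 1]]
        rs, covered = [], 0
        for _ in range(reps):
            xy = rng.multivariate_normal([0, 0], cov, size=n)
            res = intraclass_correlation(xy[:, 0], xy[:, 1])
            rs.append(res.r)
            if res.ci_low <= rho <= res.ci_high:
                covered += 1
        assert np.mean(rs) == pytest.approx(rho, abs=0.01)
        assert covered / reps == pytest.approx(0.95, abs=0.02)


class TestFitTwinModel:
    def test_pure_noise_null_recovery(self):
        spec = TwinSimSpec(
            a2_m=0, c2_m=0, e2_m=1, a2_f=0, c2_f=0, e2_f=1,
            n_pairs_by_group={"MZm": 2500, "MZf": 2500, "DZm": 2500,
                              "DZf": 2500, "DZos": 0}, seed=10,
        )
        ds = simulate_twin_dataset(spec)
        fit = fit_twin_model(ds, "AE")
        assert fit.estimates.a2 < 0.05

    def test_near_perfect_heritability(self):
        spec = TwinSimSpec(
            a2_m=0.99, c2_m=0, e2_m=0.01, a2_f=0.99, c2_f=0, e2_f=0.01,
            n_pairs_by_group={"MZm": 500, "MZf": 500, "DZm": 500,
                              "DZf": 500, "DZos": 0}, seed=11,
        )
        fit = fit_twin_model(simulate_twin_dataset(spec), "AE")
        assert fit.estimates.a2 > 0.95

    def test_ae_recovery_paper_scale(self):
        # a2=.32 generative, 700 MZ + 1,140 DZ pairs, a handful of seeds
        vals = [
            fit_twin_model(simulate_twin_dataset(ae_spec(0.32, 700, 1140, seed=s)),
                           "AE").estimates.a2
            for s in range(8)
        ]
        assert np.mean(vals) == pytest.approx(0.32, abs=0.03)

    def test_likelihood_nesting(self, ae_dataset):
        fits = {m: fit_twin_model(ae_dataset, m)
                for m in ("saturated", "ACE", "AE", "E")}
        tol = 1e-6
        assert fits["saturated"].minus2ll <= fits["ACE"].minus2ll + tol
        assert fits["ACE"].minus2ll <= fits["AE"].minus2ll + tol
        assert fits["AE"].minus2ll <= fits["E"].minus2ll + tol

    def test_c2_zero_ae_equals_ace(self, ae_dataset):
        ace = fit_twin_model(ae_dataset, "ACE")
        ae = fit_twin_model(ae_dataset, "AE")
        if ace.estimates.c2 < 1e-4:
            assert ace.minus2ll == pytest.approx(ae.minus2ll, abs=1e-4)

    def test_falconer_oracle_large_n(self):
        ds = simulate_twin_dataset(ae_spec(0.4, 25_000, 25_000, seed=12))
        fit = fit_twin_model(ds, "ACE")
        x1, x2 = ds.complete_pairs(["MZm", "MZf"])
        rmz = np.corrcoef(np.r_[x1, x2], np.r_[x2, x1])[0, 1]
        y1, y2 = ds.complete_pairs(["DZm", "DZf", "DZos"])
        rdz = np.corrcoef(np.r_[y1, y2], np.r_[y2, y1])[0, 1]
        assert fit.estimates.a2 == pytest.approx(2 * (rmz - rdz), abs=0.02)
        assert fit.estimates.c2 == pytest.approx(max(2 * rdz - rmz, 0), abs=0.02)

    def test_components_sum_to_one(self, ae_dataset):
        for m in ("ACE", "AE"):
            est = fit_twin_model(ae_dataset, m).estimates
            assert est.a2 + est.c2 + est.e2 == pytest.approx(1.0, abs=1e-6)

    def test_fiml_equals_complete_pair_likelihood(self):
        # no singletons: -2LL must equal the exact bivariate-normal value
        rng = np.random.default_rng(13)
        ds = simulate_twin_dataset(ae_spec(0.4, 300, 300, seed=14))
        fit = fit_twin_model(ds, "ACE")
        a, c, e = fit.paths
        mu, v = fit.mu, a**2 + c**2 + e**2
        ll = 0.0
        for groups, cov in ((["MZm", "MZf"], a**2 + c**2),
                            (["DZm", "DZf", "DZos"], 0.5 * a**2 + c**2)):
            x1, x2 = ds.complete_pairs(groups)
            mvn = multivariate_normal([mu, mu], [[v, cov], [cov, v]])
            ll += mvn.logpdf(np.column_stack([x1, x2])).sum()
        assert fit.minus2ll == pytest.approx(-2 * ll, rel=1e-10)

    def test_singletons_enter_likelihood(self):
        spec = ae_spec(0.32, 400, 400, seed=15)
        spec.missing_rate = 0.2
        ds = simulate_twin_dataset(spec)
        fit = fit_twin_model(ds, "AE")
        assert fit.n_obs == ds.n_observations()
        assert fit.df == fit.n_obs - 3

    def test_e_model_closed_form(self, ae_dataset):
        fit = fit_twin_model(ae_dataset, "E")
        vals = ae_dataset.df["pheno"].dropna().to_numpy()
        e2 = np.mean(vals**2)  # mean fixed at 0
        expect = len(vals) * (math.log(2 * math.pi * e2) + 1)
        assert fit.minus2ll == pytest.approx(expect, rel=1e-12)
        assert fit.n_params == 1

    def test_information_criteria(self, ae_dataset):
        fit = fit_twin_model(ae_dataset, "AE")
        assert fit.aic == pytest.approx(fit.minus2ll + 2 * fit.n_params)
        assert fit.aic_mx == pytest.approx(fit.minus2ll - 2 * fit.df)
        assert fit.bic == pytest.approx(
            fit.minus2ll + fit.n_params * math.log(fit.n_obs))

    def test_unknown_model(self, ae_dataset):
        with pytest.raises(ValueError):
            fit_twin_model(ae_dataset, "ADE")

    def test_saturated_moments_match_sample(self):
        ds = simulate_twin_dataset(ae_spec(0.4, 2000, 2000, seed=16))
        fit = fit_twin_model(ds, "saturated")
        x1, x2 = ds.complete_pairs(["MZm", "MZf"])
        m = fit.saturated_moments["MZ"]
        assert m["mu1"] == pytest.approx(x1.mean(), abs=1e-4)
        assert m["v1"] == pytest.approx(x1.var(), rel=1e-3)
        assert m["r"] == pytest.approx(np.corrcoef(x1, x2)[0, 1], abs=1e-4)


class TestProfileCi:
    def test_large_n_narrow(self):
        ds = simulate_twin_dataset(ae_spec(0.35, 25_000, 25_000, seed=17))
        fit = fit_twin_model(ds, "AE")
        lo, hi = profile_ci(fit, "a2")
        assert lo <= fit.estimates.a2 <= hi
        assert hi - lo < 0.03

    def test_c2_zero_lower_bound(self):
        ds = simulate_twin_dataset(ae_spec(0.4, 3000, 3000, seed=18))
        fit = fit_twin_model(ds, "ACE")
        lo, hi = profile_ci(fit, "c2")
        assert lo == 0.0

    def test_tiny_n_wide(self):
        ds = simulate_twin_dataset(ae_spec(0.4, 6, 6, seed=19))
        fit = fit_twin_model(ds, "AE")
        lo, hi = profile_ci(fit, "a2")
        assert hi - lo > 0.6

    def test_coverage_moderate_n(self):
        hits = 0
        for s in range(20):
            ds = simulate_twin_dataset(ae_spec(0.32, 700, 1140, seed=100 + s))
            fit = fit_twin_model(ds, "AE")
            lo, hi = profile_ci(fit, "a2")
            if lo <= 0.32 <= hi:
                hits += 1
        assert hits >= 16  # ~95% nominal, binomial slack


class TestComparison:
    def test_identical_models(self, ae_dataset):
        fit = fit_twin_model(ae_dataset, "AE")
        cmp = compare_models(fit, fit)
        assert cmp.delta_minus2ll == 0.0 and cmp.p_value == 1.0

    def test_drop_true_zero_not_rejected(self):
        # c2 is 0 generatively: ACE -> AE LRT should rarely reject
        big_p = 0
        for s in range(30):
            ds = simulate_twin_dataset(ae_spec(0.32, 700, 1140, seed=200 + s))
            ace = fit_twin_model(ds, "ACE")
            ae = fit_twin_model(ds, "AE")
            if compare_models(ace, ae).p_value > 0.05:
                big_p += 1
        assert big_p >= 24  # boundary mixture makes non-rejection >= 95% nominal

    def test_wrong_direction_raises(self, ae_dataset):
        ace = fit_twin_model(ae_dataset, "ACE")
        ae = fit_twin_model(ae_dataset, "AE")
        with pytest.raises(ValueError):
            compare_models(ae, ace)

    def test_e_drop_detected(self, ae_dataset):
        ace = fit_twin_model(ae_dataset, "ACE")
        e = fit_twin_model(ae_dataset, "E")
        cmp = compare_models(ace, e)
        assert cmp.p_value < 1e-6


class TestSelection:
    def test_single_fit(self, ae_dataset):
        fit = fit_twin_model(ae_dataset, "AE")
        assert select_best([fit])["selected"] == "AE"

    def test_ae_selected_on_ae_data(self):
        wins = 0
        reps = 25
        for s in range(reps):
            ds = simulate_twin_dataset(ae_spec(0.35, 730, 1175, seed=300 + s))
            fits = [fit_twin_model(ds, m) for m in ("saturated", "ACE", "AE", "E")]
            if select_best(fits)["by_bic"] == "AE":
                wins += 1
        assert wins >= 0.8 * reps

    def test_e_selected_on_noise(self):
        wins = 0
        reps = 15
        for s in range(reps):
            spec = TwinSimSpec(
                a2_m=0, c2_m=0, e2_m=1, a2_f=0, c2_f=0, e2_f=1,
                n_pairs_by_group={"MZm": 350, "MZf": 350, "DZm": 300,
                                  "DZf": 300, "DZos": 540}, seed=400 + s,
            )
            ds = simulate_twin_dataset(spec)
            fits = [fit_twin_model(ds, m) for m in ("ACE", "AE", "E")]
            if select_best(fits)["by_bic"] == "E":
                wins += 1
        assert wins > reps / 2
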