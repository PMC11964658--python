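import numpy as np
import pandas as pd
import pytest
from scipy import stats

from featurexcan import (
    GwasSummary,
    WeightsDB,
    adjust_multiple,
    associate_individual,
    associate_summary,
    build_banded_cov,
    correct_inflation,
    estimate_phi,
    predict_features,
    run_gwas,
    standardize,
)

from conftest import toy_genotypes


def _db_from(geno, weight_vectors, prefix="f"):
    db = WeightsDB(variants=list(geno.variants))
    for i, w in enumerate(weight_vectors):
        db.add(f"{prefix}{i}", w)
    return db


class TestPredictFeatures:
    def test_zero_weights_give_zero_column(self):
        g = toy_genotypes(n=30, P=10)
        db = _db_from(g, [np.zeros(10)])
        pred = predict_features(g, db)
        np.testing.assert_array_equal(pred["f0"], np.zeros(30))

    def test_unit_weight_returns_standardized_dosage(self):
        g = toy_genotypes(n=40, P=10, seed=2)
        w = np.zeros(10); w[3] = 1.0
        pred = predict_features(g, _db_from(g, [w]))
        np.testing.assert_allclose(pred["f0"], standardize(g)[:, 3], atol=1e-12)

    def test_matches_matrix_product_oracle(self):
        g = toy_genotypes(n=50, P=100, seed=3)
        rng = np.random.default_rng(4)
        W = [rng.normal(size=100) for _ in range(3)]
        pred = predict_features(g, _db_from(g, W))
        expected = standardize(g) @ np.column_stack(W)
        np.testing.assert_allclose(pred.to_numpy(), expected, atol=1e-10)

    def test_missing_weight_mass_renormalized(self):
        g = toy_genotypes(n=30, P=10, seed=5)
        sub = g.subset_variants(np.arange(5))  # half the universe missing
        rng = np.random.default_rng(6)
        w = rng.normal(size=10)
        db = _db_from(g, [w])
        with pytest.warns(UserWarning, match="renormaliz"):
            pred = predict_features(sub, db)
        frac = np.abs(w[:5]).sum() / np.abs(w).sum()
        expected = (standardize(sub) @ w[:5]) / frac
        np.testing.assert_allclose(pred["f0"], expected, atol=1e-10)


class TestAssociateIndividual:
    def test_perfect_fit(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=100)
        res = associate_individual(x, x)
        assert res.bhat == pytest.approx(1.0, abs=1e-10)
        assert res.p_raw < 1e-100

    def test_permutation_null_z_is_standard(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=300)
        zs = []
        for _ in range(300):
            y = rng.permutation(x) + rng.normal(size=300)
            zs.append(associate_individual(x, y).z)
        assert 0.9 < np.std(zs) < 1.1

    def test_logistic_matches_irls_oracle(self):
        rng = np.random.default_rng(2)
        n = 200
        x = rng.normal(size=n)
        p = 1 / (1 + np.exp(-(0.5 + 0.8 * x)))
        y = (rng.uniform(size=n) < p).astype(float)

        # hand-rolled IRLS for logistic regression
        D = np.column_stack([np.ones(n), x])
        beta = np.zeros(2)
        for _ in range(50):
            eta = D @ beta
            mu = 1 / (1 + np.exp(-eta))
            Wd = mu * (1 - mu)
            z = eta + (y - mu) / Wd
            beta = np.linalg.solve(D.T @ (Wd[:, None] * D), D.T @ (Wd * z))
        cov = np.linalg.inv(D.T @ ((mu * (1 - mu))[:, None] * D))

        res = associate_individual(x, y, family="logistic")
        assert res.bhat == pytest.approx(beta[1], abs=1e-6)
        assert res.se == pytest.approx(np.sqrt(cov[1, 1]), abs=1e-6)

    def test_constant_trait_raises(self):
        with pytest.raises(ValueError):
            associate_individual(np.arange(10.0), np.ones(10))


class TestAssociateSummary:
    def test_single_snp_weight_recovers_gwas_z(self):
        g = toy_genotypes(n=200, P=12, seed=7)
        rng = np.random.default_rng(8)
        y = standardize(g)[:, 4] * 0.3 + rng.normal(size=200)
        y = (y - y.mean()) / y.std()
        gwas = run_gwas(y, g)
        w = np.zeros(12); w[4] = 1.0
        cov = build_banded_cov(g, bandwidth=12)
        res = associate_summary(gwas, _db_from(g, [w]), cov)[0]
        z_gwas = float(gwas.table.loc[gwas.table["rsid"] == "rs5", "z"].iloc[0])
        assert res.z == pytest.approx(z_gwas, rel=1e-10)

    def test_beta_matches_regression_oracle_dense_band(self):
        g = toy_genotypes(n=500, P=30, seed=9)
        Z = standardize(g)
        rng = np.random.default_rng(10)
        w = rng.normal(size=30) * 0.2
        pred = Z @ w
        y = pred + rng.normal(size=500) * 2.0
        y = (y - y.mean()) / y.std()
        gwas = run_gwas(y, g)
        cov = build_banded_cov(g, bandwidth=30)
        res = associate_summary(gwas, _db_from(g, [w]), cov)[0]
        slope = float(np.polyfit(pred, y, 1)[0])
        assert res.bhat == pytest.approx(slope, rel=0.02)

    def test_warns_on_missing_gwas_variants(self):
        g = toy_genotypes(n=100, P=20, seed=11)
        rng = np.random.default_rng(12)
        y = rng.normal(size=100)
        gwas = run_gwas(y, g.subset_variants(np.arange(10)))  # half missing
        cov = build_banded_cov(g, bandwidth=20)
        w = rng.normal(size=20)
        with pytest.warns(UserWarning, match="weight variants"):
            associate_summary(gwas, _db_from(g, [w]), cov)


@pytest.fixture(scope="module")
def phi_setup(small_cohort):
    cfg, geno, idps, *_ = small_cohort
    rng = np.random.default_rng(13)
    W = [rng.normal(size=geno.n_variants) / geno.n_variants for _ in range(2)]
    db = _db_from(geno, W)
    return geno, db


class TestEstimatePhi:

    def test_zero_h2_row_is_calibrated(self, phi_setup):
        geno, db = phi_setup
        tab = estimate_phi(db, geno, N_grid=(400,), h2_grid=(0.0, 0.5),
                           n_reps=1000, seed=1)
        null_rows = tab.mean_chi2[tab.mean_chi2["h2"] == 0.0]
        assert ((null_rows["mean_chi2"] > 0.9) & (null_rows["mean_chi2"] < 1.1)).all()

    def test_mean_chi2_increases_with_n_h2(self, phi_setup):
        geno, db = phi_setup
        tab = estimate_phi(db, geno, N_grid=(100, 250, 500), h2_grid=(0.2, 0.5, 0.9),
                           n_reps=400, seed=2)
        for fid, grp in tab.mean_chi2.groupby("feature_id"):
            x = grp["N"] * grp["h2"]
            rho = stats.spearmanr(x, grp["mean_chi2"]).statistic
            assert rho > 0

    def test_phi_nonnegative_and_finite(self, phi_setup):
        geno, db = phi_setup
        tab = estimate_phi(db, geno, N_grid=(200, 500), h2_grid=(0.3, 0.8),
                           n_reps=300, seed=3)
        for v in tab.phi.values():
            assert np.isfinite(v) and v >= 0

    def test_n_grid_exceeding_cohort_raises(self, phi_setup):
        geno, db = phi_setup
        with pytest.raises(ValueError):
            estimate_phi(db, geno, N_grid=(10_000,), h2_grid=(0.5,), n_reps=10)


class TestCorrectInflation:
    def test_phi_zero_preserves_raw_p(self):
        for z in (0.5, 1.7, -2.3):
            raw = 2 * stats.norm.sf(abs(z))
            assert correct_inflation(z, 10_000, 0.5, 0.0) == pytest.approx(raw, rel=1e-10)

    def test_chi2_divided_by_sqrt(self):
        # N*h2*phi = 3 -> statistic divided by sqrt(4) = 2
        z = 2.0
        p = correct_inflation(z, N=300, h2_trait=0.1, phi=0.1)
        assert p == pytest.approx(float(stats.chi2.sf(z**2 / 2.0, df=1)), rel=1e-12)

    def test_correction_never_decreases_p(self):
        z = 3.0
        raw = correct_inflation(z, 1000, 0.5, 0.0)
        corrected = correct_inflation(z, 1000, 0.5, 0.01)
        assert corrected >= raw

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            correct_inflation(1.0, 100, 1.5, 0.1)
        with pytest.raises(ValueError):
            correct_inflation(1.0, 100, 0.5, -0.1)


class TestAdjustMultiple:
    def test_all_ones_flag_nothing(self):
        flags, _ = adjust_multiple(np.ones(20), "bonferroni")
        assert not flags.any()
        flags, _ = adjust_multiple(np.ones(20), "bh")
        assert not flags.any()

    def test_bonferroni_cutoff_arithmetic(self):
        # one strong p among m=261 at level 0.05: 1e-5 < 0.05/261
        p = np.full(261, 0.5)
        p[7] = 1e-5
        flags, _ = adjust_multiple(p, "bonferroni", level=0.05)
        assert flags[7] and flags.sum() == 1

    def test_bh_matches_step_up_oracle(self):
        rng = np.random.default_rng(14)
        p = rng.uniform(size=10) ** 2
        flags, _ = adjust_multiple(p, "bh", level=0.1)
        # brute-force step-up
        order = np.argsort(p)
        m = len(p)
        k_max = 0
        for i, idx in enumerate(order, start=1):
            if p[idx] <= 0.1 * i / m:
                k_max = i
        expected = np.zeros(m, dtype=bool)
        expected[order[:k_max]] = True
        np.testing.assert_array_equal(flags, expected)

    def test_bonferroni_subset_of_bh(self):
        rng = np.random.default_rng(15)
        p = rng.uniform(size=50) ** 3
        fb, _ = adjust_multiple(p, "bonferroni", level=0.05)
        ff, _ = adjust_multiple(p, "bh", level=0.05)
        assert np.all(ff[fb])
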