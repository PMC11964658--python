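import numpy as np
import pandas as pd
import pytest
from scipy import stats

from featurexcan import (
    GwasSummary,
    InstrumentSet,
    build_instruments,
    ld_clump,
    mr_egger,
    mr_ivw,
    mr_weighted_median,
    run_bidirectional_mr,
    run_gwas,
    signed_acat,
    standardize,
)

from conftest import toy_genotypes


def _inst(bexp, seexp, bout, seout):
    return InstrumentSet(pd.DataFrame({
        "rsid": [f"rs{i}" for i in range(len(bexp))],
        "bhat_exp": bexp, "se_exp": seexp, "bhat_out": bout, "se_out": seout,
    }))


class TestRunGwas:
    def test_self_regression(self):
        g = toy_genotypes(n=100, P=5, seed=1)
        y = g.dosages[:, 2].copy()
        gwas = run_gwas(y, g)
        row = gwas.table[gwas.table["rsid"] == "rs3"].iloc[0]
        assert row["bhat"] == pytest.approx(1.0, abs=1e-10)
        assert row["pval"] < 1e-100

    def test_null_calibration(self):
        g = toy_genotypes(n=400, P=5000, seed=2)
        rng = np.random.default_rng(3)
        gwas = run_gwas(rng.standard_normal(400), g)
        frac = (gwas.table["pval"] < 0.05).mean()
        assert 0.04 <= frac <= 0.06

    def test_matches_ols_closed_form(self):
        g = toy_genotypes(n=100, P=8, seed=4)
        rng = np.random.default_rng(5)
        y = rng.standard_normal(100)
        gwas = run_gwas(y, g)
        for j in range(8):
            x = g.dosages[:, j]
            expected = np.cov(x, y, ddof=0)[0, 1] / np.var(x)
            assert gwas.table["bhat"].iloc[j] == pytest.approx(expected, abs=1e-10)


class TestLdClump:
    def _gwas_from(self, geno, pvals):
        vf = geno.variant_frame().reset_index(drop=True)
        z = stats.norm.isf(np.asarray(pvals) / 2)
        return GwasSummary(pd.DataFrame({
            "rsid": vf["rsid"], "chrom": vf["chrom"], "pos": vf["pos"],
            "effect_allele": vf["a1"], "other_allele": vf["a0"],
            "bhat": z * 0.01, "se": np.full(len(vf), 0.01), "pval": pvals,
        }))

    def test_single_significant_snp(self):
        g = toy_genotypes(n=100, P=10, seed=6)
        p = np.ones(10) * 0.5
        p[4] = 1e-9
        assert ld_clump(self._gwas_from(g, p), g, p_thresh=5e-8) == ["rs5"]

    def test_correlated_pair_keeps_smaller_p(self):
        rng = np.random.default_rng(7)
        g = toy_genotypes(n=200, P=4, seed=8)
        d = g.dosages.copy()
        d[:, 1] = d[:, 0]  # r^2 = 1 pair
        flip = rng.random(200) < 0.02
        d[flip, 1] = 2 - d[flip, 1]  # nearly perfect LD
        g.dosages = d
        p = np.array([1e-6, 1e-9, 0.5, 0.5])
        out = ld_clump(self._gwas_from(g, p), g, p_thresh=1e-5, r2_thresh=0.001)
        assert out == ["rs2"]

    def test_none_significant_returns_empty(self):
        g = toy_genotypes(n=50, P=5, seed=9)
        assert ld_clump(self._gwas_from(g, np.full(5, 0.9)), g, p_thresh=5e-8) == []

    def test_matches_exhaustive_greedy_oracle(self):
        rng = np.random.default_rng(10)
        g = toy_genotypes(n=150, P=20, seed=11)
        Z = standardize(g)
        R2 = (Z.T @ Z / 150) ** 2
        for rep in range(20):
            p = rng.uniform(1e-12, 1e-4, size=20)
            got = ld_clump(self._gwas_from(g, p), g, p_thresh=1e-3, r2_thresh=0.05)
            # independent greedy enumeration on the dense r^2 matrix
            order = np.argsort(p)
            accepted = []
            for j in order:
                if all(R2[j, a] <= 0.05 for a in accepted):
                    accepted.append(j)
            assert got == [f"rs{j+1}" for j in accepted]


class TestIvw:
    def test_single_instrument_is_wald_ratio(self):
        res = mr_ivw(_inst([0.2], [0.01], [0.05], [0.02]))
        assert res.estimate == pytest.approx(0.25)

    def test_exact_proportionality(self):
        b = np.array([0.1, 0.2, -0.15])
        res = mr_ivw(_inst(b, [0.01] * 3, 0.4 * b, [0.02, 0.03, 0.02]))
        assert res.estimate == pytest.approx(0.4, abs=1e-12)

    def test_matches_wls_closed_form(self):
        a = np.array([0.1, 0.2, 0.3])
        b = np.array([0.05, 0.01, 0.12])
        se = np.array([0.02, 0.05, 0.01])
        w = 1 / se**2
        expected = np.sum(w * a * b) / np.sum(w * a**2)
        res = mr_ivw(_inst(a, [0.01] * 3, b, se))
        assert res.estimate == pytest.approx(expected, abs=1e-12)

    def test_zero_instruments_raise(self):
        with pytest.raises(ValueError):
            mr_ivw(_inst([], [], [], []))


class TestWeightedMedian:
    def test_equal_weight_interpolation(self):
        res = mr_weighted_median(
            _inst([1.0, 1.0, 1.0], [1e-6] * 3, [1.0, 2.0, 10.0], [1.0] * 3),
            n_boot=50, seed=0)
        assert res.estimate == pytest.approx(2.0)

    def test_identical_ratios_with_tiny_errors(self):
        res = mr_weighted_median(
            _inst([0.1, 0.2, 0.3], [1e-8] * 3, [0.05, 0.10, 0.15], [1e-8] * 3),
            n_boot=100, seed=1)
        assert res.estimate == pytest.approx(0.5, abs=1e-4)
        assert res.se < 1e-4

    def test_seeded_determinism(self):
        rng = np.random.default_rng(12)
        a = rng.uniform(0.1, 0.3, 10)
        b = 0.3 * a + rng.normal(0, 0.01, 10)
        i = _inst(a, np.full(10, 0.01), b, np.full(10, 0.01))
        r1 = mr_weighted_median(i, seed=7)
        r2 = mr_weighted_median(i, seed=7)
        assert (r1.estimate, r1.se, r1.p) == (r2.estimate, r2.se, r2.p)

    def test_minimum_instruments(self):
        with pytest.raises(ValueError):
            mr_weighted_median(_inst([0.1, 0.2], [0.01] * 2, [0.1, 0.2], [0.01] * 2))


class TestEgger:
    def test_matches_weighted_normal_equations(self):
        a = np.array([0.1, 0.25, 0.3, 0.15])
        b = np.array([0.06, 0.11, 0.14, 0.08])
        se = np.array([0.02, 0.01, 0.03, 0.02])
        res = mr_egger(_inst(a, [0.01] * 4, b, se))
        w = 1 / se**2
        D = np.column_stack([np.ones(4), a])
        coef = np.linalg.solve(D.T @ (w[:, None] * D), D.T @ (w * b))
        assert res.egger_intercept == pytest.approx(coef[0], abs=1e-12)
        assert res.estimate == pytest.approx(coef[1], abs=1e-12)

    def test_sign_orientation_invariance(self):
        rng = np.random.default_rng(13)
        a = rng.uniform(0.1, 0.4, 6) * rng.choice([-1, 1], 6)
        b = 0.5 * a + rng.normal(0, 0.02, 6)
        i1 = _inst(a, np.full(6, 0.01), b, np.full(6, 0.02))
        i2 = _inst(-a, np.full(6, 0.01), -b, np.full(6, 0.02))
        r1, r2 = mr_egger(i1), mr_egger(i2)
        assert r1.estimate == pytest.approx(r2.estimate, abs=1e-12)
        assert r1.egger_intercept == pytest.approx(r2.egger_intercept, abs=1e-12)

    def test_balanced_pleiotropy_intercept_calibrated(self):
        rng = np.random.default_rng(14)
        intercepts, pvals = [], []
        for _ in range(200):
            k = 25
            a = rng.uniform(0.1, 0.5, k)
            pleio = rng.normal(0, 0.02, k)  # balanced: mean zero
            b = 0.3 * a + pleio + rng.normal(0, 0.02, k)
            res = mr_egger(_inst(a, np.full(k, 0.01), b, np.full(k, 0.02)))
            intercepts.append(res.egger_intercept)
            pvals.append(res.intercept_p)
        assert abs(np.mean(intercepts)) < 0.01
        assert (np.array(pvals) < 0.05).mean() < 0.12

    def test_directional_pleiotropy_detected(self):
        rng = np.random.default_rng(15)
        hits, closer = 0, 0
        for _ in range(60):
            k = 30
            a = rng.uniform(0.1, 0.5, k)
            b = 0.3 * a + 0.05 + rng.normal(0, 0.02, k)  # directional pleiotropy
            inst = _inst(a, np.full(k, 0.01), b, np.full(k, 0.02))
            eg, ivw = mr_egger(inst), mr_ivw(inst)
            hits += eg.intercept_p < 0.05
            closer += abs(eg.estimate - 0.3) < abs(ivw.estimate - 0.3)
        assert hits > 30
        assert closer > 30

    def test_minimum_instruments(self):
        with pytest.raises(ValueError):
            mr_egger(_inst([0.1, 0.2], [0.01] * 2, [0.1, 0.2], [0.01] * 2))


class TestSignedAcat:
    def test_identical_inputs_return_same_p(self):
        for p0 in (0.01, 0.2, 0.8):
            assert signed_acat(np.array([p0, p0, p0]), np.array([1, 1, 1])) == \
                pytest.approx(p0, rel=1e-10)

    def test_discordant_pair_cancels(self):
        assert signed_acat(np.array([0.03, 0.03]), np.array([1, -1])) == pytest.approx(1.0)

    def test_reduces_to_plain_acat_when_signs_agree(self):
        rng = np.random.default_rng(16)
        p = rng.uniform(0.001, 0.9, 5)
        w = np.full(5, 0.2)
        combined = signed_acat(p, np.ones(5), w)
        # plain ACAT on one-sided p, folded two-sided
        T = np.sum(w * np.tan((0.5 - p / 2) * np.pi))
        q = 0.5 - np.arctan(T) / np.pi
        assert combined == pytest.approx(2 * min(q, 1 - q), rel=1e-12)

    def test_null_uniformity(self):
        rng = np.random.default_rng(17)
        combined = []
        for _ in range(3000):
            p = rng.uniform(size=3)
            s = rng.choice([-1.0, 1.0], 3)
            combined.append(signed_acat(p, s))
        assert stats.kstest(combined, "uniform").pvalue > 0.01

    def test_input_validation(self):
        with pytest.raises(ValueError):
            signed_acat(np.array([0.1]), np.array([0.5]))
        with pytest.raises(ValueError):
            signed_acat(np.array([0.1, 0.2]), np.array([1, 1]), np.array([0.9, 0.9]))


class TestBidirectional:
    def test_estimate_sign_flips_with_exposure(self):
        rng = np.random.default_rng(18)
        a = rng.uniform(0.1, 0.4, 8)
        b = 0.3 * a + rng.normal(0, 0.01, 8)
        i1 = _inst(a, np.full(8, 0.01), b, np.full(8, 0.02))
        i2 = _inst(-a, np.full(8, 0.01), b, np.full(8, 0.02))
        for f in (mr_ivw, mr_weighted_median, mr_egger):
            r1, r2 = f(i1), f(i2)
            assert r1.estimate == pytest.approx(-r2.estimate, rel=1e-6)
            assert r1.p == pytest.approx(r2.p, rel=1e-6)

    def test_underpowered_direction_flagged_not_errored(self, small_cohort):
        cfg, geno, idps, L, R = small_cohort
        rng = np.random.default_rng(19)
        # exposure with one strong variant; outcome pure noise (no instruments)
        y_exp = standardize(geno)[:, 10] * 1.2 + rng.normal(size=geno.n_samples) * 0.3
        y_out = rng.standard_normal(geno.n_samples)
        fwd, rev = run_bidirectional_mr(run_gwas(y_exp, geno), run_gwas(y_out, geno),
                                        geno, seed=0)
        assert rev.underpowered
        assert fwd.results  # at least IVW ran forward

    def test_instrument_pairwise_r2_respects_threshold(self, small_cohort):
        cfg, geno, idps, *_ = small_cohort
        rng = np.random.default_rng(20)
        Z = standardize(geno)
        y = Z @ rng.standard_normal(geno.n_variants) * 0.05 + rng.normal(size=geno.n_samples)
        gwas = run_gwas((y - y.mean()) / y.std(), geno)
        rsids = ld_clump(gwas, geno, p_thresh=0.01, r2_thresh=0.05)
        idx = [geno.rsids.index(r) for r in rsids]
        n = Z.shape[0]
        for i, ji in enumerate(idx):
            for jk in idx[:i]:
                r2 = (float(Z[:, ji] @ Z[:, jk]) / n) ** 2
                assert r2 <= 0.05 + 1e-12
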