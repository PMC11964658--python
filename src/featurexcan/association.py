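"""Association of genetically predicted features with complex traits.

Two routes give the same feature-level Z-score:

* individual level — predict each feature from genotypes with the trained
  weights, then regress the observed trait on the prediction (linear or
  logistic GLM);
* summary level — reconstruct the same statistic from per-SNP GWAS
  Z-scores, the weight vectors, and a reference-panel banded LD matrix:

      z_k = (1 / sigma_k) * sum_j w_kj * sqrt(R_jj) * z_gwas_j,
      sigma_k^2 = w_k' R w_k,

  where R is the (banded) SNP covariance. With standardized-dosage
  conventions R_jj = 1 and sigma_k^2 is the reference-panel variance of
  the predicted feature.

Because both the trait and the predicted features are polygenic, the null
distribution of z_k is inflated: E[Z^2] ~ 1 + N h2 Phi with a
feature-specific factor Phi estimated once by simulating polygenic null
phenotypes on a reference cohort. The variance-control correction divides
the chi-square statistic by sqrt(1 + N h2 Phi) before taking the tail
probability.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import GenotypeSet, GwasSummary, standardize
from .ld import BandedCov, quad_form
from .weightsdb import WeightsDB

logger = logging.getLogger(__name__)


@dataclass
class AssociationResult:
    """Feature-level association statistic (either route)."""

    feature_id: str
    bhat: float
    se: float
    z: float
    p_raw: float
    method: str  # "individual" | "summary"
    n: int
    p_corrected: float = np.nan


@dataclass
class PhiTable:
    """Per-feature inflation factors with fit diagnostics.

    ``phi`` maps feature_id -> Phi >= 0. ``mean_chi2`` is the simulation
    table indexed by (feature_id, N, h2) used for the fit; ``n_reps`` the
    simulation count per cell.
    """

    phi: dict[str, float]
    mean_chi2: pd.DataFrame
    n_reps: int
    intercept: float


def predict_features(genotypes: GenotypeSet, weights: WeightsDB) -> pd.DataFrame:
    """Predicted feature matrix X_std @ W (n samples x K features).

    Genotype variants must already be harmonized to the weight alleles.
    When more than 10% of a feature's absolute weight mass is missing from
    the genotypes, a warning is emitted and the prediction is renormalized
    by the available weight fraction.
    """
    geno_index = {v.rsid: j for j, v in enumerate(genotypes.variants)}
    rows = [geno_index.get(v.rsid) for v in weights.variants]
    present = np.array([r is not None for r in rows])
    cols = np.array([r for r in rows if r is not None], dtype=int)
    X = standardize(genotypes.subset_variants(cols)) if cols.size else np.zeros((genotypes.n_samples, 0))

    out = {}
    for fid in weights.feature_ids:
        w = weights.weights[fid]
        total_mass = np.abs(w).sum()
        avail_mass = np.abs(w[present]).sum()
        pred = X @ w[present] if cols.size else np.zeros(genotypes.n_samples)
        if total_mass > 0 and avail_mass < 0.9 * total_mass:
            frac = avail_mass / total_mass
            warnings.warn(
                f"{fid}: only {frac:.1%} of weight mass present; renormalizing"
            )
            if avail_mass > 0:
                pred = pred / frac
        out[fid] = pred
    return pd.DataFrame(out, index=list(genotypes.samples))


def associate_individual(
    pred_k: np.ndarray, trait: np.ndarray, family: str = "linear",
    feature_id: str = "feature",
) -> AssociationResult:
    """Regress the trait on one predicted feature (with intercept).

    ``family`` selects an ordinary linear model or a logistic GLM for a
    binary 0/1 trait. Returns the slope, its standard error, z, and the
    two-sided p-value.
    """
    import statsmodels.api as sm

    y = np.asarray(trait, dtype=float)
    x = np.asarray(pred_k, dtype=float)
    if np.std(y) == 0:
        raise ValueError("trait is constant")
    design = sm.add_constant(x)
    if family == "linear":
        fit = sm.OLS(y, design).fit()
    elif family == "logistic":
        fit = sm.GLM(y, design, family=sm.families.Binomial()).fit()
    else:
        raise ValueError(f"unknown family {family!r}")
    bhat = float(fit.params[1])
    se = float(fit.bse[1])
    z = bhat / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return AssociationResult(
        feature_id=feature_id, bhat=bhat, se=se, z=z,
        p_raw=max(p, np.nextafter(0.0, 1.0)), method="individual", n=len(y),
    )


def associate_summary(
    gwas: GwasSummary, weights: WeightsDB, cov: BandedCov,
) -> list[AssociationResult]:
    """Summary-level feature association from GWAS Z-scores and banded LD.

    The GWAS must be harmonized to the weight alleles. Weight variants
    absent from the GWAS contribute nothing (their terms are dropped, with
    a warning when fewer than 90% are found). The covariance is on
    standardized dosages, so sqrt(R_jj) = 1.

    Raises
    ------
    ValueError
        If a feature's predicted variance w' R w is non-positive.
    """
    rsid_to_row = {r: i for i, r in enumerate(gwas.table["rsid"])}
    z_gwas = gwas.table["z"].to_numpy()
    n_gwas = int(np.nanmax(gwas.table["n_gwas"])) if "n_gwas" in gwas.table else 0

    P = len(weights.variants)
    rows = np.array([rsid_to_row.get(v.rsid, -1) for v in weights.variants])
    present = rows >= 0
    frac_found = present.mean() if P else 0.0
    if frac_found < 0.9:
        warnings.warn(f"only {frac_found:.1%} of weight variants found in the GWAS")

    diag = np.concatenate([cb.diags[0] for cb in cov.chroms.values()])
    results = []
    for fid in weights.feature_ids:
        w = weights.weights[fid].copy()
        w[~present] = 0.0
        sigma2 = quad_form(w, cov)
        if sigma2 <= 0:
            raise ValueError(f"{fid}: predicted-feature variance {sigma2:.3g} <= 0")
        sigma = np.sqrt(sigma2)
        zvec = np.zeros(P)
        zvec[present] = z_gwas[rows[present]]
        z_k = float((w * np.sqrt(diag) * zvec).sum() / sigma)
        # effect size on the standardized scale: with per-allele GWAS betas
        # b_j, R_jj b_j equals the standardized-scale effect z_j / sqrt(N)
        # (trait in sd units), so beta_k = z_k / (sigma_k sqrt(N))
        if n_gwas > 0:
            se_k = 1.0 / (sigma * np.sqrt(n_gwas))
            bhat_k = z_k * se_k
        else:
            se_k = np.nan
            bhat_k = np.nan
        p = float(2.0 * stats.norm.sf(abs(z_k)))
        results.append(
            AssociationResult(
                feature_id=fid, bhat=bhat_k, se=se_k, z=z_k,
                p_raw=max(p, np.nextafter(0.0, 1.0)), method="summary", n=n_gwas,
            )
        )
    return results


def estimate_phi(
    weights: WeightsDB,
    genotypes: GenotypeSet,
    N_grid: tuple[int, ...] = (1000, 2000, 4000),
    h2_grid: tuple[float, ...] = (0.1, 0.3, 0.5, 0.8),
    n_reps: int = 1000,
    seed: int = 0,
) -> PhiTable:
    """Estimate per-feature inflation factors Phi by simulation.

    For each (N, h2) grid cell: draw polygenic null phenotypes
    Y = X delta + eps with dense normal effects delta (genetic variance
    rescaled to h2), on N individuals subsampled from the reference
    cohort; regress Y on each predicted feature and average the squared
    Z-score over ``n_reps`` replicates. Phi_k is then the per-feature
    slope of mean chi-square on N*h2 with a pooled intercept, shrunk
    toward the common slope (method-of-moments empirical Bayes), and
    floored at zero.

    The reference cohort must be disjoint from any GWAS cohort whose
    statistics will be corrected (a documented contract, not checked).
    """
    rng = np.random.default_rng(seed)
    X = standardize(genotypes)
    n_total = X.shape[0]
    if max(N_grid) > n_total:
        raise ValueError(f"N_grid max {max(N_grid)} exceeds cohort size {n_total}")

    pred = predict_features(genotypes, weights).to_numpy()
    fids = weights.feature_ids
    K = pred.shape[1]

    # genetic component: X @ delta for delta ~ N(0, I) has covariance X X';
    # drawn in chunks to bound the P x n_reps effect-size buffer
    G = np.empty((n_total, n_reps))
    chunk = max(1, min(n_reps, int(2e7 // X.shape[1])))
    for s in range(0, n_reps, chunk):
        e = min(s + chunk, n_reps)
        G[:, s:e] = X @ rng.standard_normal((X.shape[1], e - s))

    records = []
    for N in N_grid:
        idx = np.arange(N)  # cohort rows are already in random order
        g = G[idx]
        g = g / g.std(axis=0, keepdims=True)  # unit genetic variance per replicate
        pz = pred[idx]
        pz = (pz - pz.mean(axis=0)) / pz.std(axis=0)
        for h2 in h2_grid:
            noise = rng.standard_normal((N, n_reps))
            Y = g * np.sqrt(h2) + noise * np.sqrt(1.0 - h2)
            Y = (Y - Y.mean(axis=0)) / Y.std(axis=0)
            # slope z^2 from correlation: z^2 = (N-2) r^2 / (1 - r^2)
            r = (pz.T @ Y) / N  # K x n_reps
            chi2 = (N - 2) * r**2 / (1.0 - r**2)
            mean_chi2 = chi2.mean(axis=1)
            if not np.all(np.isfinite(mean_chi2)):
                raise ValueError("non-finite mean chi-square in Phi simulation")
            for k in range(K):
                records.append((fids[k], N, h2, float(mean_chi2[k])))
    table = pd.DataFrame(records, columns=["feature_id", "N", "h2", "mean_chi2"])
    table["x"] = table["N"] * table["h2"]

    # joint fit: common intercept, per-feature slope
    x = table["x"].to_numpy()
    y = table["mean_chi2"].to_numpy()
    if not np.any(x):  # degenerate grid (all N*h2 = 0): no inflation signal
        return PhiTable(phi={fid: 0.0 for fid in fids},
                        mean_chi2=table[["feature_id", "N", "h2", "mean_chi2"]],
                        n_reps=n_reps, intercept=float(y.mean()))
    design = np.zeros((len(table), 1 + K))
    design[:, 0] = 1.0
    for k, fid in enumerate(fids):
        mask = (table["feature_id"] == fid).to_numpy()
        design[mask, 1 + k] = x[mask]
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    intercept = float(coef[0])
    slopes = coef[1:]

    # per-feature slope sampling variance, for empirical-Bayes shrinkage
    resid = y - design @ coef
    dof = max(len(table) - (1 + K), 1)
    s2 = float(resid @ resid) / dof
    slope_var = np.array([
        s2 / float(np.sum(x[(table["feature_id"] == fid).to_numpy()] ** 2))
        for fid in fids
    ])
    mean_slope = slopes.mean()
    tau2 = max(float(np.var(slopes)) - float(slope_var.mean()), 0.0)
    shrink = tau2 / (tau2 + slope_var) if tau2 > 0 else np.zeros(K)
    phi = mean_slope + shrink * (slopes - mean_slope)
    phi = np.clip(phi, 0.0, None)
    return PhiTable(
        phi={fid: float(p) for fid, p in zip(fids, phi)},
        mean_chi2=table[["feature_id", "N", "h2", "mean_chi2"]],
        n_reps=n_reps,
        intercept=intercept,
    )


def correct_inflation(z: float, N: int, h2_trait: float, phi: float) -> float:
    """Variance-control corrected p-value.

    Divides the chi-square statistic z^2 by sqrt(1 + N * h2 * Phi) and
    returns the upper-tail chi-square(1) probability. Phi = 0 (or h2 = 0)
    reproduces the raw p-value.
    """
    if phi < 0:
        raise ValueError("phi must be >= 0")
    if not (0.0 <= h2_trait <= 1.0):
        raise ValueError("h2_trait must be in [0, 1]")
    if N <= 0:
        raise ValueError("N must be positive")
    stat = z**2 / np.sqrt(1.0 + N * h2_trait * phi)
    return float(max(stats.chi2.sf(stat, df=1), np.nextafter(0.0, 1.0)))


def adjust_multiple(
    pvals: np.ndarray, method: str = "bonferroni", level: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Multiple-testing flags and adjusted p-values.

    ``bonferroni`` flags p < level/m; ``bh`` applies the Benjamini-Hochberg
    step-up at the given level. Returns (flags, adjusted p-values).
    """
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvals, dtype=float)
    if method == "bonferroni":
        flags = p < level / len(p)
        adj = np.minimum(p * len(p), 1.0)
        return flags, adj
    if method == "bh":
        flags, adj, *_ = multipletests(p, alpha=level, method="fdr_bh")
        return flags, adj
    raise ValueError(f"unknown method {method!r}")
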