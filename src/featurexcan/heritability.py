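"""SNP heritability by REML on a genetic relatedness matrix.

The variance-component model is y = mu + g + e with g ~ N(0, sigma_g^2 K)
and e ~ N(0, sigma_e^2 I), where K = X X' / P is the GRM on standardized
genotypes. Following the EMMA strategy, K is eigendecomposed once and the
restricted likelihood is optimized over the single ratio
delta = sigma_e^2 / sigma_g^2 in the rotated basis, so fitting many
phenotypes against the same cohort costs one decomposition plus a cheap
1-D search per phenotype.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .datamodel import GenotypeSet, standardize

logger = logging.getLogger(__name__)

_EIG_CLIP = 1e-10


@dataclass
class GRM:
    """Genetic relatedness matrix K = X_std X_std' / P with sample ids."""

    matrix: np.ndarray
    samples: list[str] = field(default_factory=list)
    _eig: tuple[np.ndarray, np.ndarray] | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("GRM must be square")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("GRM must be symmetric")
        if not self.samples:
            self.samples = [f"sample_{i}" for i in range(self.matrix.shape[0])]

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def eig(self) -> tuple[np.ndarray, np.ndarray]:
        """Cached eigendecomposition with PSD repair (eigenvalues clipped
        at 1e-10; clipping is logged)."""
        if self._eig is None:
            vals, vecs = np.linalg.eigh(self.matrix)
            n_neg = int(np.sum(vals < _EIG_CLIP))
            if n_neg:
                logger.info("GRM: clipped %d eigenvalues below %g", n_neg, _EIG_CLIP)
            vals = np.clip(vals, _EIG_CLIP, None)
            self._eig = (vals, vecs)
        return self._eig


@dataclass
class HeritabilityEstimate:
    """REML variance components for one phenotype.

    ``h2 = sigma_g2 / (sigma_g2 + sigma_e2)``; ``se_h2`` is the
    curvature-based approximation from the numerical second derivative of
    the restricted log-likelihood in h2. ``at_boundary`` flags optima at
    h2 = 0 or 1, where the quadratic approximation behind ``se_h2`` is
    unreliable.
    """

    h2: float
    sigma_g2: float
    sigma_e2: float
    loglik: float
    se_h2: float
    at_boundary: bool = False


def compute_grm(genotypes: GenotypeSet) -> GRM:
    """GRM = (standardized X)(standardized X)' / P.

    With population-sd standardization the expected diagonal is 1.
    """
    if genotypes.n_samples < 2:
        raise ValueError("GRM requires at least 2 samples")
    if genotypes.n_variants < 1:
        raise ValueError("GRM requires at least 1 variant")
    X = standardize(genotypes)
    K = (X @ X.T) / X.shape[1]
    K = (K + K.T) / 2.0
    return GRM(matrix=K, samples=list(genotypes.samples))


def _restricted_loglik(delta: float, lam: np.ndarray, eta2: np.ndarray) -> float:
    """Restricted log-likelihood profile in delta = sigma_e^2/sigma_g^2.

    ``lam`` are the nonzero eigenvalues of the projected GRM (intercept
    removed) and ``eta2`` the squared rotated phenotype contrasts; both have
    length n - 1. Constants independent of delta are dropped.
    """
    w = lam + delta
    m = lam.shape[0]
    return -0.5 * (m * np.log(np.sum(eta2 / w)) + np.sum(np.log(w)))


class HeritabilityEstimator:
    """REML heritability for many phenotypes sharing one GRM.

    The projected-GRM eigendecomposition is computed on first use and
    cached, so repeated calls with different phenotypes only pay the 1-D
    likelihood search. The cache is purely an optimization: results are
    identical to a fresh estimator.
    """

    #: log10 range and resolution of the initial delta grid
    GRID = np.logspace(-5, 5, 100)

    def __init__(self, grm: GRM):
        self.grm = grm
        self._proj: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def _eigenbasis(self) -> tuple[np.ndarray, np.ndarray]:
        key = 0
        if key not in self._proj:
            n = self.grm.n
            ones = np.ones(n) / np.sqrt(n)
            K = self.grm.matrix
            Kc = K - np.outer(ones, ones @ K)
            Kc = Kc - np.outer(Kc @ ones, ones)
            vals, vecs = np.linalg.eigh((Kc + Kc.T) / 2.0)
            order = np.argsort(np.abs(vecs.T @ np.ones(n)))
            keep = np.sort(order[: n - 1])
            lam = np.clip(vals[keep], _EIG_CLIP, None)
            self._proj[key] = (lam, vecs[:, keep])
        return self._proj[key]

    def estimate(self, y: np.ndarray) -> HeritabilityEstimate:
        """REML estimate of h2 for one phenotype (intercept-only model)."""
        y = np.asarray(y, dtype=float)
        if not np.all(np.isfinite(y)):
            raise ValueError("phenotype contains non-finite values")
        if y.shape[0] != self.grm.n:
            raise ValueError("phenotype length does not match GRM")
        lam, vecs = self._eigenbasis()
        eta2 = (vecs.T @ (y - y.mean())) ** 2

        ll = np.array([_restricted_loglik(d, lam, eta2) for d in self.GRID])
        if not np.all(np.isfinite(ll)):
            raise ValueError("non-finite restricted likelihood on the delta grid")
        i = int(np.argmax(ll))
        lo = self.GRID[max(i - 1, 0)]
        hi = self.GRID[min(i + 1, len(self.GRID) - 1)]
        at_boundary = False
        if i == 0 or i == len(self.GRID) - 1:
            at_boundary = True
            delta = float(self.GRID[i])
        else:
            res = optimize.minimize_scalar(
                lambda t: -_restricted_loglik(np.exp(t), lam, eta2),
                bounds=(np.log(lo), np.log(hi)),
                method="bounded",
                options={"xatol": 1e-10},
            )
            delta = float(np.exp(res.x))

        m = lam.shape[0]
        sigma_g2 = float(np.sum(eta2 / (lam + delta)) / m)
        sigma_e2 = float(delta * sigma_g2)
        best_ll = float(_restricted_loglik(delta, lam, eta2))
        if at_boundary:
            # snap to the boundary, preserving the total-variance estimate
            sigma_p = sigma_g2 + sigma_e2
            if delta <= self.GRID[0]:
                sigma_g2, sigma_e2 = sigma_p, 0.0
            else:
                sigma_g2, sigma_e2 = 0.0, sigma_p
        h2 = sigma_g2 / (sigma_g2 + sigma_e2)

        se_h2 = self._se_from_curvature(h2, lam, eta2)
        return HeritabilityEstimate(
            h2=float(h2),
            sigma_g2=sigma_g2,
            sigma_e2=sigma_e2,
            loglik=best_ll,
            se_h2=se_h2,
            at_boundary=at_boundary,
        )

    @staticmethod
    def _se_from_curvature(h2: float, lam: np.ndarray, eta2: np.ndarray) -> float:
        """Approximate se(h2) from the numerical curvature of the restricted
        log-likelihood reparameterized in h2 (delta = (1-h2)/h2)."""
        eps = 1e-4
        h = min(max(h2, 2 * eps), 1 - 2 * eps)

        def ll_h2(hv: float) -> float:
            return _restricted_loglik((1.0 - hv) / hv, lam, eta2)

        d2 = (ll_h2(h + eps) - 2 * ll_h2(h) + ll_h2(h - eps)) / eps**2
        if d2 >= 0:
            return float("nan")
        return float(1.0 / np.sqrt(-d2))


def estimate_heritability(y: np.ndarray, grm: GRM) -> HeritabilityEstimate:
    """One-shot REML heritability (see :class:`HeritabilityEstimator`).

    For many phenotypes against the same cohort, construct the estimator
    once and call :meth:`HeritabilityEstimator.estimate` repeatedly to
    reuse the eigendecomposition.
    """
    return HeritabilityEstimator(grm).estimate(y)
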