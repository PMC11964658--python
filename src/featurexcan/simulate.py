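"""Synthetic cohorts: LD-structured genotypes, generative-model brain
features, polygenic traits, and polygenic null phenotypes.

The genotype model is a fast emulation, not population genetics: each
haplotype is a latent Gaussian AR(1) process along the chromosome,
thresholded at each variant's allele frequency, and the two haplotypes are
summed to a dosage. Adjacent-variant LD is controlled by the AR(1)
parameter ``ld_rho``; separate chromosomes are independent, matching the
zero between-chromosome covariance assumed downstream.

Brain features follow the latent-component generative model: a brain-wide
component L (variance fixed at 1) shared by all regions of a subtype, a
region-specific component R_k with variance s2, and measurement noise with
variance t2, so IDP_k = L + R_k + eps_k. Both L and R_k carry a dense
polygenic genetic basis (normal weights over all variants) with
heritabilities h2_L and h2_R; setting h2_R = 0 recovers the purely
environmental region components of the literal generative model. The
complex trait is Y = alpha*L + sum_k beta_k*R_k + eps_Y, rescaled to unit
total variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .datamodel import GenotypeSet, Variant

#: Non-ambiguous allele pair used for all simulated variants.
_A0, _A1 = "A", "G"


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the generative-model study conditions used throughout:
    30 features per subtype with region variance s2 = 0.25 and measurement
    noise t2 = 0.25, a brain-wide latent of unit variance, and moderately
    polygenic heritable components.
    """

    n: int = 2000
    P: int = 2000
    K: int = 30
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_rho: float = 0.7
    s2: float = 0.25
    t2: float = 0.25
    alpha: float = 0.3
    betas: np.ndarray | None = None
    h2_L: float = 0.5
    h2_R: float = 0.5
    h2_null: float = 0.5
    seed: int = 0
    n_chrom: int = 2

    def __post_init__(self) -> None:
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError(f"ld_rho must be in [0, 1), got {self.ld_rho}")
        for name in ("s2", "t2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("h2_L", "h2_R", "h2_null"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.betas is None:
            self.betas = np.zeros(self.K)
        self.betas = np.asarray(self.betas, dtype=float)
        if self.betas.shape != (self.K,):
            raise ValueError("betas must have length K")


def simulate_genotypes(cfg: SimConfig) -> GenotypeSet:
    """Draw an LD-structured biallelic dosage matrix.

    Per chromosome and per haplotype, a latent AR(1) Gaussian z_j with
    lag-one correlation ``ld_rho`` is thresholded: the haplotype carries the
    effect allele at variant j iff z_j < Phi^-1(f_j), where f_j is the
    variant's allele frequency (drawn uniform in ``maf_range``). Dosage is
    the sum of two independent haplotypes. Deterministic under ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    n, P = cfg.n, cfg.P
    freqs = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=P)
    thresholds = stats.norm.ppf(freqs)

    # split variants across chromosomes as evenly as possible
    sizes = np.full(cfg.n_chrom, P // cfg.n_chrom)
    sizes[: P % cfg.n_chrom] += 1

    dosage = np.empty((n, P), dtype=float)
    start = 0
    rho = cfg.ld_rho
    innov_sd = np.sqrt(1.0 - rho**2)
    for size in sizes:
        for _hap in range(2):
            z = np.empty((n, size))
            z[:, 0] = rng.standard_normal(n)
            if size > 1:
                eps = rng.standard_normal((n, size - 1)) * innov_sd
                for j in range(1, size):
                    z[:, j] = rho * z[:, j - 1] + eps[:, j - 1]
            alleles = (z < thresholds[start : start + size]).astype(float)
            if _hap == 0:
                dosage[:, start : start + size] = alleles
            else:
                dosage[:, start : start + size] += alleles
        start += size

    variants = []
    start = 0
    for c, size in enumerate(sizes, start=1):
        for j in range(size):
            f = freqs[start + j]
            variants.append(
                Variant(
                    chrom=str(c),
                    pos=(j + 1) * 1000,
                    rsid=f"rs{start + j + 1}",
                    a0=_A0,
                    a1=_A1,
                    maf=float(min(f, 1.0 - f)),
                )
            )
        start += size
    samples = [f"id_{i:06d}" for i in range(n)]
    return GenotypeSet(dosages=dosage, variants=variants, samples=samples)


def _polygenic_component(
    X_std: np.ndarray, h2: float, total_var: float, rng: np.random.Generator
) -> np.ndarray:
    """A latent component with genetic fraction h2 and variance total_var.

    The genetic part is a dense polygenic score (normal weights over all
    variants) rescaled to empirical variance h2*total_var; the rest is
    Gaussian noise. h2 = 0 returns pure noise, h2 = 1 a pure genetic score.
    """
    n, P = X_std.shape
    out = np.zeros(n)
    if h2 > 0:
        g = X_std @ rng.standard_normal(P)
        sd = g.std()
        if sd > 0:
            out += g * np.sqrt(h2 * total_var) / sd
    if h2 < 1:
        out += rng.standard_normal(n) * np.sqrt((1.0 - h2) * total_var)
    return out


def simulate_idps(
    genotypes: GenotypeSet, cfg: SimConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Generate K observed features plus their latent components.

    Returns ``(idps, L, R)`` where ``idps`` is n x K with
    IDP_k = L + R_k + eps_k, ``L`` is the brain-wide latent (variance 1,
    genetic fraction h2_L), and ``R`` is n x K of region-specific latents
    (variance s2 each, genetic fraction h2_R, independent across regions
    and of L). Measurement noise eps_k has variance t2.
    """
    from .datamodel import standardize

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    X_std = standardize(genotypes)
    n = X_std.shape[0]
    L = _polygenic_component(X_std, cfg.h2_L, 1.0, rng)
    R = np.empty((n, cfg.K))
    for k in range(cfg.K):
        if cfg.s2 == 0:
            R[:, k] = 0.0
        else:
            R[:, k] = _polygenic_component(X_std, cfg.h2_R, cfg.s2, rng)
    noise = rng.standard_normal((n, cfg.K)) * np.sqrt(cfg.t2)
    idps = L[:, None] + R + noise
    return idps, L, R


def simulate_trait(
    latents: tuple[np.ndarray, np.ndarray], cfg: SimConfig
) -> np.ndarray:
    """Complex trait Y = alpha*L + sum_k beta_k*R_k + eps_Y, var(Y) = 1.

    The systematic variance is alpha^2 + s2*sum(beta_k^2); the residual is
    filled with Gaussian noise so total variance is 1.

    Raises
    ------
    ValueError
        If the requested effect variances exceed 1.
    """
    L, R = latents
    sys_var = cfg.alpha**2 + cfg.s2 * float(np.sum(cfg.betas**2))
    if sys_var > 1.0:
        raise ValueError(f"effect variances sum to {sys_var:.3f} > 1")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    y = cfg.alpha * L + R @ cfg.betas
    y = y + rng.standard_normal(L.shape[0]) * np.sqrt(1.0 - sys_var)
    return y


def simulate_null_polygenic(
    genotypes: GenotypeSet, h2: float, seed: int
) -> np.ndarray:
    """Polygenic null phenotype: dense normal effects over all variants.

    Y = X @ delta + eps with delta ~ Normal, the genetic part rescaled to
    empirical variance exactly h2 and noise variance 1 - h2. Such traits
    are 'null' with respect to any particular predicted feature but share
    its polygenic basis, which inflates naive association statistics.
    """
    from .datamodel import standardize

    if not (0.0 <= h2 <= 1.0):
        raise ValueError(f"h2 must be in [0, 1], got {h2}")
    rng = np.random.default_rng(seed)
    X_std = standardize(genotypes)
    n, P = X_std.shape
    y = np.zeros(n)
    if h2 > 0:
        g = X_std @ rng.standard_normal(P)
        y += g * np.sqrt(h2) / g.std()
    y += rng.standard_normal(n) * np.sqrt(1.0 - h2)
    return y
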