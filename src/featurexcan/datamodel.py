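"""Core genotype and GWAS summary-statistic containers.

Everything downstream (prediction, association, MR) operates on three
containers: :class:`Variant` metadata, a dense :class:`GenotypeSet` of
dosages, and a :class:`GwasSummary` table of per-variant marginal effects.
Allele harmonization is centralized here so that every weighted sum over
variants uses a consistent effect-allele orientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Strand-ambiguous allele pairs (reverse complement of themselves).
AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass(frozen=True)
class Variant:
    """A biallelic variant.

    Parameters
    ----------
    chrom : str
        Chromosome label.
    pos : int
        1-based position.
    rsid : str
        Variant identifier.
    a0 : str
        Non-effect (reference) allele.
    a1 : str
        Effect (counted) allele; dosages count copies of ``a1``.
    maf : float
        Minor-allele frequency, in [0, 0.5].
    """

    chrom: str
    pos: int
    rsid: str
    a0: str
    a1: str
    maf: float

    def __post_init__(self) -> None:
        if self.a0 == self.a1:
            raise ValueError(f"{self.rsid}: alleles must differ, got {self.a0}/{self.a1}")
        if not (0.0 <= self.maf <= 0.5):
            raise ValueError(f"{self.rsid}: maf {self.maf} outside [0, 0.5]")

    @property
    def is_ambiguous(self) -> bool:
        """True for A/T and C/G pairs whose strand cannot be resolved."""
        return (self.a0, self.a1) in AMBIGUOUS_PAIRS


@dataclass
class GenotypeSet:
    """Dense dosage matrix with aligned variant metadata.

    ``dosages`` is n_samples x n_variants with entries in [0, 2] counting
    effect-allele (``a1``) copies. Variants must be sorted by (chrom, pos).
    """

    dosages: np.ndarray
    variants: list[Variant]
    samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x variants)")
        if self.dosages.shape[1] != len(self.variants):
            raise ValueError(
                f"{self.dosages.shape[1]} dosage columns vs {len(self.variants)} variants"
            )
        if not self.samples:
            self.samples = [f"sample_{i}" for i in range(self.dosages.shape[0])]
        if len(self.samples) != self.dosages.shape[0]:
            raise ValueError("sample list length does not match dosage rows")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def rsids(self) -> list[str]:
        return [v.rsid for v in self.variants]

    def subset_variants(self, index: np.ndarray | list[int]) -> "GenotypeSet":
        """Return a new set restricted to the given variant column indices."""
        index = np.asarray(index, dtype=int)
        return GenotypeSet(
            dosages=self.dosages[:, index],
            variants=[self.variants[i] for i in index],
            samples=list(self.samples),
        )

    def subset_samples(self, index: np.ndarray | list[int]) -> "GenotypeSet":
        index = np.asarray(index, dtype=int)
        return GenotypeSet(
            dosages=self.dosages[index, :],
            variants=list(self.variants),
            samples=[self.samples[i] for i in index],
        )

    def variant_frame(self) -> pd.DataFrame:
        """Variant metadata as a DataFrame indexed by rsid."""
        return pd.DataFrame(
            {
                "chrom": [v.chrom for v in self.variants],
                "pos": [v.pos for v in self.variants],
                "rsid": [v.rsid for v in self.variants],
                "a0": [v.a0 for v in self.variants],
                "a1": [v.a1 for v in self.variants],
                "maf": [v.maf for v in self.variants],
            }
        ).set_index("rsid", drop=False)


class GwasSummary:
    """Per-variant GWAS marginal statistics.

    Wraps a DataFrame with columns ``rsid, chrom, pos, effect_allele,
    other_allele, bhat, se, z, pval, n_gwas``. ``z`` is derived as
    ``bhat / se`` when absent, ``pval`` as the two-sided normal tail of z.
    """

    REQUIRED = ["rsid", "effect_allele", "other_allele"]

    def __init__(self, table: pd.DataFrame):
        from scipy import stats

        df = table.copy()
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"GWAS table missing columns: {missing}")
        if "z" not in df.columns:
            if "bhat" not in df.columns or "se" not in df.columns:
                raise ValueError("GWAS table needs z, or bhat and se")
            df["z"] = df["bhat"] / df["se"]
        if "bhat" not in df.columns:
            df["bhat"] = np.nan
        if "se" not in df.columns:
            df["se"] = np.nan
        if "pval" not in df.columns:
            df["pval"] = 2.0 * stats.norm.sf(np.abs(df["z"]))
        # guard the open-interval invariant p in (0, 1]
        df["pval"] = df["pval"].clip(lower=np.nextafter(0.0, 1.0), upper=1.0)
        self.table = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def rsids(self) -> pd.Series:
        return self.table["rsid"]

    def copy(self) -> "GwasSummary":
        return GwasSummary(self.table.copy())


def select_variants(
    genotypes: GenotypeSet, maf_min: float = 0.05, drop_ambiguous: bool = True
) -> GenotypeSet:
    """Filter the variant universe by MAF and strand ambiguity.

    Retains variants with ``maf > maf_min`` (strict) and, when
    ``drop_ambiguous``, whose allele pair is not A/T or C/G (those pairs are
    their own reverse complement, so strand cannot be verified against an
    external study). Column order is preserved; an empty result is legal.
    """
    keep = [
        j
        for j, v in enumerate(genotypes.variants)
        if v.maf > maf_min and not (drop_ambiguous and v.is_ambiguous)
    ]
    return genotypes.subset_variants(keep)


def harmonize_to_weights(gwas: GwasSummary, weights_variants: list[Variant]) -> GwasSummary:
    """Orient GWAS effects to the weight database's effect alleles.

    The output is restricted to shared rsids, in the order of
    ``weights_variants``. Where the GWAS effect allele equals the weight's
    non-effect allele (with the other allele matching), ``bhat`` and ``z``
    are sign-flipped. Variants whose allele pairs do not match either
    orientation are dropped and counted in the log.

    Raises
    ------
    ValueError
        If no variants remain after intersection.
    """
    wmap = {v.rsid: v for v in weights_variants}
    df = gwas.table
    rows: list[int] = []
    flips: list[bool] = []
    n_mismatch = 0
    by_rsid = {r: i for i, r in enumerate(df["rsid"])}
    for v in weights_variants:
        i = by_rsid.get(v.rsid)
        if i is None:
            continue
        ea, oa = df.at[i, "effect_allele"], df.at[i, "other_allele"]
        if ea == v.a1 and oa == v.a0:
            rows.append(i)
            flips.append(False)
        elif ea == v.a0 and oa == v.a1:
            rows.append(i)
            flips.append(True)
        else:
            n_mismatch += 1
    if n_mismatch:
        logger.warning("harmonize_to_weights: dropped %d allele-mismatched variants", n_mismatch)
    if not rows:
        raise ValueError("no variants shared between GWAS and weights after harmonization")
    out = df.iloc[rows].copy().reset_index(drop=True)
    flip = np.asarray(flips)
    out.loc[flip, "bhat"] = -out.loc[flip, "bhat"]
    out.loc[flip, "z"] = -out.loc[flip, "z"]
    ea = out["effect_allele"].copy()
    out.loc[flip, "effect_allele"] = out.loc[flip, "other_allele"]
    out.loc[flip, "other_allele"] = ea[flip]
    return GwasSummary(out)


def standardize(genotypes: GenotypeSet | np.ndarray) -> np.ndarray:
    """Column-standardize dosages: mean 0, sd 1 (denominator n).

    The population (1/n) standard deviation is used so that the sample
    covariance of the standardized matrix has unit diagonal and the dual and
    primal ridge solutions agree exactly.

    Raises
    ------
    ValueError
        If any column is monomorphic (sd == 0); offending rsids are listed
        when variant metadata is available.
    """
    if isinstance(genotypes, GenotypeSet):
        X = genotypes.dosages
        rsids = genotypes.rsids
    else:
        X = np.asarray(genotypes, dtype=float)
        rsids = None
    # mean-impute missing dosages per variant before standardizing
    if np.isnan(X).any():
        n_missing = int(np.isnan(X).sum())
        logger.info("standardize: mean-imputing %d missing dosages (%.3f%%)",
                    n_missing, 100.0 * n_missing / X.size)
        col_mean = np.nanmean(X, axis=0)
        X = np.where(np.isnan(X), col_mean, X)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)  # ddof=0
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = [rsids[j] for j in bad] if rsids is not None else bad.tolist()
        raise ValueError(f"monomorphic columns cannot be standardized: {names}")
    return (X - mu) / sd
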