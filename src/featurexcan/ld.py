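"""Banded per-chromosome SNP covariance for summary-level association.

Genome-wide predictors touch every chromosome, so the full SNP covariance
is far too large to ship. Two approximations make it tractable: covariance
between chromosomes is taken as zero, and within a chromosome any pair
separated by more than ``bandwidth`` variants (default 200) is zeroed —
LD decays fast enough with distance that the truncation loses little.
Storage is b+1 diagonal arrays per chromosome, and the quadratic form
w' R w runs in O(P * b).

Covariance is computed on standardized dosages (denominator n_ref), so the
store is a correlation matrix with unit diagonal, matching the scale of
weights trained on standardized genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import GenotypeSet, standardize


@dataclass
class ChromBand:
    """Banded covariance of one chromosome: ``diags[d][j] = Cov(X_j, X_{j+d})``."""

    diags: list[np.ndarray]
    variants: pd.DataFrame  # columns rsid, pos, a0, a1

    @property
    def n_variants(self) -> int:
        return len(self.diags[0])

    @property
    def bandwidth(self) -> int:
        return len(self.diags) - 1

    def dense(self) -> np.ndarray:
        """Materialize the full (symmetric) matrix; entries beyond the band
        are exactly zero. For tests and small panels only."""
        p = self.n_variants
        R = np.zeros((p, p))
        for d, diag in enumerate(self.diags):
            idx = np.arange(len(diag))
            R[idx, idx + d] = diag
            R[idx + d, idx] = diag
        return R


@dataclass
class BandedCov:
    """Per-chromosome banded SNP covariance aligned to a variant universe."""

    chroms: dict[str, ChromBand]
    bandwidth: int
    n_ref: int

    @property
    def chrom_order(self) -> list[str]:
        return list(self.chroms)

    def variant_frame(self) -> pd.DataFrame:
        """All variants, concatenated in chromosome order."""
        return pd.concat([cb.variants for cb in self.chroms.values()], ignore_index=True)


def build_banded_cov(genotypes: GenotypeSet, bandwidth: int = 200) -> BandedCov:
    """Sample covariance of standardized dosages, banded per chromosome.

    Variants must arrive sorted by (chrom, pos). ``bandwidth = 0`` stores
    only the (unit) variances.

    Raises
    ------
    ValueError
        If variants are not sorted by (chrom, pos) within chromosomes.
    """
    keys = [(v.chrom, v.pos) for v in genotypes.variants]
    seen: dict[str, int] = {}
    last: tuple[str, int] | None = None
    for c, p in keys:
        if c in seen and (last is None or last[0] != c):
            raise ValueError("variants not grouped by chromosome")
        if last is not None and last[0] == c and p < last[1]:
            raise ValueError("variants not sorted by position within chromosome")
        seen[c] = 1
        last = (c, p)

    X = standardize(genotypes)
    n = X.shape[0]
    vf = genotypes.variant_frame().reset_index(drop=True)
    chroms: dict[str, ChromBand] = {}
    for chrom, grp in vf.groupby("chrom", sort=False):
        cols = grp.index.to_numpy()
        Z = X[:, cols]
        p = Z.shape[1]
        diags = []
        for d in range(min(bandwidth, p - 1) + 1):
            # sample covariance with denominator n (columns are mean-zero, sd 1)
            diags.append(np.einsum("ij,ij->j", Z[:, : p - d], Z[:, d:]) / n)
        chroms[str(chrom)] = ChromBand(
            diags=diags,
            variants=grp[["rsid", "pos", "a0", "a1"]].reset_index(drop=True),
        )
    return BandedCov(chroms=chroms, bandwidth=bandwidth, n_ref=n)


def quad_form(weights: np.ndarray, cov: BandedCov) -> float:
    """Band-aware quadratic form w' R w in O(P * b).

    ``weights`` must be aligned to the covariance's variant order
    (chromosome blocks concatenated). Cross-chromosome terms are zero by
    construction.

    Raises
    ------
    ValueError
        If the result is not strictly positive for a nonzero weight vector
        (a symptom of LD misspecification).
    """
    w = np.asarray(weights, dtype=float)
    total = 0.0
    offset = 0
    for cb in cov.chroms.values():
        p = cb.n_variants
        wc = w[offset : offset + p]
        offset += p
        if not np.any(wc):
            continue
        total += float(wc @ (cb.diags[0] * wc))
        for d in range(1, len(cb.diags)):
            total += 2.0 * float((wc[: p - d] * cb.diags[d]) @ wc[d:])
    if offset != w.shape[0]:
        raise ValueError(f"weight length {w.shape[0]} != covariance universe {offset}")
    if np.any(w) and total <= 0:
        raise ValueError(f"quadratic form non-positive ({total:.3g}): LD misspecification")
    return total


def band_matvec(weights: np.ndarray, cov: BandedCov) -> np.ndarray:
    """R w, band-aware: used for covariances between predicted features."""
    w = np.asarray(weights, dtype=float)
    out = np.zeros_like(w)
    offset = 0
    for cb in cov.chroms.values():
        p = cb.n_variants
        wc = w[offset : offset + p]
        oc = out[offset : offset + p]
        oc += cb.diags[0] * wc
        for d in range(1, len(cb.diags)):
            oc[: p - d] += cb.diags[d] * wc[d:]
            oc[d:] += cb.diags[d] * wc[: p - d]
        offset += p
    return out


def save_banded_cov(cov: BandedCov, path: str) -> None:
    """Persist to an HDF5 container: /chr{c}/diag{d} arrays plus a
    /chr{c}/variants table; root attributes ``bandwidth`` and ``n_ref``."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["bandwidth"] = cov.bandwidth
        f.attrs["n_ref"] = cov.n_ref
        f.attrs["chrom_order"] = list(cov.chroms)
        for chrom, cb in cov.chroms.items():
            g = f.create_group(f"chr{chrom}")
            for d, diag in enumerate(cb.diags):
                g.create_dataset(f"diag{d}", data=diag)
            v = cb.variants
            g.create_dataset("rsid", data=np.array(v["rsid"], dtype="S"))
            g.create_dataset("pos", data=np.asarray(v["pos"], dtype=np.int64))
            g.create_dataset("a0", data=np.array(v["a0"], dtype="S"))
            g.create_dataset("a1", data=np.array(v["a1"], dtype="S"))


def load_banded_cov(path: str) -> BandedCov:
    """Read a container written by :func:`save_banded_cov`."""
    import h5py

    chroms: dict[str, ChromBand] = {}
    with h5py.File(path, "r") as f:
        bandwidth = int(f.attrs["bandwidth"])
        n_ref = int(f.attrs["n_ref"])
        for chrom in f.attrs["chrom_order"]:
            g = f[f"chr{chrom}"]
            diags = []
            d = 0
            while f"diag{d}" in g:
                diags.append(np.asarray(g[f"diag{d}"]))
                d += 1
            variants = pd.DataFrame(
                {
                    "rsid": [s.decode() for s in g["rsid"][()]],
                    "pos": np.asarray(g["pos"]),
                    "a0": [s.decode() for s in g["a0"][()]],
                    "a1": [s.decode() for s in g["a1"][()]],
                }
            )
            chroms[str(chrom)] = ChromBand(diags=diags, variants=variants)
    return BandedCov(chroms=chroms, bandwidth=bandwidth, n_ref=n_ref)
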