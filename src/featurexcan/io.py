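"""File-format adapters: PLINK BED/BIM/FAM, VCF, GWAS summary tables,
feature tables.

The PLINK codec handles the standard variant-major 2-bit BED layout
directly (00 = hom a1... per the v1.00 spec: 00 hom first-listed/minor,
01 missing, 10 het, 11 hom second-listed). Dosages returned count copies
of the BIM's allele-1 column, matching the :class:`Variant` effect-allele
convention. VCF dosages come from the DS field when present, else from GT.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import GenotypeSet, GwasSummary, Variant
from .preprocess import FeatureTable

logger = logging.getLogger(__name__)

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit code -> dosage of allele 1 (BIM column 5); 1 codes missing
_BED_DECODE = np.array([2.0, np.nan, 1.0, 0.0])


def _maf_from_dosage(col: np.ndarray) -> float:
    f = np.nanmean(col) / 2.0
    return float(min(f, 1.0 - f))


def read_plink(prefix: str) -> GenotypeSet:
    """Read a PLINK BED/BIM/FAM fileset (variant-major BED v1)."""
    prefix = str(prefix)
    bim = pd.read_csv(
        prefix + ".bim", sep=r"\s+", header=None,
        names=["chrom", "rsid", "cm", "pos", "a1", "a0"],
        dtype={"chrom": str},
    )
    fam = pd.read_csv(
        prefix + ".fam", sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype={"fid": str, "iid": str},
    )
    n, P = len(fam), len(bim)
    raw = Path(prefix + ".bed").read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise ValueError(f"{prefix}.bed: not a variant-major PLINK v1 BED file")
    bytes_per_variant = (n + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != bytes_per_variant * P:
        raise ValueError(f"{prefix}.bed: unexpected size")
    body = body.reshape(P, bytes_per_variant)
    # unpack 2-bit codes, little-endian within each byte
    shifts = np.arange(4) * 2
    codes = (body[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(P, -1)[:, :n]
    dosages = _BED_DECODE[codes].T  # n x P

    variants = [
        Variant(chrom=str(r.chrom), pos=int(r.pos), rsid=str(r.rsid),
                a0=str(r.a0), a1=str(r.a1),
                maf=_maf_from_dosage(dosages[:, j]))
        for j, r in enumerate(bim.itertuples(index=False))
    ]
    return GenotypeSet(dosages=dosages, variants=variants, samples=list(fam["iid"]))


def write_plink(genotypes: GenotypeSet, prefix: str) -> None:
    """Write a GenotypeSet as PLINK BED/BIM/FAM (dosages rounded to 0/1/2)."""
    prefix = str(prefix)
    n, P = genotypes.n_samples, genotypes.n_variants
    with open(prefix + ".bim", "w") as f:
        for v in genotypes.variants:
            f.write(f"{v.chrom}\t{v.rsid}\t0\t{v.pos}\t{v.a1}\t{v.a0}\n")
    with open(prefix + ".fam", "w") as f:
        for s in genotypes.samples:
            f.write(f"{s}\t{s}\t0\t0\t0\t-9\n")
    code_map = {0: 3, 1: 2, 2: 0}
    bytes_per_variant = (n + 3) // 4
    out = np.zeros((P, bytes_per_variant), dtype=np.uint8)
    D = genotypes.dosages
    for j in range(P):
        col = np.rint(D[:, j])
        codes = np.full(n, 1, dtype=np.uint8)  # missing
        for d, c in code_map.items():
            codes[col == d] = c
        padded = np.zeros(bytes_per_variant * 4, dtype=np.uint8)
        padded[:n] = codes
        packed = (padded.reshape(-1, 4) << (np.arange(4) * 2)).sum(axis=1)
        out[j] = packed.astype(np.uint8)
    with open(prefix + ".bed", "wb") as f:
        f.write(_BED_MAGIC)
        f.write(out.tobytes())


def read_vcf(path: str) -> GenotypeSet:
    """Read dosages from a VCF: the DS FORMAT field when present, else GT."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    dosages = []
    variants = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            logger.info("read_vcf: skipping multi-allelic site %s", rec.ID)
            continue
        try:
            ds = rec.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            col = np.asarray(ds, dtype=float).ravel()
        else:
            gt = np.asarray(rec.genotype.array())[:, :2]
            col = np.where((gt < 0).any(axis=1), np.nan, gt.clip(0).sum(axis=1)).astype(float)
        dosages.append(col)
        variants.append(
            Variant(chrom=str(rec.CHROM), pos=int(rec.POS),
                    rsid=str(rec.ID or f"{rec.CHROM}:{rec.POS}"),
                    a0=str(rec.REF), a1=str(rec.ALT[0]),
                    maf=_maf_from_dosage(col))
        )
    return GenotypeSet(dosages=np.column_stack(dosages), variants=variants, samples=samples)


#: Canonical GWAS column names and common aliases.
_GWAS_ALIASES = {
    "rsid": ["rsid", "variant_id", "snp", "id"],
    "chrom": ["chrom", "chr", "chromosome"],
    "pos": ["pos", "position", "bp"],
    "effect_allele": ["effect_allele", "a1", "alt", "ea"],
    "other_allele": ["other_allele", "a0", "ref", "oa", "non_effect_allele"],
    "bhat": ["bhat", "beta", "effect_size", "b"],
    "se": ["se", "standard_error", "stderr"],
    "z": ["z", "zscore", "z_score"],
    "pval": ["pval", "p", "pvalue", "p_value"],
    "n_gwas": ["n_gwas", "n", "sample_size"],
}


def read_gwas(path: str, column_map: dict[str, str] | None = None) -> GwasSummary:
    """Read a tab-delimited GWAS summary table with header.

    Column names are remapped to the canonical set via common aliases;
    ``column_map`` (canonical -> actual) overrides the alias search.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    rename: dict[str, str] = {}
    lower = {c.lower(): c for c in df.columns}
    for canon, aliases in _GWAS_ALIASES.items():
        if column_map and canon in column_map:
            rename[column_map[canon]] = canon
            continue
        for a in aliases:
            if a in lower:
                rename[lower[a]] = canon
                break
    return GwasSummary(df.rename(columns=rename))


def write_gwas(gwas: GwasSummary, path: str) -> None:
    gwas.table.to_csv(path, sep="\t", index=False)


def read_feature_table(values_path: str, meta_path: str) -> FeatureTable:
    """Read a feature table (first column sample id, header of feature ids)
    plus a two-column metadata file (feature_id, subtype[, modality])."""
    vals = pd.read_csv(values_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t").set_index("feature_id")
    subtype = [str(meta.at[f, "subtype"]) for f in vals.columns]
    modality = (
        [str(meta.at[f, "modality"]) for f in vals.columns]
        if "modality" in meta.columns else None
    )
    return FeatureTable(
        values=vals.to_numpy(dtype=float),
        feature_ids=list(vals.columns),
        subtype=subtype,
        modality=modality,
        samples=[str(s) for s in vals.index],
    )


def write_feature_table(features: FeatureTable, values_path: str, meta_path: str) -> None:
    pd.DataFrame(features.values, index=features.samples,
                 columns=features.feature_ids).to_csv(values_path, sep="\t")
    pd.DataFrame({
        "feature_id": features.feature_ids,
        "subtype": features.subtype,
        "modality": features.modality,
    }).to_csv(meta_path, sep="\t", index=False)
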