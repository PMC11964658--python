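"""PredictDB-style SQLite weight database.

Two tables: ``weights`` (feature_id, rsid, ref_allele, eff_allele, weight)
holding the nonzero prediction weights, and ``extra`` (feature_id,
model_type, hyperparameter, cv_R2, cv_pearson, cv_spearman, phi) holding
per-feature model metadata including the inflation factor Phi filled in by
the association module. Ridge models store the full dense weight vector;
sparse (elastic-net) models store only nonzero entries — reading
reconstructs a dense vector over the supplied variant universe.
"""

from __future__ import annotations

import sqlite3
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import Variant

_SCHEMA = """
CREATE TABLE weights (
    feature_id TEXT NOT NULL,
    rsid TEXT NOT NULL,
    ref_allele TEXT NOT NULL,
    eff_allele TEXT NOT NULL,
    weight REAL NOT NULL,
    PRIMARY KEY (feature_id, rsid)
);
CREATE TABLE extra (
    feature_id TEXT PRIMARY KEY,
    model_type TEXT,
    hyperparameter REAL,
    cv_R2 REAL,
    cv_pearson REAL,
    cv_spearman REAL,
    phi REAL
);
"""


@dataclass
class WeightsDB:
    """In-memory weight store: per-feature weight vectors over a shared
    variant universe, plus model metadata."""

    variants: list[Variant]
    weights: dict[str, np.ndarray] = field(default_factory=dict)
    extra: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        P = len(self.variants)
        for fid, w in self.weights.items():
            w = np.asarray(w, dtype=float)
            if w.shape != (P,):
                raise ValueError(f"{fid}: weight length {w.shape} != variant universe {P}")
            self.weights[fid] = w
        if self.extra is None:
            self.extra = pd.DataFrame(
                columns=["feature_id", "model_type", "hyperparameter",
                         "cv_R2", "cv_pearson", "cv_spearman", "phi"]
            ).set_index("feature_id", drop=False)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.weights)

    def add(self, feature_id: str, weights: np.ndarray, model_type: str = "ridge",
            hyperparameter: float = np.nan, cv_R2: float = np.nan,
            cv_pearson: float = np.nan, cv_spearman: float = np.nan,
            phi: float = np.nan) -> None:
        w = np.asarray(weights, dtype=float)
        if w.shape != (len(self.variants),):
            raise ValueError("weight vector length mismatch")
        self.weights[feature_id] = w
        self.extra.loc[feature_id] = [feature_id, model_type, hyperparameter,
                                      cv_R2, cv_pearson, cv_spearman, phi]

    def set_phi(self, feature_id: str, phi: float) -> None:
        self.extra.loc[feature_id, "phi"] = phi

    def weight_matrix(self) -> np.ndarray:
        """P x K dense matrix of weights, columns ordered by feature_ids."""
        return np.column_stack([self.weights[f] for f in self.feature_ids])


def export_weights(db: WeightsDB, path: str) -> None:
    """Write a :class:`WeightsDB` to a PredictDB-style SQLite file.

    Sparse models (any model_type other than ``ridge``) store only nonzero
    weights; dense ridge vectors are stored in full so a round trip is
    bitwise exact.

    Raises
    ------
    ValueError
        On duplicate (feature, rsid) rows, which would corrupt the store.
    """
    rsids = [v.rsid for v in db.variants]
    if len(set(rsids)) != len(rsids):
        raise ValueError("duplicate rsids in variant universe")
    con = sqlite3.connect(path)
    try:
        con.executescript("DROP TABLE IF EXISTS weights; DROP TABLE IF EXISTS extra;")
        con.executescript(_SCHEMA)
        rows = []
        for fid in db.feature_ids:
            w = db.weights[fid]
            model_type = str(db.extra.loc[fid, "model_type"]) if fid in db.extra.index else "ridge"
            dense = model_type == "ridge"
            for j, v in enumerate(db.variants):
                if dense or w[j] != 0.0:
                    rows.append((fid, v.rsid, v.a0, v.a1, float(w[j])))
        con.executemany("INSERT INTO weights VALUES (?,?,?,?,?)", rows)
        ex = db.extra.reset_index(drop=True)
        con.executemany(
            "INSERT INTO extra VALUES (?,?,?,?,?,?,?)",
            ex[["feature_id", "model_type", "hyperparameter", "cv_R2",
                "cv_pearson", "cv_spearman", "phi"]].itertuples(index=False, name=None),
        )
        con.commit()
    finally:
        con.close()


def load_weights(path: str, variants: list[Variant] | None = None) -> WeightsDB:
    """Read a PredictDB-style SQLite file back into a :class:`WeightsDB`.

    If ``variants`` is omitted, the variant universe is reconstructed from
    the union of rsids in the weights table (positions unknown, maf set to
    0.25 as a placeholder — pass the training variants for full metadata).
    """
    con = sqlite3.connect(path)
    try:
        wdf = pd.read_sql_query("SELECT * FROM weights", con)
        extra = pd.read_sql_query("SELECT * FROM extra", con)
    finally:
        con.close()
    if variants is None:
        seen: dict[str, Variant] = {}
        for row in wdf.itertuples(index=False):
            if row.rsid not in seen:
                seen[row.rsid] = Variant(chrom="0", pos=len(seen) + 1, rsid=row.rsid,
                                         a0=row.ref_allele, a1=row.eff_allele, maf=0.25)
        variants = list(seen.values())
    index = {v.rsid: j for j, v in enumerate(variants)}
    P = len(variants)
    weights: dict[str, np.ndarray] = {}
    for fid, grp in wdf.groupby("feature_id", sort=False):
        w = np.zeros(P)
        for row in grp.itertuples(index=False):
            j = index.get(row.rsid)
            if j is not None:
                w[j] = row.weight
        weights[fid] = w
    extra = extra.set_index("feature_id", drop=False)
    return WeightsDB(variants=variants, weights=weights, extra=extra)
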