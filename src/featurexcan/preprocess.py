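"""Feature preprocessing: volumetric scaling, covariate residualization,
subtype PCA decomposition, and rank-based inverse normalization.

Regional brain features within a subtype (e.g. all cortical gray-matter
volumes, or all tract-wise FA values) are strongly correlated because they
share a brain-wide component. PC1 of the subtype serves as a proxy for that
shared component; per-feature residuals after removing PC1 proxy the
region-specific components. Downstream association then distinguishes
brain-wide from region-specific signals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class FeatureTable:
    """n x K feature matrix with per-feature subtype/modality labels."""

    values: np.ndarray
    feature_ids: list[str]
    subtype: list[str]
    modality: list[str] | None = None
    samples: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        K = self.values.shape[1]
        if len(self.feature_ids) != K or len(self.subtype) != K:
            raise ValueError("feature_ids and subtype must have one entry per column")
        if self.modality is None:
            self.modality = ["dMRI"] * K
        if self.samples is None:
            self.samples = [f"sample_{i}" for i in range(self.values.shape[0])]

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            self.values.copy(), list(self.feature_ids), list(self.subtype),
            list(self.modality), list(self.samples),
        )


@dataclass
class DecomposedFeatures:
    """Per-subtype PC1 scores/loadings and region-specific residuals.

    ``pc1_scores`` maps subtype -> n-vector, ``pc1_loadings`` maps subtype
    -> loading vector over that subtype's features (oriented so the mean
    loading is non-negative, making PC1 a weighted average of features),
    ``variance_explained`` maps subtype -> fraction of the subtype's
    standardized variance carried by PC1. ``residuals`` holds every
    feature's OLS residual on its subtype's PC1, aligned with
    ``feature_ids``.
    """

    pc1_scores: dict[str, np.ndarray]
    pc1_loadings: dict[str, np.ndarray]
    residuals: np.ndarray
    feature_ids: list[str]
    subtype: list[str]
    variance_explained: dict[str, float]


def scale_structural(features: FeatureTable, head_scale: np.ndarray) -> FeatureTable:
    """Multiply T1 structural (volume) columns by the per-subject head-size
    scaling factor; diffusion columns pass through unchanged.

    The scaling factor maps native volumes toward a standard head size, so
    scaled volumes are relative to total brain volume.
    """
    head_scale = np.asarray(head_scale, dtype=float)
    if np.any(head_scale <= 0):
        raise ValueError("head_scale must be strictly positive")
    out = features.copy()
    is_t1 = np.array([m == "T1" for m in features.modality])
    out.values[:, is_t1] = out.values[:, is_t1] * head_scale[:, None]
    return out


def residualize(features: FeatureTable, covariates: np.ndarray) -> FeatureTable:
    """Replace each feature column by its OLS residual on the covariates.

    An intercept is always included, so residuals are mean-zero and
    orthogonal to every covariate column.

    Raises
    ------
    ValueError
        If the covariate matrix (with intercept) is rank deficient; the
        offending columns are named by index.
    """
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    design = np.column_stack([np.ones(C.shape[0]), C])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify columns that do not increase rank when added left to right
        bad = []
        r = 0
        for j in range(design.shape[1]):
            rj = np.linalg.matrix_rank(design[:, : j + 1])
            if rj == r:
                bad.append(j - 1)  # report in covariate indexing
            r = rj
        raise ValueError(f"covariate matrix rank deficient; collinear columns {bad}")
    Q, _ = np.linalg.qr(design)
    out = features.copy()
    out.values = out.values - Q @ (Q.T @ out.values)
    return out


def decompose_subtype(features: FeatureTable) -> DecomposedFeatures:
    """PC1-plus-residual decomposition within each feature subtype.

    PCA is run on column-standardized values per subtype; PC1 loadings are
    oriented so their mean is non-negative (ties broken toward a positive
    first loading), so the score is a weighted average of the subtype's
    features. Residuals are per-column OLS residuals on the PC1 score.
    Subtypes with a single feature pass through residual-only (the single
    column becomes its own residual after centering; no PC is extracted).

    Raises
    ------
    ValueError
        If any subtype column has zero variance.
    """
    values = features.values
    n = values.shape[0]
    subtypes = list(dict.fromkeys(features.subtype))
    pc1_scores: dict[str, np.ndarray] = {}
    pc1_loadings: dict[str, np.ndarray] = {}
    variance_explained: dict[str, float] = {}
    residuals = np.empty_like(values)

    sub_arr = np.asarray(features.subtype)
    for st in subtypes:
        cols = np.flatnonzero(sub_arr == st)
        block = values[:, cols]
        sd = block.std(axis=0)
        if np.any(sd == 0):
            bad = [features.feature_ids[cols[j]] for j in np.flatnonzero(sd == 0)]
            raise ValueError(f"zero-variance features in subtype {st}: {bad}")
        Z = (block - block.mean(axis=0)) / sd
        if len(cols) == 1:
            residuals[:, cols[0]] = Z[:, 0] * sd[0]
            continue
        # PC1 via SVD of the standardized block
        U, S, Vt = np.linalg.svd(Z, full_matrices=False)
        loading = Vt[0]
        if loading.mean() < 0 or (loading.mean() == 0 and loading[0] < 0):
            loading = -loading
        score = Z @ loading
        pc1_scores[st] = score
        pc1_loadings[st] = loading
        variance_explained[st] = float(S[0] ** 2 / np.sum(S**2))
        # per-column OLS residual on the score (score is mean-zero)
        coef = (Z.T @ score) / (score @ score)
        residuals[:, cols] = Z - np.outer(score, coef)

    return DecomposedFeatures(
        pc1_scores=pc1_scores,
        pc1_loadings=pc1_loadings,
        residuals=residuals,
        feature_ids=list(features.feature_ids),
        subtype=list(features.subtype),
        variance_explained=variance_explained,
    )


def inverse_normal(x: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal (Blom) transform.

    Maps x to Phi^-1((rank - 3/8) / (n + 1/4)) with average ranks for ties.
    Monotone in the input and invariant to any strictly increasing
    transform, which damps the influence of outliers.

    Raises
    ------
    ValueError
        If fewer than 2 observations or all values are identical.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if n < 2:
        raise ValueError("inverse_normal requires at least 2 observations")
    if np.all(x == x[0]):
        raise ValueError("inverse_normal undefined for a constant vector")
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - 0.375) / (n + 0.25))
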