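"""Whole-transcriptome structure: batch-aware scaling, Ward clustering, correlation PCA.

The two-stage z-score first standardizes every transcript within each batch of
experiments (removing per-batch location/scale), then re-standardizes across
all samples so each row ends with mean 0 and sd 1.  Samples are then clustered
agglomeratively with the Ward criterion applied to *unsquared* Euclidean
distances — the classic "ward.D" convention — and summarized by
correlation-mode PCA (variables standardized to unit variance before the
eigendecomposition).  Fold-change tables for heatmaps and MA plots are
produced as tidy matrices rather than rendered figures.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list
from scipy.spatial.distance import squareform, pdist
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin


def _zscore_rows(values: np.ndarray, ddof: int = 1) -> np.ndarray:
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=ddof, keepdims=True)
    out = np.zeros_like(values, dtype=float)
    ok = (sd > 0).ravel()
    out[ok] = (values[ok] - mean[ok]) / sd[ok]
    if not ok.all():
        warnings.warn(f"{(~ok).sum()} constant row slice(s) set to zero during z-scoring")
    return out


def double_zscore(values: pd.DataFrame, batches: pd.Series) -> pd.DataFrame:
    """Two-stage per-transcript standardization.

    Stage 1 z-scores each row within each batch (sample sd, n−1); stage 2
    z-scores each row across all samples.  Rows constant within a slice are
    set to zero there with a warning.  Batches of a single sample are an
    error (their sd is undefined).
    """
    batches = batches.reindex(values.columns)
    if batches.isna().any():
        raise ValueError("every sample needs a batch assignment")
    by_batch = values.columns.groupby(batches.to_numpy())
    for batch, cols in by_batch.items():
        if len(cols) < 2:
            raise ValueError(f"batch {batch!r} has a single sample; sd undefined")
    out = np.empty(values.shape, dtype=float)
    for batch, cols in by_batch.items():
        ix = values.columns.get_indexer(cols)
        out[:, ix] = _zscore_rows(values.to_numpy(dtype=float)[:, ix])
    out = _zscore_rows(out)
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def _ward_d_linkage(dist: np.ndarray) -> np.ndarray:
    """Agglomerative Ward linkage on an (unsquared) distance matrix.

    Lance–Williams update with Ward coefficients applied directly to the
    supplied dissimilarities (the R ``ward.D`` convention).  Ties break on the
    smallest (i, j) cluster-index pair, giving a deterministic merge order.
    Returns a scipy-style linkage matrix.
    """
    n = dist.shape[0]
    d = dist.astype(float).copy()
    np.fill_diagonal(d, np.inf)
    sizes = {i: 1 for i in range(n)}
    active = list(range(n))
    labels = {i: i for i in range(n)}  # position → cluster id
    Z = np.zeros((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        best = (np.inf, None, None)
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                i, j = active[ai], active[bi]
                if d[i, j] < best[0] - 1e-15:
                    best = (d[i, j], ai, bi)
        h, ai, bi = best
        if step > 0 and h < Z[step - 1, 2]:
            # Ward is monotone; round off float-noise inversions from tie-breaking
            if Z[step - 1, 2] - h < 1e-9 * max(1.0, abs(h)):
                h = Z[step - 1, 2]
        i, j = active[ai], active[bi]
        ci, cj = labels[i], labels[j]
        ni, nj = sizes[ci], sizes[cj]
        Z[step] = (min(ci, cj), max(ci, cj), h, ni + nj)
        for k in active:
            if k in (i, j):
                continue
            nk = sizes[labels[k]]
            tot = ni + nj + nk
            d_new = ((ni + nk) * d[i, k] + (nj + nk) * d[j, k] - nk * d[i, j]) / tot
            d[i, k] = d[k, i] = d_new
        labels[i] = next_id
        sizes[next_id] = ni + nj
        next_id += 1
        d[j, :] = d[:, j] = np.inf
        active.pop(bi)
    return Z


def hierarchical_cluster(scaled: pd.DataFrame, axis: str = "samples"
                         ) -> dict:
    """Ward ("ward.D") agglomerative clustering of samples (or transcripts).

    ``scaled`` is transcripts × samples; ``axis='samples'`` clusters columns.
    Returns ``{"linkage": Z, "labels": [...], "heights": [...]}`` with a
    scipy-compatible linkage matrix.
    """
    X = scaled.to_numpy(dtype=float)
    if axis == "samples":
        X = X.T
        names = list(scaled.columns)
    elif axis == "transcripts":
        names = list(scaled.index)
    else:
        raise ValueError("axis must be 'samples' or 'transcripts'")
    if np.isnan(X).any():
        raise ValueError("NaNs in clustering input")
    if X.shape[0] < 2:
        raise ValueError("clustering needs at least 2 observations")
    dist = squareform(pdist(X, metric="euclidean"))
    Z = _ward_d_linkage(dist)
    return {"linkage": Z, "labels": names, "heights": Z[:, 2].tolist()}


def cut_clusters(dendrogram: dict, n_clusters: int) -> pd.Series:
    """Flat cluster assignment from a dendrogram at a fixed cluster count."""
    flat = fcluster(dendrogram["linkage"], t=n_clusters, criterion="maxclust")
    return pd.Series(flat, index=dendrogram["labels"], name="cluster")


def pca_samples(values: pd.DataFrame, n_components: int | None = None) -> dict:
    """Correlation-mode PCA of samples over transcripts.

    Transcripts (variables) are standardized to unit variance (n−1) before
    the decomposition, equivalent to an eigendecomposition of their
    correlation matrix.  Zero-variance transcripts are dropped with a
    warning.  Returns sample scores, loadings, eigenvalues and variance
    fractions (summing to 1).
    """
    X = values.to_numpy(dtype=float).T  # samples × transcripts
    n, p = X.shape
    if n < 2 or p < 2:
        raise ValueError("PCA needs ≥2 samples and ≥2 transcripts")
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {(~keep).sum()} zero-variance transcript(s) from PCA")
        X = X[:, keep]
        sd = sd[keep]
    Xs = (X - X.mean(axis=0)) / sd
    U, s, Vt = np.linalg.svd(Xs, full_matrices=False)
    eigvals = s ** 2 / (n - 1)
    k = len(s) if n_components is None else min(n_components, len(s))
    scores = U[:, :k] * s[:k]
    return {
        "scores": pd.DataFrame(scores, index=values.columns,
                               columns=[f"PC{i + 1}" for i in range(k)]),
        "loadings": pd.DataFrame(Vt[:k].T, index=values.index[keep],
                                 columns=[f"PC{i + 1}" for i in range(k)]),
        "eigenvalues": eigvals,
        "variance_fractions": eigvals / eigvals.sum(),
    }


def heatmap_matrix(values: pd.DataFrame, samples: pd.DataFrame,
                   reference_group: str = "IVF_ectoderm",
                   pseudocount: float = 1.0,
                   cluster_rows: bool = False,
                   cluster_cols: bool = False) -> pd.DataFrame:
    """log2 fold change of every cell over the reference mean.

    ``reference_group`` may be a sample group or ``"pooled"`` for the mean of
    all samples.  When requested, rows/columns are reordered by Ward ward.D
    clustering leaf order.
    """
    if reference_group == "pooled":
        ref_cols = list(values.columns)
    else:
        ref_cols = list(samples.loc[samples["group"] == reference_group, "sample_id"])
    if not ref_cols:
        raise ValueError(f"reference group {reference_group!r} is empty")
    ref_mean = values[ref_cols].mean(axis=1)
    mat = np.log2(values.add(pseudocount)).sub(np.log2(ref_mean + pseudocount), axis=0)
    if cluster_rows and len(mat) > 1:
        order = leaves_list(_to_scipy_monotonic(hierarchical_cluster(mat.T)["linkage"]))
        mat = mat.iloc[order]
    if cluster_cols and mat.shape[1] > 1:
        order = leaves_list(_to_scipy_monotonic(hierarchical_cluster(mat)["linkage"]))
        mat = mat.iloc[:, order]
    return mat


def _to_scipy_monotonic(Z: np.ndarray) -> np.ndarray:
    # leaves_list only needs the merge topology; heights untouched
    return np.ascontiguousarray(Z)


def ma_table(de_nt_ivf: pd.DataFrame, donor_rpkm: pd.DataFrame,
             labels: pd.DataFrame | None = None) -> pd.DataFrame:
    """MA-plot table: x = mean over donor samples of log2(1 + RPKM), y = NT/IVF logFC."""
    if not de_nt_ivf.index.equals(donor_rpkm.index):
        raise ValueError("transcript universes differ")
    out = pd.DataFrame({
        "mean_log2_rpkm_donor": np.log2(1.0 + donor_rpkm).mean(axis=1),
        "logFC_nt_ivf": de_nt_ivf["logFC"],
    }, index=de_nt_ivf.index)
    if labels is not None:
        out["primary_class"] = labels["primary_class"].reindex(out.index)
    return out


class DoubleZScore(BaseEstimator, TransformerMixin):
    """Transformer form of the two-stage batch z-score.

    ``X`` is (n_samples, n_transcripts); the batch label per sample is given
    at construction or to ``fit``.  Stateless across fits apart from
    validation, since standardization is per input matrix.
    """

    def __init__(self, batches=None):
        self.batches = batches

    def fit(self, X, y=None, batches=None):
        b = batches if batches is not None else self.batches
        if b is None:
            raise ValueError("batch labels are required")
        self.batches_ = np.asarray(b)
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def transform(self, X, batches=None) -> np.ndarray:
        b = np.asarray(batches) if batches is not None else self.batches_
        X = np.asarray(X, dtype=float)
        df = pd.DataFrame(X.T, columns=[f"s{i}" for i in range(X.shape[0])])
        out = double_zscore(df, pd.Series(b, index=df.columns))
        return out.to_numpy().T

    def fit_transform(self, X, y=None, **fit_params):
        return self.fit(X, **fit_params).transform(X)


class WardClustering(BaseEstimator, ClusterMixin):
    """Agglomerative ward.D clustering with a flat cut, sklearn style."""

    def __init__(self, n_clusters: int = 2):
        self.n_clusters = n_clusters

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        df = pd.DataFrame(X.T, columns=[f"s{i}" for i in range(X.shape[0])])
        dendro = hierarchical_cluster(df, axis="samples")
        self.linkage_ = dendro["linkage"]
        self.labels_ = fcluster(self.linkage_, t=self.n_clusters,
                                criterion="maxclust") - 1
        return self


class CorrelationPCA(BaseEstimator, TransformerMixin):
    """Correlation-mode PCA (unit-variance variables), sklearn style."""

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        df = pd.DataFrame(X.T, columns=[f"s{i}" for i in range(X.shape[0])])
        res = pca_samples(df, n_components=self.n_components)
        self.components_ = res["loadings"].to_numpy().T
        self.explained_variance_ = res["eigenvalues"]
        self.explained_variance_ratio_ = res["variance_fractions"]
        self.scores_ = res["scores"].to_numpy()
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0, ddof=1)
        self._keep = self.scale_ > 0
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        Xs = (X[:, self._keep] - self.mean_[self._keep]) / self.scale_[self._keep]
        k = self.components_.shape[0]
        return Xs @ self.components_[:k].T

    def fit_transform(self, X, y=None):
        self.fit(X)
        return self.scores_
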