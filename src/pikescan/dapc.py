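"""Multivariate machinery: genotype PCA, BIC-driven k-means cluster search,
linear discriminant analysis on retained components, and a loading-based
structural-marker selector.

The PCA/LDA composition mirrors the discriminant-analysis-of-principal-
components workflow: samples are projected onto retained PCs, discriminant
axes maximise the between/within variance ratio there, and per-variant
loadings are the composition of PC loadings with discriminant coefficients.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import scipy.cluster.hierarchy as sch
import scipy.linalg

from pikescan.io import MISSING, GenotypeTable


@dataclasses.dataclass
class PcaResult:
    scores: np.ndarray  # (n_samples, n_pc)
    loadings: np.ndarray  # (n_variants, n_pc)
    explained_variance: np.ndarray
    mean: np.ndarray
    scale: np.ndarray | None


@dataclasses.dataclass
class DapcModel:
    n_pc: int
    n_df: int
    pca: PcaResult
    discriminant_coef: np.ndarray  # (n_pc, n_df)
    df_scores: np.ndarray  # (n_samples, n_df)
    variant_loadings: np.ndarray  # (n_variants, n_df)
    groups: list
    group_labels: np.ndarray
    group_centroids: np.ndarray  # (n_groups, n_df)

    def assign(self, df_scores: np.ndarray) -> np.ndarray:
        """Nearest-centroid group assignment in discriminant space."""
        d = ((df_scores[:, None, :] - self.group_centroids[None, :, :]) ** 2).sum(axis=2)
        return np.asarray(self.groups, dtype=object)[np.argmin(d, axis=1)]


@dataclasses.dataclass
class ClusterSearch:
    k_values: list
    bic: list
    wss: list

    @property
    def selected_k(self) -> int:
        return self.k_values[int(np.argmin(self.bic))]


# ---------------------------------------------------------------------------
# PCA


def dosage_matrix(table: GenotypeTable) -> np.ndarray:
    """0/1/2 alternate dosage with missing genotypes mean-imputed per site."""
    d = table.codes.astype(float).T  # samples x sites
    d[table.codes.T == MISSING] = np.nan
    col_mean = np.nanmean(d, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    nan_at = np.isnan(d)
    d[nan_at] = np.broadcast_to(col_mean, d.shape)[nan_at]
    return d


def genotype_pca(matrix: np.ndarray, n_pc: int, scale: bool = False) -> PcaResult:
    """Centered (optionally unit-scaled) SVD of a samples x variants matrix."""
    if matrix.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    mean = matrix.mean(axis=0)
    x = matrix - mean
    scl = None
    if scale:
        scl = x.std(axis=0, ddof=0)
        scl[scl == 0] = 1.0
        x = x / scl
    if not np.any(x):
        raise ValueError("all-constant genotype matrix: PCA undefined")
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-10))
    if n_pc > rank:
        warnings.warn(f"n_pc={n_pc} exceeds matrix rank {rank}; truncating")
        n_pc = rank
    scores = u[:, :n_pc] * s[:n_pc]
    loadings = vt[:n_pc].T
    explained = (s**2) / (matrix.shape[0] - 1)
    return PcaResult(scores, loadings, explained[:n_pc], mean, scl)


def pca_from_table(table: GenotypeTable, n_pc: int, scale: bool = False) -> PcaResult:
    return genotype_pca(dosage_matrix(table), n_pc, scale=scale)


# ---------------------------------------------------------------------------
# k-means + BIC cluster search


def _kmeans_once(x: np.ndarray, k: int, rng: np.random.Generator, n_iter: int = 100):
    n = x.shape[0]
    centers = x[rng.choice(n, size=k, replace=False)].copy()
    labels = np.zeros(n, dtype=int)
    for _ in range(n_iter):
        d = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new_labels = d.argmin(axis=1)
        if np.array_equal(new_labels, labels) and _ > 0:
            break
        labels = new_labels
        for c in range(k):
            members = x[labels == c]
            if len(members):
                centers[c] = members.mean(axis=0)
            else:  # re-seed an empty cluster at the worst-fit point
                centers[c] = x[d.min(axis=1).argmax()]
    wss = float(((x - centers[labels]) ** 2).sum())
    return labels, centers, wss


def kmeans(x: np.ndarray, k: int, seed: int = 0, n_restarts: int = 10):
    """Seeded Lloyd's k-means with best-WSS restart selection."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, k]))
    best = None
    for _ in range(n_restarts):
        labels, centers, wss = _kmeans_once(x, k, rng)
        if best is None or wss < best[2]:
            best = (labels, centers, wss)
    return best


def find_clusters(scores: np.ndarray, k_max: int, seed: int = 0, n_restarts: int = 10) -> ClusterSearch:
    """Per-k BIC ``n*ln(WSS/n) + k*ln(n)``; the selected k minimises BIC."""
    n = scores.shape[0]
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    if k_max >= n:
        raise ValueError("k_max must be below the number of samples")
    ks, bics, wsss = [], [], []
    for k in range(1, k_max + 1):
        _, _, wss = kmeans(scores, k, seed=seed, n_restarts=n_restarts)
        wss = max(wss, 1e-12)  # keep BIC finite for degenerate fits
        bic = n * np.log(wss / n) + k * np.log(n)
        ks.append(k)
        bics.append(float(bic))
        wsss.append(wss)
    return ClusterSearch(ks, bics, wsss)


# ---------------------------------------------------------------------------
# LDA


def lda_fit(pca: PcaResult, group_labels, n_df: int, ridge: float = 1e-8) -> DapcModel:
    """Discriminant axes on retained PC scores, with per-variant loadings.

    Within-group scatter is ridge-regularised when singular (logged via a
    warning).  ``n_df`` is capped at ``min(n_groups - 1, n_pc)``.
    """
    labels = np.asarray(group_labels, dtype=object)
    groups = list(dict.fromkeys(labels))
    if len(groups) < 2:
        raise ValueError("LDA needs at least 2 groups")
    for g in groups:
        if (labels == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    x = pca.scores
    n_pc = x.shape[1]
    n_df = min(n_df, len(groups) - 1, n_pc)

    overall = x.mean(axis=0)
    sw = np.zeros((n_pc, n_pc))
    sb = np.zeros((n_pc, n_pc))
    for g in groups:
        xg = x[labels == g]
        mu = xg.mean(axis=0)
        diff = xg - mu
        sw += diff.T @ diff
        m = (mu - overall)[:, None]
        sb += len(xg) * (m @ m.T)
    eps = ridge * np.trace(sw) / n_pc if np.trace(sw) > 0 else ridge
    try:
        np.linalg.cholesky(sw)
    except np.linalg.LinAlgError:
        warnings.warn(f"singular within-group scatter: ridge epsilon {eps:.3g} applied")
    sw_reg = sw + eps * np.eye(n_pc)
    vals, vecs = scipy.linalg.eigh(sb, sw_reg)
    order = np.argsort(vals)[::-1]
    coef = vecs[:, order[:n_df]]
    df_scores = x @ coef
    variant_loadings = pca.loadings @ coef
    centroids = np.vstack([df_scores[labels == g].mean(axis=0) for g in groups])
    return DapcModel(
        n_pc=n_pc, n_df=n_df, pca=pca, discriminant_coef=coef,
        df_scores=df_scores, variant_loadings=variant_loadings,
        groups=groups, group_labels=labels, group_centroids=centroids,
    )


def loo_assignment_accuracy(matrix: np.ndarray, group_labels, n_pc: int, n_df: int) -> float:
    """Leave-one-out nearest-centroid accuracy of the PCA+LDA composition."""
    labels = np.asarray(group_labels, dtype=object)
    n = matrix.shape[0]
    correct = 0
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pca = genotype_pca(matrix[keep], n_pc)
            model = lda_fit(pca, labels[keep], n_df)
        held = matrix[i] - pca.mean
        if pca.scale is not None:
            held = held / pca.scale
        df = (held @ pca.loadings) @ model.discriminant_coef
        if model.assign(df[None, :])[0] == labels[i]:
            correct += 1
    return correct / n


# ---------------------------------------------------------------------------
# structural-marker selection


def snpzip_select(loadings) -> np.ndarray:
    """Indices of the high-contribution cluster of |loadings|.

    One-dimensional Ward clustering into 2 groups; the cluster with the
    higher mean absolute loading is the structural set.  All-equal loadings
    yield an empty set with a warning.
    """
    arr = np.abs(np.asarray(loadings, dtype=float))
    if arr.size == 0:
        raise ValueError("empty loadings")
    if arr.size == 1:
        return np.asarray([0])
    if np.allclose(arr, arr[0]):
        warnings.warn("all loadings equal: empty structural set")
        return np.asarray([], dtype=int)
    link = sch.linkage(arr[:, None], method="ward")
    labels = sch.fcluster(link, t=2, criterion="maxclust")
    means = {c: arr[labels == c].mean() for c in np.unique(labels)}
    top = max(means, key=means.get)
    return np.flatnonzero(labels == top)
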