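"""Cluster inference and ordination: k-means over principal components with
BIC model selection, DAPC, and principal coordinates analysis."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .dataset import MISSING, DistanceMatrix, SSRDataset
from .diversity import POOLED, allele_frequencies


# ---------------------------------------------------------------------------
# Allele dosage matrix
# ---------------------------------------------------------------------------

def genotypes_to_allele_matrix(dataset: SSRDataset, na_policy: str = "mean"
                               ) -> tuple[np.ndarray, list[tuple[str, int]], list[str]]:
    """Encode genotypes as an individuals x (locus, allele) dosage matrix.

    Each cell counts the copies (0, 1, 2) of that allele carried. Missing
    genotypes are mean-imputed per locus column (``na_policy='mean'``, i.e.
    2 x the pooled allele frequency) or left NaN (``'nan'``). Individuals with
    no scored locus are dropped with a warning. Returns the matrix, the
    (locus, allele) column labels and the retained individual ids.
    """
    table = allele_frequencies(dataset)
    columns: list[tuple[str, int]] = []
    for locus in dataset.loci:
        for a in table.alleles(locus):
            columns.append((locus, a))
    col_index = {c: k for k, c in enumerate(columns)}
    n = dataset.n_individuals
    x = np.full((n, len(columns)), np.nan)
    scored = dataset.scored_mask
    for j, locus in enumerate(dataset.loci):
        cols = [col_index[(locus, a)] for a in table.alleles(locus)]
        al = [c[1] for c in (columns[k] for k in cols)]
        for i in range(n):
            if not scored[i, j]:
                continue
            pair = dataset.genotypes[i, j]
            for k, a in zip(cols, al):
                x[i, k] = float((pair == a).sum())
    if na_policy == "mean":
        pooled = {}
        for locus in dataset.loci:
            if table.has_entry(POOLED, locus):
                pooled[locus] = table.frequencies(POOLED, locus)
        for k, (locus, a) in enumerate(columns):
            fill = 2.0 * pooled.get(locus, {}).get(a, 0.0)
            col = x[:, k]
            col[np.isnan(col)] = fill
    elif na_policy != "nan":
        raise ValueError(f"unknown na_policy {na_policy!r}")
    keep = ~np.all(np.isnan(x) if na_policy == "nan" else ~scored, axis=1)
    if not keep.all():
        warnings.warn(f"dropped {int((~keep).sum())} individuals with no scored locus")
    ids = [dataset.individual_ids[i] for i in np.nonzero(keep)[0]]
    return x[keep], columns, ids


# ---------------------------------------------------------------------------
# BIC-selected k-means
# ---------------------------------------------------------------------------

@dataclass
class ClusterSolution:
    K: int
    assignments: dict[str, int]
    bic_curve: dict[int, float]
    n_pcs: int
    pc_scores: np.ndarray
    individual_ids: list[str]


def _pca_scores(x: np.ndarray, n_pcs: int | None, var_fraction: float = 0.9
                ) -> np.ndarray:
    xc = x - x.mean(axis=0)
    pca = PCA()
    scores = pca.fit_transform(xc)
    if n_pcs is None:
        cum = np.cumsum(pca.explained_variance_ratio_)
        n_pcs = int(np.searchsorted(cum, var_fraction) + 1)
    n_pcs = min(n_pcs, scores.shape[1])
    return scores[:, :n_pcs]


def find_clusters(dataset: SSRDataset, max_K: int = 8, n_pcs: int | None = None,
                  n_restarts: int = 10, seed: int | None = None,
                  var_fraction: float = 1.0) -> ClusterSolution:
    """Select the number of genetic clusters by k-means + BIC on PC scores.

    BIC(K) = n ln(WSS_K / n) + K ln(n); the selected K minimizes the curve
    (smallest K on ties). K = 1 uses the total sum of squares. By default
    all principal components are retained for clustering (truncation loses
    information here and only matters for the discriminant step of DAPC).
    """
    if max_K < 2:
        raise ValueError("max_K must be >= 2")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    x, _, ids = genotypes_to_allele_matrix(dataset)
    scores = _pca_scores(x, n_pcs, var_fraction)
    n = scores.shape[0]
    max_K = min(max_K, n - 1)
    rng = np.random.default_rng(seed)
    bic: dict[int, float] = {}
    best_assign: dict[int, np.ndarray] = {}
    centered = scores - scores.mean(axis=0)
    for K in range(1, max_K + 1):
        if K == 1:
            wss = float((centered ** 2).sum())
            best_assign[1] = np.zeros(n, dtype=int)
        else:
            km = KMeans(n_clusters=K, n_init=n_restarts,
                        random_state=int(rng.integers(2 ** 31)))
            labels = km.fit_predict(scores)
            wss = float(km.inertia_)
            best_assign[K] = labels
        bic[K] = n * math.log(max(wss, 1e-12) / n) + K * math.log(n)
    k_sel = min(bic, key=lambda k: (round(bic[k], 12), k))
    return ClusterSolution(
        K=k_sel,
        assignments=dict(zip(ids, best_assign[k_sel].tolist())),
        bic_curve=bic, n_pcs=scores.shape[1], pc_scores=scores,
        individual_ids=ids,
    )


# ---------------------------------------------------------------------------
# DAPC
# ---------------------------------------------------------------------------

@dataclass
class DapcResult:
    coordinates: np.ndarray            # individuals x discriminant axes
    centroids: np.ndarray              # clusters x axes
    axis_variance: np.ndarray          # fraction of discriminant variance
    posterior: np.ndarray              # individuals x clusters, rows sum to 1
    cluster_labels: list
    individual_ids: list[str]


def dapc(dataset: SSRDataset, clusters: dict[str, int] | None = None,
         n_pcs: int | None = None, n_da: int | None = None,
         var_fraction: float = 0.9) -> DapcResult:
    """Discriminant analysis of principal components.

    Runs LDA on retained PCs of the allele-dosage matrix; prioritizes
    between-group over within-group variation. ``clusters`` defaults to the
    population labels. The number of discriminant axes is
    ``min(n_da, K - 1)``.
    """
    x, _, ids = genotypes_to_allele_matrix(dataset)
    if clusters is None:
        pops = {i: p for i, p in zip(dataset.individual_ids, dataset.population_ids)}
        clusters = {i: pops[i] for i in ids}
    y = np.asarray([clusters[i] for i in ids])
    labels = sorted(set(y.tolist()), key=str)
    if len(labels) < 2:
        raise ValueError("DAPC needs >= 2 clusters")
    scores = _pca_scores(x, n_pcs, var_fraction)
    k = len(labels)
    n_axes = k - 1 if n_da is None else min(n_da, k - 1)
    lda = LinearDiscriminantAnalysis(n_components=n_axes)
    coords = lda.fit_transform(scores, y)
    post = lda.predict_proba(scores)
    ev = lda.explained_variance_ratio_[:n_axes]
    cents = np.vstack([coords[y == lab].mean(axis=0) for lab in labels])
    return DapcResult(coords, cents, ev / ev.sum(), post, labels, ids)


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------

@dataclass
class PcoaResult:
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    labels: list[str]

    @property
    def proportion_explained(self) -> np.ndarray:
        pos = np.clip(self.eigenvalues, 0.0, None)
        return pos / pos.sum() if pos.sum() > 0 else pos


def pcoa(dist: DistanceMatrix) -> PcoaResult:
    """Classical metric multidimensional scaling (principal coordinates).

    Double-centers -D^2/2, eigendecomposes, and scales eigenvectors by the
    square root of their (positive) eigenvalues. Negative eigenvalues are
    reported as-is with zero coordinates on those axes; axes are ordered by
    decreasing eigenvalue.
    """
    d = dist.values
    n = d.shape[0]
    b = -0.5 * d ** 2
    jc = np.eye(n) - np.ones((n, n)) / n
    b = jc @ b @ jc
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    coords = evecs * np.sqrt(np.clip(evals, 0.0, None))
    return PcoaResult(coords, evals, list(dist.labels))
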