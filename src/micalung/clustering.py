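"""Cluster analysis core: correlation-matrix PCA, K-means / hierarchical /
Gaussian-mixture clustering, internal validity indices and bootstrap
Jaccard stability.

The central object is :class:`MicaClusterer`, an sklearn-style estimator
running the full chain

    z-score (sd with n-1 denominator)  ->  PCA on the correlation matrix
    ->  retain components (Kaiser / scree / parallel analysis, majority)
    ->  cluster the retained component scores

with seeded determinism.  Module-level functions (:func:`standardize`,
:func:`fit_pca`, :func:`retain_components`, :func:`cluster`,
:func:`internal_indices`, :func:`jaccard_stability`) are thin wrappers kept
for pipeline scripting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, ClusterMixin, clone
from sklearn.cluster import AgglomerativeClustering, KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score
from sklearn.mixture import GaussianMixture
from sklearn.neighbors import NearestNeighbors


def _as_array(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    X = np.asarray(X, dtype=float)
    return X, [f"x{j}" for j in range(X.shape[1])]


def standardize(X) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-wise z-scores with the n-1 (sample) sd denominator.

    Returns ``(Z, means, sds)``.  A constant column makes the correlation
    matrix undefined and is rejected by name.
    """
    arr, names = _as_array(X)
    means = arr.mean(axis=0)
    sds = arr.std(axis=0, ddof=1)
    bad = np.nonzero(sds == 0)[0]
    if bad.size:
        raise ValueError(f"constant column(s): {[names[j] for j in bad[:5]]}")
    return (arr - means) / sds, means, sds


@dataclass
class PCAModel:
    """Correlation-matrix PCA: loadings, eigenvalues and subject scores."""

    loadings: np.ndarray      # (p, p_eff) orthonormal eigenvectors
    eigenvalues: np.ndarray   # nonincreasing eigenvalues of the correlation matrix
    scores: np.ndarray        # (n, p_eff) = Z @ loadings
    means: np.ndarray
    sds: np.ndarray
    n_retained: int | None = None


def fit_pca(Z: np.ndarray, means: np.ndarray | None = None, sds: np.ndarray | None = None) -> PCAModel:
    """PCA of z-scored data; eigenvalues are those of the correlation matrix.

    Because ``Z`` is standardized with the n-1 denominator, the sample
    covariance of ``Z`` *is* the correlation matrix, so sklearn's
    ``explained_variance_`` equals its eigenvalues exactly.  Near-zero
    eigenvalues from rank deficiency are truncated.
    """
    n, p = Z.shape
    pca = PCA(n_components=min(n - 1, p), svd_solver="full")
    scores = pca.fit_transform(Z)
    ev = pca.explained_variance_
    keep = ev > 1e-10 * max(ev[0], 1.0)
    return PCAModel(
        loadings=pca.components_[keep].T,
        eigenvalues=ev[keep],
        scores=scores[:, keep],
        means=means if means is not None else np.zeros(p),
        sds=sds if sds is not None else np.ones(p),
    )


def _parallel_null_eigenvalues(
    Z: np.ndarray, n_sim: int, rng: np.random.Generator, quantile: float | None = None
) -> np.ndarray:
    """Mean (or upper-quantile) eigenvalue per rank over column-permuted data."""
    n, p = Z.shape
    sims = np.empty((n_sim, min(n - 1, p)))
    for s in range(n_sim):
        perm = np.column_stack([rng.permutation(Z[:, j]) for j in range(p)])
        corr = np.corrcoef(perm, rowvar=False)
        ev = np.sort(np.linalg.eigvalsh(corr))[::-1]
        sims[s] = ev[: sims.shape[1]]
    if quantile is not None:
        return np.quantile(sims, quantile, axis=0)
    return sims.mean(axis=0)


def retain_components(
    model: PCAModel,
    method: str = "majority",
    Z: np.ndarray | None = None,
    n_sim: int = 100,
    seed: int | None = None,
    parallel_quantile: float | None = None,
    fallback: int = 7,
) -> int:
    """Number of principal components to keep.

    * ``kaiser`` — eigenvalues greater than 1;
    * ``scree``  — automatic elbow at the maximum second difference of the
      eigenvalue curve (components strictly before the elbow are kept);
    * ``parallel`` — Horn's parallel analysis: observed eigenvalues exceeding
      the mean (or ``parallel_quantile``) eigenvalue of ``n_sim``
      column-permuted datasets of identical shape;
    * ``majority`` — the value on which at least two of the three criteria
      agree; if all three disagree the ``fallback`` (default 7) is used,
      favouring more components.
    """
    ev = model.eigenvalues
    if method == "kaiser":
        return max(int(np.sum(ev > 1.0)), 1)
    if method == "scree":
        if ev.size < 3:
            return ev.size
        d2 = ev[2:] - 2.0 * ev[1:-1] + ev[:-2]  # second difference at 1..p-2
        elbow = int(np.argmax(d2)) + 1
        return max(elbow, 1)
    if method == "parallel":
        if Z is None:
            raise ValueError("parallel analysis needs the z-scored matrix Z")
        if n_sim < 2:
            raise ValueError("parallel analysis needs n_sim >= 2")
        rng = np.random.default_rng(seed)
        null = _parallel_null_eigenvalues(Z, n_sim, rng, parallel_quantile)
        m = min(len(ev), len(null))
        exceeds = ev[:m] > null[:m]
        # count leading ranks that beat the null
        k = 0
        for flag in exceeds:
            if not flag:
                break
            k += 1
        return max(k, 1)
    if method == "majority":
        votes = [
            retain_components(model, "kaiser"),
            retain_components(model, "scree"),
            retain_components(model, "parallel", Z=Z, n_sim=n_sim, seed=seed,
                              parallel_quantile=parallel_quantile),
        ]
        for v in sorted(set(votes), reverse=True):  # tie toward more components
            if votes.count(v) >= 2:
                return v
        return fallback
    raise ValueError(f"unknown retention method {method!r}")


# --------------------------------------------------------------------------
# Internal validity indices
# --------------------------------------------------------------------------


def dunn_index(points: np.ndarray, labels: np.ndarray) -> float:
    """Min inter-cluster distance over max intra-cluster diameter.

    Singleton clusters contribute zero diameter; if every cluster is a
    singleton the index is infinite.
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("need at least two clusters")
    D = squareform(pdist(points))
    if any(np.sum(labels == u) == 1 for u in uniq):
        warnings.warn("singleton cluster: zero-diameter convention used")
    diam = max(
        (D[np.ix_(labels == u, labels == u)].max() for u in uniq),
        default=0.0,
    )
    min_sep = min(
        D[np.ix_(labels == a, labels == b)].min()
        for i, a in enumerate(uniq)
        for b in uniq[i + 1:]
    )
    if diam == 0.0:
        return float("inf")
    return float(min_sep / diam)


def connectivity_index(points: np.ndarray, labels: np.ndarray, n_neighbors: int = 10) -> float:
    """Sum over points of 1/j for each j-th nearest neighbour (j <= L) that
    is not co-clustered; 0 for perfectly locally-coherent clusterings."""
    labels = np.asarray(labels)
    n = len(labels)
    L = min(n_neighbors, n - 1)
    nn = NearestNeighbors(n_neighbors=L + 1).fit(points)
    _, idx = nn.kneighbors(points)
    total = 0.0
    for i in range(n):
        for rank, j in enumerate(idx[i, 1:], start=1):
            if labels[j] != labels[i]:
                total += 1.0 / rank
    return float(total)


def internal_indices(points: np.ndarray, labels: np.ndarray, n_neighbors: int = 10) -> dict[str, float]:
    """Connectivity (lower better), Dunn (higher better), silhouette (higher)."""
    return {
        "connectivity": connectivity_index(points, labels, n_neighbors),
        "dunn": dunn_index(points, labels),
        "silhouette": float(silhouette_score(points, labels)),
    }


# --------------------------------------------------------------------------
# The clustering estimator
# --------------------------------------------------------------------------


class MicaClusterer(BaseEstimator, ClusterMixin):
    """Standardize -> correlation-matrix PCA -> cluster the retained scores.

    Parameters
    ----------
    method : {'kmeans', 'hierarchical', 'gmm'}
        Clustering algorithm on the retained component scores.  K-means uses
        greedy (k-means++) seeding with ``restarts`` random initialisations;
        hierarchical uses Ward linkage on Euclidean distances; the Gaussian
        mixture uses full covariances with the best of ``restarts``
        initialisations by log-likelihood.
    k : int
        Number of clusters.
    n_components : int or 'auto'
        Retained principal components; 'auto' applies the majority of the
        Kaiser, scree and parallel-analysis criteria.
    retention, n_sim : str, int
        Retention rule (when ``n_components='auto'``) and the number of
        parallel-analysis permutations.
    restarts : int
        Random restarts for K-means / GMM.
    random_state : int or None
        Seed for every stochastic step.

    Attributes
    ----------
    labels_ : ndarray of int, 0..k-1 cluster labels.
    centroids_ : DataFrame, per-cluster means in *original feature units*.
    pca_ : PCAModel with eigenvalues and loadings.
    n_components_ : retained component count.
    indices_ : internal validity indices of the fitted partition.
    """

    def __init__(
        self,
        method: str = "kmeans",
        k: int = 4,
        n_components: int | str = "auto",
        retention: str = "majority",
        n_sim: int = 100,
        restarts: int = 50,
        random_state: int | None = None,
        compute_indices: bool = True,
    ):
        self.method = method
        self.k = k
        self.n_components = n_components
        self.retention = retention
        self.n_sim = n_sim
        self.restarts = restarts
        self.random_state = random_state
        self.compute_indices = compute_indices

    # -- fitting ------------------------------------------------------------

    def fit(self, X, y=None):
        arr, names = _as_array(X)
        n, p = arr.shape
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.k > n:
            raise ValueError(f"k={self.k} exceeds the number of subjects n={n}")
        Z, means, sds = standardize(arr)
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.pca_ = fit_pca(Z, means, sds)
        if self.n_components == "auto":
            self.n_components_ = retain_components(
                self.pca_, self.retention, Z=Z, n_sim=self.n_sim, seed=self.random_state
            )
        else:
            self.n_components_ = int(self.n_components)
        self.pca_.n_retained = self.n_components_
        scores = self.pca_.scores[:, : self.n_components_]
        self.scores_ = scores
        self.labels_, self.model_ = self._cluster_scores(scores)
        self.centroids_ = pd.DataFrame(
            [arr[self.labels_ == c].mean(axis=0) for c in range(self.k)],
            columns=names,
            index=[f"cluster_{c + 1}" for c in range(self.k)],
        )
        self.cluster_sizes_ = np.bincount(self.labels_, minlength=self.k)
        if self.compute_indices:
            self.indices_ = internal_indices(scores, self.labels_)
        return self

    def _cluster_scores(self, scores: np.ndarray):
        seed = self.random_state
        if self.method == "kmeans":
            km = KMeans(
                n_clusters=self.k, n_init=self.restarts, random_state=seed
            ).fit(scores)
            return km.labels_.astype(int), km
        if self.method == "hierarchical":
            hc = AgglomerativeClustering(n_clusters=self.k, linkage="ward").fit(scores)
            return hc.labels_.astype(int), hc
        if self.method == "gmm":
            rng = np.random.default_rng(seed)
            for attempt in range(5):
                gm = GaussianMixture(
                    n_components=self.k,
                    covariance_type="full",
                    n_init=self.restarts,
                    random_state=int(rng.integers(2**31)),
                    reg_covar=1e-4,
                ).fit(scores)
                labels = gm.predict(scores).astype(int)
                if np.unique(labels).size == self.k:
                    return labels, gm
            raise RuntimeError("GMM produced an empty cluster after 5 retries")
        raise ValueError(f"unknown clustering method {self.method!r}")

    # -- prediction ---------------------------------------------------------

    def transform(self, X) -> np.ndarray:
        """Project new subjects onto the retained components."""
        arr, _ = _as_array(X)
        Z = (arr - self.pca_.means) / self.pca_.sds
        return (Z @ self.pca_.loadings)[:, : self.n_components_]

    def predict(self, X) -> np.ndarray:
        scores = self.transform(X)
        if self.method == "kmeans":
            return self.model_.predict(scores).astype(int)
        if self.method == "gmm":
            return self.model_.predict(scores).astype(int)
        # hierarchical: nearest fitted-cluster mean in score space
        centers = np.vstack(
            [self.scores_[self.labels_ == c].mean(axis=0) for c in range(self.k)]
        )
        d = np.linalg.norm(scores[:, None, :] - centers[None, :, :], axis=2)
        return np.argmin(d, axis=1).astype(int)

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def cluster(
    scores: np.ndarray,
    method: str = "kmeans",
    k: int = 4,
    seed: int | None = None,
    restarts: int = 50,
):
    """Cluster pre-computed component scores; returns (labels, fitted model).

    Thin functional wrapper over the algorithm selection in
    :class:`MicaClusterer`.
    """
    est = MicaClusterer(method=method, k=k, restarts=restarts, random_state=seed)
    est.k = k
    if k > len(scores):
        raise ValueError("k exceeds the number of points")
    if k < 2:
        raise ValueError("k must be >= 2")
    return est._cluster_scores(np.asarray(scores, dtype=float))


# --------------------------------------------------------------------------
# Model selection, stability, validation split
# --------------------------------------------------------------------------


def select_k(
    X,
    k_grid=range(2, 7),
    method: str = "kmeans",
    n_components: int | str = "auto",
    restarts: int = 50,
    seed: int | None = None,
) -> tuple[int, pd.DataFrame]:
    """Choose k by internal validity.

    The silhouette criterion decides; the Dunn index and connectivity are
    computed and returned alongside for inspection.  Connectivity decreases
    monotonically toward the smallest k on nested solutions, so its minimum
    carries no model-selection signal, and the Dunn index (a min/max
    statistic) is highly variance-prone at cohort sample sizes.
    Returns (best_k, per-k index table).
    """
    rows = []
    for k in k_grid:
        est = MicaClusterer(
            method=method, k=k, n_components=n_components,
            restarts=restarts, random_state=seed,
        ).fit(X)
        rows.append({"k": k, **est.indices_})
    table = pd.DataFrame(rows).set_index("k")
    return int(table["silhouette"].idxmax()), table


def compare_methods(
    X,
    k: int = 4,
    methods: tuple[str, ...] = ("kmeans", "hierarchical", "gmm"),
    n_components: int | str = "auto",
    restarts: int = 50,
    seed: int | None = None,
) -> pd.DataFrame:
    """Internal validity indices of each clustering method at fixed k."""
    rows = []
    for method in methods:
        est = MicaClusterer(
            method=method, k=k, n_components=n_components,
            restarts=restarts, random_state=seed,
        ).fit(X)
        rows.append({"method": method, **est.indices_})
    return pd.DataFrame(rows).set_index("method")


def jaccard_matrix(labels_a: np.ndarray, labels_b: np.ndarray) -> np.ndarray:
    """Pairwise Jaccard overlap |A∩B| / |A∪B| between the clusters of two
    labelings of the same points."""
    ua, ub = np.unique(labels_a), np.unique(labels_b)
    J = np.zeros((ua.size, ub.size))
    for i, a in enumerate(ua):
        in_a = labels_a == a
        for j, b in enumerate(ub):
            in_b = labels_b == b
            inter = np.count_nonzero(in_a & in_b)
            union = np.count_nonzero(in_a | in_b)
            J[i, j] = inter / union if union else 0.0
    return J


def best_label_agreement(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """Fraction of points agreeing after the best one-to-one label matching
    (Hungarian assignment on the contingency table)."""
    ua, ub = np.unique(labels_a), np.unique(labels_b)
    C = np.zeros((ua.size, ub.size))
    for i, a in enumerate(ua):
        for j, b in enumerate(ub):
            C[i, j] = np.count_nonzero((labels_a == a) & (labels_b == b))
    ri, cj = linear_sum_assignment(-C)
    return float(C[ri, cj].sum() / len(labels_a))


@dataclass
class StabilityReport:
    """Bootstrap Jaccard stability of each original cluster."""

    mean_jaccard: np.ndarray          # per original cluster, averaged over B
    B: int
    dissolution_count: np.ndarray     # replicates with Jaccard < 0.5, per cluster
    per_replicate: np.ndarray = field(repr=False, default=None)  # (B, k)

    @property
    def min_mean_jaccard(self) -> float:
        return float(self.mean_jaccard.min())


def jaccard_stability(
    X,
    estimator: MicaClusterer | None = None,
    B: int = 100,
    seed: int | None = None,
) -> StabilityReport:
    """Clusterwise bootstrap stability of the full clustering chain.

    The chain is fitted on the full data, then refitted on ``B``
    nonparametric bootstrap resamples; each original cluster is matched to
    the replicate cluster maximising the Jaccard overlap over the subjects
    present in the resample.  Replicates where a cluster's best Jaccard
    falls below 0.5 count as dissolutions of that cluster.
    """
    if B < 10:
        warnings.warn("B < 10 bootstrap replicates gives unstable Jaccard estimates")
    est = estimator or MicaClusterer(random_state=seed)
    arr, names = _as_array(X)
    rng = np.random.default_rng(seed)
    base = clone(est)
    if base.random_state is None:
        base.random_state = int(rng.integers(2**31))
    base.compute_indices = False
    base.fit(arr)
    k = base.k
    original = base.labels_
    n = len(original)

    per_rep = np.zeros((B, k))
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        present = np.unique(idx)
        rep = clone(base)
        rep.random_state = int(rng.integers(2**31))
        rep.compute_indices = False
        rep.fit(arr[idx])
        # identical rows get identical assignments; read each unique
        # subject's replicate label off its first occurrence
        first_pos = {}
        for pos, subject in enumerate(idx):
            if subject not in first_pos:
                first_pos[subject] = pos
        rep_labels = np.array([rep.labels_[first_pos[s]] for s in present])
        orig_labels = original[present]
        for c in range(k):
            in_c = orig_labels == c
            if not in_c.any():
                per_rep[b, c] = 0.0  # cluster absent from resample: dissolved
                continue
            best = 0.0
            for rc in np.unique(rep_labels):
                in_rc = rep_labels == rc
                inter = np.count_nonzero(in_c & in_rc)
                union = np.count_nonzero(in_c | in_rc)
                if union and inter / union > best:
                    best = inter / union
            per_rep[b, c] = best
    return StabilityReport(
        mean_jaccard=per_rep.mean(axis=0),
        B=B,
        dissolution_count=(per_rep < 0.5).sum(axis=0),
        per_replicate=per_rep,
    )


def split_half_validation(
    X,
    estimator: MicaClusterer | None = None,
    seed: int | None = None,
) -> float:
    """Stratified-by-cluster 50/50 train/validation split: fit the chain on
    each half and report the validation half's agreement (after best label
    matching) between its own clustering and the training model's
    prediction."""
    arr, _ = _as_array(X)
    rng = np.random.default_rng(seed)
    base = clone(estimator or MicaClusterer(random_state=seed))
    base.random_state = int(rng.integers(2**31))
    base.compute_indices = False
    full = clone(base).fit(arr)
    train_idx, val_idx = [], []
    for c in range(full.k):
        members = np.nonzero(full.labels_ == c)[0]
        members = rng.permutation(members)
        half = len(members) // 2
        train_idx.extend(members[:half])
        val_idx.extend(members[half:])
    train_idx, val_idx = np.array(train_idx), np.array(val_idx)
    m_train = clone(base).fit(arr[train_idx])
    m_val = clone(base).fit(arr[val_idx])
    pred = m_train.predict(arr[val_idx])
    return best_label_agreement(m_val.labels_, pred)
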