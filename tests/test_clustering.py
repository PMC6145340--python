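"""Clustering chain: standardization, PCA, retention, validity indices
(against brute-force oracles), stability and determinism."""

import numpy as np
import pandas as pd
import pytest

from micalung import MicaClusterer, best_label_agreement, internal_indices, standardize
from micalung.clustering import (
    PCAModel,
    compare_methods,
    connectivity_index,
    dunn_index,
    fit_pca,
    jaccard_stability,
    retain_components,
    select_k,
    split_half_validation,
)

from _oracles import brute_connectivity, brute_dunn, brute_silhouette

# ----------------------------------------------------------- standardization


def test_standardize_columns_and_convention():
    Z, means, sds = standardize(np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 9.0]]))
    # sample (n-1) sd convention: column (1,2,3) has sd 1
    assert Z[:, 0] == pytest.approx([-1.0, 0.0, 1.0])
    assert Z.mean(axis=0) == pytest.approx([0.0, 0.0], abs=1e-12)
    assert Z.std(axis=0, ddof=1) == pytest.approx([1.0, 1.0])
    Z2, _, _ = standardize(Z)
    assert np.abs(Z2 - Z).max() < 1e-12  # idempotence


def test_standardize_rejects_constant_column():
    X = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
    with pytest.raises(ValueError, match="b"):
        standardize(X)


# ----------------------------------------------------------------------- PCA


def test_pca_rank_one_pair_and_reconstruction():
    rng = np.random.default_rng(0)
    x = rng.standard_normal(50)
    Z, _, _ = standardize(np.column_stack([x, 2 * x + 1]))
    model = fit_pca(Z)
    assert model.eigenvalues[0] == pytest.approx(2.0)
    assert len(model.eigenvalues) == 1  # zero eigenvalue truncated
    # full reconstruction on a well-conditioned matrix
    Z2, _, _ = standardize(rng.standard_normal((40, 6)))
    m2 = fit_pca(Z2)
    recon = m2.scores @ m2.loadings.T
    assert np.abs(recon - Z2).max() < 1e-8
    assert np.all(np.diff(m2.eigenvalues) <= 1e-12)


def test_pca_noise_eigenvalues_near_one():
    rng = np.random.default_rng(1)
    Z, _, _ = standardize(rng.standard_normal((500, 10)))
    ev = fit_pca(Z).eigenvalues
    # Marchenko-Pastur band for p/n = 0.02: (1 +- sqrt(0.02))^2 ~ (0.73, 1.31)
    assert ev.min() > 0.6 and ev.max() < 1.5


def test_retention_rules():
    model = PCAModel(
        loadings=np.eye(5), eigenvalues=np.array([3.0, 2.0, 0.9, 0.5, 0.4]),
        scores=np.zeros((10, 5)), means=np.zeros(5), sds=np.ones(5),
    )
    assert retain_components(model, "kaiser") == 2
    rng = np.random.default_rng(2)
    Z, _, _ = standardize(rng.standard_normal((200, 8)))
    noise_model = fit_pca(Z)
    assert retain_components(noise_model, "parallel", Z=Z, n_sim=50, seed=0) <= 1


# ------------------------------------------------------------------ indices


def test_indices_match_brute_force_on_small_instances():
    rng = np.random.default_rng(3)
    X = np.vstack([
        rng.standard_normal((10, 3)),
        rng.standard_normal((9, 3)) + 4.0,
        rng.standard_normal((8, 3)) - 4.0,
    ])
    labels = np.repeat([0, 1, 2], [10, 9, 8])
    got = internal_indices(X, labels)
    assert got["dunn"] == pytest.approx(brute_dunn(X, labels), abs=1e-12)
    assert got["silhouette"] == pytest.approx(brute_silhouette(X, labels), abs=1e-12)
    assert got["connectivity"] == pytest.approx(brute_connectivity(X, labels), abs=1e-12)


def test_indices_on_clean_versus_split_clusters():
    rng = np.random.default_rng(4)
    X = np.vstack([rng.standard_normal((15, 2)), rng.standard_normal((15, 2)) + 50.0])
    good = np.repeat([0, 1], 15)
    idx = internal_indices(X, good)
    assert idx["silhouette"] > 0.95
    assert idx["connectivity"] == 0.0
    assert idx["dunn"] > 5.0
    # splitting one tight cluster arbitrarily in half is a bad partition
    one = rng.standard_normal((20, 2))
    arbitrary = np.tile([0, 1], 10)
    assert brute_silhouette(one, arbitrary) < 0.1
    assert internal_indices(one, arbitrary)["silhouette"] < 0.1


def test_index_label_permutation_invariance(toy_blobs):
    X, labels = toy_blobs
    perm = (labels + 2) % 4
    a, b = internal_indices(X, labels), internal_indices(X, perm)
    for key in a:
        assert a[key] == pytest.approx(b[key], abs=1e-12)


# ---------------------------------------------------------------- clustering


def test_separated_blobs_recovered_exactly(toy_blobs):
    X, labels = toy_blobs
    est = MicaClusterer(k=4, n_components=4, random_state=0).fit(X)
    assert best_label_agreement(labels, est.labels_) == 1.0


def test_duplication_invariance(toy_blobs):
    X, labels = toy_blobs
    est1 = MicaClusterer(k=4, n_components=3, random_state=0).fit(X)
    est2 = MicaClusterer(k=4, n_components=3, random_state=0).fit(np.vstack([X, X]))
    c1 = est1.centroids_.to_numpy()
    c2 = est2.centroids_.to_numpy()
    # same centroid set up to row permutation
    d = np.linalg.norm(c1[:, None] - c2[None, :], axis=2)
    assert d.min(axis=1).max() < 1e-8


def test_seeded_determinism(smokers):
    a = MicaClusterer(random_state=11, restarts=10).fit(smokers.data)
    b = MicaClusterer(random_state=11, restarts=10).fit(smokers.data)
    assert np.array_equal(a.labels_, b.labels_)
    assert a.n_components_ == b.n_components_


def test_chain_recovers_generating_partition(smokers, fitted):
    truth = smokers.true_cluster.to_numpy() - 1
    assert best_label_agreement(truth, fitted.labels_) >= 0.90
    assert fitted.n_components_ == 7


def test_invalid_k_rejected(toy_blobs):
    X, _ = toy_blobs
    with pytest.raises(ValueError):
        MicaClusterer(k=1).fit(X)
    with pytest.raises(ValueError):
        MicaClusterer(k=len(X) + 1).fit(X)


def test_method_comparison_table(smokers):
    table = compare_methods(smokers.data, k=4, restarts=5, seed=0)
    assert list(table.index) == ["kmeans", "hierarchical", "gmm"]
    assert table.notna().all().all()


# ----------------------------------------------------------------- stability


def test_jaccard_perfect_on_separated_blobs(toy_blobs):
    X, _ = toy_blobs
    est = MicaClusterer(k=4, n_components=3, restarts=10, random_state=0)
    rep = jaccard_stability(X, est, B=20, seed=0)
    assert rep.mean_jaccard.min() > 0.95
    assert rep.dissolution_count.sum() == 0


def test_jaccard_unstable_for_forced_split_of_one_gaussian():
    rng = np.random.default_rng(5)
    X = rng.standard_normal((200, 10))
    est = MicaClusterer(k=2, n_components=10, restarts=10, random_state=0)
    rep = jaccard_stability(X, est, B=30, seed=0)
    assert rep.mean_jaccard.mean() < 0.75


def test_split_half_validation_agrees_on_separable_cohort(smokers):
    est = MicaClusterer(restarts=10, n_components=7)
    agreement = split_half_validation(smokers.data, est, seed=0)
    assert agreement >= 0.85


def test_select_k_prefers_four_on_default_cohort(smokers):
    best, table = select_k(smokers.data, restarts=10, seed=0)
    assert best == 4
    assert set(table.columns) == {"connectivity", "dunn", "silhouette"}
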