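"""Independent brute-force oracles used to validate the validity indices
and Wilks' lambda on small instances (exhaustive pairwise computations)."""

import numpy as np


def brute_dunn(X, labels):
    n = len(X)
    d = np.linalg.norm(X[:, None] - X[None, :], axis=2)
    inter = min(d[i, j] for i in range(n) for j in range(n) if labels[i] != labels[j])
    intra = max(
        (d[i, j] for i in range(n) for j in range(n) if labels[i] == labels[j]),
        default=0.0,
    )
    return inter / intra


def brute_silhouette(X, labels):
    n = len(X)
    d = np.linalg.norm(X[:, None] - X[None, :], axis=2)
    vals = []
    for i in range(n):
        same = [j for j in range(n) if labels[j] == labels[i] and j != i]
        a = np.mean([d[i, j] for j in same]) if same else 0.0
        b = min(
            np.mean([d[i, j] for j in range(n) if labels[j] == c])
            for c in set(labels) if c != labels[i]
        )
        vals.append(0.0 if not same else (b - a) / max(a, b))
    return float(np.mean(vals))


def brute_connectivity(X, labels, L=10):
    n = len(X)
    d = np.linalg.norm(X[:, None] - X[None, :], axis=2)
    total = 0.0
    for i in range(n):
        order = [j for j in np.argsort(d[i]) if j != i]
        for rank, j in enumerate(order[:L], start=1):
            if labels[j] != labels[i]:
                total += 1.0 / rank
    return total


def brute_wilks(X, labels):
    grand = X.mean(axis=0)
    T = sum(np.outer(x - grand, x - grand) for x in X)
    W = np.zeros_like(T)
    for g in np.unique(labels):
        mg = X[labels == g].mean(axis=0)
        W += sum(np.outer(x - mg, x - mg) for x in X[labels == g])
    return np.linalg.det(W) / np.linalg.det(T)
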