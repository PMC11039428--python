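"""Independent brute-force oracles used across the test suite.

Everything here deliberately avoids the library's own computational
paths: correlations come from explicit root-to-tip path enumeration,
likelihoods from dense textbook linear algebra, and the ratio-variance
from Monte-Carlo simulation.
"""

from __future__ import annotations

import numpy as np


def mc_percent_change_variance(
    mean_c, sd_c, n_c, mean_a, sd_a, n_a, *, ndraws=1_000_000, seed=0
):
    """Empirical variance of 100*(c-a)/c with the two group means drawn
    from their implied normal sampling distributions."""
    rng = np.random.default_rng(seed)
    c = rng.normal(mean_c, sd_c / np.sqrt(n_c), ndraws)
    a = rng.normal(mean_a, sd_a / np.sqrt(n_a), ndraws)
    pc = 100.0 * (c - a) / c
    return float(np.var(pc, ddof=1))


def _root_paths(tree):
    """Map tip label -> list of (edge id, length) from root to tip,
    including the root edge if present."""
    paths = {}
    root = tree.seed_node
    root_len = root.edge.length if root.edge is not None and root.edge.length else 0.0
    for leaf in tree.leaf_node_iter():
        path = []
        node = leaf
        while node is not root:
            path.append((id(node), float(node.edge.length)))
            node = node.parent_node
        if root_len:
            path.append((id(root), float(root_len)))
        paths[leaf.taxon.label] = path[::-1]
    return paths


def bm_correlation_bruteforce(tree):
    """Shared root-path covariance -> correlation by direct enumeration."""
    paths = _root_paths(tree)
    labels = sorted(paths)
    n = len(labels)
    C = np.zeros((n, n))
    for i, a in enumerate(labels):
        ea = dict(paths[a])
        C[i, i] = sum(ea.values())
        for j in range(i + 1, n):
            eb = dict(paths[labels[j]])
            shared = sum(length for e, length in ea.items() if e in eb)
            C[i, j] = C[j, i] = shared
    d = np.sqrt(np.diag(C))
    return C / np.outer(d, d), labels


def pairwise_tip_distances(tree):
    """Tip-to-tip path lengths by brute-force root-path comparison."""
    paths = _root_paths(tree)
    labels = sorted(paths)
    n = len(labels)
    D = np.zeros((n, n))
    for i, a in enumerate(labels):
        ea = dict(paths[a])
        for j in range(i + 1, n):
            eb = dict(paths[labels[j]])
            d = sum(l for e, l in ea.items() if e not in eb)
            d += sum(l for e, l in eb.items() if e not in ea)
            D[i, j] = D[j, i] = d
    return D, labels


def dense_reml_loglik(y, v, X, *, study=None, R_records=None, vc=(0.0, 0.0, 0.0)):
    """Textbook REML log-likelihood with explicit dense inverses."""
    y = np.asarray(y, float)
    v = np.asarray(v, float)
    X = np.atleast_2d(np.asarray(X, float))
    n, p = X.shape
    s_study, s_within, s_phylo = vc
    M = np.diag(v) + s_within * np.eye(n)
    if study is not None:
        study = np.asarray(study)
        M = M + s_study * (study[:, None] == study[None, :])
    if R_records is not None:
        M = M + s_phylo * np.asarray(R_records, float)
    Minv = np.linalg.inv(M)
    XtMX = X.T @ Minv @ X
    P = Minv - Minv @ X @ np.linalg.inv(XtMX) @ X.T @ Minv
    return float(
        -0.5
        * (
            np.linalg.slogdet(M)[1]
            + np.linalg.slogdet(XtMX)[1]
            + y @ P @ y
            + (n - p) * np.log(2 * np.pi)
        )
    )


def wls_fit(y, v, X):
    """Weighted least squares with weights 1/v: (beta, cov_beta)."""
    y = np.asarray(y, float)
    w = 1.0 / np.asarray(v, float)
    X = np.atleast_2d(np.asarray(X, float))
    XtWX = X.T @ (X * w[:, None])
    cov = np.linalg.inv(XtWX)
    beta = cov @ (X.T @ (w * y))
    return beta, cov
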