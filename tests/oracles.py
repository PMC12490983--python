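"""Independent brute-force reference implementations used only by tests.

Everything here is written as directly as possible from the defining
formulas — explicit loops, one-hot matrices, exhaustive pair counting,
exact rational arithmetic — and deliberately shares no code with the
package paths it checks.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np


def relu(x):
    return np.maximum(x, 0.0)


# ---------------------------------------------------------------- hypergraph


def degrees_loop(H: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """d(v) = sum_e w(e) H(v,e); delta(e) = sum_v H(v,e), by double loop."""
    N, M = H.shape
    node = np.zeros(N)
    edge = np.zeros(M)
    for a in range(N):
        for b in range(M):
            node[a] += w[b] * H[a, b]
    for b in range(M):
        for a in range(N):
            edge[b] += H[a, b]
    return node, edge


def hyperedge_weights_loop(H: np.ndarray, positive_mask: np.ndarray) -> np.ndarray:
    """w(e) = (# positive members) / delta(e) by explicit membership loop."""
    N, M = H.shape
    w = np.zeros(M)
    for b in range(M):
        members = [a for a in range(N) if H[a, b] == 1]
        w[b] = sum(positive_mask[a] for a in members) / len(members)
    return w


def laplacian_dense(H: np.ndarray, w: np.ndarray) -> np.ndarray:
    node, edge = degrees_loop(H, w)
    Dv_isqrt = np.diag(1.0 / np.sqrt(node))
    De_inv = np.diag(1.0 / edge)
    W = np.diag(w)
    return np.eye(H.shape[0]) - Dv_isqrt @ H @ W @ De_inv @ H.T @ Dv_isqrt


# -------------------------------------------------------------------- model


def forward_onehot(
    H: np.ndarray,
    w: np.ndarray,
    node_deg: np.ndarray,
    embed: np.ndarray,
    b0: np.ndarray,
    theta_ve: list[np.ndarray],
    theta_ev: list[np.ndarray],
    theta_out: np.ndarray,
    b_out: np.ndarray,
) -> np.ndarray:
    """Full forward pass with an explicit one-hot input and per-entity loops."""
    N, M = H.shape
    onehot = np.eye(N)
    X = relu(onehot @ embed + b0)
    for t_ve, t_ev in zip(theta_ve, theta_ev):
        Y = np.zeros((M, embed.shape[1]))
        for e in range(M):
            acc = np.zeros(embed.shape[1])
            for v in range(N):
                if H[v, e] == 1:
                    acc += X[v] / node_deg[v]
            Y[e] = relu(acc @ t_ve)
        X_next = np.zeros_like(X)
        for v in range(N):
            acc = np.zeros(embed.shape[1])
            for e in range(M):
                if H[v, e] == 1:
                    acc += w[e] * Y[e]
            X_next[v] = relu(acc @ t_ev + X[v])
        X = X_next
    logits = X @ theta_out + b_out
    Z = np.exp(logits - logits.max(axis=1, keepdims=True))
    return Z / Z.sum(axis=1, keepdims=True)


def hgnn_layer_dense(H, w, X, theta):
    """sigma(Dv^-1/2 H W De^-1 H^T Dv^-1/2 X Theta) as a dense matrix chain."""
    node, edge = degrees_loop(H, w)
    Dv_isqrt = np.diag(1.0 / np.sqrt(node))
    return relu(Dv_isqrt @ H @ np.diag(w) @ np.diag(1.0 / edge) @ H.T @ Dv_isqrt @ X @ theta)


# ------------------------------------------------------------------ metrics


def auroc_pairs(scores, labels) -> float:
    """P(score_pos > score_neg) + 0.5 P(tie) by exhaustive pair counting."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def average_precision_sweep(scores, labels) -> float:
    """AP by sweeping every distinct score threshold (step interpolation)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    ap = 0.0
    prev_recall = 0.0
    for t in sorted(set(scores), reverse=True):
        predicted = scores >= t
        tp = int(((labels == 1) & predicted).sum())
        precision = tp / int(predicted.sum())
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


# --------------------------------------------------------------- statistics


def hypergeom_upper_tail_exact(overlap: int, universe: int, term: int, bin_size: int) -> Fraction:
    """P(X >= overlap) for X ~ Hypergeom(universe, term, bin_size), exact."""
    denom = comb(universe, bin_size)
    total = Fraction(0)
    for i in range(overlap, min(term, bin_size) + 1):
        total += Fraction(comb(term, i) * comb(universe - term, bin_size - i), denom)
    return total


def kendall_taub_pairs(x, y) -> float:
    """Tau-b by exhaustive concordant/discordant counting with tie corrections."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    concordant = discordant = ties_x = ties_y = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy = x[i] - x[j], y[i] - y[j]
            if dx == 0 and dy == 0:
                continue
            if dx == 0:
                ties_x += 1
            elif dy == 0:
                ties_y += 1
            elif dx * dy > 0:
                concordant += 1
            else:
                discordant += 1
    n0 = n * (n - 1) // 2
    tx = sum(t * (t - 1) // 2 for t in np.unique(x, return_counts=True)[1])
    ty = sum(t * (t - 1) // 2 for t in np.unique(y, return_counts=True)[1])
    return (concordant - discordant) / np.sqrt((n0 - tx) * (n0 - ty))


def bh_step_up(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted values by the textbook step-up recursion."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * m / rank_from_top)
        adjusted[i] = running_min
    return np.minimum(adjusted, 1.0)
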