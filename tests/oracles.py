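"""Independent brute-force oracles the implementation is checked against.

Everything here is written as plain loops / textbook linear algebra,
deliberately sharing no code with the package's vectorised paths.
"""

from __future__ import annotations

import math

import numpy as np


def attention_oracle(H, adj, weight, a_left, a_right, head, heads, slope=0.0):
    """Per-head attention coefficients by exhaustive logit enumeration."""
    dh = weight.shape[1] // heads
    Wk = weight[:, head * dh : (head + 1) * dh]
    proj = H @ Wk
    L = adj.shape[0]
    alpha = np.zeros((L, L))
    for i in range(L):
        logits = {}
        for j in range(L):
            if adj[i, j]:
                z = float(a_left @ proj[i] + a_right @ proj[j])
                logits[j] = z if z > 0 else slope * z
        m = max(logits.values())
        exps = {j: math.exp(v - m) for j, v in logits.items()}
        total = sum(exps.values())
        for j, v in exps.items():
            alpha[i, j] = v / total
    return alpha


def gat_layer_oracle(H, adj, layer, heads, slope=0.0):
    """Full GAT layer: per-head aggregation, activation, concat, layer norm."""
    W = layer.weight.data
    dh = W.shape[1] // heads
    outs = []
    for k in range(heads):
        alpha = attention_oracle(
            H, adj, W, layer.attn_left.data[k], layer.attn_right.data[k], k, heads, slope
        )
        agg = alpha @ (H @ W[:, k * dh : (k + 1) * dh])
        outs.append(np.maximum(agg, 0) if slope == 0 else np.where(agg > 0, agg, slope * agg))
    h = np.hstack(outs)
    mu = h.mean(axis=1, keepdims=True)
    var = h.var(axis=1, keepdims=True)
    return (h - mu) / np.sqrt(var + 1e-5) * layer.gain.data + layer.offset.data


def gcn_layer_oracle(H, adj, weight, slope=0.0):
    """sigma(D^-1/2 A D^-1/2 H W) with explicitly materialised matrices."""
    A = np.asarray(adj, dtype=float)
    d_inv_sqrt = np.diag(1.0 / np.sqrt(A.sum(axis=1)))
    out = d_inv_sqrt @ A @ d_inv_sqrt @ H @ weight
    return np.maximum(out, 0) if slope == 0 else np.where(out > 0, out, slope * out)


def auc_pair_oracle(scores, labels):
    """(wins + half-ties) / (P*N) by exhaustive pair counting."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def confusion_oracle(scores, labels, threshold):
    """(tp, fp, tn, fn) counted one sample at a time at strict > threshold."""
    tp = fp = tn = fn = 0
    for s, y in zip(scores, labels):
        called = s > threshold
        if y == 1:
            tp, fn = tp + called, fn + (not called)
        else:
            fp, tn = fp + called, tn + (not called)
    return tp, fp, tn, fn


def mcc_oracle(tp, fp, tn, fn):
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return (tp * tn - fp * fn) / denom if denom else 0.0


def contact_probability_oracle(bins, lo=1, hi=13):
    """Per-pair loop over the inclusive short-range bin window."""
    L = bins.shape[0]
    C = np.zeros((L, L))
    for i in range(L):
        for j in range(L):
            C[i, j] = sum(bins[i, j, n] for n in range(lo, hi + 1))
    return C


def random_graph(rng, n_nodes, width, edge_prob=0.4):
    """A random symmetric self-looped adjacency plus node features."""
    upper = np.triu(rng.random((n_nodes, n_nodes)) < edge_prob, k=1)
    adj = (upper | upper.T).astype(float)
    np.fill_diagonal(adj, 1.0)
    return rng.normal(size=(n_nodes, width)), adj
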