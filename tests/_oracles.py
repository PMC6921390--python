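"""Independent scalar-loop reference implementations used as test oracles.

Everything here is written with explicit Python loops over plain floats /
small numpy arrays and never calls the package's autograd path, so agreement
between the two is a meaningful check.
"""

from __future__ import annotations

import math

import numpy as np


def sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def softmax_vec(scores) -> list[float]:
    m = max(scores)
    exps = [math.exp(s - m) for s in scores]
    z = sum(exps)
    return [e / z for e in exps]


def embed_code(stacked: np.ndarray, window_sizes, weights, biases) -> list[float]:
    """CNN code embedding: per (window, filter) ReLU conv then max pool.

    `weights[h]` is (m, h, k), `biases[h]` is (m,); feature order is window
    size ascending then filter index ascending.
    """
    n, k = stacked.shape
    feats = []
    for h in sorted(window_sizes):
        m = weights[h].shape[0]
        for j in range(m):
            fmap = []
            for i in range(n - h + 1):
                acc = biases[h][j]
                for a in range(h):
                    for b in range(k):
                        acc += weights[h][j, a, b] * stacked[i + a, b]
                fmap.append(max(acc, 0.0))
            feats.append(max(fmap))
    return feats


def gru_step(v, h_prev, p) -> list[float]:
    """One GRU step; p maps names W_z..b_h to numpy arrays (in,out)/(g,g)."""
    g = len(h_prev)
    d = len(v)
    z, r, hh, out = [], [], [], []
    for j in range(g):
        az = p["b_z"][j] + sum(v[i] * p["W_z"][i, j] for i in range(d)) \
            + sum(h_prev[i] * p["U_z"][i, j] for i in range(g))
        ar = p["b_r"][j] + sum(v[i] * p["W_r"][i, j] for i in range(d)) \
            + sum(h_prev[i] * p["U_r"][i, j] for i in range(g))
        z.append(sigmoid(az))
        r.append(sigmoid(ar))
    for j in range(g):
        ah = p["b_h"][j] + sum(v[i] * p["W_h"][i, j] for i in range(d)) \
            + r[j] * sum(h_prev[i] * p["U_h"][i, j] for i in range(g))
        hh.append(math.tanh(ah))
    for j in range(g):
        out.append(z[j] * h_prev[j] + (1.0 - z[j]) * hh[j])
    return out


def gru_sequence(vs, p, g: int) -> list[list[float]]:
    h = [0.0] * g
    states = []
    for v in vs:
        h = gru_step(v, h, p)
        states.append(h)
    return states


def location_attention(states, w_alpha, b_alpha):
    """Returns (weights, context) for a list of g-vectors."""
    scores = [sum(h[i] * w_alpha[i] for i in range(len(h))) + b_alpha
              for h in states]
    weights = softmax_vec(scores)
    g = len(states[0])
    context = [sum(weights[t] * states[t][i] for t in range(len(states)))
               for i in range(g)]
    return weights, context


def graph_attention(ancestors: dict[int, list[int]], emb: np.ndarray,
                    u_a, W_a, b_a) -> np.ndarray:
    """Explicit-loop ancestor attention; emb is (n_nodes, d)."""
    l = len(u_a)
    d = emb.shape[1]
    n_leaves = len(ancestors)
    G = np.zeros((n_leaves, d))
    for i in range(n_leaves):
        scores = []
        for j in ancestors[i]:
            pair = list(emb[i]) + list(emb[j])
            acc = 0.0
            for a in range(l):
                s = b_a[a] + sum(W_a[b, a] * pair[b] for b in range(2 * d))
                acc += u_a[a] * math.tanh(s)
            scores.append(acc)
        weights = softmax_vec(scores)
        for w, j in zip(weights, ancestors[i]):
            G[i] += w * emb[j]
    return G


def retain_context(vs, alpha_states, beta_states, w_alpha, b_alpha,
                   W_beta, b_beta) -> list[float]:
    t = len(vs)
    d = len(vs[0])
    g = len(alpha_states[0])
    scores = [sum(h[i] * w_alpha[i] for i in range(g)) + b_alpha
              for h in alpha_states]
    alphas = softmax_vec(scores)
    betas = []
    for h in beta_states:
        betas.append([math.tanh(b_beta[j] + sum(h[i] * W_beta[i, j]
                                                for i in range(g)))
                      for j in range(d)])
    return [sum(alphas[i] * betas[i][j] * vs[i][j] for i in range(t))
            for j in range(d)]


def top_k(yhat, k: int) -> list[int]:
    """Full sort, ties broken toward the lower label index."""
    order = sorted(range(len(yhat)), key=lambda i: (-yhat[i], i))
    return order[:k]


def visit_precision_at_k(yhat, true_labels, k: int) -> float:
    top = set(top_k(yhat, k))
    return len(top & set(true_labels)) / min(k, len(set(true_labels)))


def code_accuracy_at_k(pairs, k: int) -> float:
    hits = total = 0
    for yhat, true_labels in pairs:
        top = set(top_k(yhat, k))
        for lab in true_labels:
            hits += int(lab in top)
            total += 1
    return hits / total


def frequency_groups(counts: list[int]) -> dict[int, str]:
    """Rank-and-slice quartile binning, rarest quarter first."""
    order = sorted(range(len(counts)), key=lambda i: (counts[i], i))
    names = ("0-25", "25-50", "50-75", "75-100")
    chunks = np.array_split(np.asarray(order), 4)
    out = {}
    for name, chunk in zip(names, chunks):
        for lab in chunk:
            out[int(lab)] = name
    return out


def numeric_grad(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central finite differences of scalar-valued f() w.r.t. array x in place."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        fp = f()
        x[i] = orig - eps
        fm = f()
        x[i] = orig
        g[i] = (fp - fm) / (2 * eps)
    return g
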