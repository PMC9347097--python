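"""Independent reference implementations used as test oracles.

Deliberately written with different idioms (plain Python loops, closed-form
least squares, unmasked textbook attention) than the package code they
check, so agreement is evidence rather than tautology.
"""

from __future__ import annotations

import numpy as np


# -- naive BPE trainer ------------------------------------------------------
def naive_bpe(corpus, threshold):
    """O(T * corpus) reference BPE: recount everything from scratch each
    iteration, pick the most frequent pair (lexicographic tie-break), stop
    when the best frequency drops below 2."""
    seqs = [tuple(s) for s in corpus]
    merges = []
    for _ in range(threshold):
        freq = {}
        for seq in seqs:
            for i in range(len(seq) - 1):
                pair = (seq[i], seq[i + 1])
                freq[pair] = freq.get(pair, 0) + 1
        ranked = sorted(freq.items(), key=lambda kv: (-kv[1], kv[0]))
        if not ranked or ranked[0][1] < 2:
            break
        pair = ranked[0][0]
        merges.append(pair)
        new_seqs = []
        for seq in seqs:
            out, i = [], 0
            while i < len(seq):
                if i + 1 < len(seq) and (seq[i], seq[i + 1]) == pair:
                    out.append(seq[i] + seq[i + 1])
                    i += 2
                else:
                    out.append(seq[i])
                    i += 1
            new_seqs.append(tuple(out))
        seqs = new_seqs
    return merges


# -- concordance index ------------------------------------------------------
def brute_force_ci(y_true, y_pred):
    """Enumerate every ordered pair with strictly greater true affinity."""
    total, n_pairs = 0.0, 0
    n = len(y_true)
    for i in range(n):
        for j in range(n):
            if y_true[i] > y_true[j]:
                n_pairs += 1
                diff = y_pred[i] - y_pred[j]
                if diff > 0:
                    total += 1.0
                elif diff == 0:
                    total += 0.5
    return total / n_pairs


# -- r2m via two explicit least-squares fits --------------------------------
def two_ols_r2m(y_true, y_pred):
    """r2 from OLS with intercept; r2_0 from through-origin OLS."""
    y = np.asarray(y_true, float)
    t = np.asarray(y_pred, float)
    X = np.column_stack([np.ones_like(t), t])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum((y - X @ beta) ** 2) / ss_tot
    k, *_ = np.linalg.lstsq(t[:, None], y, rcond=None)
    r20 = 1.0 - np.sum((y - k[0] * t) ** 2) / ss_tot
    return r2 * (1.0 - np.sqrt(max(r2 - r20, 0.0)))


# -- textbook attention -----------------------------------------------------
def softmax(x, axis=-1):
    z = np.exp(x - x.max(axis=axis, keepdims=True))
    return z / z.sum(axis=axis, keepdims=True)


def vanilla_attention(E, W_Q, W_K, W_V):
    """Unmasked single-head scaled dot-product attention."""
    Q, K, V = E @ W_Q, E @ W_K, E @ W_V
    weights = softmax(Q @ K.T / np.sqrt(W_Q.shape[1]))
    return weights @ V


def vanilla_mha_block(E, heads, ln1, ffn, ln2):
    """Standard Transformer encoder block with concatenated heads, residual
    + LayerNorm, one ReLU feed-forward layer, residual + LayerNorm.

    ``heads`` is a list of (W_Q, W_K, W_V); ``ln1``/``ln2`` are (gamma,
    beta); ``ffn`` is (W, b).
    """

    def layernorm(x, gamma, beta, eps=1e-5):
        mu = x.mean(-1, keepdims=True)
        var = ((x - mu) ** 2).mean(-1, keepdims=True)
        return (x - mu) / np.sqrt(var + eps) * gamma + beta

    out = np.concatenate([vanilla_attention(E, *h) for h in heads], axis=-1)
    Z = layernorm(out + E, *ln1)
    F = np.maximum(Z @ ffn[0] + ffn[1], 0.0)
    return layernorm(Z + F, *ln2)
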