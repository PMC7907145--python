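"""Independent brute-force oracles used by the test suite.

These deliberately re-derive every quantity with literal loops and closed
forms, independent of the package implementations they check.
"""

from __future__ import annotations

import cmath
import math

import numpy as np


def fuzzyen_bruteforce(u, m: int, n: float, r: float) -> float:
    """Literal fuzzy-entropy computation: embeddings with their window mean
    removed, pairwise Chebyshev distances, exponential memberships, and the
    log-ratio of the mean similarity at dimensions m and m+1 (both averaged
    over the first N - m vectors)."""
    u = [float(v) for v in u]
    big_n = len(u)
    n_vec = big_n - m

    def phi(dim: int) -> float:
        vectors = []
        for i in range(n_vec):
            seg = [u[i + p] for p in range(dim)]
            baseline = sum(seg) / dim
            vectors.append([s - baseline for s in seg])
        total = 0.0
        for i in range(n_vec):
            inner = 0.0
            for j in range(n_vec):
                if j == i:
                    continue
                dist = max(abs(vectors[i][p] - vectors[j][p]) for p in range(dim))
                inner += math.exp(-(dist**n) / r)
            total += inner / (n_vec - 1)
        return total / n_vec

    return math.log(phi(m)) - math.log(phi(m + 1))


def dft_direct(x) -> np.ndarray:
    """O(N^2) definition of the DFT: X(k) = sum_n x(n) exp(-2i pi nk / N)."""
    x = list(x)
    big_n = len(x)
    out = []
    for k in range(big_n):
        acc = 0j
        for idx, val in enumerate(x):
            acc += val * cmath.exp(-2j * math.pi * idx * k / big_n)
        out.append(acc)
    return np.array(out)


def welch_t(a, b) -> tuple:
    """Closed-form Welch t statistic and degrees of freedom."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    va = a.var(ddof=1) / len(a)
    vb = b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return t, df


def conv_size(n: int, f: int, p: int, s: int) -> float:
    return (n + 2 * p - f) / s + 1


def pool_size(n: int, f: int, s: int) -> float:
    return (n - f) / s + 1


def conv_param_count(c_in: int, c_out: int, k: int = 3) -> int:
    return (c_in * k * k + 1) * c_out


def dense_param_count(n_in: int, n_out: int) -> int:
    return (n_in + 1) * n_out


def lstm_param_count(n_in: int, hidden: int) -> int:
    return 4 * (n_in * hidden + hidden * hidden + hidden)


def lstm_step(x, h_prev, c_prev, w_i, w_f, w_c, w_o, b_i, b_f, b_c, b_o):
    """One LSTM step from the gate equations, on concatenated [h, x].

    Returns (h_t, c_t) computed with plain loops and math functions.
    """

    def sigmoid(z: float) -> float:
        return 1.0 / (1.0 + math.exp(-z))

    concat = list(h_prev) + list(x)
    hidden = len(h_prev)

    def gate(w, b, activation):
        out = []
        for row in range(hidden):
            acc = b[row]
            for col, val in enumerate(concat):
                acc += w[row][col] * val
            out.append(activation(acc))
        return out

    i_t = gate(w_i, b_i, sigmoid)
    f_t = gate(w_f, b_f, sigmoid)
    cbar = gate(w_c, b_c, math.tanh)
    o_t = gate(w_o, b_o, sigmoid)
    c_t = [c_prev[r] * f_t[r] + cbar[r] * i_t[r] for r in range(hidden)]
    h_t = [math.tanh(c_t[r]) * o_t[r] for r in range(hidden)]
    return np.array(h_t), np.array(c_t)
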