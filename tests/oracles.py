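"""Independent brute-force oracles used to check the fast implementations.

Everything here is written longhand (explicit sums and profile construction,
per-entry loops) and deliberately shares no code with the package internals.
"""

from __future__ import annotations

import math

import numpy as np


def pearson_longhand(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation from its defining sums, no library call."""
    t = len(x)
    mx = sum(x) / t
    my = sum(y) / t
    num = sum((x[k] - mx) * (y[k] - my) for k in range(t))
    dx = math.sqrt(sum((x[k] - mx) ** 2 for k in range(t)))
    dy = math.sqrt(sum((y[k] - my) ** 2 for k in range(t)))
    if dx == 0.0 or dy == 0.0:
        return 0.0
    return num / (dx * dy)


def lofc_longhand(data: np.ndarray) -> np.ndarray:
    t, n = data.shape
    out = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i != j:
                out[i, j] = pearson_longhand(data[:, i], data[:, j])
    return out


def thofc_longhand(w: np.ndarray) -> np.ndarray:
    """Profile-construction oracle: build both (N−2)-length profiles explicitly."""
    n = w.shape[0]
    out = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            keep = [k for k in range(n) if k != i and k != j]
            out[i, j] = pearson_longhand(w[i, keep], w[j, keep])
    return out


def ahofc_longhand(thofc: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Raw cross-layer profile correlations, then explicit (A + A')/2."""
    n = w.shape[0]
    raw = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            keep = [k for k in range(n) if k != i and k != j]
            raw[i, j] = pearson_longhand(thofc[i, keep], w[j, keep])
    return (raw + raw.T) / 2.0


def pooled_ttest_longhand(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided pooled-variance two-sample t statistic and p-value."""
    from scipy.stats import t as student_t

    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    sa2 = sum((v - ma) ** 2 for v in a) / (na - 1)
    sb2 = sum((v - mb) ** 2 for v in b) / (nb - 1)
    sp2 = ((na - 1) * sa2 + (nb - 1) * sb2) / (na + nb - 2)
    tstat = (ma - mb) / math.sqrt(sp2 * (1 / na + 1 / nb))
    df = na + nb - 2
    p = 2.0 * student_t.sf(abs(tstat), df)
    return tstat, p


def paired_ttest_longhand(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    from scipy.stats import t as student_t

    d = np.asarray(a, float) - np.asarray(b, float)
    n = len(d)
    md = d.mean()
    sd = math.sqrt(sum((v - md) ** 2 for v in d) / (n - 1))
    tstat = md / (sd / math.sqrt(n))
    return tstat, 2.0 * student_t.sf(abs(tstat), n - 1)


def plain_bce_mean(yhat: np.ndarray, y: np.ndarray, eps: float = 1e-7) -> float:
    """Unweighted per-class-summed BCE averaged over samples."""
    yhat = np.clip(yhat, eps, 1 - eps)
    total = 0.0
    n, c = yhat.shape
    for s in range(n):
        for k in range(c):
            total += -(
                y[s, k] * math.log(yhat[s, k]) + (1 - y[s, k]) * math.log(1 - yhat[s, k])
            )
    return total / n


def upper_triangle_pairs_enumerated(n: int) -> list[tuple[int, int]]:
    """Row-major upper-triangle enumeration, written as the obvious double loop."""
    return [(i, j) for i in range(n) for j in range(i + 1, n)]
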