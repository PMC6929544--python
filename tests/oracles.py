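"""Independent reference implementations used only to check pestcast.

Each oracle is deliberately naive — exhaustive enumeration, dynamic
programming, pairwise counting, finite differences — and shares no code
with the implementation it validates.
"""

from itertools import combinations

import numpy as np


def brute_force_frequent(transactions, minsupport):
    """Supports of ALL itemsets meeting minsupport, by full enumeration."""
    items = sorted({i for t in transactions for i in t})
    n = len(transactions)
    out = {}
    for r in range(1, len(items) + 1):
        for combo in combinations(items, r):
            s = frozenset(combo)
            count = sum(1 for t in transactions if s <= t)
            if count / n >= minsupport:
                out[s] = count / n
    return out


def brute_force_rules(transactions, minsupport, minconfidence):
    """All rules over frequent itemsets, by enumerating every split."""
    freq = brute_force_frequent(transactions, minsupport)
    rules = {}
    for s, sup in freq.items():
        if len(s) < 2:
            continue
        for r in range(1, len(s)):
            for ante in combinations(sorted(s), r):
                a = frozenset(ante)
                conf = sup / freq[a]
                if conf >= minconfidence:
                    rules[(a, s - a)] = (sup, conf)
    return rules


def dp_optimal_sse(values, k):
    """Exact minimal within-cluster SSE over contiguous 1-D partitions.

    The 1-D k-means optimum is attained by a contiguous partition of the
    sorted values, so an O(n^2 k) dynamic program finds it exactly.
    """
    x = np.sort(np.asarray(values, float))
    n = len(x)
    pre = np.concatenate([[0.0], np.cumsum(x)])
    pre2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def cost(i, j):  # SSE of x[i:j] around its mean
        m = j - i
        s = pre[j] - pre[i]
        return (pre2[j] - pre2[i]) - s * s / m

    best = np.full((k + 1, n + 1), np.inf)
    best[0, 0] = 0.0
    for kk in range(1, k + 1):
        for j in range(kk, n + 1):
            best[kk, j] = min(best[kk - 1, i] + cost(i, j)
                              for i in range(kk - 1, j))
    return best[k, n]


def pairwise_auc(y_true, scores):
    """Concordant-pair fraction with half credit for ties."""
    y = np.asarray(y_true)
    s = np.asarray(scores, float)
    pos = s[y == 1]
    neg = s[y == 0]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


def finite_difference_gradients(loss_fn, params, step=1e-6):
    """Central finite differences of a scalar loss over a dict of arrays."""
    out = {}
    for key, block in params.blocks.items():
        fd = np.zeros_like(block)
        it = np.nditer(block, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = block[idx]
            block[idx] = orig + step
            up = loss_fn()
            block[idx] = orig - step
            down = loss_fn()
            block[idx] = orig
            fd[idx] = (up - down) / (2.0 * step)
        out[key] = fd
    return out
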