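"""Independent brute-force oracles used to pin the production code.

Everything here is written as a naive loop straight off the defining
formulas, deliberately sharing no code with the package implementation.
"""
from __future__ import annotations

import numpy as np


def naive_rank(scores, j):
    """Rank of 0-based label j: 1 + #strictly-greater + #tied-with-smaller-index."""
    r = 1
    for l in range(len(scores)):
        if scores[l] > scores[j] or (scores[l] == scores[j] and l < j):
            r += 1
    return r


def naive_coverage(scores_matrix, label_sets):
    total = 0.0
    for scores, Y in zip(scores_matrix, label_sets):
        total += max(naive_rank(scores, lab - 1) for lab in Y)
    return total / len(label_sets) - 1.0


def naive_ranking_loss(scores_matrix, label_sets):
    total = 0.0
    for scores, Y in zip(scores_matrix, label_sets):
        N = len(scores)
        Ybar = set(range(1, N + 1)) - set(Y)
        viol = 0
        for k in Y:
            for l in Ybar:
                if scores[k - 1] <= scores[l - 1]:
                    viol += 1
        total += viol / (len(Y) * len(Ybar))
    return total / len(label_sets)


def naive_average_precision(scores_matrix, label_sets):
    total = 0.0
    for scores, Y in zip(scores_matrix, label_sets):
        inner = 0.0
        for lab in Y:
            r = naive_rank(scores, lab - 1)
            above = sum(
                1 for lab2 in Y if naive_rank(scores, lab2 - 1) <= r
            )
            inner += above / r
        total += inner / len(Y)
    return total / len(label_sets)


def naive_instance_error(c, Y):
    """Pairwise exponential error by explicit pair enumeration."""
    N = len(c)
    Ybar = set(range(1, N + 1)) - set(Y)
    s = 0.0
    for k in Y:
        for l in Ybar:
            s += np.exp(-(c[k - 1] - c[l - 1]))
    return s / (len(Y) * len(Ybar))


def finite_difference(f, arrays, eps=1e-6):
    """Central finite differences of scalar f with respect to each array
    in ``arrays`` (modified in place while probing)."""
    grads = []
    for arr in arrays:
        g = np.zeros_like(arr)
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = arr[idx]
            arr[idx] = orig + eps
            fp = f()
            arr[idx] = orig - eps
            fm = f()
            arr[idx] = orig
            g[idx] = (fp - fm) / (2 * eps)
        grads.append(g)
    return grads


def random_scored_instances(rng, n_draws, max_m=50, max_n=12):
    """Random (scores, proper label sets) batches for oracle comparisons."""
    for _ in range(n_draws):
        N = int(rng.integers(2, max_n + 1))
        m = int(rng.integers(1, max_m + 1))
        scores = rng.uniform(0, 1, size=(m, N))
        # occasional exact ties to exercise the tie-break
        if rng.random() < 0.3:
            scores[rng.integers(m), rng.integers(N)] = scores[
                rng.integers(m), rng.integers(N)
            ]
        labels = []
        for _i in range(m):
            size = int(rng.integers(1, N))
            labels.append(
                frozenset(int(x) + 1 for x in rng.choice(N, size=size, replace=False))
            )
        yield scores, labels
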