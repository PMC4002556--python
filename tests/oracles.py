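"""Independent brute-force oracles used to cross-check the measure kernels.

Everything here is deliberately written as naive enumeration over raw
subjects so it shares no code path with the package implementation.
"""

import numpy as np


def expand_table(counts):
    """One (a, b) pair per counted subject."""
    counts = np.asarray(counts)
    a, b = [], []
    m = counts.shape[0]
    for i in range(m):
        for j in range(m):
            for _ in range(int(counts[i, j])):
                a.append(i + 1)
                b.append(j + 1)
    return np.array(a), np.array(b)


def rp_bruteforce(counts):
    """P(A<B) − P(B<A) by enumerating all n² cross-pairings of the two
    marginal samples (self-pairings included)."""
    a, b = expand_table(counts)
    n = len(a)
    lt = gt = 0
    for x in a:
        for y in b:
            if x < y:
                lt += 1
            elif x > y:
                gt += 1
    return (lt - gt) / (n * n)


def disorder_bruteforce(a, b):
    """Discordant proportion by enumerating all C(n,2) subject pairs."""
    n = len(a)
    dis = 0
    total = 0
    for k in range(n):
        for l in range(k + 1, n):
            total += 1
            if (a[k] - a[l]) * (b[k] - b[l]) < 0:
                dis += 1
    return dis / total


def augmented_ranks_bruteforce(counts):
    """Mean per-cell ranks from explicitly sorted subject lists."""
    counts = np.asarray(counts)
    m = counts.shape[0]
    a, b = expand_table(counts)
    n = len(a)

    def mean_ranks(primary, secondary):
        order = sorted(range(n), key=lambda k: (primary[k], secondary[k]))
        rank_of = {}
        for pos, k in enumerate(order):
            rank_of[k] = pos + 1
        sums = np.zeros((m, m))
        cnt = np.zeros((m, m))
        for k in range(n):
            sums[a[k] - 1, b[k] - 1] += rank_of[k]
            cnt[a[k] - 1, b[k] - 1] += 1
        with np.errstate(invalid="ignore"):
            return np.where(cnt > 0, sums / np.maximum(cnt, 1), np.nan)

    return mean_ranks(a, b), mean_ranks(b, a)


def rv_bruteforce(counts):
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    rx, ry = augmented_ranks_bruteforce(counts)
    occ = counts > 0
    return 6.0 / n**3 * float((counts[occ] * (rx[occ] - ry[occ]) ** 2).sum())


def rv_uniform_closed_form(m):
    """RV of the uniform m×m table: 6 (m−1)² S(m) / m⁶ with
    S(m) = Σ_{i,j} (i−j)²."""
    s = sum((i - j) ** 2 for i in range(1, m + 1) for j in range(1, m + 1))
    return 6.0 * (m - 1) ** 2 * s / m**6


def random_table(rng, m=None, n=None):
    """A random m×m table with exactly n subjects, occasionally sparse."""
    if m is None:
        m = int(rng.integers(2, 7))
    if n is None:
        n = int(rng.integers(2, 51))
    probs = rng.dirichlet(np.full(m * m, rng.choice([0.3, 1.0, 3.0])))
    return rng.multinomial(n, probs).reshape(m, m)
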