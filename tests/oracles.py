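"""Independent brute-force oracles used across the test suite.

These deliberately avoid the package's optimized code paths: plain
enumeration over subsequences, Hamming balls, order statistics and the
textbook t statistic.
"""

import itertools
import math

ALPHABET = "ACGT"


def brute_spectrum(seq: str, k: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if all(c in ALPHABET for c in w):
            counts[w] = counts.get(w, 0) + 1
    return counts


def brute_gappy(seq: str, k: int, g: int) -> dict[str, int]:
    """All position tuples i1 < ... < ik with span <= k-1+g spelling a word."""
    counts: dict[str, int] = {}
    for tup in itertools.combinations(range(len(seq)), k):
        if tup[-1] - tup[0] > k - 1 + g:
            continue
        w = "".join(seq[i] for i in tup)
        if all(c in ALPHABET for c in w):
            counts[w] = counts.get(w, 0) + 1
    return counts


def brute_mismatch(seq: str, k: int, m: int) -> dict[str, int]:
    """For every word, count contiguous instances within Hamming distance m."""
    instances = [
        seq[i : i + k]
        for i in range(len(seq) - k + 1)
        if all(c in ALPHABET for c in seq[i : i + k])
    ]
    counts: dict[str, int] = {}
    for word in map("".join, itertools.product(ALPHABET, repeat=k)):
        n = sum(
            1
            for inst in instances
            if sum(a != b for a, b in zip(word, inst)) <= m
        )
        if n:
            counts[word] = n
    return counts


def counts_to_dict(feature_names, row) -> dict[str, int]:
    return {n: int(v) for n, v in zip(feature_names, row) if v}


def brute_percentile(values, q: float) -> float:
    """Linear interpolation between order statistics, written longhand."""
    v = sorted(values)
    if len(v) == 1:
        return float(v[0])
    pos = (q / 100.0) * (len(v) - 1)
    lo = math.floor(pos)
    frac = pos - lo
    if lo + 1 >= len(v):
        return float(v[-1])
    return v[lo] + frac * (v[lo + 1] - v[lo])


def classic_paired_t(a, b) -> float:
    """Textbook paired t statistic (unbiased variance), written longhand."""
    d = [x - y for x, y in zip(a, b)]
    n = len(d)
    mean = sum(d) / n
    var = sum((x - mean) ** 2 for x in d) / (n - 1)
    return mean / math.sqrt(var / n)


def brute_nearest(train_X, train_y, point, nn: int):
    """Sorted (distance, index, label) triples for a query point."""
    dists = [
        (math.dist(point, row), i, train_y[i]) for i, row in enumerate(train_X)
    ]
    dists.sort(key=lambda t: (t[0], t[1]))
    return dists[:nn]
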