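"""Shared fixtures and independent brute-force oracles.

The oracles here recompute encodings and scores position-by-position in
pure Python, deliberately avoiding the package's vectorized code paths,
so agreement between the two is a real cross-check.
"""

from __future__ import annotations

from math import ceil, sqrt

import numpy as np
import pytest

from aoxpred.sequence_io import ALPHABET, ProteinSequence


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_sequence(rng: np.random.Generator, name: str, lo: int = 6, hi: int = 50) -> ProteinSequence:
    L = int(rng.integers(lo, hi + 1))
    return ProteinSequence(name, "".join(rng.choice(list(ALPHABET), size=L)))


# ---------------------------------------------------------------- oracles


def brute_aac(s: str) -> list[float]:
    return [s.count(a) / len(s) for a in ALPHABET]


def brute_ctd(s: str, groups: tuple[str, str, str], denom: str = "L") -> list[float]:
    """Naive content/distribution/transition recomputation for one property."""
    L = len(s)

    def group_of(c: str) -> int:
        for g, members in enumerate(groups):
            if c in members:
                return g
        raise KeyError(c)

    content = [sum(1 for c in s if c in g) / L for g in groups]

    dist: list[float] = []
    for g in range(3):
        positions = [i + 1 for i, c in enumerate(s) if group_of(c) == g]
        n = len(positions)
        if n == 0:
            dist += [0.0] * 5
        else:
            ranks = [1, ceil(0.25 * n), ceil(0.50 * n), ceil(0.75 * n), n]
            dist += [positions[r - 1] / L for r in ranks]

    bs = [0, 0, 0]
    for i in range(L - 1):
        pair = {group_of(s[i]), group_of(s[i + 1])}
        if pair == {0, 1}:
            bs[0] += 1
        elif pair == {0, 2}:
            bs[1] += 1
        elif pair == {1, 2}:
            bs[2] += 1
    d = L if denom == "L" else L - 1
    trans = [b / d for b in bs]
    return content + dist + trans


def brute_cksaap(s: str, k: int) -> dict[str, float]:
    """Naive gapped-pair enumeration; returns {pair_label: frequency}."""
    N = len(s)
    assert N >= k + 2
    counts: dict[str, int] = {}
    for p in range(N - k - 1):
        pair = s[p] + s[p + k + 1]
        counts[pair] = counts.get(pair, 0) + 1
    return {pair: c / (N - k - 1) for pair, c in counts.items()}


def brute_pearson(x, y) -> float:
    x = list(map(float, x))
    y = list(map(float, y))
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    dx = sqrt(sum((a - mx) ** 2 for a in x))
    dy = sqrt(sum((b - my) ** 2 for b in y))
    if dx == 0 or dy == 0:
        return 0.0
    return num / (dx * dy)


def brute_mrmd_scores(X, y, method: str = "mean"):
    """Double-loop MR/MD/score recomputation on a plain 2-D array."""
    X = [[float(v) for v in row] for row in X]
    n = len(X)
    f = len(X[0])
    cols = [[X[i][j] for i in range(n)] for j in range(f)]

    # min-max scale each column
    scaled = []
    for col in cols:
        lo, hi = min(col), max(col)
        span = hi - lo if hi > lo else 1.0
        scaled.append([(v - lo) / span for v in col])

    def dist(a, b):
        eu = sqrt(sum((p - q) ** 2 for p, q in zip(a, b)))
        na = sqrt(sum(p * p for p in a))
        nb = sqrt(sum(q * q for q in b))
        dot = sum(p * q for p, q in zip(a, b))
        if na == 0 and nb == 0:
            cos_sim = tan_sim = 1.0
        elif na == 0 or nb == 0:
            cos_sim = tan_sim = 0.0
        else:
            cos_sim = dot / (na * nb)
            tan_sim = dot / (na * na + nb * nb - dot)
        d = {"euclidean": eu, "cosine": 1 - cos_sim, "tanimoto": 1 - tan_sim}
        d["mean"] = (d["euclidean"] + d["cosine"] + d["tanimoto"]) / 3
        return d[method]

    mr = [abs(brute_pearson(col, y)) for col in cols]
    md = []
    for i in range(f):
        if f == 1:
            md.append(0.0)
        else:
            md.append(sum(dist(scaled[i], scaled[j]) for j in range(f) if j != i) / (f - 1))
    return mr, md, [a + b for a, b in zip(mr, md)]


def brute_auc(scores, labels01) -> float:
    """Pairwise Mann-Whitney statistic with tie correction."""
    pos = [s for s, l in zip(scores, labels01) if l == 1]
    neg = [s for s, l in zip(scores, labels01) if l == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def brute_confusion_metrics(pairs):
    """SN/SP/ACC/MCC re-derived from raw (label, prediction) pairs."""
    tp = sum(1 for t, p in pairs if t == 1 and p == 1)
    fp = sum(1 for t, p in pairs if t == 0 and p == 1)
    tn = sum(1 for t, p in pairs if t == 0 and p == 0)
    fn = sum(1 for t, p in pairs if t == 1 and p == 0)
    sn = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    acc = (tp + tn) / len(pairs) if pairs else 0.0
    den = (tp + fn) * (tp + fp) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / sqrt(den) if den else 0.0
    return sn, sp, acc, mcc
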