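"""Independent brute-force oracles used to validate the implementation.

Each oracle is written from the mathematical definition with data
structures and control flow deliberately different from the library code:
flood fill recomputes the region mean from scratch at every acceptance,
the percentile oracle interpolates between hand-sorted order statistics,
AUC counts all positive/negative pairs, the binomial interval inverts
tail probabilities by bisection, and the optimal-threshold oracle scans
every candidate exhaustively.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import binom


def flood_fill_oracle(image: np.ndarray, seed: tuple[int, int], tolerance: float) -> np.ndarray:
    """Reference seeded region growing: BFS, row-major tie-break, running mean.

    The running region-mean chromaticity is recomputed with ``np.mean``
    over the list of accepted chromaticities at every step.
    """
    image = np.asarray(image, dtype=float)
    h, w = image.shape[:2]
    sums = image.sum(axis=-1)
    mask = np.zeros((h, w), dtype=bool)
    accepted = [seed]
    mask[seed] = True

    def chroma(p):
        return image[p] / sums[p]

    def neighbors(p):
        r, c = p
        for rr, cc in ((r - 1, c), (r, c - 1), (r, c + 1), (r + 1, c)):
            if 0 <= rr < h and 0 <= cc < w:
                yield rr, cc

    frontier = list(neighbors(seed))
    seen = {seed, *frontier}
    while frontier:
        p = frontier.pop(0)  # FIFO
        if sums[p] <= 0:
            continue
        mean = np.mean([chroma(q) for q in accepted], axis=0)
        if np.linalg.norm(chroma(p) - mean) <= tolerance:
            mask[p] = True
            accepted.append(p)
            for q in neighbors(p):
                if q not in seen:
                    seen.add(q)
                    frontier.append(q)
    return mask


def percentile_oracle(values, q: float) -> float:
    """Linear interpolation between closest order statistics, by hand."""
    xs = sorted(float(v) for v in values)
    n = len(xs)
    if n == 1:
        return xs[0]
    h = (n - 1) * q / 100.0
    lo = int(np.floor(h))
    hi = min(lo + 1, n - 1)
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])


def auc_pairwise_oracle(scores, labels) -> float:
    """Mann–Whitney AUC: fraction of (pos, neg) pairs ordered correctly."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = scores[labels]
    neg = scores[~labels]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def clopper_pearson_bisection(k: int, n: int, level: float = 0.95, iters: int = 60):
    """Exact binomial interval by bisecting binomial tail probabilities."""
    alpha = 1.0 - level

    def bisect(f, target, increasing):
        lo, hi = 0.0, 1.0
        for _ in range(iters):
            mid = 0.5 * (lo + hi)
            if (f(mid) < target) == increasing:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    # Lower bound: p with P(X >= k | p) = alpha/2 (increasing in p).
    lower = 0.0 if k == 0 else bisect(lambda p: binom.sf(k - 1, n, p), alpha / 2, True)
    # Upper bound: p with P(X <= k | p) = alpha/2 (decreasing in p).
    upper = 1.0 if k == n else bisect(lambda p: binom.cdf(k, n, p), alpha / 2, False)
    return lower, upper


def optimal_threshold_scan(scores, labels):
    """Exhaustively scan distinct scores for the three optimality indices.

    Returns {index: (threshold, value)} with ties resolved to the smallest
    threshold, under the 'score >= threshold is positive' orientation.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos, neg = scores[labels], scores[~labels]
    best = {"youden": None, "liu": None, "efficiency": None}
    for t in sorted(set(scores.tolist())):
        sens = float(np.mean(pos >= t))
        spec = float(np.mean(neg < t))
        acc = (sens * len(pos) + spec * len(neg)) / len(scores)
        for name, value in (("youden", sens + spec - 1), ("liu", sens * spec),
                            ("efficiency", acc)):
            if best[name] is None or value > best[name][1] + 1e-12:
                best[name] = (t, value)
    return best
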