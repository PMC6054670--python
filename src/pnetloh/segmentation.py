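"""Circular binary segmentation of an ordered log-ratio signal.

The change-point statistic is the two-sample t statistic between an arc
``x[i:j]`` and its complement; the best arc is accepted when its
permutation p-value falls below ``alpha``, and the procedure recurses into
the resulting pieces.  Permutations shuffle tile labels with a fixed seed,
and stop early once significance is no longer attainable, which leaves the
accept/reject decision unchanged.

Arcs wrapping the ends of a chromosome are equivalent (as label
partitions) to complementary interior arcs, so scanning interior arcs with
both endpoints free covers the circular family.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def max_arc_t(x, min_width):
    """Max squared t statistic over arcs x[i:j] vs complement.

    Constraints: the arc has >= min_width tiles; each non-empty flanking
    piece (x[:i] and x[j:]) also has >= min_width tiles; the complement is
    non-empty.  Returns (t2, i, j); t2 = -1.0 when no valid arc exists.

    Uses the identity t^2 = (n - 2) * B / (T - B) with between-group sum
    of squares B = d^2 * k * m / n and total (centered) sum of squares T,
    so the inner loop needs only the cumulative sum.
    """
    n = x.size
    S = np.empty(n + 1, dtype=np.float64)
    S[0] = 0.0
    qtotal = 0.0
    for k in range(n):
        S[k + 1] = S[k] + x[k]
        qtotal += x[k] * x[k]
    total = S[n]
    T = qtotal - total * total / n  # total centered sum of squares
    inv = np.empty(n + 1, dtype=np.float64)
    inv[0] = 0.0
    for k in range(1, n + 1):
        inv[k] = 1.0 / k
    # maximizing t^2 over arcs is equivalent to maximizing B (monotone map)
    best_b = -1.0
    bi = 0
    bj = 0
    for i in range(n):
        if i != 0 and i < min_width:
            continue
        si = S[i]
        for j in range(i + min_width, n + 1):
            right = n - j
            if right != 0 and right < min_width:
                continue
            k = j - i
            m = n - k
            if m < 1:
                continue
            d = (S[j] - si) * inv[k] - (total - S[j] + si) * inv[m]
            b = d * d * k * m * inv[n]
            if b > best_b:
                best_b = b
                bi = i
                bj = j
    if best_b < 0.0:
        return -1.0, 0, 0
    resid = T - best_b
    if resid <= 1e-300:
        return 1e300, bi, bj
    return (n - 2) * best_b / resid, bi, bj


@njit(cache=True)
def perm_exceedances(x, obs_stat, n_perm, exceed_limit, min_width, seed):
    """Count permutation max-arc statistics >= obs_stat.

    Stops early once ``exceed_limit`` exceedances are reached (the final
    p-value is then guaranteed to be >= alpha).  Returns
    (exceedances, permutations_run).
    """
    np.random.seed(seed)
    y = x.copy()
    count = 0
    for p in range(n_perm):
        np.random.shuffle(y)
        s, _, _ = max_arc_t(y, min_width)
        if s >= obs_stat:
            count += 1
            if count >= exceed_limit:
                return count, p + 1
    return count, n_perm


def _split_interval(x, lo, hi, alpha, n_perm, min_width, seed_seq):
    """Recursive CBS on x[lo:hi]; returns list of (lo, hi) pieces."""
    n = hi - lo
    if n < 2 * min_width:
        return [(lo, hi)]
    stat, bi, bj = max_arc_t(x[lo:hi], min_width)
    if stat < 0:
        return [(lo, hi)]
    exceed_limit = max(1, math.ceil(alpha * (n_perm + 1)))
    child = np.random.SeedSequence(entropy=seed_seq, spawn_key=(lo, hi))
    perm_seed = int(child.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))
    count, n_done = perm_exceedances(x[lo:hi], stat, n_perm, exceed_limit,
                                     min_width, perm_seed)
    p = (count + 1) / (n_done + 1)
    if p >= alpha:
        return [(lo, hi)]
    cuts = [c for c in (lo, lo + bi, lo + bj, hi)]
    pieces = []
    for a, b in zip(cuts[:-1], cuts[1:]):
        if b > a:
            pieces.extend(_split_interval(x, a, b, alpha, n_perm, min_width, seed_seq))
    return pieces


def robust_noise_sd(x: np.ndarray) -> float:
    """Per-tile noise SD from the median absolute first difference."""
    if x.size < 2:
        return 0.0
    return 1.4826 * float(np.median(np.abs(np.diff(x)))) / math.sqrt(2.0)


def segment_signal(
    x: np.ndarray,
    alpha: float = 0.01,
    n_perm: int = 1000,
    min_width: int = 3,
    merge_tol: float = 0.05,
    undo_sd: float = 1.0,
    seed: int = 0,
) -> list[tuple[int, int]]:
    """Segment a 1-D signal; returns half-open index intervals.

    After recursive splitting, adjacent segments whose means differ by less
    than ``max(merge_tol, undo_sd * sigma_hat)`` are merged back
    (``sigma_hat`` is the robust per-tile noise SD); splits below the tile
    noise floor are more often artifacts than real copy-number steps.
    """
    x = np.ascontiguousarray(x, dtype=np.float64)
    if x.size == 0:
        return []
    if x.size < 2 * min_width:
        return [(0, x.size)]
    pieces = _split_interval(x, 0, x.size, alpha, n_perm, min_width, seed)
    pieces.sort()
    tol = max(merge_tol, undo_sd * robust_noise_sd(x))
    return _merge_pieces(x, pieces, tol)


def _merge_pieces(x, pieces, tol):
    """Iteratively merge the most similar adjacent pair under tol."""
    pieces = list(pieces)
    while len(pieces) > 1:
        means = [float(np.mean(x[a:b])) for a, b in pieces]
        diffs = [abs(means[k + 1] - means[k]) for k in range(len(means) - 1)]
        k = int(np.argmin(diffs))
        if diffs[k] >= tol:
            break
        a, _ = pieces[k]
        _, b = pieces[k + 1]
        pieces[k:k + 2] = [(a, b)]
    return pieces
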