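"""Independent brute-force oracles used only by the test suite.

Deliberately naive implementations: per-base-pair boolean masks for
interval arithmetic, a two-pass loop for the running-sum curve, and a
stdlib-erfc normal CDF with bisection inversion. None of them share code
with the package paths they check.
"""

from __future__ import annotations

import math

import numpy as np

# ---------------------------------------------------------------------------
# Normal distribution (math.erfc + bisection; no scipy)


def norm_sf(z: float) -> float:
    return 0.5 * math.erfc(z / math.sqrt(2.0))


def norm_cdf(z: float) -> float:
    return 0.5 * math.erfc(-z / math.sqrt(2.0))


def norm_isf(q: float, lo: float = -45.0, hi: float = 45.0) -> float:
    """Inverse survival function by bisection on the erfc-based CDF."""
    assert 0.0 < q < 1.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if norm_sf(mid) > q:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def two_sided_p(z: float) -> float:
    return 2.0 * norm_sf(abs(z))


# ---------------------------------------------------------------------------
# Per-bp boolean-mask interval oracle (chromosomes up to ~1e5 bp)


def masks_from_tuples(tuples, chrom_len: int) -> dict[str, np.ndarray]:
    """Rasterise (chrom, start, end) tuples onto boolean per-bp masks."""
    masks: dict[str, np.ndarray] = {}
    for chrom, start, end in tuples:
        m = masks.setdefault(chrom, np.zeros(chrom_len, dtype=bool))
        m[start:end] = True
    return masks


def runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, end) half-open pairs."""
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def mask_tuples(masks: dict[str, np.ndarray]) -> list[tuple[str, int, int]]:
    out = []
    for chrom in sorted(masks):
        out.extend((chrom, s, e) for s, e in runs(masks[chrom]))
    return out


def mask_merge(tuples, chrom_len: int) -> list[tuple[str, int, int]]:
    return mask_tuples(masks_from_tuples(tuples, chrom_len))


def mask_cluster(tuples, chrom_len: int, max_gap: int) -> list[tuple[str, int, int]]:
    out = []
    for chrom in sorted({t[0] for t in tuples}):
        mask = masks_from_tuples([t for t in tuples if t[0] == chrom], chrom_len)[chrom]
        merged: list[list[int]] = []
        for s, e in runs(mask):
            if merged and s - merged[-1][1] < max_gap:
                merged[-1][1] = e
            else:
                merged.append([s, e])
        out.extend((chrom, s, e) for s, e in merged)
    return out


def _binary_op(a_tuples, b_tuples, chrom_len: int, op) -> list[tuple[str, int, int]]:
    am = masks_from_tuples(a_tuples, chrom_len)
    bm = masks_from_tuples(b_tuples, chrom_len)
    zeros = np.zeros(chrom_len, dtype=bool)
    out = {}
    for chrom in sorted(set(am) | set(bm)):
        out[chrom] = op(am.get(chrom, zeros), bm.get(chrom, zeros))
    return mask_tuples(out)


def mask_intersect(a, b, chrom_len: int):
    return _binary_op(a, b, chrom_len, np.logical_and)


def mask_subtract(a, b, chrom_len: int):
    return _binary_op(a, b, chrom_len, lambda x, y: x & ~y)


def mask_overlap_bp(a, b, chrom_len: int) -> int:
    am = masks_from_tuples(a, chrom_len)
    bm = masks_from_tuples(b, chrom_len)
    return int(sum((am[c] & bm[c]).sum() for c in set(am) & set(bm)))


def mask_total_bp(tuples, chrom_len: int) -> int:
    return int(sum(m.sum() for m in masks_from_tuples(tuples, chrom_len).values()))


# ---------------------------------------------------------------------------
# Naive running-sum (GSEA) curve: explicit loop, no cumsum


def naive_es_curve(scores, membership) -> list[float]:
    scores = list(scores)
    membership = list(membership)
    n = len(scores)
    n_e = sum(membership)
    n_r = sum(s for s, m in zip(scores, membership) if m)
    p_hit = p_miss = 0.0
    curve = []
    for s, m in zip(scores, membership):
        if m:
            p_hit += s / n_r
        else:
            p_miss += 1.0 / (n - n_e)
        curve.append(p_hit - p_miss)
    return curve


def random_interval_tuples(rng, chrom_len: int, n_max: int = 30, chroms=("c1", "c2")):
    """A random list of raw interval tuples for oracle comparisons."""
    n = int(rng.integers(1, n_max + 1))
    out = []
    for _ in range(n):
        chrom = str(rng.choice(chroms))
        start = int(rng.integers(0, chrom_len - 1))
        length = int(rng.integers(1, max(2, chrom_len // 10)))
        out.append((chrom, start, min(start + length, chrom_len)))
    return out
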