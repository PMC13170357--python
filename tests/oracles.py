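"""Independent brute-force oracles for the pipeline's decision rules.

These deliberately use the most naive formulation available (exhaustive
window scans, all-pairs distance matrices, full enumeration of sign
assignments / group assignments) so the fast implementations can be
checked against them on small instances.
"""

from __future__ import annotations

import itertools

import numpy as np
import scipy.stats


def junction_oracle(read: str, junction: str, max_mm: int) -> tuple[int, int] | None:
    """Exhaustive scan of every offset; minimal mismatches, then minimal
    offset. Returns (offset, mismatches) or None."""
    candidates = []
    for offset in range(len(read) - len(junction) + 1):
        window = read[offset : offset + len(junction)]
        mm = sum(1 for a, b in zip(window, junction) if a != b)
        if mm <= max_mm:
            candidates.append((mm, offset))
    if not candidates:
        return None
    mm, offset = min(candidates)
    return offset, mm


def collapse_oracle(counts: dict[str, int]) -> dict[str, int]:
    """All-pairs Hamming matrix + greedy absorption by descending count
    (smallest-count barcodes absorbed first; among equally supported
    absorbers the lexicographically smaller wins), iterated to fixpoint."""
    counts = dict(counts)
    barcodes = sorted(counts)
    dist = {
        (a, b): sum(1 for x, y in zip(a, b) if x != y)
        for a in barcodes
        for b in barcodes
    }
    while True:
        order = sorted(counts, key=lambda b: (counts[b], b))
        moved = False
        for bc in order:
            if bc not in counts:
                continue
            absorbers = [
                other for other in counts
                if other != bc and dist[(bc, other)] == 1 and counts[other] > counts[bc]
            ]
            if absorbers:
                target = sorted(absorbers, key=lambda b: (-counts[b], b))[0]
                counts[target] += counts.pop(bc)
                moved = True
        if not moved:
            return counts


def near_position_oracle(positions: dict[int, int], near_bp: int = 10) -> dict[int, int]:
    """Enumerative greedy: repeatedly pick the best-supported position
    (ties: smallest coordinate), absorb everything strictly closer than
    ``near_bp``."""
    positions = dict(positions)
    out = {}
    while positions:
        best = sorted(positions, key=lambda p: (-positions[p], p))[0]
        near = [p for p in positions if abs(p - best) < near_bp]
        out[best] = sum(positions[p] for p in near)
        for p in near:
            positions.pop(p)
    return out


def signed_rank_oracle(values) -> float:
    """Exact two-sided one-sample signed-rank p by enumerating all 2^n
    sign assignments (zeros dropped, mid-ranks for ties)."""
    x = np.asarray(values, dtype=float)
    x = x[x != 0]
    n = len(x)
    ranks = scipy.stats.rankdata(np.abs(x))
    w_obs = ranks[x > 0].sum()
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(r for s, r in zip(signs, ranks) if s))
    ws = np.array(ws)
    eps = 1e-9
    p_le = np.mean(ws <= w_obs + eps)
    p_ge = np.mean(ws >= w_obs - eps)
    return float(min(1.0, 2 * min(p_le, p_ge)))


def mann_whitney_oracle(a, b) -> float:
    """Exact two-sided Mann-Whitney p by enumerating all C(n+m, n) group
    assignments of the pooled values (mid-ranks for ties)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n, m = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = scipy.stats.rankdata(pooled)
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    us = []
    for idx in itertools.combinations(range(n + m), n):
        us.append(ranks[list(idx)].sum() - n * (n + 1) / 2)
    us = np.array(us)
    eps = 1e-9
    p_le = np.mean(us <= u_obs + eps)
    p_ge = np.mean(us >= u_obs - eps)
    return float(min(1.0, 2 * min(p_le, p_ge)))
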