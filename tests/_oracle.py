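"""Independent brute-force oracles for the scanner.

Everything here is derived directly from the PQS definition with plain
nested loops and character comparisons — no regexes, no run tables, no
shared code with the implementation — so agreement between the two routes
is meaningful.
"""

from __future__ import annotations

from bisect import bisect_left
from functools import lru_cache


def oracle_score(t: int, loops: tuple[int, int, int]) -> int:
    return 24 * t - (max(loops) - min(loops))


def oracle_candidates(seq: str, params) -> list[tuple]:
    """All parses as (group_starts, t, loops, span, score) tuples."""
    n = len(seq)

    def gblock(s: int, t: int) -> bool:
        return s + t <= n and all(c == "G" for c in seq[s:s + t])

    res = []
    for t in range(params.min_g_group, n // 4 + 1):
        for s1 in range(n):
            if not gblock(s1, t):
                continue
            for l1 in range(params.loop_min, params.loop_max + 1):
                s2 = s1 + t + l1
                if not gblock(s2, t):
                    continue
                for l2 in range(params.loop_min, params.loop_max + 1):
                    s3 = s2 + t + l2
                    if not gblock(s3, t):
                        continue
                    for l3 in range(params.loop_min, params.loop_max + 1):
                        s4 = s3 + t + l3
                        span = s4 + t - s1
                        if span > params.max_length or not gblock(s4, t):
                            continue
                        loops = (l1, l2, l3)
                        res.append(((s1, s2, s3, s4), t, loops, span,
                                    oracle_score(t, loops)))
    return res


def oracle_best(seq: str, params) -> tuple | None:
    """Best parse under (score desc, span, start, t desc, layout)."""
    cands = oracle_candidates(seq, params)
    if not cands:
        return None
    return min(cands, key=lambda c: (-c[4], c[3], c[0][0], -c[1], c[0]))


def _key(c: tuple) -> tuple:
    starts, t, loops, span, score = c
    return (starts[0], span, -t, starts)


def oracle_select(seq: str, params) -> list[tuple]:
    """Thresholded optimal non-overlapping selection, canonical tie-break.

    Maximum total score over disjoint candidate sets; among optima the
    canonically earliest set (candidates ordered by start, span, -t,
    layout; earlier candidates preferred) is returned, sorted by start.
    """
    eligible = [c for c in oracle_candidates(seq, params)
                if c[4] > params.score_threshold]
    order = sorted(eligible, key=_key)
    starts = [c[0][0] for c in order]
    n = len(order)

    @lru_cache(maxsize=None)
    def total_from(frontier: int) -> int:
        best = 0
        for i in range(bisect_left(starts, frontier), n):
            c = order[i]
            if c[0][0] >= frontier:
                best = max(best, c[4] + total_from(c[0][3] + c[1]))
        return best

    chosen: list[tuple] = []
    frontier = 0
    acc = 0
    goal = total_from(0)
    for c in order:
        if c[0][0] < frontier:
            continue
        end = c[0][3] + c[1]
        if acc + c[4] + total_from(end) == goal:
            chosen.append(c)
            acc += c[4]
            frontier = end
    total_from.cache_clear()
    return sorted(chosen, key=lambda c: c[0][0])
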