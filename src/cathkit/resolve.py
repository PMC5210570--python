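"""Optimal domain-architecture resolution.

Given a list of scored domain hits on one query protein, select the subset
with maximum total score in which no residue is claimed by two hits — a
single, consistent architecture.  Hits whose regions are all single
segments form a weighted-interval-scheduling problem and are solved by the
classic O(n log n) dynamic program; as soon as any hit is discontiguous the
problem is solved exactly by branch and bound over the pairwise conflict
graph (exponential in the worst case, bounded by ``max_hits``).

Ties between equally scoring subsets are broken toward fewer hits, then the
lexicographically earliest sorted list of match IDs, so results are
deterministic.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass

from .types import HitRecord


@dataclass
class Architecture:
    chosen: list[HitRecord]
    total_score: float

    def match_ids(self) -> list[str]:
        return [h.match_id for h in self.chosen]


def _better(score_a: float, hits_a: list[HitRecord], score_b: float, hits_b: list[HitRecord]) -> bool:
    """True if solution A beats B: score, then fewer hits, then earliest IDs."""
    if score_a != score_b:
        return score_a > score_b
    if len(hits_a) != len(hits_b):
        return len(hits_a) < len(hits_b)
    return sorted(h.match_id for h in hits_a) < sorted(h.match_id for h in hits_b)


def _conflicts(a: HitRecord, b: HitRecord) -> bool:
    return a.region.overlaps(b.region)


def _validate(hits: list[HitRecord]) -> None:
    queries = {h.query_id for h in hits}
    if len(queries) > 1:
        raise ValueError(f"hits span multiple queries: {sorted(queries)}")


def _as_architecture(hits: list[HitRecord]) -> Architecture:
    chosen = sorted(hits, key=lambda h: (h.region.segments[0].start, h.match_id))
    return Architecture(chosen, sum(h.score for h in chosen))


def resolve_architecture(hits: list[HitRecord], max_hits: int = 30) -> Architecture:
    """Maximum-score pairwise-disjoint subset of ``hits`` (exact)."""
    _validate(hits)
    if not hits:
        return Architecture([], 0.0)
    if len(hits) > max_hits:
        raise ValueError(
            f"{len(hits)} hits exceeds max_hits={max_hits}; raise the bound to keep exactness"
        )
    if all(len(h.region.segments) == 1 for h in hits):
        return _resolve_intervals(hits)
    return _branch_and_bound(hits)


def _resolve_intervals(hits: list[HitRecord]) -> Architecture:
    """Weighted interval scheduling over single-segment hits."""
    order = sorted(hits, key=lambda h: (h.region.segments[0].stop, h.region.segments[0].start))
    stops = [h.region.segments[0].stop for h in order]
    # best[k]: optimal solution over the first k hits of `order`
    best: list[tuple[float, list[HitRecord]]] = [(0.0, [])]
    for k, hit in enumerate(order, start=1):
        # latest hit ending strictly before this one starts
        j = bisect.bisect_left(stops, hit.region.segments[0].start)
        take_score = best[j][0] + hit.score
        take = best[j][1] + [hit]
        skip_score, skip = best[k - 1]
        if _better(take_score, take, skip_score, skip):
            best.append((take_score, take))
        else:
            best.append((skip_score, skip))
    return _as_architecture(best[-1][1])


def _branch_and_bound(hits: list[HitRecord]) -> Architecture:
    n = len(hits)
    order = sorted(range(n), key=lambda i: -hits[i].score)
    conflict = [[_conflicts(hits[i], hits[j]) for j in range(n)] for i in range(n)]
    suffix = [0.0] * (n + 1)
    for k in range(n - 1, -1, -1):
        suffix[k] = suffix[k + 1] + hits[order[k]].score

    best_score, best = 0.0, []

    def recurse(k: int, chosen_idx: list[int], score: float) -> None:
        nonlocal best_score, best
        if score + suffix[k] < best_score:
            return
        if k == n:
            chosen = [hits[i] for i in chosen_idx]
            if _better(score, chosen, best_score, best):
                best_score, best = score, chosen
            return
        i = order[k]
        if all(not conflict[i][j] for j in chosen_idx):
            recurse(k + 1, chosen_idx + [i], score + hits[i].score)
        recurse(k + 1, chosen_idx, score)

    recurse(0, [], 0.0)
    return _as_architecture(best)


def brute_force_resolve(hits: list[HitRecord]) -> Architecture:
    """Exhaustive-subset oracle with the identical contract (|hits| <= 20).

    Enumerates every one of the 2^n subsets as a bitmask; a subset is valid
    iff valid with its lowest bit removed and that bit conflicts with none
    of the rest.
    """
    _validate(hits)
    n = len(hits)
    if n > 20:
        raise ValueError("brute force limited to 20 hits")
    conflict_bits = [
        sum(1 << j for j in range(n) if j != i and _conflicts(hits[i], hits[j])) for i in range(n)
    ]
    valid = [False] * (1 << n)
    score = [0.0] * (1 << n)
    valid[0] = True
    best_score, best = 0.0, []
    for mask in range(1, 1 << n):
        low = (mask & -mask).bit_length() - 1
        rest = mask & (mask - 1)
        valid[mask] = valid[rest] and not (conflict_bits[low] & rest)
        if not valid[mask]:
            continue
        score[mask] = score[rest] + hits[low].score
        if score[mask] >= best_score:
            subset = [hits[i] for i in range(n) if mask >> i & 1]
            if _better(score[mask], subset, best_score, best):
                best_score, best = score[mask], subset
    return _as_architecture(best)
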