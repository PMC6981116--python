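"""Independent brute-force oracles used by the test suite.

These deliberately avoid the algorithms they check: the DCJ oracle is a
uniform-cost graph search over all legal double-cut-and-join operations on
explicit adjacency states (no cycle counting), and the chaining oracle is
an exhaustive enumeration of every collinear chain (no dynamic program).
"""

from __future__ import annotations

import heapq
from itertools import combinations

from paleokaryo.homology import AnchorPair
from paleokaryo.karyotype import Karyotype

TEL = 255  # telomere sentinel in partner arrays


def genome_state(k: Karyotype, marker_index: dict[str, int]) -> bytes:
    """Encode a genome as a partner array over extremities 2i (tail) and
    2i+1 (head) of marker i."""
    n = len(marker_index)
    partner = [TEL] * (2 * n)

    def ext(fam: str, sign: int, side: str) -> int:
        i = marker_index[fam]
        tail, head = 2 * i, 2 * i + 1
        if sign >= 0:
            return tail if side == "left" else head
        return head if side == "left" else tail

    for chrom in k.chromosomes:
        for (f1, s1), (f2, s2) in zip(chrom, chrom[1:]):
            a = ext(f1, s1, "right")
            b = ext(f2, s2, "left")
            partner[a] = b
            partner[b] = a
    return bytes(partner)


def _successors(state: bytes):
    partner = list(state)
    n2 = len(partner)
    adjacencies = [(e, partner[e]) for e in range(n2)
                   if partner[e] != TEL and e < partner[e]]
    telomeres = [e for e in range(n2) if partner[e] == TEL]

    def new_state(*pairs):
        p = list(partner)
        seen = set()
        for a, b in pairs:
            seen.update((a, b))
        for a, b in pairs:
            if b == TEL:
                p[a] = TEL
            else:
                p[a] = b
                p[b] = a
        return bytes(p)

    out = []
    for (a, b), (c, d) in combinations(adjacencies, 2):
        out.append(new_state((a, c), (b, d)))
        out.append(new_state((a, d), (b, c)))
    for (a, b) in adjacencies:
        for t in telomeres:
            out.append(new_state((a, t), (b, TEL)))
            out.append(new_state((b, t), (a, TEL)))
        out.append(new_state((a, TEL), (b, TEL)))
    for t1, t2 in combinations(telomeres, 2):
        out.append(new_state((t1, t2)))
    return out


def dcj_distance_search(a: Karyotype, b: Karyotype) -> int:
    """Uniform-cost search (A* with an admissible adjacency-deficit
    heuristic) over all legal DCJ operations."""
    fams = sorted(a.families())
    assert set(fams) == b.families()
    idx = {f: i for i, f in enumerate(fams)}
    start = genome_state(a, idx)
    goal = genome_state(b, idx)
    goal_adj = {(e, goal[e]) for e in range(len(goal)) if goal[e] != TEL and e < goal[e]}

    def h(state: bytes) -> int:
        missing = sum(1 for (e, f) in goal_adj if state[e] != f)
        if missing:
            return (missing + 1) // 2
        return 0 if state == goal else 1

    dist = {start: 0}
    queue = [(h(start), 0, start)]
    while queue:
        f, g, state = heapq.heappop(queue)
        if state == goal:
            return g
        if g > dist.get(state, 1 << 30):
            continue
        for nxt in _successors(state):
            ng = g + 1
            if ng < dist.get(nxt, 1 << 30):
                dist[nxt] = ng
                heapq.heappush(queue, (ng + h(nxt), ng, nxt))
    raise AssertionError("goal unreachable: marker sets differ?")


def random_karyotype(rng, families: list[str], max_chroms: int = 2,
                     genome_id: str = "rand") -> Karyotype:
    """Random signed arrangement of ``families`` into 1..max_chroms linear
    chromosomes."""
    order = list(rng.permutation(families))
    signs = rng.choice([-1, 1], size=len(order))
    n_chrom = int(rng.integers(1, min(max_chroms, len(order)) + 1))
    cuts = sorted(rng.choice(range(1, len(order)), size=n_chrom - 1, replace=False)) \
        if n_chrom > 1 else []
    chroms = []
    prev = 0
    for cut in list(cuts) + [len(order)]:
        chroms.append(tuple((order[i], int(signs[i])) for i in range(prev, cut)))
        prev = cut
    return Karyotype(genome_id, chroms)


# ---------------------------------------------------------------------------
# exhaustive collinear chain enumeration
# ---------------------------------------------------------------------------

def best_chain_exhaustive(anchors: list[AnchorPair], max_gap: int,
                          min_genes: int = 2):
    """Highest-scoring collinear chain by explicit enumeration of every
    strictly monotone chain obeying the gap constraint; None if no chain
    with >= min_genes anchors exists."""
    n = len(anchors)
    best = None  # (score, frozenset of indices)

    def extend(chain: list[int], orient: int | None):
        nonlocal best
        if len(chain) >= min_genes:
            score = sum(anchors[i].weight for i in chain)
            key = (score, -len(chain))
            if best is None or key > best[0]:
                best = (key, list(chain))
        last = chain[-1]
        for j in range(n):
            if j in chain:
                continue
            da = anchors[j].rank_a - anchors[last].rank_a
            db = anchors[j].rank_b - anchors[last].rank_b
            if da < 1 or da > max_gap:
                continue
            for o in ((orient,) if orient is not None else (1, -1)):
                if 1 <= o * db <= max_gap:
                    chain.append(j)
                    extend(chain, o)
                    chain.pop()

    for i in range(n):
        extend([i], None)
    if best is None:
        return None
    score_key, chain = best
    return score_key[0], [anchors[i] for i in chain]
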