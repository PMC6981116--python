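"""Collinear synteny-block chaining and intragenomic syntenic depth.

Anchors on one chromosome pair are chained into maximal-score collinear
runs: strictly monotone in rank on both sides (increasing/increasing =
parallel, increasing/decreasing = antiparallel), with consecutive rank gaps
bounded by ``max_gap`` on both genomes.  Chaining is a heaviest-chain
dynamic program with iterated extraction: the best chain is removed and the
search repeated, so each anchor belongs to at most one block.  Chains with
fewer than ``min_genes`` anchors are discarded.

Nearby same-orientation blocks are merged when separated by at most
``merge_gap`` ranks on both sides.  Genome-vs-self chaining (with the
trivial diagonal removed and mirror pairs collapsed) yields segmental
duplication blocks, whose per-gene coverage depth is the polyploidy readout:
a genome whose regions typically have two intragenomic homologs (modal depth
2) derives from a triplication.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .homology import AnchorPair

DEFAULT_MAX_GAP = 20        # gene ranks, both genomes
DEFAULT_MIN_GENES = 5       # inter-genome blocks
DEFAULT_SELF_MIN_GENES = 10  # genome-vs-self blocks
DEFAULT_MERGE_GAP = 500     # gene ranks
DEFAULT_MIN_SPAN = 10_000   # bp, both sides, self blocks
DEFAULT_COVERAGE_FRAC = 0.3

PARALLEL = "parallel"
ANTIPARALLEL = "antiparallel"


@dataclass
class SyntenyBlock:
    genome_a: str
    genome_b: str
    chrom_a: str
    chrom_b: str
    anchors: list[AnchorPair]
    orientation: str

    @property
    def n_genes(self) -> int:
        return len(self.anchors)

    @property
    def score(self) -> float:
        return sum(a.weight for a in self.anchors)

    @property
    def rank_range_a(self) -> tuple[int, int]:
        ranks = [a.rank_a for a in self.anchors]
        return min(ranks), max(ranks)

    @property
    def rank_range_b(self) -> tuple[int, int]:
        ranks = [a.rank_b for a in self.anchors]
        return min(ranks), max(ranks)

    @property
    def span_a(self) -> int:
        return (max(a.end_a for a in self.anchors)
                - min(a.start_a for a in self.anchors))

    @property
    def span_b(self) -> int:
        return (max(a.end_b for a in self.anchors)
                - min(a.start_b for a in self.anchors))

    def validate(self) -> None:
        ra = [a.rank_a for a in self.anchors]
        rb = [a.rank_b for a in self.anchors]
        assert all(x < y for x, y in zip(ra, ra[1:])), "rank_a not strictly increasing"
        if self.orientation == PARALLEL:
            assert all(x < y for x, y in zip(rb, rb[1:])), "parallel block not increasing in rank_b"
        else:
            assert all(x > y for x, y in zip(rb, rb[1:])), "antiparallel block not decreasing in rank_b"


def _single_chrom_pair(anchors: Sequence[AnchorPair]) -> None:
    pairs = {(a.genome_a, a.chrom_a, a.genome_b, a.chrom_b) for a in anchors}
    if len(pairs) > 1:
        raise ValueError(
            f"anchors span multiple chromosome pairs in one chaining call: {sorted(pairs)}")


def _best_chain(anchors: list[AnchorPair], max_gap: int,
                orientation: str) -> tuple[tuple[float, int, int, int], list[int]] | None:
    """Heaviest chain under the gap constraint, one orientation.

    Returns (key, indices) where key = (score, n_anchors, -span_a, -start_a)
    is the maximized tie-break tuple; None if no anchor exists.
    """
    n = len(anchors)
    if n == 0:
        return None
    sign = 1 if orientation == PARALLEL else -1
    order = sorted(range(n), key=lambda i: (anchors[i].rank_a, sign * anchors[i].rank_b,
                                            anchors[i].gene_a, anchors[i].gene_b))
    # DP over anchors in rank_a order; state: best chain ending at i.
    best_key: list[tuple] = [None] * n  # type: ignore[list-item]
    parent: list[int] = [-1] * n
    start_a: list[int] = [0] * n
    for oi, i in enumerate(order):
        ai = anchors[i]
        cand_key = (ai.weight, 1, 0, -ai.rank_a)
        cand_parent, cand_start = -1, ai.rank_a
        for j in order[:oi]:
            aj = anchors[j]
            da = ai.rank_a - aj.rank_a
            db = sign * (ai.rank_b - aj.rank_b)
            if da < 1 or db < 1 or da > max_gap or db > max_gap:
                continue
            sj, nj, _, _ = best_key[j]
            key = (sj + ai.weight, nj + 1, -(ai.rank_a - start_a[j]), -start_a[j])
            if key > cand_key:
                cand_key, cand_parent, cand_start = key, j, start_a[j]
        best_key[i] = cand_key
        parent[i] = cand_parent
        start_a[i] = cand_start
    end = max(range(n), key=lambda i: best_key[i])
    chain: list[int] = []
    cur = end
    while cur != -1:
        chain.append(cur)
        cur = parent[cur]
    chain.reverse()
    return best_key[end], chain


def chain_anchors(anchors: Iterable[AnchorPair],
                  max_gap: int = DEFAULT_MAX_GAP,
                  min_genes: int = DEFAULT_MIN_GENES) -> list[SyntenyBlock]:
    """Chain anchors of one chromosome pair into collinear blocks.

    Determinism: ties between equal-score chains are broken toward more
    anchors, then smaller rank span, then smaller starting rank, and the
    input order is normalized internally, so permuting the input never
    changes the result.
    """
    if max_gap < 1 or min_genes < 1:
        raise ValueError("max_gap and min_genes must be >= 1")
    pool = sorted(anchors, key=lambda a: (a.rank_a, a.rank_b, a.gene_a, a.gene_b))
    if not pool:
        return []
    _single_chrom_pair(pool)
    blocks: list[SyntenyBlock] = []
    while pool:
        candidates = []
        for orient in (PARALLEL, ANTIPARALLEL):
            res = _best_chain(pool, max_gap, orient)
            if res is not None:
                candidates.append((res[0], orient, res[1]))
        if not candidates:
            break
        key, orient, idx = max(candidates, key=lambda c: c[0])
        chain = [pool[i] for i in idx]
        if len(chain) >= max(min_genes, 2) or (min_genes == 1 and len(chain) == 1):
            blk = SyntenyBlock(
                genome_a=chain[0].genome_a, genome_b=chain[0].genome_b,
                chrom_a=chain[0].chrom_a, chrom_b=chain[0].chrom_b,
                anchors=chain, orientation=orient)
            blk.validate()
            blocks.append(blk)
        used = set(idx)
        pool = [a for i, a in enumerate(pool) if i not in used]
    blocks.sort(key=lambda b: (b.rank_range_a[0], b.rank_range_b[0]))
    return blocks


def _mergeable(left: SyntenyBlock, right: SyntenyBlock, merge_gap: int) -> bool:
    if left.orientation != right.orientation:
        return False
    gap_a = right.rank_range_a[0] - left.rank_range_a[1] - 1
    if gap_a < 0 or gap_a > merge_gap:
        return False
    if left.orientation == PARALLEL:
        gap_b = right.rank_range_b[0] - left.rank_range_b[1] - 1
    else:
        gap_b = left.rank_range_b[0] - right.rank_range_b[1] - 1
    return 0 <= gap_b <= merge_gap


def merge_adjacent_blocks(blocks: Iterable[SyntenyBlock],
                          merge_gap: int = DEFAULT_MERGE_GAP) -> list[SyntenyBlock]:
    """Concatenate same-orientation, non-overlapping blocks separated by at
    most ``merge_gap`` ranks on both sides; repeated to a fixed point, so the
    result does not depend on input order."""
    blocks = sorted(blocks, key=lambda b: (b.rank_range_a[0], b.rank_range_b[0]))
    if blocks:
        _single_chrom_pair([b.anchors[0] for b in blocks])
    changed = True
    while changed:
        changed = False
        out: list[SyntenyBlock] = []
        for blk in blocks:
            if out and _mergeable(out[-1], blk, merge_gap):
                prev = out.pop()
                merged = SyntenyBlock(
                    genome_a=prev.genome_a, genome_b=prev.genome_b,
                    chrom_a=prev.chrom_a, chrom_b=prev.chrom_b,
                    anchors=prev.anchors + blk.anchors,
                    orientation=prev.orientation)
                merged.validate()
                out.append(merged)
                changed = True
            else:
                out.append(blk)
        blocks = out
    return blocks


def find_blocks(anchors: Iterable[AnchorPair],
                max_gap: int = DEFAULT_MAX_GAP,
                min_genes: int = DEFAULT_MIN_GENES,
                merge_gap: int = DEFAULT_MERGE_GAP,
                quota: int = 1) -> list[SyntenyBlock]:
    """Chain and merge anchors of one genome pair across all its chromosome
    pairs, enforcing a per-gene block quota.

    ``quota`` bounds how many blocks any single gene may occur in (1 for
    comparisons between unduplicated genomes; raise it when one side carries
    retained polyploidy copies).  Blocks are accepted in decreasing score
    order; anchors whose genes already exhausted the quota are trimmed and
    the trimmed block must still satisfy ``min_genes``.
    """
    groups: dict[tuple, list[AnchorPair]] = defaultdict(list)
    for a in anchors:
        groups[(a.genome_a, a.chrom_a, a.genome_b, a.chrom_b)].append(a)
    candidates: list[SyntenyBlock] = []
    for key in sorted(groups):
        chained = chain_anchors(groups[key], max_gap=max_gap, min_genes=min_genes)
        candidates.extend(merge_adjacent_blocks(chained, merge_gap=merge_gap))
    candidates.sort(key=lambda b: (-b.score, b.chrom_a, b.rank_range_a[0],
                                   b.chrom_b, b.rank_range_b[0]))
    used_a: Counter[str] = Counter()
    used_b: Counter[str] = Counter()
    accepted: list[SyntenyBlock] = []
    for blk in candidates:
        keep = [a for a in blk.anchors
                if used_a[a.gene_a] < quota and used_b[a.gene_b] < quota]
        if len(keep) < min_genes:
            continue
        trimmed = SyntenyBlock(blk.genome_a, blk.genome_b, blk.chrom_a, blk.chrom_b,
                               keep, blk.orientation)
        for a in keep:
            used_a[a.gene_a] += 1
            used_b[a.gene_b] += 1
        accepted.append(trimmed)
    accepted.sort(key=lambda b: (b.chrom_a, b.rank_range_a[0],
                                 b.chrom_b, b.rank_range_b[0]))
    return accepted


def self_duplications(anchors: Iterable[AnchorPair],
                      max_gap: int = DEFAULT_MAX_GAP,
                      min_genes: int = DEFAULT_SELF_MIN_GENES,
                      merge_gap: int = DEFAULT_MERGE_GAP,
                      min_span: int = DEFAULT_MIN_SPAN,
                      quota: int = 4) -> list[SyntenyBlock]:
    """Segmental-duplication blocks from a genome-vs-self anchor set.

    Gene-vs-itself anchors are dropped; mirror pairs (A-vs-B and B-vs-A) are
    collapsed to the copy whose (chrom, rank) sorts first, so every
    duplication is reported once.  Only blocks whose genomic span exceeds
    ``min_span`` on *both* sides are returned.
    """
    canonical: dict[tuple[str, str], AnchorPair] = {}
    for a in anchors:
        if a.gene_a == a.gene_b:
            continue
        key = tuple(sorted((a.gene_a, a.gene_b)))
        if key not in canonical:
            if (a.chrom_b, a.rank_b) < (a.chrom_a, a.rank_a):
                a = AnchorPair(
                    genome_a=a.genome_b, genome_b=a.genome_a,
                    gene_a=a.gene_b, gene_b=a.gene_a,
                    chrom_a=a.chrom_b, chrom_b=a.chrom_a,
                    rank_a=a.rank_b, rank_b=a.rank_a,
                    strand_concordance=a.strand_concordance, weight=a.weight,
                    start_a=a.start_b, end_a=a.end_b,
                    start_b=a.start_a, end_b=a.end_a)
            canonical[key] = a
    blocks = find_blocks(canonical.values(), max_gap=max_gap, min_genes=min_genes,
                         merge_gap=merge_gap, quota=quota)
    return [b for b in blocks if min(b.span_a, b.span_b) >= min_span]


@dataclass
class DepthProfile:
    """Per-gene intragenomic duplication coverage for one genome."""

    genome_id: str
    depth: pd.Series  # index: gene_id, values: block coverage count
    modal_depth: int
    inferred_copy_number: int
    covered_fraction: float = 0.0


def syntenic_depth(dup_blocks: Iterable[SyntenyBlock],
                   gene_table: pd.DataFrame,
                   genome_id: str,
                   coverage_frac: float = DEFAULT_COVERAGE_FRAC) -> DepthProfile:
    """Per-gene depth = number of duplication blocks covering the gene's rank
    interval on either side; the modal depth over covered genes (when enough
    of the genome is covered) + 1 estimates the ploidy-derived copy number.
    """
    genes = gene_table[gene_table["genome"] == genome_id]
    depth: dict[str, int] = {g: 0 for g in genes.index}
    by_chrom: dict[str, pd.DataFrame] = {
        str(c): sub.sort_values("rank") for c, sub in genes.groupby("chrom")}
    for blk in dup_blocks:
        covered: set[str] = set()
        for chrom, (lo, hi) in ((blk.chrom_a, blk.rank_range_a),
                                (blk.chrom_b, blk.rank_range_b)):
            sub = by_chrom.get(str(chrom))
            if sub is None:
                continue
            sel = sub[(sub["rank"] >= lo) & (sub["rank"] <= hi)]
            covered.update(sel.index)
        for g in covered:
            depth[g] += 1
    ser = pd.Series(depth, name="depth").sort_index()
    positive = ser[ser > 0]
    covered_fraction = float(len(positive)) / max(len(ser), 1)
    if len(positive) and covered_fraction >= coverage_frac:
        modal = int(positive.mode().iloc[0])
    else:
        modal = 0
    return DepthProfile(genome_id=genome_id, depth=ser, modal_depth=modal,
                        inferred_copy_number=modal + 1,
                        covered_fraction=covered_fraction)
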