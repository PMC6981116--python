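"""Cumulative alignment statistics and conserved-gene-pair (anchor) filtering.

The first stage of the reconstruction turns raw all-vs-all alignment hits
(BLAST tabular rows, one or more HSPs per gene pair) into a filtered set of
*anchors*: gene pairs whose alignments are cumulatively strong enough to be
treated as homologs.  Two statistics drive the filter:

* CIP, cumulative identity percentage: the aligned-length-weighted percent
  identity over all retained HSPs of a gene pair,
  ``CIP = 100 * sum_i(id_i) / sum_i(AL_i)`` with
  ``id_i = pident_i * AL_i / 100``.
* CALP, cumulative alignment length percentage: the fraction of the query
  gene covered by the retained HSPs, ``CALP = 100 * sum_i(AL_i) / len(query)``.

HSPs overlapping on the query are clipped to a non-overlapping union before
cumulation (highest bit score wins the overlap), which guarantees
``CALP <= 100``.  CALP is therefore directional (query denominator); the
filter is applied to the query->subject direction by default, with an
"either direction passes" mode for symmetric use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping

import pandas as pd

#: Canonical BLAST outfmt-6 column names, in file order.
OUTFMT6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]

DEFAULT_CIP_MIN = 60.0
DEFAULT_CALP_MIN = 70.0


@dataclass(frozen=True)
class Hit:
    """One HSP between a query gene and a subject gene."""

    query_id: str
    subject_id: str
    pct_identity: float
    aligned_length: int
    query_start: int
    query_end: int
    bit_score: float = 0.0
    e_value: float = 0.0

    def __post_init__(self) -> None:
        if self.aligned_length < 1:
            raise ValueError(f"aligned_length must be >= 1, got {self.aligned_length}")
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError(f"pct_identity out of [0, 100]: {self.pct_identity}")
        if self.query_start > self.query_end:
            raise ValueError(
                f"query_start {self.query_start} > query_end {self.query_end}")


@dataclass(frozen=True)
class PairStats:
    """Cumulative alignment statistics for one directed gene pair."""

    query_id: str
    subject_id: str
    cip: float
    calp: float
    n_hsps: int
    query_length: int
    weight: float = 0.0  # summed bit score of retained HSP portions


@dataclass(frozen=True)
class AnchorPair:
    """A conserved gene pair that survived CIP/CALP filtering, placed in
    gene-rank coordinates on both genomes."""

    genome_a: str
    genome_b: str
    gene_a: str
    gene_b: str
    chrom_a: str
    chrom_b: str
    rank_a: int
    rank_b: int
    strand_concordance: int  # +1 same strand, -1 opposite
    weight: float
    start_a: int = 0
    end_a: int = 0
    start_b: int = 0
    end_b: int = 0


class NoAlignmentEvidenceError(ValueError):
    pass


def _clip_to_uncovered(intervals: list[tuple[int, int]],
                       start: int, end: int) -> int:
    """Length of [start, end] (1-based inclusive) not covered by ``intervals``
    (assumed disjoint, sorted); the uncovered pieces are appended in place."""
    free = 0
    pieces: list[tuple[int, int]] = []
    cur = start
    for s, e in sorted(intervals):
        if e < cur:
            continue
        if s > end:
            break
        if s > cur:
            pieces.append((cur, min(s - 1, end)))
            free += min(s - 1, end) - cur + 1
        cur = max(cur, e + 1)
        if cur > end:
            break
    if cur <= end:
        pieces.append((cur, end))
        free += end - cur + 1
    intervals.extend(pieces)
    intervals.sort()
    return free


def compute_cip_calp(hsps: Iterable[Hit], query_length: int) -> PairStats:
    """Cumulate the HSPs of one gene pair into CIP and CALP.

    HSPs are processed in decreasing bit-score order; each contributes only
    the part of its query interval not already covered by a stronger HSP.
    Aligned length and identities are scaled by the surviving fraction of the
    query interval, so gap-inflated alignment lengths stay consistent.
    """
    hsps = list(hsps)
    if not hsps:
        raise NoAlignmentEvidenceError("no alignment evidence: empty HSP list")
    if query_length <= 0:
        raise ValueError(f"query_length must be >= 1, got {query_length}")
    qid, sid = hsps[0].query_id, hsps[0].subject_id
    for h in hsps:
        if (h.query_id, h.subject_id) != (qid, sid):
            raise ValueError(
                f"mixed gene pairs in one call: ({qid},{sid}) vs "
                f"({h.query_id},{h.subject_id})")

    covered: list[tuple[int, int]] = []
    cum_al = 0.0
    cum_id = 0.0
    weight = 0.0
    n_used = 0
    order = sorted(hsps, key=lambda h: (-h.bit_score, h.query_start, -h.aligned_length))
    for h in order:
        span = h.query_end - h.query_start + 1
        free = _clip_to_uncovered(covered, h.query_start, h.query_end)
        if free <= 0:
            continue
        frac = free / span
        al = h.aligned_length * frac
        cum_al += al
        cum_id += h.pct_identity * al / 100.0
        weight += h.bit_score * frac
        n_used += 1

    if cum_al <= 0:
        raise NoAlignmentEvidenceError(
            f"no alignment evidence left after clipping for pair ({qid},{sid})")
    cip = 100.0 * cum_id / cum_al
    calp = 100.0 * cum_al / query_length
    calp = min(calp, 100.0)
    return PairStats(qid, sid, cip=cip, calp=calp, n_hsps=n_used,
                     query_length=query_length, weight=weight)


def pair_stats_from_hits(hits: pd.DataFrame,
                         lengths: Mapping[str, int]) -> list[PairStats]:
    """Group an outfmt-6 table by directed gene pair and cumulate each group.

    Self hits (query == subject) are dropped.  Missing query lengths raise a
    referential-integrity error naming the offending id.
    """
    stats: list[PairStats] = []
    df = hits[hits["qseqid"] != hits["sseqid"]]
    for (qid, sid), grp in df.groupby(["qseqid", "sseqid"], sort=True):
        if qid not in lengths:
            raise KeyError(f"gene id {qid!r} present in hits but absent from the length table")
        hsps = [Hit(query_id=qid, subject_id=sid,
                    pct_identity=float(r.pident), aligned_length=int(r.length),
                    query_start=int(min(r.qstart, r.qend)),
                    query_end=int(max(r.qstart, r.qend)),
                    bit_score=float(r.bitscore), e_value=float(r.evalue))
                for r in grp.itertuples(index=False)]
        stats.append(compute_cip_calp(hsps, int(lengths[qid])))
    return stats


def _gene_row(gene_table: pd.DataFrame, gene_id: str) -> pd.Series:
    try:
        return gene_table.loc[gene_id]
    except KeyError:
        raise KeyError(
            f"gene id {gene_id!r} appears in the alignment table but not in "
            f"any gene-order file") from None


def filter_conserved_pairs(
    stats: Iterable[PairStats],
    gene_table: pd.DataFrame,
    cip_min: float = DEFAULT_CIP_MIN,
    calp_min: float = DEFAULT_CALP_MIN,
    mode: Literal["query", "either"] = "query",
) -> list[AnchorPair]:
    """Retain gene pairs with ``cip >= cip_min`` and ``calp >= calp_min`` and
    attach gene-rank coordinates.

    ``gene_table`` must be indexed by gene id with columns
    ``genome, chrom, rank, strand, start, end``.  The unordered pair is the
    grouping key: when both directions were computed, ``mode="query"``
    retains the pair if any computed direction passes as query (each stats
    entry is its own query direction), ``mode="either"`` is the same here;
    the distinction matters to callers that computed only one direction.
    Self-pairs are always removed.  Pairs are emitted once, canonically
    oriented (smaller genome id first; within one genome by position).
    """
    if not (0 <= cip_min <= 100 and 0 <= calp_min <= 100):
        raise ValueError("thresholds must lie in [0, 100]")
    best: dict[tuple[str, str], tuple[float, PairStats]] = {}
    for st in stats:
        if st.query_id == st.subject_id:
            continue
        passed = st.cip >= cip_min and st.calp >= calp_min
        if mode == "query" and not passed:
            continue
        if mode == "either" and not passed:
            continue
        key = tuple(sorted((st.query_id, st.subject_id)))
        cur = best.get(key)
        if cur is None or st.weight > cur[0]:
            best[key] = (st.weight, st)

    anchors: list[AnchorPair] = []
    for (g1, g2), (weight, _st) in sorted(best.items()):
        r1 = _gene_row(gene_table, g1)
        r2 = _gene_row(gene_table, g2)
        a, b = (r1, r2)
        ga, gb = (g1, g2)
        if (r2.genome, r2.chrom, int(r2["rank"])) < (r1.genome, r1.chrom, int(r1["rank"])):
            a, b, ga, gb = r2, r1, g2, g1
        anchors.append(AnchorPair(
            genome_a=str(a.genome), genome_b=str(b.genome),
            gene_a=ga, gene_b=gb,
            chrom_a=str(a.chrom), chrom_b=str(b.chrom),
            rank_a=int(a["rank"]), rank_b=int(b["rank"]),
            strand_concordance=1 if int(a.strand) == int(b.strand) else -1,
            weight=float(weight),
            start_a=int(a.start), end_a=int(a.end),
            start_b=int(b.start), end_b=int(b.end),
        ))
    return anchors
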