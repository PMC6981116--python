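"""Collinear chaining, block merging, self-duplications and syntenic depth."""

import numpy as np
import pytest

from paleokaryo.homology import AnchorPair
from paleokaryo.synteny import (ANTIPARALLEL, PARALLEL, chain_anchors,
                                merge_adjacent_blocks, self_duplications,
                                syntenic_depth)

from oracles import best_chain_exhaustive


def anchor(ra, rb, weight=1.0, genome_a="gA", genome_b="gB",
           chrom_a="c1", chrom_b="c2", bp=10_000):
    return AnchorPair(
        genome_a=genome_a, genome_b=genome_b,
        gene_a=f"a{ra}", gene_b=f"b{rb}",
        chrom_a=chrom_a, chrom_b=chrom_b, rank_a=ra, rank_b=rb,
        strand_concordance=1, weight=weight,
        start_a=ra * bp + 1, end_a=ra * bp + 3000,
        start_b=rb * bp + 1, end_b=rb * bp + 3000)


class TestChainAnchors:
    def test_diagonal_with_outlier(self):
        anchors = [anchor(i, i) for i in range(5)] + [anchor(1, 40)]
        # two anchors share rank_a=1; the diagonal one wins, outlier unchained
        blocks = chain_anchors(anchors, max_gap=20, min_genes=5)
        assert len(blocks) == 1
        blk = blocks[0]
        assert blk.orientation == PARALLEL
        assert blk.n_genes == 5
        assert [a.rank_b for a in blk.anchors] == [0, 1, 2, 3, 4]

    def test_gap_constraint_splits_below_min_genes(self):
        anchors = [anchor(i, i) for i in range(4)] + \
                  [anchor(i, i) for i in range(29, 33)]
        blocks = chain_anchors(anchors, max_gap=20, min_genes=5)
        assert blocks == []
        # the same two runs survive when min_genes allows them
        blocks = chain_anchors(anchors, max_gap=20, min_genes=4)
        assert [b.n_genes for b in blocks] == [4, 4]

    def test_antiparallel_chain(self):
        anchors = [anchor(i, 9 - i) for i in range(5)]
        blocks = chain_anchors(anchors, max_gap=20, min_genes=5)
        assert len(blocks) == 1
        assert blocks[0].orientation == ANTIPARALLEL
        assert [a.rank_b for a in blocks[0].anchors] == [9, 8, 7, 6, 5]

    def test_mixed_chromosome_pairs_rejected(self):
        with pytest.raises(ValueError, match="multiple chromosome pairs"):
            chain_anchors([anchor(0, 0), anchor(1, 1, chrom_b="c9")])

    def test_permutation_invariance(self):
        rng = np.random.default_rng(123)
        anchors = [anchor(int(a), int(b), float(w))
                   for a, b, w in zip(rng.choice(40, 12, replace=False),
                                      rng.integers(0, 40, 12),
                                      rng.uniform(1, 5, 12))]
        ref = chain_anchors(anchors, max_gap=10, min_genes=3)
        for _ in range(5):
            rng.shuffle(anchors)
            blocks = chain_anchors(list(anchors), max_gap=10, min_genes=3)
            assert [[a.gene_a for a in b.anchors] for b in blocks] == \
                   [[a.gene_a for a in b.anchors] for b in ref]

    def test_matches_exhaustive_enumeration(self):
        """DP chaining equals brute-force max-score chain search on random
        instances with <= 12 anchors (distinct weights make the optimum
        unique)."""
        rng = np.random.default_rng(2024)
        for _ in range(300):
            n = int(rng.integers(1, 13))
            ra = rng.choice(60, size=n, replace=False)
            rb = rng.integers(0, 60, size=n)
            anchors = [anchor(int(a), int(b), float(w)) for a, b, w in
                       zip(ra, rb, rng.uniform(0.5, 10, size=n))]
            gap = int(rng.integers(1, 25))
            oracle = best_chain_exhaustive(anchors, gap, min_genes=2)
            blocks = chain_anchors(anchors, max_gap=gap, min_genes=2)
            if oracle is None:
                assert blocks == []
            else:
                top = max(blocks, key=lambda b: b.score)
                assert top.score == pytest.approx(oracle[0])
                assert {a.gene_a for a in top.anchors} == \
                       {a.gene_a for a in oracle[1]}

    def test_every_block_satisfies_invariants(self):
        rng = np.random.default_rng(77)
        ra = rng.choice(200, size=80, replace=False)
        rb = rng.integers(0, 200, size=80)
        anchors = [anchor(int(a), int(b)) for a, b in zip(ra, rb)]
        for blk in chain_anchors(anchors, max_gap=20, min_genes=3):
            blk.validate()


class TestMergeBlocks:
    def _block_pair(self, offset):
        left = chain_anchors([anchor(i, i) for i in range(5)], 20, 5)[0]
        right = chain_anchors([anchor(i + offset, i + offset) for i in range(5)],
                              20, 5)[0]
        return [left, right]

    def test_merge_within_gap(self):
        merged = merge_adjacent_blocks(self._block_pair(105), merge_gap=500)
        assert len(merged) == 1
        assert merged[0].n_genes == 10

    def test_no_merge_beyond_gap(self):
        merged = merge_adjacent_blocks(self._block_pair(605), merge_gap=500)
        assert len(merged) == 2

    def test_empty_input(self):
        assert merge_adjacent_blocks([], 500) == []

    def test_opposite_orientations_never_merge(self):
        par = chain_anchors([anchor(i, i) for i in range(5)], 20, 5)[0]
        anti = chain_anchors([anchor(i + 50, 120 - i) for i in range(5)], 20, 5)[0]
        assert len(merge_adjacent_blocks([par, anti], merge_gap=500)) == 2


def _dup_anchors(n_fam=20, rank_offset=30, bp=10_000, genome="gS"):
    """Genome-vs-self anchors of a segmental duplication: families at ranks
    0..n-1 duplicated at ranks offset..offset+n-1 on the same chromosome."""
    out = []
    for i in range(n_fam):
        out.append(AnchorPair(
            genome_a=genome, genome_b=genome,
            gene_a=f"s{i}", gene_b=f"s{i + rank_offset}",
            chrom_a="c1", chrom_b="c1", rank_a=i, rank_b=i + rank_offset,
            strand_concordance=1, weight=2.0,
            start_a=i * bp + 1, end_a=i * bp + 3000,
            start_b=(i + rank_offset) * bp + 1, end_b=(i + rank_offset) * bp + 3000))
    return out


class TestSelfDuplications:
    def test_no_duplication_no_blocks(self):
        assert self_duplications([]) == []

    def test_tandem_duplication_reported_once(self):
        anchors = _dup_anchors()
        # both orders of the mirror pair present in the input
        mirrored = [AnchorPair(
            genome_a=a.genome_a, genome_b=a.genome_b, gene_a=a.gene_b,
            gene_b=a.gene_a, chrom_a=a.chrom_b, chrom_b=a.chrom_a,
            rank_a=a.rank_b, rank_b=a.rank_a, strand_concordance=1,
            weight=a.weight, start_a=a.start_b, end_a=a.end_b,
            start_b=a.start_a, end_b=a.end_a) for a in anchors]
        blocks = self_duplications(anchors + mirrored, min_genes=10,
                                   min_span=10_000)
        assert len(blocks) == 1
        assert blocks[0].n_genes == 20
        assert blocks[0].span_a > 190_000  # 20 genes at 10 kb spacing

    def test_min_span_filters_short_duplications(self):
        anchors = _dup_anchors(n_fam=12, bp=600)  # ~9.6 kb span
        assert self_duplications(anchors, min_genes=10, min_span=10_000) == []
        assert len(self_duplications(anchors, min_genes=10, min_span=5_000)) == 1


def _gene_table_for(genome, n_genes, n_chrom=1, bp=10_000):
    import pandas as pd
    rows = []
    per = n_genes // n_chrom
    for c in range(n_chrom):
        for r in range(per):
            rows.append({"genome": genome, "gene_id": f"{genome}_c{c}_{r}",
                         "chrom": f"c{c}", "rank": r, "strand": 1,
                         "start": r * bp + 1, "end": r * bp + 3000,
                         "length": 3000})
    return pd.DataFrame(rows).set_index("gene_id")


class TestSyntenicDepth:
    def test_no_blocks_means_single_copy(self):
        genes = _gene_table_for("gS", 40)
        prof = syntenic_depth([], genes, "gS")
        assert prof.modal_depth == 0
        assert prof.inferred_copy_number == 1
        assert (prof.depth == 0).all()

    @pytest.mark.parametrize("multiplier", [2, 3])
    def test_whole_genome_multiplication_depth(self, multiplier):
        """A WGD genome has modal depth 1 (copy number 2); a WGT genome has
        modal depth 2 (copy number 3).  Simulated via one multiplied
        ancestor chromosome and pipeline self-synteny."""
        from paleokaryo.homology import filter_conserved_pairs, PairStats
        from paleokaryo.karyotype import Karyotype
        from paleokaryo.scenario import apply_wgm
        import pandas as pd
        n = 30
        anc = Karyotype("anc", [tuple((f"F{i}", 1) for i in range(n))])
        poly = apply_wgm(anc, multiplier)
        rows, stats = [], []
        for ci, chrom in enumerate(poly.chromosomes):
            for r, (fam, _s) in enumerate(chrom):
                rows.append({"genome": "gP", "gene_id": f"{fam}@{ci}",
                             "chrom": f"c{ci}", "rank": r, "strand": 1,
                             "start": r * 10_000 + 1, "end": r * 10_000 + 3000,
                             "length": 3000})
        genes = pd.DataFrame(rows).set_index("gene_id")
        for i in range(n):
            copies = [f"F{i}.{c}@{c - 1}" for c in range(1, multiplier + 1)]
            for x in range(len(copies)):
                for y in range(x + 1, len(copies)):
                    stats.append(PairStats(copies[x], copies[y], cip=95.0,
                                           calp=95.0, n_hsps=1,
                                           query_length=3000, weight=60.0))
        anchors = filter_conserved_pairs(stats, genes, cip_min=60, calp_min=70)
        blocks = self_duplications(anchors, min_genes=10, min_span=10_000)
        prof = syntenic_depth(blocks, genes, "gP")
        assert prof.modal_depth == multiplier - 1
        assert prof.inferred_copy_number == multiplier
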