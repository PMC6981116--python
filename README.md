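# paleokaryo

Ancestral karyotype reconstruction from gene order and homology, for
comparative genomicists studying how modern chromosome sets arose: given a
clade of annotated genomes and their all-vs-all gene alignments, the
package rebuilds the ancestral chromosome structure as Conserved Ancestral
Regions (CARs) and protochromosomes, detects whole-genome duplications and
triplications from intragenomic synteny, and infers a fewest-rearrangement
scenario (inversions, translocations, fusions, fissions) from the ancestor
to each modern genome.  A genome-evolution simulator with a complete
ground-truth log makes the whole analysis testable without any downloads.

## The method in brief

1. **Anchors.**  Alignment HSPs of each gene pair are clipped to a
   non-overlapping query union and cumulated into
   `CIP = 100·Σᵢ idᵢ / Σᵢ ALᵢ` (length-weighted identity) and
   `CALP = 100·Σᵢ ALᵢ / len(query)` (query coverage); pairs with
   CIP ≥ 60 and CALP ≥ 70 become anchors, and gene families are the
   connected components of the anchor graph.
2. **Synteny blocks.**  Anchors on a chromosome pair are chained into
   maximal-weight collinear runs (strictly monotone gene ranks both sides,
   rank gaps ≤ 20), blocks under 5 genes discarded, nearby blocks merged
   (gap ≤ 500 ranks).  Genome-vs-self blocks (≥ 10 genes, span ≥ 10 kb on
   both copies) give each gene a *syntenic depth*; the modal depth + 1 is
   the genome's ploidy-derived copy number (2 = paleoduplication,
   3 = paleotriplication).
3. **CARs.**  Each family's two extremities (tail/head) define
   orientation-aware adjacencies; adjacencies realized in every genome
   containing both families are assembled into conflict-free linear paths
   — the CARs — which partial support (≥ half the genomes) then merges
   into protochromosomes, with telomere evidence blocking joins that look
   like lineage-restricted fusions and rescuing ends no genome shows as a
   chromosome end.
4. **Scenarios.**  Under the DCJ model, `d = N − (C + I/2)` on the
   adjacency graph (N markers, C cycles, I odd paths) lower-bounds the
   rearrangement count; a greedy sorter emits an explicit, replayable
   event list restricted to the four classical operations and reports its
   length next to the bound.

## Worked example

The repository ships a small simulated clade (three genomes, 60 gene
families, a couple of rearrangements per branch, realistic alignment
noise) in `tests/data/small_fixture/`.  A YAML file points the pipeline at
its inputs:

```yaml
genomes:
  A: tests/data/small_fixture/A.gff3
  B: tests/data/small_fixture/B.gff3
  C: tests/data/small_fixture/C.gff3
hits: tests/data/small_fixture/hits.tsv
lengths: tests/data/small_fixture/lengths.tsv
out_dir: example_out
```

```
$ paleokaryo run-all --config example.yaml
genomes: 3  genes: 180  hits: 203
gene pairs: 189  anchors: 180  inter-genome blocks: 12
families: 60 (universe 60)  adjacencies: 72
CARs: 14 at full support -> 3 protochromosomes (0 small)
inferred copy numbers: A=1, B=1, C=1
scenario ancestor->A: 4 events (fis 1, fus 2, inv 0, tra 1; DCJ lower bound 4)
scenario ancestor->B: 4 events (fis 0, fus 2, inv 2, tra 0; DCJ lower bound 4)
scenario ancestor->C: 8 events (fis 1, fus 2, inv 2, tra 3; DCJ lower bound 8)
```

Reading the report: 203 alignment rows collapse to 189 gene pairs, of
which 180 pass the CIP/CALP filter — the 9 rejected pairs are the
fixture's simulated spurious hits.  Requiring every genome's agreement
fragments the ancestor into 14 CARs; partial support re-merges them into 3
protochromosomes (the simulated ancestor had 2 chromosomes — one stem
inversion is ambiguous with only three genomes, so one true join stays
split rather than being guessed).  No genome shows elevated syntenic
depth, so all copy numbers are 1.  Each modern genome is then explained by
a replayable event list whose length here meets its DCJ lower bound.
Per-stage tables (anchors, blocks, depth profiles, adjacencies with
support counts, CARs, scenarios as JSON) are written to `out_dir`.

Stages can be run individually (`paleokaryo homology`, `synteny`,
`selfsynteny`, `cars`, `scenario`), and `paleokaryo simulate` generates
new synthetic clades with a truth log.

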