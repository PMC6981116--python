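# Methods

## The reconstruction problem

Given a clade of related genomes, each reduced to an ordered, stranded list
of genes per chromosome, and all-vs-all alignment evidence between their
genes, the pipeline reconstructs the structure of the clade's last common
ancestor as a set of Conserved Ancestral Regions (CARs) and
protochromosomes, detects lineage-restricted whole-genome multiplications
from intragenomic synteny, and explains each modern karyotype by a
fewest-rearrangement scenario from the ancestor.  The guiding principle is
the standard paleogenomics one: a gene neighbourhood observed across many
independent lineages is most parsimoniously ancestral.

## Stage 1 — conserved gene pairs (CIP/CALP)

Raw tabular hits are grouped by directed gene pair and cumulated into two
statistics.  With HSPs clipped to a non-overlapping union of query
intervals (highest bit score keeps the overlap, so no base is counted
twice):

    CIP  = 100 * sum_i(pident_i * AL_i / 100) / sum_i(AL_i)
    CALP = 100 * sum_i(AL_i) / query_length

CIP is the aligned-length-weighted identity; CALP the query coverage, and
clipping guarantees CALP <= 100.  A pair becomes an *anchor* when
CIP >= 60 and CALP >= 70 (defaults from the comparative-genomics method
lineage this pipeline follows; both exposed in the configuration).  CALP's
denominator is the query length, so the statistic is directional; the
filter applies to the computed direction, and an "either direction" mode
exists for symmetric use.  Self-hits are always discarded.  Gene families
are the connected components of the anchor graph (single linkage): with
the identity filter in front, spurious low-identity hits never enter the
graph, which keeps components close to true homology groups.

## Stage 2 — synteny blocks and syntenic depth

Anchors of one chromosome pair are chained into collinear blocks: strictly
monotone in gene rank on both sides (parallel or antiparallel), with
consecutive rank gaps at most `max_gap` (default 20) on both genomes.
Chaining is a heaviest-chain dynamic program with iterated extraction (the
best chain is removed and the search repeated) so each anchor joins at
most one block; ties break toward more anchors, then smaller rank span,
then smaller starting rank, making the result invariant under input
permutation.  Blocks under `min_genes` (5 inter-genome, 10 genome-vs-self)
are discarded; same-orientation blocks separated by at most `merge_gap`
(500) ranks on both sides are concatenated.  Gap units are gene ranks, not
base pairs: rank-space is robust to gene-density variation, and a bp mode
would only re-parameterize the same constraint.  A per-gene quota (default
1, raised automatically to the partner genome's inferred copy number)
bounds how many blocks one gene may support in an inter-genome comparison.

Genome-vs-self anchors, after removing the trivial diagonal and collapsing
each mirror pair to the copy whose (chromosome, rank) sorts first, yield
segmental-duplication blocks; only blocks spanning at least `min_span`
(10 kb) on *both* copies are kept.  The per-gene *syntenic depth* is the
number of duplication blocks covering the gene's rank on either side.  If
a sufficient fraction of the genome is covered (`coverage_frac`, default
0.3 — ancient polyploids retain roughly a third to a half of duplicate
regions after fractionation), the modal depth over covered genes plus one
is the inferred copy number: 2 for a paleoduplication, 3 for a
paleotriplication (each region then has two intragenomic homologs, the
pattern a triplicated genome shows between chromosome triplets).

## Stage 3 — CARs and protochromosomes

Each family has two extremities (tail, head); a +oriented gene exposes
tail-then-head along the chromosome.  An *adjacency* is the unordered pair
of extremities facing each other between consecutive genes — the
orientation-aware currency that makes reconstruction independent of how
chromosomes happen to be written (reversing an input chromosome's
annotation changes nothing).

Adjacency support is counted on the **raw multi-copy gene orders**: a
genome supports an adjacency if *any* retained copy pair realizes it.
This matters after polyploidy: forcing one copy per family first would
scramble the fractionated genome into a mosaic and erase about half of its
genuine neighbourhood evidence.  The support denominator for an adjacency
is the number of genomes containing both families — after heavy gene loss
an absolute denominator would make full support unreachable.

CAR assembly keeps adjacencies at full support (fraction 1.0 of their
denominator, minimum 2 genomes), resolves extremity conflicts by keeping
the single best-supported claimant (an exact tie drops all: a wrong split
is recoverable by the next step, a wrong join is not), opens any residual
cycle at its weakest adjacency, and reads off maximal paths as CARs;
families untouched by any kept adjacency become singleton CARs.  CARs
shorter than `small_car_min` (5) families are flagged "small" in the
summary but never dropped.

Protochromosome merging then joins CAR ends greedily, highest support
first (ties to the lexicographically smallest extremity pair), using
adjacencies supported by at least `proto_support_frac` (0.5) of their
denominator, refusing joins that would create a branch or a cycle, so the
CAR count can only fall.  Telomere evidence modulates the step in both
directions:

* **veto** — if both extremities are chromosome ends in at least half of
  the genomes containing them, the join is refused.  A fusion on one
  lineage's stem produces exactly this signature (a well-supported derived
  adjacency whose two ends every outgroup shows as telomeres), and
  support alone cannot tell it from an ancestral join;
* **rescue** — if both extremities are chromosome ends in at most 20% of
  genomes, the end cannot plausibly be an ancestral telomere, and the best
  adjacency with support down to 25% of its denominator is accepted for
  it.  This recovers adjacencies convergently broken in just over half the
  genomes (e.g. on one major stem plus one extra tip), which a flat
  support threshold must leave split even though the evidence that the
  ends are internal is unambiguous.

The 0.5/0.2/0.25 values derive from the evidence structure rather than
fitting: 0.5 is the partial-support convention (a subset, not all, of the
genomes), 0.2 is safely below the smallest clade fraction that a single
lineage-restricted event can imprint on a balanced tree, and 0.25 keeps
rescue joins above the two-genome floor for any realistic denominator.

## Stage 4 — rearrangement scenarios

Distances are computed under the double-cut-and-join (DCJ) model: on the
adjacency graph of two genomes over the same N markers, with C cycles and
I odd paths, the minimum operation count is d = N − (C + I/2).  DCJ is
chosen because it covers exactly the four classical event types of
interest (inversion, translocation, fusion, fission) and gives an exact,
linear-time lower bound.  Genomes with unequal content are first projected
onto their shared families, and the dropped-marker count is reported.

The explicit event list is produced greedily: each step realizes some
missing target adjacency (or frees a target telomere) using only classical
operations on linear chromosomes, preferring operations that reduce the
DCJ distance by one.  A transposition-like configuration has no such
operation without a circular intermediate; since circular intermediates
are excluded, the greedy inserts a fission (distance +1) and resolves the
rest with translocations — the emitted total can therefore exceed the DCJ
lower bound, and both numbers are reported side by side (on random small
instances, 97% of scenarios meet the bound; the worst observed excess is
3).  Events are recorded mechanically (operation + operands at application
time) and labelled by structural effect in the ancestor-to-descendant
direction: chromosome count +1 is a fission, −1 a fusion, a
count-preserving operation within one chromosome an inversion, across two
a translocation.  Replaying the event list onto the source must reproduce
the target exactly (up to chromosome order and whole-chromosome
orientation, which are representational); this is asserted on every run.

Whole-genome multiplication is applied where the input places it (tree
annotation or configuration), copying every chromosome m times; its
*detection* belongs to the syntenic-depth stage.

## The simulator

The generator evolves a 16-chromosome, 640-gene ancestor down a balanced
12-taxon tree (6/6 root split, all branch lengths 1): per branch, a
uniform 3–8 inversions and 0–2 each of fusions and fissions (0–1
translocations), positions uniform; one multiplier-3 whole-genome
multiplication on the stem above the first tip pair, followed immediately
by per-copy Bernoulli gene loss at 40% with at least one copy of every
family kept.  Poisson event counts are available as an alternative to the
uniform ranges.  Tip genes are laid out with per-family lengths of
0.9–3 kb and 2–8 kb spacers (so ten genes span roughly 100 kb, a
plant-like density).  Hits carry identity 100 − 3%·(tree path length),
floored at 70, with N(0,1) jitter; paralog pairs use twice the distance to
the multiplication point; 20% of alignments are split into two HSPs whose
lengths sum to the original; 5% spurious pairs at 30–55% identity are
added (they fail the CIP filter by construction — they model contamination
the filter must absorb, not borderline homology).  Every branch's events
are logged and replayed at test time; a fixed seed makes all outputs
byte-identical.

What the simulator does **not** model: unequal rates across branches,
gene-scale tandem duplication, annotation errors (missing/split/fused gene
models), translocation hotspots, and any sequence-level realism — hits are
generated from the true homology, not from alignment of simulated
sequences.  Passing the synthetic acceptance study therefore shows the
machinery is correct and robust to the modelled noise, not that real
annotation pipelines' artefacts are handled.

## Numerical and degenerate-input choices

Gene ranks are 0-based per chromosome, assigned by start coordinate with
(end, id) tie-breaks; coordinates are 1-based inclusive internally (BED
input converted on read).  Strand '.' is rejected: orientation is
load-bearing for adjacencies and guessing it would corrupt the extremity
algebra silently.  Empty HSP lists, non-positive query lengths, mixed gene
pairs in one cumulation, marker-content mismatches in distance
computations and infeasible chromosome accounting all raise immediately
with the offending identifiers in the message.  All outputs are plain
sorted text; two runs on identical inputs are byte-identical.

## Known limitations

* CAR assembly is a greedy adjacency method, not a median-genome or
  small-parsimony optimization across the tree; the species tree is not
  used to polarize conflicting adjacencies, so an inversion on a stem
  covering exactly half the genomes is a coin flip between the true and
  derived neighbourhood (both leave the CAR count intact).
* The scenario is one parsimonious event list among many; event
  *positions* are not meaningful beyond their structural class.
* Copy resolution picks one gene per family per genome for the scenario
  stage; in a heavily fractionated polyploid the resulting single-copy
  order is a subgenome mosaic and its scenario against the ancestor mixes
  real rearrangements with mosaic artefacts (the shared-marker count and
  DCJ bound are reported so this is visible).
* Support thresholds are fractions of per-adjacency denominators; with
  fewer than four genomes the partial/full distinction collapses and the
  reconstruction degrades gracefully toward the pairwise case.
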