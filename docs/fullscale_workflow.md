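# Reproducing the full-scale legume analysis

The numbers published for the real twelve-legume dataset (16 ancestral
CARs; 15 fissions and 21 fusions to a 9-chromosome lupin ancestor; a
triplication to n = 27; 17 major shuffling events between the two lupins;
928 intragenomic duplication blocks larger than 10 kb) depend on inputs
this repository cannot ship: twelve genome annotations totalling hundreds
of megabytes and an all-vs-all CDS alignment that takes CPU-days.  They are
also sensitive to annotation versions and aligner settings.  The automated
tests therefore validate the method on simulated clades with known ground
truth, and this note documents how to run the same pipeline on the real
data.

## Inputs to prepare

1. Gene annotations (GFF3, `gene` features with stable `ID=` attributes)
   for the twelve genomes: white lupin, narrow-leafed lupin, garden pea,
   peanut, *Lotus japonicus*, barrel medic, chickpea, pigeonpea, soybean,
   common bean, mungbean and adzuki bean.
2. All-vs-all CDS alignments in BLAST tabular format
   (`-outfmt 6`, the default twelve columns), concatenated into one file.
   Both inter-genome and genome-vs-self comparisons must be included; the
   self comparison drives the polyploidy readout.
3. CDS lengths, either as a two-column TSV (`id<TAB>length`) or the CDS
   FASTA itself.

## Configuration

```yaml
genomes:
  white_lupin: annotations/Lalbus.gff3
  narrow_leafed_lupin: annotations/Langustifolius.gff3
  garden_pea: annotations/Psativum.gff3
  peanut: annotations/Ahypogaea.gff3
  lotus: annotations/Ljaponicus.gff3
  barrel_medic: annotations/Mtruncatula.gff3
  chickpea: annotations/Carietinum.gff3
  pigeonpea: annotations/Ccajan.gff3
  soybean: annotations/Gmax.gff3
  common_bean: annotations/Pvulgaris.gff3
  mungbean: annotations/Vradiata.gff3
  adzuki_bean: annotations/Vangularis.gff3
hits: alignments/all_vs_all.outfmt6.tsv
lengths: alignments/cds_lengths.tsv
out_dir: results/legumes
cip_min: 60.0          # conserved-pair thresholds
calp_min: 70.0
max_gap: 20            # chaining: max rank distance between matches
min_genes: 5           # inter-genome blocks below 5 genes are discarded
self_min_genes: 10     # genome-vs-self blocks need 10 aligned pairs
merge_gap: 500         # max distance between blocks for merging
min_span: 10000        # self blocks must span 10 kb on both copies
quota: 1               # raised automatically against polyploid genomes
car_support_frac: 1.0
proto_support_frac: 0.5
small_car_min: 5
copy_policy: best_synteny
reference_genome: barrel_medic
```

Run with:

```
paleokaryo run-all --config legumes.yaml
```

`results/legumes/report.txt` then contains the CAR and protochromosome
counts, the per-genome fission/fusion/inversion/translocation tallies with
their DCJ lower bounds, and the inferred copy numbers (the triplication
shows up as `white_lupin=3`, `narrow_leafed_lupin=3`, soybean as `2`);
`self_blocks.white_lupin.tsv` holds the intragenomic duplication blocks
whose span filter corresponds to the published 10 kb cut-off.
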