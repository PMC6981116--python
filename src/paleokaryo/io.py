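"""Readers and writers for the pipeline's external formats.

Internal conventions, stated in every output header: genomic coordinates
are 1-based inclusive; gene ranks are 0-based ordinals along a chromosome,
assigned by start coordinate (ties broken by end, then gene id).  Strands
are restricted to ``+``/``-``: orientation is load-bearing for adjacency
reconstruction, so strandless records are rejected rather than guessed.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
import pandas as pd
from Bio import SeqIO

from .ancestor import Adjacency, CARSet
from .homology import OUTFMT6_COLUMNS, AnchorPair, PairStats
from .scenario import RearrangementScenario
from .synteny import DepthProfile, SyntenyBlock

COORD_HEADER = "# coordinates: 1-based inclusive bp; ranks: 0-based gene ordinals"


class ParseError(ValueError):
    pass


def _validate_gff3_lines(path: Path) -> None:
    seen_ids: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, "
                    f"got {len(fields)}")
            if fields[2] != "gene":
                continue
            for attr in fields[8].split(";"):
                if attr.startswith("ID="):
                    fid = attr[3:]
                    if fid in seen_ids:
                        raise ParseError(
                            f"{path}:{lineno}: duplicate gene id {fid!r}")
                    seen_ids.add(fid)


def _read_gff3_genes(path: Path, genome: str) -> list[dict]:
    _validate_gff3_lines(path)
    db = gffutils.create_db(str(path), ":memory:", force=True,
                            merge_strategy="create_unique", keep_order=True)
    rows = []
    for feat in db.features_of_type("gene"):
        if feat.strand not in ("+", "-"):
            raise ParseError(
                f"{path}: gene {feat.id!r} has strand {feat.strand!r}; "
                "orientation is required (use + or -)")
        rows.append({"genome": genome, "gene_id": feat.id, "chrom": feat.seqid,
                     "start": feat.start, "end": feat.end,
                     "strand": 1 if feat.strand == "+" else -1})
    return rows


def _read_bed6_genes(path: Path, genome: str) -> list[dict]:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(
                    f"{path}:{lineno}: BED6 needs 6 columns, got {len(fields)}")
            chrom, start, end, name, _score, strand = fields[:6]
            if strand not in ("+", "-"):
                raise ParseError(
                    f"{path}:{lineno}: gene {name!r} has strand {strand!r}; "
                    "orientation is required (use + or -)")
            rows.append({"genome": genome, "gene_id": name, "chrom": chrom,
                         # BED is 0-based half-open; internal is 1-based inclusive
                         "start": int(start) + 1, "end": int(end),
                         "strand": 1 if strand == "+" else -1})
    return rows


def read_gene_orders(paths: Mapping[str, str | Path]) -> pd.DataFrame:
    """Read per-genome gene coordinate files (GFF3 or BED6 by extension) into
    one gene table indexed by gene id, with 0-based ranks per chromosome."""
    rows: list[dict] = []
    for genome in sorted(paths):
        p = Path(paths[genome])
        if not p.exists():
            raise FileNotFoundError(f"gene-order file for {genome!r} not found: {p}")
        if p.suffix.lower() in (".bed", ".bed6"):
            rows.extend(_read_bed6_genes(p, genome))
        else:
            rows.extend(_read_gff3_genes(p, genome))
    df = pd.DataFrame(rows)
    dup = df[df.duplicated(["genome", "gene_id"], keep=False)]
    if len(dup):
        raise ParseError(
            f"duplicate gene ids within a genome: {sorted(dup.gene_id.unique())[:10]}")
    df = df.sort_values(["genome", "chrom", "start", "end", "gene_id"]).reset_index(drop=True)
    df["rank"] = df.groupby(["genome", "chrom"]).cumcount()
    df["length"] = df["end"] - df["start"] + 1
    dup_all = df[df.duplicated("gene_id", keep=False)]
    if len(dup_all):
        raise ParseError(
            "gene ids shared between genomes: "
            f"{sorted(dup_all.gene_id.unique())[:10]}; ids must be globally unique")
    return df.set_index("gene_id")


def read_hits(path: str | Path) -> pd.DataFrame:
    """BLAST tabular (outfmt 6) reader."""
    df = pd.read_csv(path, sep="\t", names=OUTFMT6_COLUMNS, comment="#")
    if df.isnull().any().any():
        raise ParseError(f"{path}: malformed outfmt-6 table (missing fields)")
    return df


def read_lengths(path: str | Path) -> dict[str, int]:
    """Sequence lengths from a two-column TSV (id, length) or a FASTA file."""
    p = Path(path)
    with open(p) as fh:
        first = fh.read(1)
    if first == ">":
        return {rec.id: len(rec.seq) for rec in SeqIO.parse(str(p), "fasta")}
    df = pd.read_csv(p, sep="\t", names=["id", "length"], comment="#")
    return dict(zip(df["id"].astype(str), df["length"].astype(int)))


# ---------------------------------------------------------------------------
# writers (bit-exact for fixed inputs: plain formatted text, sorted rows)
# ---------------------------------------------------------------------------

def write_pair_stats(stats: Iterable[PairStats], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("query_id\tsubject_id\tcip\tcalp\tn_hsps\tquery_length\n")
        for s in sorted(stats, key=lambda s: (s.query_id, s.subject_id)):
            fh.write(f"{s.query_id}\t{s.subject_id}\t{s.cip:.2f}\t{s.calp:.2f}"
                     f"\t{s.n_hsps}\t{s.query_length}\n")


def write_anchors(anchors: Iterable[AnchorPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(COORD_HEADER + "\n")
        fh.write("genome_a\tgene_a\tchrom_a\trank_a\tgenome_b\tgene_b\tchrom_b"
                 "\trank_b\tstrand_concordance\tweight\n")
        for a in sorted(anchors, key=lambda a: (a.genome_a, a.chrom_a, a.rank_a,
                                                a.genome_b, a.chrom_b, a.rank_b)):
            sc = "+" if a.strand_concordance > 0 else "-"
            fh.write(f"{a.genome_a}\t{a.gene_a}\t{a.chrom_a}\t{a.rank_a}"
                     f"\t{a.genome_b}\t{a.gene_b}\t{a.chrom_b}\t{a.rank_b}"
                     f"\t{sc}\t{a.weight:.1f}\n")


def write_blocks(blocks: Iterable[SyntenyBlock], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(COORD_HEADER + "\n")
        fh.write("genome_a\tchrom_a\tstart_a\tend_a\tgenome_b\tchrom_b\tstart_b"
                 "\tend_b\tn_genes\torientation\tscore\n")
        for b in blocks:
            sa = min(a.start_a for a in b.anchors)
            ea = max(a.end_a for a in b.anchors)
            sb = min(a.start_b for a in b.anchors)
            eb = max(a.end_b for a in b.anchors)
            fh.write(f"{b.genome_a}\t{b.chrom_a}\t{sa}\t{ea}\t{b.genome_b}"
                     f"\t{b.chrom_b}\t{sb}\t{eb}\t{b.n_genes}\t{b.orientation}"
                     f"\t{b.score:.1f}\n")


def write_depth(profile: DepthProfile, gene_table: pd.DataFrame,
                path: str | Path) -> None:
    genes = gene_table[gene_table["genome"] == profile.genome_id]
    with open(path, "w") as fh:
        fh.write(COORD_HEADER + "\n")
        fh.write("genome\tchrom\tgene_id\trank\tdepth\n")
        for gid, r in genes.sort_values(["chrom", "rank"]).iterrows():
            fh.write(f"{profile.genome_id}\t{r.chrom}\t{gid}\t{int(r['rank'])}"
                     f"\t{int(profile.depth.get(gid, 0))}\n")


def write_cars(carset: CARSet, path: str | Path, summary_path: str | Path | None = None) -> None:
    small = set(carset.small_cars())
    with open(path, "w") as fh:
        fh.write("car_id\tposition\tfamily\torientation\n")
        for i, car in enumerate(carset.cars, start=1):
            for pos, (fam, sign) in enumerate(car):
                fh.write(f"CAR{i:03d}\t{pos}\t{fam}\t{'+' if sign > 0 else '-'}\n")
    if summary_path is not None:
        with open(summary_path, "w") as fh:
            fh.write("car_id\tn_families\tsmall\tmin_support\tmean_support\n")
            for i, car in enumerate(carset.cars, start=1):
                sups = []
                for left, right in zip(car, car[1:]):
                    from .karyotype import marker_extremities
                    key = tuple(sorted((marker_extremities(left)[1],
                                        marker_extremities(right)[0])))
                    if key in carset.adjacency_support:
                        sups.append(carset.adjacency_support[key])
                mn = min(sups) if sups else 0
                mean = sum(sups) / len(sups) if sups else 0.0
                fh.write(f"CAR{i:03d}\t{len(car)}\t{'yes' if (i - 1) in small else 'no'}"
                         f"\t{mn}\t{mean:.2f}\n")


def write_adjacencies(adjacencies: Iterable[Adjacency], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("family_1\tend_1\tfamily_2\tend_2\tsupport\tdenominator"
                 "\tsupport_fraction\tsupporting_genomes\n")
        for a in sorted(adjacencies, key=lambda a: a.key):
            (f1, e1), (f2, e2) = a.key
            fh.write(f"{f1}\t{e1}\t{f2}\t{e2}\t{a.support}\t{a.denominator}"
                     f"\t{a.support_fraction:.3f}\t{','.join(sorted(a.supporting_genomes))}\n")


def write_scenario(scen: RearrangementScenario, json_path: str | Path) -> None:
    doc = {
        "source": scen.source, "target": scen.target,
        "dcj_lower_bound": scen.dcj_lower_bound,
        "shared_markers": scen.shared_markers,
        "counts": scen.counts,
        "events": [{"kind": e.kind, "label": e.label, "operands": e.operands}
                   for e in scen.events],
    }
    Path(json_path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


def write_scenario_summary(scenarios: Iterable[RearrangementScenario],
                           path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("source\ttarget\tfissions\tfusions\tinversions\ttranslocations"
                 "\twgm\tdcj_lower_bound\ttotal_events\tshared_markers\n")
        for s in scenarios:
            c = s.counts
            fh.write(f"{s.source}\t{s.target}\t{c.get('fission', 0)}"
                     f"\t{c.get('fusion', 0)}\t{c.get('inversion', 0)}"
                     f"\t{c.get('translocation', 0)}\t{c.get('wgm', 0)}"
                     f"\t{s.dcj_lower_bound}\t{s.n_events}\t{s.shared_markers}\n")
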