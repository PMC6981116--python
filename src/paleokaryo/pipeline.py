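"""End-to-end orchestration: hits -> anchors -> blocks -> CARs -> scenarios.

Stage order follows the reconstruction recipe: (1) alignment statistics and
conserved-pair filtering, (2) synteny chaining (genome-vs-self first, which
yields the ploidy readout, then inter-genome blocks used for copy
resolution), (3) conserved-adjacency collection and CAR/protochromosome
assembly, (4) a rearrangement scenario from the reconstructed ancestor to
each modern genome.  All intermediate tables are persisted; a run is fully
deterministic for fixed inputs and configuration.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import ancestor as anc_mod
from . import homology, synteny
from .config import RunConfig
from .io import (read_gene_orders, read_hits, read_lengths, write_adjacencies,
                 write_anchors, write_blocks, write_cars, write_depth,
                 write_pair_stats, write_scenario, write_scenario_summary)
from .karyotype import Karyotype
from .scenario import greedy_scenario, restrict_to_shared

log = logging.getLogger("paleokaryo")


@dataclass
class RunReport:
    n_genomes: int = 0
    n_genes: int = 0
    n_hits: int = 0
    n_pairs: int = 0
    n_anchors: int = 0
    n_blocks: int = 0
    n_self_blocks: dict[str, int] = field(default_factory=dict)
    inferred_copy_number: dict[str, int] = field(default_factory=dict)
    n_families: int = 0
    universe_size: int = 0
    n_adjacencies: int = 0
    n_cars_full: int = 0
    n_cars: int = 0
    car_sizes: list[int] = field(default_factory=list)
    small_cars: int = 0
    scenarios: dict[str, dict] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    #: in-memory stage products (CAR sets, karyotypes, family map, gene
    #: table); populated by run_all, never serialized
    products: dict = field(default_factory=dict, repr=False, compare=False)

    def to_json(self) -> str:
        doc = {k: v for k, v in self.__dict__.items() if k != "products"}
        return json.dumps(doc, indent=1, sort_keys=True)

    def to_text(self) -> str:
        lines = [
            f"genomes: {self.n_genomes}  genes: {self.n_genes}  hits: {self.n_hits}",
            f"gene pairs: {self.n_pairs}  anchors: {self.n_anchors}  "
            f"inter-genome blocks: {self.n_blocks}",
            f"families: {self.n_families} (universe {self.universe_size})  "
            f"adjacencies: {self.n_adjacencies}",
            f"CARs: {self.n_cars_full} at full support -> "
            f"{self.n_cars} protochromosomes ({self.small_cars} small)",
            "inferred copy numbers: " + ", ".join(
                f"{g}={c}" for g, c in sorted(self.inferred_copy_number.items())),
        ]
        for target, c in sorted(self.scenarios.items()):
            lines.append(
                f"scenario ancestor->{target}: {c['total_events']} events "
                f"(fis {c['fission']}, fus {c['fusion']}, inv {c['inversion']}, "
                f"tra {c['translocation']}; DCJ lower bound {c['dcj_lower_bound']})")
        for w in self.warnings:
            lines.append(f"WARNING: {w}")
        return "\n".join(lines) + "\n"


def _timed(name: str):
    class _T:
        def __enter__(self):
            self.t0 = time.time()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, *exc):
            log.info("stage %s: done in %.1fs", name, time.time() - self.t0)
    return _T()


def run_all(cfg: RunConfig, scenarios: bool = True) -> RunReport:
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport()

    with _timed("read"):
        genes = read_gene_orders(cfg.genomes)
        hits = read_hits(cfg.hits)
        lengths = read_lengths(cfg.lengths)
        report.n_genomes = len(cfg.genomes)
        report.n_genes = len(genes)
        report.n_hits = len(hits)

    with _timed("homology"):
        stats = homology.pair_stats_from_hits(hits, lengths)
        anchors = homology.filter_conserved_pairs(
            stats, genes, cip_min=cfg.cip_min, calp_min=cfg.calp_min)
        report.n_pairs = len(stats)
        report.n_anchors = len(anchors)
        write_pair_stats(stats, out / "pair_stats.tsv")
        write_anchors(anchors, out / "anchors.tsv")

    inter = [a for a in anchors if a.genome_a != a.genome_b]
    intra = [a for a in anchors if a.genome_a == a.genome_b]

    with _timed("selfsynteny"):
        copy_number: dict[str, int] = {}
        for genome in sorted(cfg.genomes):
            mine = [a for a in intra if a.genome_a == genome]
            blocks = synteny.self_duplications(
                mine, max_gap=cfg.max_gap, min_genes=cfg.self_min_genes,
                merge_gap=cfg.merge_gap, min_span=cfg.min_span)
            profile = synteny.syntenic_depth(blocks, genes, genome,
                                             coverage_frac=cfg.coverage_frac)
            copy_number[genome] = profile.inferred_copy_number
            report.n_self_blocks[genome] = len(blocks)
            write_blocks(blocks, out / f"self_blocks.{genome}.tsv")
            write_depth(profile, genes, out / f"depth.{genome}.tsv")
        report.inferred_copy_number = copy_number

    with _timed("synteny"):
        by_pair: dict[tuple[str, str], list] = {}
        for a in inter:
            by_pair.setdefault((a.genome_a, a.genome_b), []).append(a)
        all_blocks = []
        for (ga, gb), pair_anchors in sorted(by_pair.items()):
            quota = max(cfg.quota, copy_number.get(ga, 1), copy_number.get(gb, 1))
            all_blocks.extend(synteny.find_blocks(
                pair_anchors, max_gap=cfg.max_gap, min_genes=cfg.min_genes,
                merge_gap=cfg.merge_gap, quota=quota))
        report.n_blocks = len(all_blocks)
        write_blocks(all_blocks, out / "blocks.tsv")

    with _timed("cars"):
        family_map = anc_mod.infer_families(anchors, genes)
        report.n_families = len(set(family_map.values()))
        reference = cfg.reference_genome
        if reference is None:
            unduplicated = [g for g in sorted(cfg.genomes) if copy_number.get(g, 1) == 1]
            reference = unduplicated[0] if unduplicated else sorted(cfg.genomes)[0]
        block_scores: dict[str, float] = {}
        for blk in all_blocks:
            if reference not in (blk.genome_a, blk.genome_b):
                continue
            for a in blk.anchors:
                other = a.gene_b if blk.genome_a == reference else a.gene_a
                block_scores[other] = max(block_scores.get(other, 0.0), blk.score)
                mine = a.gene_a if blk.genome_a == reference else a.gene_b
                block_scores[mine] = max(block_scores.get(mine, 0.0), blk.score)
        karyotypes, rejects = anc_mod.to_signed_orders(
            genes, family_map, copy_policy=cfg.copy_policy,
            block_scores=block_scores, min_family_genomes=cfg.min_family_genomes)
        if len(rejects):
            rejects.to_csv(out / "copy_rejects.tsv", sep="\t", index=False)
        # adjacency/telomere evidence uses every gene copy; the copy-resolved
        # karyotypes serve the scenario stage
        fam_genomes = pd.Series({g: family_map[g] for g in genes.index})
        n_per_family = genes.assign(family=fam_genomes).groupby("family")["genome"].nunique()
        universe = set(n_per_family[n_per_family >= cfg.min_family_genomes].index)
        report.universe_size = len(universe)
        orders = anc_mod.family_orders(genes, family_map, universe)
        adjacencies = anc_mod.conserved_adjacencies(orders)
        report.n_adjacencies = len(adjacencies)
        write_adjacencies(adjacencies, out / "adjacencies.tsv")
        carset = anc_mod.assemble_cars(
            adjacencies, universe, support_frac=cfg.car_support_frac,
            min_support=cfg.min_support)
        carset.small_car_min = cfg.small_car_min
        report.n_cars_full = carset.n_cars
        tel = anc_mod.telomere_support(orders)
        merged = anc_mod.merge_protochromosomes(
            carset, adjacencies, support_frac=cfg.proto_support_frac,
            min_support=cfg.min_support, telomere_fractions=tel,
            telomere_frac=cfg.telomere_frac,
            rescue_support_frac=cfg.rescue_support_frac,
            rescue_telomere_max=cfg.rescue_telomere_max)
        merged.small_car_min = cfg.small_car_min
        report.n_cars = merged.n_cars
        report.car_sizes = sorted((len(c) for c in merged.cars), reverse=True)
        report.small_cars = len(merged.small_cars())
        write_cars(carset, out / "cars_full_support.tsv")
        write_cars(merged, out / "cars.tsv", out / "cars_summary.tsv")

    if scenarios:
        with _timed("scenario"):
            anc_k = merged.as_karyotype("ancestor")
            scens = []
            for genome in sorted(cfg.genomes):
                k = karyotypes[genome]
                a, b, dropped = restrict_to_shared(anc_k, k)
                try:
                    scen = greedy_scenario(a, b)
                except RuntimeError as exc:
                    report.warnings.append(f"scenario ancestor->{genome}: {exc}")
                    continue
                scens.append(scen)
                report.scenarios[genome] = dict(
                    scen.counts, dcj_lower_bound=scen.dcj_lower_bound,
                    total_events=scen.n_events, dropped_markers=dropped)
                write_scenario(scen, out / f"scenario.{genome}.json")
            write_scenario_summary(scens, out / "scenario_summary.tsv")

    (out / "report.json").write_text(report.to_json() + "\n")
    (out / "report.txt").write_text(report.to_text())
    report.products = {
        "carset": merged, "carset_full": carset, "karyotypes": karyotypes,
        "family_map": family_map, "gene_table": genes,
        "adjacencies": adjacencies}
    return report


def _read_cars_tsv(path: Path) -> list[tuple]:
    df = pd.read_csv(path, sep="\t")
    cars = []
    for _car, sub in df.groupby("car_id", sort=True):
        sub = sub.sort_values("position")
        cars.append(tuple((r.family, 1 if r.orientation == "+" else -1)
                          for r in sub.itertuples(index=False)))
    return cars
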