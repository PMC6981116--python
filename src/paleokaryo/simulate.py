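"""Genome-evolution simulator with ground truth.

Evolves an ancestral karyotype down a species tree: each branch receives a
random number of inversions, translocations, fusions and fissions (uniform
count ranges by default, Poisson means optionally), and designated branches
undergo a whole-genome multiplication followed by immediate per-copy gene
loss (fractionation, always keeping at least one copy of every family in
the genome).  Tip genomes are laid out in base pairs (per-family gene
lengths, random intergenic spacing) and emitted as GFF3; homology evidence
is emitted as BLAST-tabular hits whose identity decays linearly with tree
path length, optionally fragmented into several HSPs and contaminated with
spurious low-identity pairs.

Everything the pipeline is asked to rediscover is recorded in a
:class:`TrueHistory`: the ancestral karyotype, the per-branch event lists
(replayable through :mod:`paleokaryo.scenario`), the gene-to-family map and
every tip karyotype.  A fixed seed makes all outputs byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import dendropy
import numpy as np
import pandas as pd

from .karyotype import Karyotype, reverse_complement, same_structure
from .scenario import RearrangementEvent, apply_event

#: Balanced 12-taxon default tree; the WGT-bearing stem is the branch above
#: the (G01,G02) pair (labelled LUP).
DEFAULT_TREE = (
    "(((G01:1,G02:1)LUP:1,((G03:1,G04:1)N2:1,(G05:1,G06:1)N3:1)N4:1)N5:1,"
    "((G07:1,G08:1)N6:1,((G09:1,G10:1)N7:1,(G11:1,G12:1)N8:1)N9:1)N10:1)ROOT;"
)

OUTFMT6_HEADER = ["qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
                  "qstart", "qend", "sstart", "send", "evalue", "bitscore"]


@dataclass
class SimulationConfig:
    """Study-condition defaults: a 16-chromosome, 640-gene ancestor evolving
    into 12 genomes, with 3-8 inversions and 0-2 fusions/fissions per
    branch, one whole-genome triplication on the LUP stem followed by 40%
    per-copy gene loss, and moderate alignment noise."""

    n_ancestral_chromosomes: int = 16
    genes_per_chromosome: int = 40
    tree_newick: str = DEFAULT_TREE
    count_mode: str = "uniform"          # "uniform" | "poisson"
    inversion_range: tuple[int, int] = (3, 8)
    translocation_range: tuple[int, int] = (0, 1)
    fusion_range: tuple[int, int] = (0, 2)
    fission_range: tuple[int, int] = (0, 2)
    inversion_rate: float = 5.0          # Poisson means (count_mode="poisson")
    translocation_rate: float = 0.5
    fusion_rate: float = 1.0
    fission_rate: float = 1.0
    wgm_events: list[tuple[str, int]] = field(default_factory=lambda: [("LUP", 3)])
    loss_fraction: float = 0.4
    gene_length_range: tuple[int, int] = (900, 3000)
    spacer_range: tuple[int, int] = (2000, 8000)
    identity_divergence: float = 3.0     # % identity lost per unit path length
    identity_floor: float = 70.0
    identity_jitter_sd: float = 1.0
    hsp_split_prob: float = 0.2
    spurious_hit_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.loss_fraction < 1.0:
            raise ValueError("loss_fraction must be in [0, 1)")
        for name in ("inversion_rate", "translocation_rate", "fusion_rate",
                     "fission_rate", "identity_divergence", "hsp_split_prob",
                     "spurious_hit_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class BranchEvent:
    """One event on a tree branch; loss and wgm carry their own operands so
    the branch is exactly replayable."""

    kind: str   # inversion/translocation/fusion/fission/wgm/loss
    operands: dict


@dataclass
class TrueHistory:
    ancestor: Karyotype                      # families only, copy suffix ".0"
    branch_events: dict[str, list[BranchEvent]]  # keyed by child node label
    node_karyotypes: dict[str, Karyotype]
    family_map: dict[str, tuple[str, int]]   # gene id -> (family, copy index)
    tree_newick: str
    wgm_tips: set[str] = field(default_factory=set)

    def true_adjacencies(self) -> set:
        return self.ancestor.adjacencies()


def _marker_id(family: str, copy: int) -> str:
    return f"{family}.{copy}"


def _split_marker(marker_id: str) -> tuple[str, int]:
    fam, copy = marker_id.rsplit(".", 1)
    return fam, int(copy)


def _apply_wgm_branch(chroms: list, multiplier: int) -> list:
    """Triplicate/duplicate in place; copy ids are remapped deterministically
    (old copy c -> c * m + k for the k-th new copy)."""
    out = []
    for k in range(multiplier):
        for chrom in chroms:
            out.append(tuple((
                _marker_id(*(lambda f, c: (f, c * multiplier + k))(*_split_marker(fam))),
                sign) for fam, sign in chrom))
    return out


def _apply_loss(chroms: list, lost: set[str]) -> list:
    out = []
    for chrom in chroms:
        reduced = tuple(m for m in chrom if m[0] not in lost)
        if reduced:
            out.append(reduced)
    return out


class Simulator:
    def __init__(self, cfg: SimulationConfig):
        self.cfg = cfg
        self.rng = np.random.default_rng(cfg.seed)
        self.tree = dendropy.Tree.get(data=cfg.tree_newick, schema="newick",
                                      suppress_internal_node_taxa=False)

    # -- event sampling -----------------------------------------------------

    def _n_events(self, kind: str) -> int:
        cfg = self.cfg
        if cfg.count_mode == "poisson":
            rate = getattr(cfg, f"{kind}_rate")
            return int(self.rng.poisson(rate))
        lo, hi = getattr(cfg, f"{kind}_range")
        return int(self.rng.integers(lo, hi + 1))

    def _sample_event(self, kind: str, chroms: list) -> RearrangementEvent | None:
        rng = self.rng
        n = len(chroms)
        if kind == "inversion":
            eligible = [i for i in range(n) if len(chroms[i]) >= 1]
            if not eligible:
                return None
            c = int(rng.choice(eligible))
            L = len(chroms[c])
            i = int(rng.integers(0, L))
            j = int(rng.integers(i + 1, L + 1))
            return RearrangementEvent("inversion", {"chrom": c, "start": i, "end": j})
        if kind == "fission":
            eligible = [i for i in range(n) if len(chroms[i]) >= 2]
            if not eligible:
                return None
            c = int(rng.choice(eligible))
            pos = int(rng.integers(1, len(chroms[c])))
            return RearrangementEvent("fission", {"chrom": c, "pos": pos})
        if kind == "fusion":
            if n < 2:
                return None
            i, j = map(int, rng.choice(n, size=2, replace=False))
            return RearrangementEvent("fusion", {
                "chrom_a": i, "chrom_b": j,
                "flip_a": bool(rng.integers(0, 2)), "flip_b": bool(rng.integers(0, 2))})
        if kind == "translocation":
            if n < 2:
                return None
            for _ in range(20):
                i, j = map(int, rng.choice(n, size=2, replace=False))
                pi = int(rng.integers(0, len(chroms[i]) + 1))
                pj = int(rng.integers(0, len(chroms[j]) + 1))
                exchanged = (len(chroms[i]) - pi) + (len(chroms[j]) - pj)
                if 0 < exchanged < len(chroms[i]) + len(chroms[j]):
                    mode = "straight" if rng.integers(0, 2) else "flipped"
                    return RearrangementEvent("translocation", {
                        "chrom_a": i, "chrom_b": j, "pos_a": pi, "pos_b": pj,
                        "mode": mode})
            return None
        raise ValueError(kind)

    def _evolve_branch(self, chroms: list, label: str) -> tuple[list, list[BranchEvent]]:
        cfg = self.cfg
        events: list[BranchEvent] = []
        for node_label, multiplier in cfg.wgm_events:
            if node_label == label:
                chroms = _apply_wgm_branch(chroms, multiplier)
                events.append(BranchEvent("wgm", {"multiplier": multiplier}))
                lost = self._sample_loss(chroms)
                if lost:
                    chroms = _apply_loss(chroms, lost)
                    events.append(BranchEvent("loss", {"markers": sorted(lost)}))
        kinds: list[str] = []
        for kind in ("inversion", "translocation", "fusion", "fission"):
            kinds.extend([kind] * self._n_events(kind))
        order = self.rng.permutation(len(kinds)) if kinds else []
        for idx in order:
            kind = kinds[int(idx)]
            for _ in range(20):  # redraw infeasible events (logged implicitly)
                ev = self._sample_event(kind, chroms)
                if ev is not None:
                    break
            if ev is None:
                continue
            chroms = apply_event(chroms, ev)
            events.append(BranchEvent(ev.kind, ev.operands))
        return chroms, events

    def _sample_loss(self, chroms: list) -> set[str]:
        cfg = self.cfg
        by_family: dict[str, list[str]] = {}
        for chrom in chroms:
            for mid, _ in chrom:
                by_family.setdefault(_split_marker(mid)[0], []).append(mid)
        lost: set[str] = set()
        for fam in sorted(by_family):
            copies = sorted(by_family[fam])
            drop = [m for m in copies if self.rng.random() < cfg.loss_fraction]
            if len(drop) == len(copies):
                keep = copies[int(self.rng.integers(0, len(copies)))]
                drop = [m for m in drop if m != keep]
            lost.update(drop)
        return lost

    # -- main entry ---------------------------------------------------------

    def ancestor(self) -> Karyotype:
        cfg = self.cfg
        chroms = []
        fam = 0
        for _ in range(cfg.n_ancestral_chromosomes):
            chrom = []
            for _ in range(cfg.genes_per_chromosome):
                fam += 1
                sign = 1 if self.rng.random() < 0.5 else -1
                chrom.append((_marker_id(f"F{fam:04d}", 0), sign))
            chroms.append(tuple(chrom))
        return Karyotype("ancestor", chroms)

    def run(self) -> TrueHistory:
        anc = self.ancestor()
        branch_events: dict[str, list[BranchEvent]] = {}
        node_karyotypes: dict[str, Karyotype] = {}
        wgm_nodes = {label for label, _ in self.cfg.wgm_events}

        root = self.tree.seed_node
        state = {id(root): list(anc.chromosomes)}
        under_wgm: dict[int, bool] = {id(root): False}
        wgm_tips: set[str] = set()
        for node in self.tree.preorder_node_iter():
            label = (node.taxon.label if node.taxon is not None else node.label) or "ROOT"
            if node is root:
                node_karyotypes[label] = Karyotype(label, state[id(node)])
                continue
            parent_chroms = state[id(node.parent_node)]
            chroms, events = self._evolve_branch(list(parent_chroms), label)
            state[id(node)] = chroms
            branch_events[label] = events
            under_wgm[id(node)] = under_wgm[id(node.parent_node)] or label in wgm_nodes
            node_karyotypes[label] = Karyotype(label, chroms)
            if node.is_leaf() and under_wgm[id(node)]:
                wgm_tips.add(label)

        tip_labels = [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]
        family_map: dict[str, tuple[str, int]] = {}
        for tip in tip_labels:
            counter = 0
            relabelled = []
            for chrom in node_karyotypes[tip].chromosomes:
                new_chrom = []
                for mid, sign in chrom:
                    counter += 1
                    gene = f"{tip}_g{counter:05d}"
                    family_map[gene] = _split_marker(mid)
                    new_chrom.append((gene, sign))
                relabelled.append(tuple(new_chrom))
            node_karyotypes[tip] = Karyotype(tip, relabelled)

        return TrueHistory(ancestor=anc, branch_events=branch_events,
                           node_karyotypes=node_karyotypes,
                           family_map=family_map,
                           tree_newick=self.cfg.tree_newick,
                           wgm_tips=wgm_tips)


def simulate_history(cfg: SimulationConfig) -> TrueHistory:
    """Evolve the configured clade and return its full ground truth."""
    return Simulator(cfg).run()


def verify_replay(truth: TrueHistory) -> None:
    """Hard check: replaying every branch's recorded events from its parent
    reproduces the stored karyotype exactly."""
    tree = dendropy.Tree.get(data=truth.tree_newick, schema="newick",
                             suppress_internal_node_taxa=False)
    states: dict[int, list] = {id(tree.seed_node): list(truth.ancestor.chromosomes)}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        label = (node.taxon.label if node.taxon is not None else node.label)
        chroms = list(states[id(node.parent_node)])
        for ev in truth.branch_events[label]:
            if ev.kind == "wgm":
                chroms = _apply_wgm_branch(chroms, ev.operands["multiplier"])
            elif ev.kind == "loss":
                chroms = _apply_loss(chroms, set(ev.operands["markers"]))
            else:
                chroms = apply_event(chroms, RearrangementEvent(ev.kind, ev.operands))
        states[id(node)] = chroms
        stored = truth.node_karyotypes[label]
        if node.is_leaf():
            # tips were relabelled to gene ids; compare family structure
            relabel = [tuple((_marker_id(*truth.family_map[g]), s) for g, s in c)
                       for c in stored.chromosomes]
            stored = Karyotype(label + "_fam", relabel)
        replayed = Karyotype(label + "_replay", chroms)
        assert same_structure(replayed, stored), f"replay mismatch on branch {label}"


# ---------------------------------------------------------------------------
# coordinate layout and evidence emission
# ---------------------------------------------------------------------------

def gene_coordinates(truth: TrueHistory, cfg: SimulationConfig) -> pd.DataFrame:
    """Lay out every tip gene in bp; per-family gene lengths are shared by
    all copies so alignment coverage is well defined.  Deterministic given
    the config seed (a dedicated child RNG stream is used)."""
    rng = np.random.default_rng(np.random.default_rng(cfg.seed).integers(2**31))
    families = sorted({fam for fam, _ in truth.family_map.values()})
    lo, hi = cfg.gene_length_range
    lengths = {fam: int(rng.integers(lo, hi + 1)) for fam in families}
    rows = []
    tips = sorted(t for t, k in truth.node_karyotypes.items()
                  if k.chromosomes and k.chromosomes[0]
                  and k.chromosomes[0][0][0] in truth.family_map)
    slo, shi = cfg.spacer_range
    for tip in tips:
        k = truth.node_karyotypes[tip]
        for ci, chrom in enumerate(k.chromosomes, start=1):
            pos = 1
            for rank, (gene, sign) in enumerate(chrom):
                fam, _copy = truth.family_map[gene]
                glen = lengths[fam]
                start = pos + int(rng.integers(slo, shi + 1))
                end = start + glen - 1
                rows.append({"genome": tip, "gene_id": gene,
                             "chrom": f"chr{ci:02d}", "start": start, "end": end,
                             "strand": sign, "rank": rank, "length": glen})
                pos = end
    df = pd.DataFrame(rows).set_index("gene_id")
    return df


def emit_hits(truth: TrueHistory, cfg: SimulationConfig,
              genes: pd.DataFrame) -> pd.DataFrame:
    """BLAST-tabular evidence for every true homolog pair (inter-genome and
    intragenomic paralog pairs), with identity decaying along the tree path,
    optional HSP fragmentation and spurious low-identity contamination."""
    rng = np.random.default_rng(np.random.default_rng(cfg.seed + 1).integers(2**31))
    tree = dendropy.Tree.get(data=truth.tree_newick, schema="newick",
                             suppress_internal_node_taxa=False)
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    tips = sorted({g for g in genes["genome"].unique()})
    dist = {(a, b): pdm.patristic_distance(taxa[a], taxa[b])
            for a in tips for b in tips if a < b}
    # paralog divergence: copies split at the WGM stem; approximate the path
    # as twice the tip depth below the WGM node
    wgm_nodes = {lbl for lbl, _ in cfg.wgm_events}
    depth_below_wgm: dict[str, float] = {}
    for node in tree.preorder_node_iter():
        label = node.taxon.label if node.taxon is not None else node.label
        if label in wgm_nodes:
            for leaf in node.leaf_iter():
                d = 0.0
                cur = leaf
                while cur is not node:
                    d += cur.edge.length or 0.0
                    cur = cur.parent_node
                depth_below_wgm[leaf.taxon.label] = d

    by_family: dict[str, list[str]] = {}
    for gene, (fam, _copy) in truth.family_map.items():
        by_family.setdefault(fam, []).append(gene)
    glen = genes["length"].to_dict()
    ggenome = genes["genome"].to_dict()

    rows: list[tuple] = []

    def add_pair(q: str, s: str, identity: float) -> None:
        qlen = glen[q]
        identity = float(np.clip(identity + rng.normal(0, cfg.identity_jitter_sd),
                                 cfg.identity_floor, 100.0))
        if rng.random() < cfg.hsp_split_prob and qlen >= 200:
            cut = int(rng.integers(qlen // 4, 3 * qlen // 4))
            parts = [(1, cut), (cut + 1, qlen)]
        else:
            parts = [(1, qlen)]
        for qs, qe in parts:
            al = qe - qs + 1
            bit = round(2.0 * al * identity / 100.0, 1)
            rows.append((q, s, round(identity, 2), al, int(al * (100 - identity) / 100),
                         0, qs, qe, qs, qe, 1e-180, bit))

    for fam in sorted(by_family):
        members = sorted(by_family[fam])
        for i, q in enumerate(members):
            for s in members[i + 1:]:
                gq, gs = ggenome[q], ggenome[s]
                if gq == gs:
                    path = 2.0 * depth_below_wgm.get(gq, 1.0)
                else:
                    path = dist[(min(gq, gs), max(gq, gs))]
                identity = 100.0 - cfg.identity_divergence * path
                add_pair(q, s, identity)

    n_true = len(rows)
    n_spurious = int(cfg.spurious_hit_rate * n_true)
    all_genes = sorted(genes.index)
    for _ in range(n_spurious):
        q, s = rng.choice(len(all_genes), size=2, replace=False)
        q, s = all_genes[int(q)], all_genes[int(s)]
        identity = float(rng.uniform(30, 55))
        al = max(30, int(0.3 * glen[q]))
        bit = round(2.0 * al * identity / 100.0, 1)
        rows.append((q, s, round(identity, 2), al, int(al * (100 - identity) / 100),
                     0, 1, al, 1, al, 1e-5, bit))
    return pd.DataFrame(rows, columns=OUTFMT6_HEADER)


# ---------------------------------------------------------------------------
# fixture writing
# ---------------------------------------------------------------------------

def write_fixture(truth: TrueHistory, cfg: SimulationConfig, out_dir: str | Path,
                  genes: pd.DataFrame | None = None,
                  hits: pd.DataFrame | None = None) -> dict[str, Path]:
    """Write GFF3 per genome, hits/lengths TSVs, the tree and the truth log.

    Returns the path of every written file keyed by role.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if genes is None:
        genes = gene_coordinates(truth, cfg)
    if hits is None:
        hits = emit_hits(truth, cfg, genes)
    paths: dict[str, Path] = {}
    for genome, sub in genes.groupby("genome"):
        p = out / f"{genome}.gff3"
        with open(p, "w") as fh:
            fh.write("##gff-version 3\n")
            sub = sub.sort_values(["chrom", "start"])
            for chrom, csub in sub.groupby("chrom", sort=True):
                fh.write(f"##sequence-region {chrom} 1 {int(csub['end'].max()) + 1000}\n")
            for gid, r in sub.iterrows():
                strand = "+" if int(r.strand) > 0 else "-"
                fh.write(f"{r.chrom}\tpaleokaryo-sim\tgene\t{int(r.start)}\t{int(r.end)}"
                         f"\t.\t{strand}\t.\tID={gid}\n")
        paths[f"gff:{genome}"] = p
    hits_path = out / "hits.tsv"
    hits.to_csv(hits_path, sep="\t", header=False, index=False)
    paths["hits"] = hits_path
    lengths_path = out / "lengths.tsv"
    genes["length"].to_csv(lengths_path, sep="\t", header=False)
    paths["lengths"] = lengths_path
    tree_path = out / "tree.nwk"
    tree_path.write_text(truth.tree_newick if truth.tree_newick.endswith("\n")
                         else truth.tree_newick + "\n")
    paths["tree"] = tree_path
    truth_path = out / "truth.json"
    truth_doc = {
        "ancestor": [[list(m) for m in c] for c in truth.ancestor.chromosomes],
        "branch_events": {
            lbl: [{"kind": ev.kind, "operands": ev.operands} for ev in evs]
            for lbl, evs in truth.branch_events.items()},
        "family_map": {g: list(v) for g, v in truth.family_map.items()},
        "tree_newick": truth.tree_newick,
        "wgm_tips": sorted(truth.wgm_tips),
        "tip_karyotypes": {
            t: [[list(m) for m in c] for c in truth.node_karyotypes[t].chromosomes]
            for t in sorted(genes["genome"].unique())},
    }
    truth_path.write_text(json.dumps(truth_doc, indent=1, sort_keys=True))
    paths["truth"] = truth_path
    return paths


def load_truth(path: str | Path) -> TrueHistory:
    doc = json.loads(Path(path).read_text())
    anc = Karyotype("ancestor", [tuple((f, int(s)) for f, s in c)
                                 for c in doc["ancestor"]])
    events = {lbl: [BranchEvent(e["kind"], e["operands"]) for e in evs]
              for lbl, evs in doc["branch_events"].items()}
    fam_map = {g: (v[0], int(v[1])) for g, v in doc["family_map"].items()}
    node_k = {t: Karyotype(t, [tuple((g, int(s)) for g, s in c) for c in chroms])
              for t, chroms in doc["tip_karyotypes"].items()}
    return TrueHistory(ancestor=anc, branch_events=events, node_karyotypes=node_k,
                       family_map=fam_map, tree_newick=doc.get("tree_newick", ""),
                       wgm_tips=set(doc["wgm_tips"]))
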