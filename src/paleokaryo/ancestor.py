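"""Conserved-adjacency collection and ancestral-karyotype (CAR) assembly.

Modern genomes, expressed as signed orders over a shared gene-family
universe, vote on the neighbourhoods of the ancestor: an orientation-aware
adjacency (unordered pair of family extremities) that is realized in enough
genomes is taken as ancestral.  Adjacencies passing the full-support
threshold are assembled into Conserved Ancestral Regions (CARs): maximal
conflict-free linear paths of family extremities.  CARs are subsequently
merged into protochromosome candidates using adjacencies supported by only
a subset of the genomes.

Support is counted against the number of genomes that contain *both*
families of an adjacency (post-polyploidy gene loss otherwise erases every
full-support adjacency), and telomere evidence is used as a guard during
protochromosome merging: two CAR ends that most genomes display as
chromosome ends are not glued together, since a lineage-restricted fusion
would otherwise masquerade as an ancestral join.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .homology import AnchorPair
from .karyotype import (HEAD, TAIL, Chromosome, Extremity, Karyotype,
                        canonical_chromosome, marker_extremities)

DEFAULT_CAR_SUPPORT_FRAC = 1.0
DEFAULT_PROTO_SUPPORT_FRAC = 0.5
DEFAULT_TELOMERE_FRAC = 0.5
DEFAULT_RESCUE_SUPPORT_FRAC = 0.25
DEFAULT_RESCUE_TELOMERE_MAX = 0.2
DEFAULT_SMALL_CAR_MIN = 5
DEFAULT_MIN_SUPPORT = 2


@dataclass(frozen=True)
class Adjacency:
    """An unordered pair of family extremities with its cross-genome support.

    ``denominator`` counts the genomes that contain both families, i.e. the
    genomes that could possibly have realized the adjacency."""

    ext1: Extremity
    ext2: Extremity
    support: int
    denominator: int
    supporting_genomes: frozenset[str]

    @property
    def key(self) -> tuple[Extremity, Extremity]:
        return tuple(sorted((self.ext1, self.ext2)))  # type: ignore[return-value]

    @property
    def support_fraction(self) -> float:
        return self.support / self.denominator if self.denominator else 0.0


@dataclass
class CARSet:
    """A set of reconstructed ancestral segments (linear signed family
    orders) partitioning the family universe."""

    cars: list[Chromosome]
    adjacency_support: dict[tuple[Extremity, Extremity], int] = field(default_factory=dict)
    small_car_min: int = DEFAULT_SMALL_CAR_MIN

    @property
    def n_cars(self) -> int:
        return len(self.cars)

    def families(self) -> set[str]:
        return {fam for car in self.cars for fam, _ in car}

    def small_cars(self) -> list[int]:
        """Indices of CARs shorter than the configured minimum (flagged for
        the report, never silently dropped)."""
        return [i for i, car in enumerate(self.cars) if len(car) < self.small_car_min]

    def as_karyotype(self, genome_id: str = "ancestor") -> Karyotype:
        return Karyotype(genome_id, list(self.cars))

    def validate(self, universe: Iterable[str] | None = None) -> None:
        seen: set[str] = set()
        for car in self.cars:
            assert len(car) >= 1
            for fam, _ in car:
                assert fam not in seen, f"family {fam} in more than one CAR"
                seen.add(fam)
        if universe is not None:
            missing = set(universe) - seen
            assert not missing, f"families missing from CAR set: {sorted(missing)[:10]}"


# ---------------------------------------------------------------------------
# family inference and signed orders
# ---------------------------------------------------------------------------

def infer_families(anchors: Iterable[AnchorPair],
                   gene_table: pd.DataFrame) -> dict[str, str]:
    """Single-linkage gene families: connected components of the anchor
    graph.  Every gene of the gene table gets a family id; genes without any
    anchor form singleton families.  Family ids are deterministic
    (``FAM%06d`` in order of the smallest member gene id)."""
    g = nx.Graph()
    g.add_nodes_from(gene_table.index)
    for a in anchors:
        g.add_edge(a.gene_a, a.gene_b)
    comps = sorted(nx.connected_components(g), key=lambda c: min(c))
    fam_map: dict[str, str] = {}
    for i, comp in enumerate(comps):
        fid = f"FAM{i + 1:06d}"
        for gene in comp:
            fam_map[gene] = fid
    return fam_map


def to_signed_orders(
    gene_table: pd.DataFrame,
    family_map: Mapping[str, str],
    copy_policy: str = "best_synteny",
    block_scores: Mapping[str, float] | None = None,
    min_family_genomes: int = 2,
) -> tuple[dict[str, Karyotype], pd.DataFrame]:
    """Signed family orders per genome over the shared family universe.

    ``gene_table`` is indexed by gene id (columns ``genome, chrom, rank,
    strand``); marker sign is the annotated coding strand, which is the one
    orientation convention shared by every copy of a family.  Families seen
    in fewer than ``min_family_genomes`` genomes are excluded from the
    universe.  Multi-copy families within a genome are resolved per
    ``copy_policy``:

    * ``best_synteny`` (default): keep the copy with the highest synteny
      block score against the reference genome (``block_scores``: gene id ->
      best containing-block score); copies without block evidence are
      dropped.
    * ``first``: keep the positionally first copy (ties by gene id).
    * ``strict``: any multi-copy family is dropped from the genome entirely.

    Returns the karyotypes and a rejects table (genome, gene_id, family,
    reason) listing every dropped copy.
    """
    block_scores = block_scores or {}
    fam_series = gene_table.index.map(lambda g: family_map.get(g))
    tab = gene_table.assign(family=fam_series)
    genomes_per_family = tab.groupby("family")["genome"].nunique()
    universe = set(genomes_per_family[genomes_per_family >= min_family_genomes].index)

    rejects: list[dict] = []
    karyotypes: dict[str, Karyotype] = {}
    for genome, sub in tab.groupby("genome"):
        sub = sub[sub["family"].isin(universe)]
        keep: dict[str, str] = {}  # family -> gene id
        for family, copies in sub.groupby("family"):
            if len(copies) == 1:
                keep[family] = copies.index[0]
                continue
            if copy_policy == "strict":
                for gid in copies.index:
                    rejects.append({"genome": genome, "gene_id": gid,
                                    "family": family, "reason": "multi-copy (strict)"})
                continue
            if copy_policy == "first":
                ordered = copies.sort_values(["chrom", "rank"]).index
                keep[family] = ordered[0]
                for gid in ordered[1:]:
                    rejects.append({"genome": genome, "gene_id": gid,
                                    "family": family, "reason": "multi-copy (kept first)"})
                continue
            # best_synteny
            scored = sorted(copies.index,
                            key=lambda g: (-block_scores.get(g, 0.0), g))
            top = scored[0]
            if block_scores.get(top, 0.0) > 0.0:
                keep[family] = top
                for gid in scored[1:]:
                    rejects.append({"genome": genome, "gene_id": gid,
                                    "family": family,
                                    "reason": "multi-copy (lower block score)"})
            else:
                for gid in scored:
                    rejects.append({"genome": genome, "gene_id": gid,
                                    "family": family,
                                    "reason": "multi-copy (no block evidence)"})
        chosen = sub.loc[sorted(keep.values())]
        chroms: list[Chromosome] = []
        for chrom, genes in sorted(chosen.groupby("chrom"), key=lambda kv: str(kv[0])):
            genes = genes.sort_values("rank")
            chroms.append(tuple(
                (family_map[g], int(genes.loc[g, "strand"])) for g in genes.index))
        karyotypes[str(genome)] = Karyotype(str(genome), chroms)
    rej = pd.DataFrame(rejects, columns=["genome", "gene_id", "family", "reason"])
    return karyotypes, rej


# ---------------------------------------------------------------------------
# adjacency collection
# ---------------------------------------------------------------------------

GenomeOrders = Mapping[str, Sequence[Sequence[tuple[str, int]]]]


def _as_orders(genomes: "Mapping[str, Karyotype] | GenomeOrders") -> dict[str, list]:
    return {gid: (k.chromosomes if isinstance(k, Karyotype) else list(k))
            for gid, k in genomes.items()}


def family_orders(gene_table: pd.DataFrame,
                  family_map: Mapping[str, str],
                  universe: Iterable[str] | None = None) -> dict[str, list]:
    """Raw signed family orders per genome, keeping *every* gene copy.

    Adjacency evidence does not require copy resolution: a fractionated
    polyploid still witnesses an ancestral gene neighbourhood through
    whichever retained copy preserves it, so support counting runs on these
    multi-copy orders (karyotypes with resolved copies are only needed where
    single-copy permutations are mandatory, e.g. rearrangement scenarios).
    """
    keep = set(universe) if universe is not None else None
    orders: dict[str, list] = {}
    for genome, sub in gene_table.groupby("genome"):
        chroms = []
        for _chrom, genes in sorted(sub.groupby("chrom"), key=lambda kv: str(kv[0])):
            genes = genes.sort_values("rank")
            chrom = [(family_map[g], int(genes.loc[g, "strand"]))
                     for g in genes.index if g in family_map]
            if keep is not None:
                chrom = [(f, s) for f, s in chrom if f in keep]
            if chrom:
                chroms.append(chrom)
        orders[str(genome)] = chroms
    return orders


def conserved_adjacencies(genomes: "Mapping[str, Karyotype] | GenomeOrders",
                          min_support: int = 1) -> list[Adjacency]:
    """All extremity adjacencies realized in at least ``min_support``
    genomes, with exact support counts and co-occurrence denominators.

    Accepts copy-resolved karyotypes or raw multi-copy family orders; in the
    latter case a genome supports an adjacency if *any* copy pair realizes
    it.  Same-family neighbours (tandem copies) carry no orientation-free
    adjacency information and are skipped."""
    orders = _as_orders(genomes)
    presence: dict[str, set[str]] = defaultdict(set)
    for gid, chroms in orders.items():
        for chrom in chroms:
            for fam, _ in chrom:
                presence[fam].add(gid)
    seen: dict[tuple[Extremity, Extremity], set[str]] = defaultdict(set)
    for gid, chroms in orders.items():
        for chrom in chroms:
            for left, right in zip(chrom, chrom[1:]):
                if left[0] == right[0]:
                    continue
                e1, e2 = sorted((marker_extremities(tuple(left))[1],
                                 marker_extremities(tuple(right))[0]))
                seen[(e1, e2)].add(gid)
    out: list[Adjacency] = []
    for (e1, e2), genomes in sorted(seen.items()):
        if len(genomes) < min_support:
            continue
        denom = len(presence[e1[0]] & presence[e2[0]])
        out.append(Adjacency(ext1=e1, ext2=e2, support=len(genomes),
                             denominator=denom,
                             supporting_genomes=frozenset(genomes)))
    return out


def telomere_support(genomes: "Mapping[str, Karyotype] | GenomeOrders") -> dict[Extremity, float]:
    """Fraction of family-containing genomes in which each extremity is a
    chromosome end (evidence that the extremity is an ancestral telomere)."""
    orders = _as_orders(genomes)
    presence: dict[str, set[str]] = defaultdict(set)
    tel: dict[Extremity, set[str]] = defaultdict(set)
    for gid, chroms in orders.items():
        for chrom in chroms:
            for fam, _ in chrom:
                presence[fam].add(gid)
            tel[marker_extremities(tuple(chrom[0]))[0]].add(gid)
            tel[marker_extremities(tuple(chrom[-1]))[1]].add(gid)
    return {ext: len(gids) / len(presence[ext[0]]) for ext, gids in tel.items()}


# ---------------------------------------------------------------------------
# CAR assembly
# ---------------------------------------------------------------------------

def _required_support(adj: Adjacency, frac: float, min_support: int) -> int:
    return max(min_support, math.ceil(frac * adj.denominator))


def _paths_to_cars(adjacencies: list[Adjacency], universe: set[str]) -> CARSet:
    """Turn a conflict-free, acyclic adjacency set into signed linear CARs."""
    partner: dict[Extremity, Extremity] = {}
    support: dict[tuple[Extremity, Extremity], int] = {}
    for adj in adjacencies:
        e1, e2 = adj.key
        partner[e1] = e2
        partner[e2] = e1
        support[adj.key] = adj.support

    def other(ext: Extremity) -> Extremity:
        fam, end = ext
        return (fam, HEAD if end == TAIL else TAIL)

    visited: set[str] = set()
    cars: list[Chromosome] = []
    # start walks at free extremities (path endpoints), smallest first
    endpoints = sorted(
        ext for fam in universe for ext in ((fam, TAIL), (fam, HEAD))
        if ext not in partner)
    for start in endpoints:
        fam = start[0]
        if fam in visited:
            continue
        car: list[tuple[str, int]] = []
        ext = start
        while True:
            fam, end = ext
            visited.add(fam)
            car.append((fam, 1 if end == TAIL else -1))
            nxt = other(ext)
            if nxt not in partner:
                break
            ext = partner[nxt]
        cars.append(canonical_chromosome(tuple(car)))
    leftover = sorted(universe - visited)
    if leftover:
        # only possible if a cycle survived, which assembly forbids
        raise AssertionError(f"cyclic component left in CAR graph: {leftover[:10]}")
    cars.sort(key=lambda c: (-len(c), c))
    return CARSet(cars=cars, adjacency_support=support)


def assemble_cars(adjacencies: Iterable[Adjacency],
                  universe: Iterable[str],
                  support_frac: float = DEFAULT_CAR_SUPPORT_FRAC,
                  min_support: int = DEFAULT_MIN_SUPPORT) -> CARSet:
    """Assemble CARs from adjacencies at full (or configured) support.

    Conflicts (an extremity claimed by several passing adjacencies) keep the
    single highest-support adjacency and drop the rest; an exact tie drops
    all claimants (a conservative split is recoverable by protochromosome
    merging, a wrong join is not).  Any residual cycle is opened at its
    lowest-support adjacency.  Families untouched by any adjacency become
    singleton CARs.
    """
    universe = set(universe)
    passing = [a for a in adjacencies
               if a.support >= _required_support(a, support_frac, min_support)
               and a.ext1[0] in universe and a.ext2[0] in universe]
    # conflict resolution at each extremity
    by_ext: dict[Extremity, list[Adjacency]] = defaultdict(list)
    for a in passing:
        by_ext[a.ext1].append(a)
        by_ext[a.ext2].append(a)
    dropped: set[tuple[Extremity, Extremity]] = set()
    for ext, claimants in by_ext.items():
        if len(claimants) <= 1:
            continue
        best = max(a.support for a in claimants)
        top = [a for a in claimants if a.support == best]
        if len(top) == 1:
            for a in claimants:
                if a is not top[0]:
                    dropped.add(a.key)
        else:
            for a in claimants:
                dropped.add(a.key)
    kept = [a for a in passing if a.key not in dropped]

    # open residual cycles at their lowest-support adjacency
    g = nx.Graph()
    for a in kept:
        g.add_edge(a.ext1, a.ext2, support=a.support, key=a.key)
    for fam in universe:
        g.add_edge((fam, TAIL), (fam, HEAD), support=None, key=None)  # marker edges
    removed: set[tuple[Extremity, Extremity]] = set()
    for cyc in nx.cycle_basis(g):
        edge_keys = []
        for u, v in zip(cyc, cyc[1:] + cyc[:1]):
            data = g.get_edge_data(u, v)
            if data and data.get("key") is not None:
                edge_keys.append((data["support"], data["key"]))
        if edge_keys:
            # lowest support; tie -> lexicographically greatest pair
            edge_keys.sort(key=lambda sk: (sk[0], tuple(reversed(sk[1]))))
            weakest = edge_keys[0][1]
            removed.add(weakest)
            g.remove_edge(*weakest)
    kept = [a for a in kept if a.key not in removed]
    carset = _paths_to_cars(kept, universe)
    carset.validate(universe)
    return carset


def merge_protochromosomes(
    carset: CARSet,
    adjacencies: Iterable[Adjacency],
    support_frac: float = DEFAULT_PROTO_SUPPORT_FRAC,
    min_support: int = DEFAULT_MIN_SUPPORT,
    telomere_fractions: Mapping[Extremity, float] | None = None,
    telomere_frac: float = DEFAULT_TELOMERE_FRAC,
    rescue_support_frac: float = DEFAULT_RESCUE_SUPPORT_FRAC,
    rescue_telomere_max: float = DEFAULT_RESCUE_TELOMERE_MAX,
) -> CARSet:
    """Greedily merge CARs into protochromosomes using partially supported
    adjacencies.

    Iteratively joins the highest-support adjacency (ties: lexicographically
    smallest extremity pair) that connects free ends of two distinct CARs;
    repeated to a fixed point, so the CAR count never increases.  Telomere
    evidence modulates the merge in both directions when
    ``telomere_fractions`` is given:

    * an adjacency whose two extremities are both chromosome ends in at
      least ``telomere_frac`` of the relevant genomes is refused —
      concordant telomere evidence outweighs a clade-restricted fusion
      signal;
    * a *rescue* tier joins free ends that almost no genome displays as a
      chromosome end (both extremities below ``rescue_telomere_max``): such
      an end cannot be an ancestral telomere, so the best adjacency with
      support down to ``rescue_support_frac`` of its denominator is accepted
      for it.  Set ``rescue_support_frac`` >= ``support_frac`` to disable
      the tier.
    """
    cars = [list(c) for c in carset.cars]
    support = dict(carset.adjacency_support)
    internal = set(support)

    def _tel(ext: Extremity) -> float:
        return telomere_fractions.get(ext, 0.0) if telomere_fractions else 0.0

    primary = sorted(
        (a for a in adjacencies
         if a.support >= _required_support(a, support_frac, min_support)
         and a.key not in internal),
        key=lambda a: (-a.support, a.key))
    if telomere_fractions:
        primary = [a for a in primary
                   if not (_tel(a.ext1) >= telomere_frac
                           and _tel(a.ext2) >= telomere_frac)]
    rescue: list[Adjacency] = []
    if telomere_fractions and rescue_support_frac < support_frac:
        chosen = {a.key for a in primary}
        rescue = sorted(
            (a for a in adjacencies
             if a.key not in internal and a.key not in chosen
             and a.support >= _required_support(a, rescue_support_frac, min_support)
             and _tel(a.ext1) <= rescue_telomere_max
             and _tel(a.ext2) <= rescue_telomere_max),
            key=lambda a: (-a.support, a.key))

    def free_ends() -> dict[Extremity, tuple[int, str]]:
        ends: dict[Extremity, tuple[int, str]] = {}
        for i, car in enumerate(cars):
            left, _ = marker_extremities(tuple(car[0]))
            _, right = marker_extremities(tuple(car[-1]))
            ends[left] = (i, "left")
            ends[right] = (i, "right")
        return ends

    def _merge_pass(candidates: list[Adjacency]) -> bool:
        any_merge = False
        progress = True
        while progress:
            progress = False
            ends = free_ends()
            for adj in candidates:
                if adj.key in support:
                    continue
                loc1 = ends.get(adj.ext1)
                loc2 = ends.get(adj.ext2)
                if loc1 is None or loc2 is None or loc1[0] == loc2[0]:
                    continue
                (i, side_i), (j, side_j) = loc1, loc2
                a = cars[i] if side_i == "right" else [(f, -s) for f, s in reversed(cars[i])]
                b = cars[j] if side_j == "left" else [(f, -s) for f, s in reversed(cars[j])]
                merged = a + b
                for idx in sorted((i, j), reverse=True):
                    del cars[idx]
                cars.append(merged)
                support[adj.key] = adj.support
                progress = True
                any_merge = True
                break
        return any_merge

    while True:
        merged_any = _merge_pass(primary)
        merged_any |= _merge_pass(rescue)
        if not merged_any:
            break

    out = CARSet(cars=sorted((canonical_chromosome(tuple(c)) for c in cars),
                             key=lambda c: (-len(c), c)),
                 adjacency_support=support,
                 small_car_min=carset.small_car_min)
    out.validate(carset.families())
    assert out.n_cars <= carset.n_cars
    return out
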