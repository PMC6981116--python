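"""Signed orders, conserved adjacencies, CAR assembly and protochromosomes."""

import numpy as np
import pandas as pd
import pytest

from paleokaryo.ancestor import (Adjacency, assemble_cars,
                                 conserved_adjacencies, family_orders,
                                 merge_protochromosomes, telomere_support,
                                 to_signed_orders)
from paleokaryo.karyotype import HEAD, TAIL, Karyotype, same_structure


def kary(gid, *chroms):
    return Karyotype(gid, [tuple(c) for c in chroms])


def adj_key(f1, e1, f2, e2):
    return tuple(sorted(((f1, e1), (f2, e2))))


class TestSignedOrders:
    def _table(self, rows):
        return pd.DataFrame(rows).set_index("gene_id")

    def test_one_to_one_families_passthrough(self):
        rows = [
            {"gene_id": g, "genome": gen, "chrom": "c1", "rank": r, "strand": s}
            for g, gen, r, s in [
                ("x1", "G1", 0, 1), ("x2", "G1", 1, 1), ("x3", "G1", 2, 1),
                ("y1", "G2", 0, 1), ("y2", "G2", 1, 1), ("y3", "G2", 2, 1)]]
        fam = {"x1": "a", "y1": "a", "x2": "b", "y2": "b", "x3": "c", "y3": "c"}
        ks, rejects = to_signed_orders(self._table(rows), fam)
        assert ks["G1"].chromosomes == [(("a", 1), ("b", 1), ("c", 1))]
        assert len(rejects) == 0

    def test_reverse_annotation_same_adjacencies(self):
        rows = [
            {"gene_id": g, "genome": gen, "chrom": "c1", "rank": r, "strand": s}
            for g, gen, r, s in [
                ("x1", "G1", 0, 1), ("x2", "G1", 1, 1), ("x3", "G1", 2, 1),
                ("y3", "G2", 0, -1), ("y2", "G2", 1, -1), ("y1", "G2", 2, -1)]]
        fam = {"x1": "a", "y1": "a", "x2": "b", "y2": "b", "x3": "c", "y3": "c"}
        ks, _ = to_signed_orders(self._table(rows), fam)
        assert ks["G1"].adjacencies() == ks["G2"].adjacencies()

    def test_multicopy_resolved_by_block_score(self):
        rows = [
            {"gene_id": g, "genome": gen, "chrom": c, "rank": r, "strand": 1}
            for g, gen, c, r in [
                ("p1", "G1", "c1", 0), ("p2", "G1", "c2", 0), ("p3", "G1", "c3", 0),
                ("q1", "G2", "c1", 0)]]
        fam = {"p1": "a", "p2": "a", "p3": "a", "q1": "a"}
        ks, rejects = to_signed_orders(
            self._table(rows), fam, copy_policy="best_synteny",
            block_scores={"p2": 80.0, "p1": 20.0})
        assert ks["G1"].chromosomes == [(("a", 1),)]
        kept_gene = rejects[rejects.genome == "G1"]["gene_id"].tolist()
        assert sorted(kept_gene) == ["p1", "p3"]  # p2 retained

    def test_strict_policy_rejects_all_copies(self):
        rows = [
            {"gene_id": g, "genome": "G1", "chrom": "c1", "rank": r, "strand": 1}
            for g, r in [("p1", 0), ("p2", 1)]] + [
            {"gene_id": "q1", "genome": "G2", "chrom": "c1", "rank": 0, "strand": 1}]
        fam = {"p1": "a", "p2": "a", "q1": "a"}
        ks, rejects = to_signed_orders(self._table(rows), fam, copy_policy="strict")
        assert ks["G1"].n_chromosomes == 0
        assert len(rejects) == 2


class TestConservedAdjacencies:
    def test_identical_genomes(self):
        k1 = kary("G1", [("a", 1), ("b", 1), ("c", 1)])
        k2 = kary("G2", [("a", 1), ("b", 1), ("c", 1)])
        adjs = conserved_adjacencies({"G1": k1, "G2": k2})
        keys = {a.key: a.support for a in adjs}
        assert keys == {adj_key("a", HEAD, "b", TAIL): 2,
                        adj_key("b", HEAD, "c", TAIL): 2}

    def test_reversal_invariance(self):
        k1 = kary("G1", [("a", 1), ("b", 1), ("c", 1)])
        k2 = kary("G2", [("c", -1), ("b", -1), ("a", -1)])
        adjs = conserved_adjacencies({"G1": k1, "G2": k2})
        assert all(a.support == 2 for a in adjs)
        assert len(adjs) == 2

    def test_minimum_support_threshold(self):
        k1 = kary("G1", [("a", 1), ("b", 1)])
        k2 = kary("G2", [("a", 1), ("c", 1)])
        adjs = conserved_adjacencies({"G1": k1, "G2": k2}, min_support=2)
        assert adjs == []
        adjs1 = conserved_adjacencies({"G1": k1, "G2": k2}, min_support=1)
        assert {a.key for a in adjs1} == {adj_key("a", HEAD, "b", TAIL),
                                          adj_key("a", HEAD, "c", TAIL)}
        # denominator reflects co-occurrence, not the genome count
        assert all(a.denominator == 1 for a in adjs1)

    def test_multicopy_orders_support_through_any_copy(self):
        table = pd.DataFrame([
            {"gene_id": "m1", "genome": "P", "chrom": "c1", "rank": 0, "strand": 1},
            {"gene_id": "m2", "genome": "P", "chrom": "c1", "rank": 1, "strand": 1},
            {"gene_id": "m3", "genome": "P", "chrom": "c2", "rank": 0, "strand": 1},
            {"gene_id": "m4", "genome": "P", "chrom": "c2", "rank": 1, "strand": 1},
        ]).set_index("gene_id")
        fam = {"m1": "a", "m2": "b", "m3": "a", "m4": "b"}
        orders = family_orders(table, fam)
        adjs = conserved_adjacencies(orders)
        assert {a.key for a in adjs} == {adj_key("a", HEAD, "b", TAIL)}


class TestAssembleCars:
    def test_identical_genomes_reproduce_chromosomes(self):
        chroms = ([("a", 1), ("b", 1)], [("c", 1), ("d", -1)])
        ks = {g: kary(g, *chroms) for g in ("G1", "G2", "G3")}
        adjs = conserved_adjacencies(ks)
        carset = assemble_cars(adjs, {"a", "b", "c", "d"})
        assert carset.n_cars == 2
        assert same_structure(carset.as_karyotype(), kary("anc", *chroms))

    def test_empty_adjacencies_give_singletons(self):
        carset = assemble_cars([], {"a", "b", "c"})
        assert carset.n_cars == 3
        assert all(len(c) == 1 for c in carset.cars)

    def test_conflict_resolution_keeps_higher_support(self):
        a_bc = Adjacency(("b", HEAD), ("c", TAIL), support=3, denominator=3,
                         supporting_genomes=frozenset({"G1", "G2", "G3"}))
        a_bd = Adjacency(("b", HEAD), ("d", TAIL), support=2, denominator=3,
                         supporting_genomes=frozenset({"G1", "G2"}))
        carset = assemble_cars([a_bc, a_bd], {"b", "c", "d"},
                               support_frac=0.0, min_support=2)
        joined = {frozenset(f for f, _ in car) for car in carset.cars}
        assert frozenset({"b", "c"}) in joined
        assert frozenset({"d"}) in joined

    def test_conflict_tie_drops_both(self):
        a_bc = Adjacency(("b", HEAD), ("c", TAIL), support=2, denominator=2,
                         supporting_genomes=frozenset({"G1", "G2"}))
        a_bd = Adjacency(("b", HEAD), ("d", TAIL), support=2, denominator=2,
                         supporting_genomes=frozenset({"G3", "G4"}))
        carset = assemble_cars([a_bc, a_bd], {"b", "c", "d"},
                               support_frac=0.0, min_support=2)
        assert carset.n_cars == 3

    def test_structural_invariants_on_random_inputs(self):
        rng = np.random.default_rng(9)
        fams = [f"f{i}" for i in range(12)]
        for _ in range(30):
            adjs = []
            for _ in range(rng.integers(0, 15)):
                f1, f2 = rng.choice(12, size=2, replace=False)
                adjs.append(Adjacency(
                    (fams[f1], HEAD if rng.random() < 0.5 else TAIL),
                    (fams[f2], HEAD if rng.random() < 0.5 else TAIL),
                    support=int(rng.integers(2, 6)), denominator=6,
                    supporting_genomes=frozenset({"G1", "G2"})))
            carset = assemble_cars(adjs, set(fams), support_frac=0.0,
                                   min_support=2)
            carset.validate(set(fams))  # partition, degree <= 1, acyclic


class TestMergeProtochromosomes:
    def _carset(self):
        return assemble_cars([], {"a", "b", "c"})

    def test_no_candidates_leaves_carset_unchanged(self):
        carset = self._carset()
        merged = merge_protochromosomes(carset, [], support_frac=0.5)
        assert merged.cars == carset.cars

    def test_single_join(self):
        carset = self._carset()
        adj = Adjacency(("a", HEAD), ("b", TAIL), support=2, denominator=4,
                        supporting_genomes=frozenset({"G1", "G2"}))
        merged = merge_protochromosomes(carset, [adj], support_frac=0.5)
        assert merged.n_cars == 2
        assert frozenset({"a", "b"}) in {frozenset(f for f, _ in c)
                                         for c in merged.cars}

    def test_equal_support_ties_join_lexicographically_smallest(self):
        carset = self._carset()
        # both want the head of a; only one can win
        adj_ab = Adjacency(("a", HEAD), ("b", TAIL), support=2, denominator=4,
                           supporting_genomes=frozenset({"G1", "G2"}))
        adj_ac = Adjacency(("a", HEAD), ("c", TAIL), support=2, denominator=4,
                           supporting_genomes=frozenset({"G3", "G4"}))
        merged = merge_protochromosomes(carset, [adj_ac, adj_ab],
                                        support_frac=0.5)
        sets = {frozenset(f for f, _ in c) for c in merged.cars}
        assert frozenset({"a", "b"}) in sets  # (a,h)-(b,t) < (a,h)-(c,t)
        assert merged.n_cars == 2

    def test_telomere_veto_blocks_concordant_chromosome_ends(self):
        carset = self._carset()
        adj = Adjacency(("a", HEAD), ("b", TAIL), support=3, denominator=6,
                        supporting_genomes=frozenset({"G1", "G2", "G3"}))
        tel = {("a", HEAD): 0.5, ("b", TAIL): 0.6}
        merged = merge_protochromosomes(carset, [adj], support_frac=0.5,
                                        telomere_fractions=tel)
        assert merged.n_cars == 3
        # the same join goes through once the ends stop looking telomeric
        tel = {("a", HEAD): 0.1, ("b", TAIL): 0.0}
        merged = merge_protochromosomes(carset, [adj], support_frac=0.5,
                                        telomere_fractions=tel)
        assert merged.n_cars == 2

    def test_rescue_tier_joins_clearly_internal_ends(self):
        carset = self._carset()
        # support below the partial threshold, but neither end ever telomeric
        adj = Adjacency(("a", HEAD), ("b", TAIL), support=2, denominator=8,
                        supporting_genomes=frozenset({"G1", "G2"}))
        tel = {("a", HEAD): 0.0, ("b", TAIL): 0.0}
        merged = merge_protochromosomes(carset, [adj], support_frac=0.5,
                                        telomere_fractions=tel,
                                        rescue_support_frac=0.25)
        assert merged.n_cars == 2
        # without telomere evidence the rescue tier stays off
        merged = merge_protochromosomes(carset, [adj], support_frac=0.5)
        assert merged.n_cars == 3


class TestEndToEndReconstruction:
    def _clade(self, chroms, n_genomes=4):
        return {f"G{i}": kary(f"G{i}", *chroms) for i in range(n_genomes)}

    def test_zero_events_reconstructs_ancestor_exactly(self):
        chroms = ([("a", 1), ("b", -1), ("c", 1)], [("d", 1), ("e", 1)])
        ks = self._clade(chroms)
        adjs = conserved_adjacencies(ks)
        universe = {"a", "b", "c", "d", "e"}
        carset = assemble_cars(adjs, universe)
        merged = merge_protochromosomes(carset, adjs,
                                        telomere_fractions=telomere_support(ks))
        assert same_structure(merged.as_karyotype(), kary("anc", *chroms))

    def test_reversal_invariance_of_reconstruction(self):
        chroms = ([("a", 1), ("b", -1), ("c", 1)],)
        ks = self._clade(chroms)
        ks["G3"] = kary("G3", [("c", -1), ("b", 1), ("a", -1)])
        adjs = conserved_adjacencies(ks)
        carset = assemble_cars(adjs, {"a", "b", "c"})
        assert same_structure(carset.as_karyotype(), kary("anc", *chroms))
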