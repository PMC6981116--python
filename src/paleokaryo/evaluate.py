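"""Scoring a reconstruction against simulator ground truth.

Inferred family ids (anchor-graph components) are mapped back to the true
ancestral families through the simulator's gene->family log (majority vote
per inferred family), after which the reconstructed CAR adjacencies can be
compared directly with the true ancestral adjacency set.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Mapping, Sequence

from .ancestor import CARSet
from .karyotype import Karyotype, chromosome_adjacencies
from .simulate import TrueHistory


@dataclass
class ReconstructionScore:
    n_true_adjacencies: int
    n_recovered: int
    n_cars: int
    true_n_chromosomes: int

    @property
    def adjacency_recovery(self) -> float:
        return self.n_recovered / self.n_true_adjacencies if self.n_true_adjacencies else 1.0


def map_inferred_families(inferred_map: Mapping[str, str],
                          truth: TrueHistory) -> dict[str, str]:
    """inferred family id -> true ancestral family id (majority vote over
    member genes; ties go to the lexicographically smallest true family)."""
    votes: dict[str, Counter] = defaultdict(Counter)
    for gene, fam in inferred_map.items():
        if gene in truth.family_map:
            votes[fam][truth.family_map[gene][0]] += 1
    out: dict[str, str] = {}
    for fam, counter in votes.items():
        best = max(counter.values())
        out[fam] = min(f for f, c in counter.items() if c == best)
    return out


def _car_adjacencies_in_true_families(carset: CARSet,
                                      fam_translation: Mapping[str, str]) -> set:
    adys = set()
    for car in carset.cars:
        translated = tuple((fam_translation[f], s) for f, s in car
                           if f in fam_translation)
        adys.update(chromosome_adjacencies(translated))
    return adys


def score_reconstruction(carset: CARSet,
                         inferred_family_map: Mapping[str, str],
                         truth: TrueHistory) -> ReconstructionScore:
    """Fraction of true ancestral adjacencies present in the reconstructed
    CAR set, plus CAR/chromosome counts.

    The true ancestor's markers carry a ``.0`` copy suffix which is stripped
    so they live in plain family space."""
    plain_anc = Karyotype("anc", [
        tuple((f.rsplit(".", 1)[0], s) for f, s in chrom)
        for chrom in truth.ancestor.chromosomes])
    true_adj = plain_anc.adjacencies()
    translation = map_inferred_families(inferred_family_map, truth)
    rec_adj = _car_adjacencies_in_true_families(carset, translation)
    return ReconstructionScore(
        n_true_adjacencies=len(true_adj),
        n_recovered=len(true_adj & rec_adj),
        n_cars=carset.n_cars,
        true_n_chromosomes=plain_anc.n_chromosomes)
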