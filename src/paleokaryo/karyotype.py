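"""Signed multichromosomal karyotypes and gene-extremity bookkeeping.

A genome is modelled as an unordered collection of linear chromosomes; each
chromosome is an ordered tuple of signed markers ``(family, sign)`` with
``sign`` in {+1, -1} giving the coding orientation of that family copy on the
chromosome.  Every marker has two *extremities*, a tail and a head; a
+oriented marker exposes its tail on the left and its head on the right, a
-oriented marker the reverse.  An *adjacency* is the unordered pair of
extremities that face each other between two consecutive markers; chromosome
ends contribute *telomeres* (single exposed extremities).

This extremity algebra is the common currency of the reconstruction
(conserved-adjacency collection, CAR assembly) and of the rearrangement
machinery (DCJ distance, event application), so it lives in one module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

TAIL = "t"
HEAD = "h"

#: A signed marker: (family identifier, orientation +1/-1).
Marker = tuple[str, int]
#: A marker extremity: (family identifier, "t" | "h").
Extremity = tuple[str, str]
Chromosome = tuple[Marker, ...]


def reverse_complement(chrom: Sequence[Marker]) -> Chromosome:
    """Reverse a chromosome and flip every marker's orientation."""
    return tuple((fam, -sign) for fam, sign in reversed(chrom))


def marker_extremities(marker: Marker) -> tuple[Extremity, Extremity]:
    """(left, right) extremity of a marker as laid on the chromosome."""
    fam, sign = marker
    if sign >= 0:
        return (fam, TAIL), (fam, HEAD)
    return (fam, HEAD), (fam, TAIL)


def chromosome_adjacencies(chrom: Sequence[Marker]) -> list[frozenset[Extremity]]:
    out = []
    for left, right in zip(chrom, chrom[1:]):
        out.append(frozenset({marker_extremities(left)[1], marker_extremities(right)[0]}))
    return out


def chromosome_telomeres(chrom: Sequence[Marker]) -> list[Extremity]:
    if not chrom:
        return []
    return [marker_extremities(chrom[0])[0], marker_extremities(chrom[-1])[1]]


def canonical_chromosome(chrom: Sequence[Marker]) -> Chromosome:
    """Orientation-independent representative: a chromosome read backwards is
    the same chromosome."""
    fwd = tuple(chrom)
    rev = reverse_complement(chrom)
    return min(fwd, rev)


@dataclass
class Karyotype:
    """An ordered-gene-content genome over signed family markers.

    Parameters
    ----------
    genome_id:
        Label of the genome (modern species or reconstructed ancestor).
    chromosomes:
        List of linear chromosomes; each a tuple of ``(family, sign)``.
    """

    genome_id: str
    chromosomes: list[Chromosome] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.chromosomes = [tuple((str(f), 1 if s >= 0 else -1) for f, s in c)
                            for c in self.chromosomes]
        seen: set[str] = set()
        for chrom in self.chromosomes:
            for fam, _ in chrom:
                if fam in seen:
                    raise ValueError(
                        f"family {fam!r} occurs more than once in genome "
                        f"{self.genome_id!r}; resolve copies first")
                seen.add(fam)

    @property
    def n_chromosomes(self) -> int:
        return len(self.chromosomes)

    @property
    def n_markers(self) -> int:
        return sum(len(c) for c in self.chromosomes)

    def families(self) -> set[str]:
        return {fam for chrom in self.chromosomes for fam, _ in chrom}

    def adjacencies(self) -> set[frozenset[Extremity]]:
        out: set[frozenset[Extremity]] = set()
        for chrom in self.chromosomes:
            out.update(chromosome_adjacencies(chrom))
        return out

    def telomeres(self) -> set[Extremity]:
        out: set[Extremity] = set()
        for chrom in self.chromosomes:
            out.update(chromosome_telomeres(chrom))
        return out

    def canonical(self) -> tuple[Chromosome, ...]:
        """Representation-independent form: chromosomes canonically oriented
        and sorted.  Two karyotypes describe the same genome structure iff
        their canonical forms are equal."""
        return tuple(sorted(canonical_chromosome(c) for c in self.chromosomes if c))

    def restricted_to(self, families: Iterable[str]) -> "Karyotype":
        """Project onto a marker subset, dropping all other markers and
        splicing their neighbours together (used to compare genomes with
        unequal gene content over their shared families)."""
        keep = set(families)
        chroms = []
        for chrom in self.chromosomes:
            reduced = tuple(m for m in chrom if m[0] in keep)
            if reduced:
                chroms.append(reduced)
        return Karyotype(self.genome_id, chroms)


def same_structure(a: Karyotype, b: Karyotype) -> bool:
    """True iff the two karyotypes are identical up to chromosome order and
    whole-chromosome orientation (both are representational freedoms)."""
    return a.canonical() == b.canonical()
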