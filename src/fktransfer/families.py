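"""Gene family maps and candidate homolog pairs.

Families (TreeFam-style) provide the shared vocabulary that makes network
neighborhoods comparable across organisms. Candidate pairs for functional
analogy are restricted to ortholog/paralog pairs within one family.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Optional, Tuple

RELATIONS = ("ortholog", "paralog", "rbh")


@dataclass
class FamilyMap:
    """gene -> family id; each gene belongs to at most one family."""

    assignments: Dict[str, str]

    @property
    def families(self) -> FrozenSet[str]:
        return frozenset(self.assignments.values())

    def family_of(self, gene: str) -> Optional[str]:
        return self.assignments.get(gene)

    def families_among(self, genes: Iterable[str]) -> FrozenSet[str]:
        """Distinct families represented among the given genes."""
        return frozenset(
            f for f in (self.assignments.get(g) for g in genes) if f is not None
        )

    @classmethod
    def read_tsv(cls, path) -> "FamilyMap":
        assignments: Dict[str, str] = {}
        with open(path, newline="") as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or row[0].startswith("#"):
                    continue
                gene, family = row[0], row[1]
                if gene in assignments and assignments[gene] != family:
                    raise ValueError(f"gene {gene!r} mapped to two families")
                assignments[gene] = family
        return cls(assignments)

    def write_tsv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            for gene in sorted(self.assignments):
                w.writerow([gene, self.assignments[gene]])


@dataclass(frozen=True, order=True)
class HomologPair:
    gene_a: str
    organism_a: str
    gene_b: str
    organism_b: str
    family_id: str
    relation: str = "ortholog"

    def __post_init__(self):
        if self.relation not in RELATIONS:
            raise ValueError(f"unknown relation {self.relation!r}")
        if self.gene_a == self.gene_b:
            raise ValueError("self-pair is not a homolog pair")

    @property
    def pair(self) -> Tuple[str, str]:
        return tuple(sorted((self.gene_a, self.gene_b)))


def read_homolog_pairs(path) -> List[HomologPair]:
    pairs: List[HomologPair] = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            pairs.append(HomologPair(*row[:6]))
    return pairs


def write_homolog_pairs(pairs: Iterable[HomologPair], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for p in sorted(pairs):
            w.writerow(
                [p.gene_a, p.organism_a, p.gene_b, p.organism_b, p.family_id, p.relation]
            )
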