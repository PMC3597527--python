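"""Gene-to-process annotations: filtering, propagation, and cross-organism
transfer between functional analogs (or sequence-only homolog pairs).

Annotations carry GO-style evidence codes, qualifiers, and curation dates.
Only direct experimental records (EXP, IDA, IPI, IMP, IGI, IEP; never
NOT-qualified) seed transfer and evaluation; transferred records keep the
source record's date and a pointer to the source gene.
"""
from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, replace
from typing import Dict, FrozenSet, Iterable, Iterator, List, Optional, Set, Tuple

from .errors import UntrainableTermError
from .ontology import OntologyDAG

#: GO experimental evidence codes retained for training/transfer/evaluation
EXPERIMENTAL_CODES = frozenset({"EXP", "IDA", "IPI", "IMP", "IGI", "IEP"})


@dataclass(frozen=True)
class Annotation:
    gene: str
    organism: str
    term: str
    evidence: str
    date: dt.date
    qualifier: str = ""
    provenance: str = "direct"  # direct | transferred
    source_gene: Optional[str] = None
    source_organism: Optional[str] = None

    def __post_init__(self):
        if self.provenance not in ("direct", "transferred"):
            raise ValueError(f"bad provenance {self.provenance!r}")
        if self.provenance == "transferred" and self.source_gene is None:
            raise ValueError("transferred annotation requires source_gene")

    @property
    def is_not(self) -> bool:
        return "NOT" in self.qualifier.split("|")


class AnnotationSet:
    """An ordered, duplicate-free collection of Annotation records."""

    def __init__(self, records: Iterable[Annotation] = ()):
        self.records: List[Annotation] = list(records)

    def __iter__(self) -> Iterator[Annotation]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def add(self, record: Annotation) -> None:
        self.records.append(record)

    def filter(self, pred) -> "AnnotationSet":
        return AnnotationSet(r for r in self.records if pred(r))

    def for_organism(self, organism: str) -> "AnnotationSet":
        return self.filter(lambda r: r.organism == organism)

    def terms(self) -> FrozenSet[str]:
        return frozenset(r.term for r in self.records)

    def genes(self) -> FrozenSet[str]:
        return frozenset(r.gene for r in self.records)

    def term_genes(
        self,
        term: str,
        organism: Optional[str] = None,
        provenance: Optional[str] = None,
    ) -> FrozenSet[str]:
        return frozenset(
            r.gene
            for r in self.records
            if r.term == term
            and (organism is None or r.organism == organism)
            and (provenance is None or r.provenance == provenance)
        )

    def gene_terms(self, gene: str) -> FrozenSet[str]:
        return frozenset(r.term for r in self.records if r.gene == gene)

    def has(self, gene: str, term: str) -> bool:
        return any(r.gene == gene and r.term == term for r in self.records)


# ---------------------------------------------------------------------------
# Filtering and propagation
# ---------------------------------------------------------------------------

def filter_experimental(anns: AnnotationSet) -> AnnotationSet:
    """Keep the six experimental evidence codes; drop every NOT annotation."""
    return anns.filter(lambda r: r.evidence in EXPERIMENTAL_CODES and not r.is_not)


def propagate(anns: AnnotationSet, dag: OntologyDAG) -> AnnotationSet:
    """Annotate every gene to all ancestors of its directly annotated terms.

    Duplicate (gene, organism, term) records collapse to one, keeping the
    earliest date (direct records win ties over transferred ones).
    """
    best: Dict[Tuple[str, str, str], Annotation] = {}

    def consider(rec: Annotation) -> None:
        key = (rec.gene, rec.organism, rec.term)
        cur = best.get(key)
        if cur is None:
            best[key] = rec
        elif (rec.date, rec.provenance == "transferred") < (
            cur.date,
            cur.provenance == "transferred",
        ):
            best[key] = rec

    for rec in anns:
        if rec.term not in dag:
            raise KeyError(f"annotated term missing from ontology: {rec.term!r}")
        consider(rec)
        for anc in dag.ancestors(rec.term):
            consider(replace(rec, term=anc))
    return AnnotationSet(
        sorted(best.values(), key=lambda r: (r.organism, r.gene, r.term, r.date))
    )


# ---------------------------------------------------------------------------
# Transfer
# ---------------------------------------------------------------------------

def _transfer_over_pairs(
    anns: AnnotationSet,
    pairs: Iterable[Tuple[str, str, str, str]],
) -> AnnotationSet:
    """Copy direct annotations both ways along (gene_a, org_a, gene_b, org_b).

    One hop only: previously transferred records are never re-transferred,
    which also makes the operation idempotent. Existing (gene, term)
    assignments are never duplicated or overwritten.
    """
    out = AnnotationSet(list(anns.records))
    have: Set[Tuple[str, str]] = {(r.gene, r.term) for r in anns}
    direct: Dict[str, List[Annotation]] = {}
    for r in anns:
        if r.provenance == "direct":
            direct.setdefault(r.gene, []).append(r)

    def copy_to(src: str, src_org: str, dst: str, dst_org: str) -> None:
        for rec in sorted(direct.get(src, ()), key=lambda r: (r.term, r.date)):
            if (dst, rec.term) in have:
                continue
            out.add(
                Annotation(
                    gene=dst,
                    organism=dst_org,
                    term=rec.term,
                    evidence=rec.evidence,
                    date=rec.date,
                    provenance="transferred",
                    source_gene=src,
                    source_organism=src_org,
                )
            )
            have.add((dst, rec.term))

    for a, org_a, b, org_b in sorted(pairs):
        copy_to(a, org_a, b, org_b)
        copy_to(b, org_b, a, org_a)
    return out


def transfer(anns: AnnotationSet, analogs) -> AnnotationSet:
    """Propagate experimental annotations between functional analogs."""
    pairs = [
        (s.gene_a, s.organism_a, s.gene_b, s.organism_b) for s in analogs.pairs
    ]
    return _transfer_over_pairs(anns, pairs)


def transfer_sequence_only(
    anns: AnnotationSet, rbh_pairs: Iterable[Tuple[str, str, str, str]]
) -> AnnotationSet:
    """Baseline transfer over reciprocal-best-hit pairs, no functional filter."""
    return _transfer_over_pairs(anns, rbh_pairs)


# ---------------------------------------------------------------------------
# Training sets
# ---------------------------------------------------------------------------

@dataclass
class TrainingSet:
    term: str
    positives: FrozenSet[str]
    negatives: FrozenSet[str]

    def __post_init__(self):
        if self.positives & self.negatives:
            raise ValueError("positives and negatives overlap")


def assemble_training_sets(
    term: str,
    anns: AnnotationSet,
    universe: FrozenSet[str] | Set[str],
    dag: OntologyDAG,
    exclusion_terms: Iterable[str] = (),
) -> TrainingSet:
    """Per-term positives (direct + transferred) and DAG-aware negatives.

    Negatives are the universe minus the positives and minus any gene
    annotated (direct or transferred) to an ancestor/descendant of the term
    or to a configured exclusion term.
    """
    universe = frozenset(universe)
    positives = frozenset(g for g in anns.term_genes(term) if g in universe)
    if not positives:
        raise UntrainableTermError(f"term {term!r} has no positive examples")
    # ontology roots annotate every gene after propagation and would wipe
    # out the negative pool, so they never drive exclusion
    excluded_terms = (set(dag.relatives(term)) - set(dag.roots)) | set(exclusion_terms)
    excluded_genes: Set[str] = set()
    for t in excluded_terms:
        excluded_genes |= anns.term_genes(t)
    negatives = universe - positives - excluded_genes
    return TrainingSet(term, positives, frozenset(negatives))
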