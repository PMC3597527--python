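"""Pairwise gold standard for network integration.

Related pairs are co-annotated to at least one expert-selected "fringe"
biological-process term. Unrelated pairs are annotated gene pairs sharing
no fringe/pathway term, excluding pairs whose two terms overlap more than
expected by chance (hypergeometric p < 0.05) and pairs co-annotated to a
configured list of minimally informative "negative" terms.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, FrozenSet, Iterable, Mapping, Optional, Set, Tuple

from scipy.stats import hypergeom

from .annotations import AnnotationSet
from .errors import ConfigurationError
from .evidence import Pair, canonical_pair


@dataclass
class PairGoldStandard:
    related: FrozenSet[Pair]
    unrelated: FrozenSet[Pair]

    def __post_init__(self):
        self.related = frozenset(canonical_pair(*p) for p in self.related)
        self.unrelated = frozenset(canonical_pair(*p) for p in self.unrelated)
        if self.related & self.unrelated:
            raise ValueError("related and unrelated pair sets overlap")


def _term_sets(
    anns: AnnotationSet, terms: Iterable[str], organism: Optional[str]
) -> Dict[str, FrozenSet[str]]:
    return {
        t: anns.term_genes(t, organism=organism) for t in terms
    }


def build_pair_gold_standard(
    anns: AnnotationSet,
    fringe_terms: Iterable[str],
    pathway_sets: Optional[Mapping[str, Iterable[str]]] = None,
    negative_terms: Iterable[str] = (),
    overlap_alpha: float = 0.05,
    organism: Optional[str] = None,
    universe: Optional[Iterable[str]] = None,
) -> PairGoldStandard:
    """Derive related/unrelated gene pairs from co-annotation.

    ``pathway_sets`` plays the role of auxiliary pathway databases whose
    co-memberships disqualify a pair from the unrelated set. ``universe``
    sets the hypergeometric background (defaults to all annotated genes).
    """
    fringe = list(dict.fromkeys(fringe_terms))
    if not fringe:
        raise ConfigurationError("empty fringe term list")
    fringe_sets = _term_sets(anns, fringe, organism)
    extra_sets: Dict[str, FrozenSet[str]] = {
        t: frozenset(gs) for t, gs in (pathway_sets or {}).items()
    }
    neg_sets = _term_sets(anns, negative_terms, organism)

    all_sets: Dict[str, FrozenSet[str]] = {**extra_sets, **fringe_sets}
    scoped = anns if organism is None else anns.for_organism(organism)
    candidate_genes = sorted(scoped.genes() | set().union(*all_sets.values(), frozenset()))
    background = sorted(universe) if universe is not None else candidate_genes
    n_bg = len(background)

    related: Set[Pair] = set()
    for genes in fringe_sets.values():
        for a, b in combinations(sorted(genes), 2):
            related.add(canonical_pair(a, b))

    # term pairs with significant gene-set overlap (hypergeometric tail)
    gene_terms: Dict[str, Set[str]] = {}
    for t, genes in all_sets.items():
        for g in genes:
            gene_terms.setdefault(g, set()).add(t)
    sig: Set[Tuple[str, str]] = set()
    term_ids = sorted(all_sets)
    for t1, t2 in combinations(term_ids, 2):
        s1, s2 = all_sets[t1], all_sets[t2]
        if not s1 or not s2:
            continue
        k = len(s1 & s2)
        p = float(hypergeom.sf(k - 1, n_bg, len(s1), len(s2)))
        if p < overlap_alpha:
            sig.add((t1, t2))
            sig.add((t2, t1))

    def significant_overlap(g1: str, g2: str) -> bool:
        for t1 in gene_terms.get(g1, ()):
            for t2 in gene_terms.get(g2, ()):
                if t1 != t2 and (t1, t2) in sig:
                    return True
        return False

    unrelated: Set[Pair] = set()
    for a, b in combinations(candidate_genes, 2):
        pair = canonical_pair(a, b)
        if pair in related:
            continue
        shared = gene_terms.get(a, set()) & gene_terms.get(b, set())
        if shared:  # co-annotated to some fringe/pathway term
            continue
        if any(a in gs and b in gs for gs in neg_sets.values()):
            continue
        if significant_overlap(a, b):
            continue
        unrelated.add(pair)

    return PairGoldStandard(frozenset(related), frozenset(unrelated))
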