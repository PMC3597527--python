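"""Functional-analog calling by hypergeometric neighborhood-family overlap.

For a candidate homolog pair (G1, G2), each gene's binary-network
neighborhood is summarized as the set of gene families of its direct
neighbors (m and n families). The functional similarity score is the
hypergeometric tail probability of observing at least k shared families
when drawing n from a background of N families; pairs with p <= 0.01 are
called functional analogs and become targets for annotation transfer.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Sequence, Tuple

import pandas as pd
from scipy.stats import hypergeom

from .errors import MissingGeneError
from .families import FamilyMap, HomologPair
from .network import FunctionalNetwork, binarize_network

logger = logging.getLogger(__name__)

Adjacency = Mapping[str, FrozenSet[str]]


@dataclass(frozen=True)
class NeighborhoodProfile:
    gene: str
    families: FrozenSet[str]

    @property
    def size(self) -> int:
        return len(self.families)


@dataclass(frozen=True)
class AnalogScore:
    gene_a: str
    organism_a: str
    gene_b: str
    organism_b: str
    k: int
    m: int
    n: int
    n_background: int
    p: float
    relation: str = "ortholog"
    family_id: str = ""
    flagged: bool = False  # empty neighborhood on one side

    @property
    def pair(self) -> Tuple[str, str]:
        return tuple(sorted((self.gene_a, self.gene_b)))


@dataclass
class AnalogMap:
    """Analog calls at a score cutoff, with the full audit table retained."""

    pairs: List[AnalogScore]
    cutoff: float
    audit: pd.DataFrame = field(default_factory=pd.DataFrame)

    def pair_set(self) -> FrozenSet[Tuple[str, str]]:
        return frozenset(s.pair for s in self.pairs)


def family_neighborhood(
    gene: str, adjacency: Adjacency, fam: FamilyMap
) -> NeighborhoodProfile:
    """Distinct families of a gene's direct neighbors (unmapped ones skipped)."""
    if gene not in adjacency:
        raise MissingGeneError(f"gene {gene!r} not in network adjacency")
    return NeighborhoodProfile(gene, fam.families_among(adjacency[gene]))


def functional_similarity(
    g1: NeighborhoodProfile, g2: NeighborhoodProfile, n_background: int
) -> Tuple[int, int, int, float, bool]:
    """(k, m, n, p, flagged) for the family-overlap hypergeometric tail.

    p = P(X >= k) with X ~ Hypergeom(N, m, n); symmetric in (m, n). An
    empty neighborhood on either side gives p = 1 (no evidence), flagged.
    """
    m = g1.size
    n = g2.size
    k = len(g1.families & g2.families)
    if n_background < max(m, n):
        raise ValueError(
            f"background family count {n_background} smaller than profile sizes"
        )
    if m == 0 or n == 0:
        return k, m, n, 1.0, True
    p = float(hypergeom.sf(k - 1, n_background, m, n))
    return k, m, n, min(p, 1.0), False


def call_analogs(
    candidates: Sequence[HomologPair],
    networks: Mapping[str, FunctionalNetwork],
    fam: FamilyMap,
    cutoff: float = 0.01,
    binarize_cutoff: float = 0.5,
) -> AnalogMap:
    """Score within-family candidate pairs and keep those with p <= cutoff.

    Neighborhood profiles are computed in each gene's own organism's
    network; the background N is the number of distinct families among
    family-mapped genes across the two organisms' networks. Candidates
    whose genes are absent from their network are skipped (logged).
    """
    adjacency: Dict[str, Adjacency] = {
        org: binarize_network(net, binarize_cutoff) for org, net in networks.items()
    }
    net_families: Dict[str, FrozenSet[str]] = {
        org: fam.families_among(net.genes) for org, net in networks.items()
    }

    rows = []
    hits: List[AnalogScore] = []
    for cand in candidates:
        if cand.organism_a not in networks or cand.organism_b not in networks:
            logger.info("skipping %s: organism without a network", cand)
            continue
        adj_a = adjacency[cand.organism_a]
        adj_b = adjacency[cand.organism_b]
        if cand.gene_a not in adj_a or cand.gene_b not in adj_b:
            logger.info("skipping %s: gene absent from its network", cand)
            continue
        prof_a = family_neighborhood(cand.gene_a, adj_a, fam)
        prof_b = family_neighborhood(cand.gene_b, adj_b, fam)
        n_bg = len(net_families[cand.organism_a] | net_families[cand.organism_b])
        k, m, n, p, flagged = functional_similarity(prof_a, prof_b, n_bg)
        score = AnalogScore(
            gene_a=cand.gene_a,
            organism_a=cand.organism_a,
            gene_b=cand.gene_b,
            organism_b=cand.organism_b,
            k=k,
            m=m,
            n=n,
            n_background=n_bg,
            p=p,
            relation=cand.relation,
            family_id=cand.family_id,
            flagged=flagged,
        )
        rows.append(
            {
                "gene_a": score.gene_a,
                "organism_a": score.organism_a,
                "gene_b": score.gene_b,
                "organism_b": score.organism_b,
                "family_id": score.family_id,
                "relation": score.relation,
                "m": m,
                "n": n,
                "k": k,
                "N": n_bg,
                "p": p,
                "analog": p <= cutoff,
            }
        )
        if p <= cutoff:
            hits.append(score)
    audit = pd.DataFrame(
        rows,
        columns=[
            "gene_a", "organism_a", "gene_b", "organism_b", "family_id",
            "relation", "m", "n", "k", "N", "p", "analog",
        ],
    )
    return AnalogMap(pairs=hits, cutoff=cutoff, audit=audit)
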