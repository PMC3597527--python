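"""Per-dataset pairwise evidence scoring and discretization.

Each genomic dataset is summarized as one real score per unordered gene
pair: Fisher z-transformed Pearson correlation for expression, supporting
assay counts for physical/genetic interactions, Pearson correlation of
binary motif-hit profiles for TF binding sites, and size-normalized
co-occurrence sums for phenotype/disease memberships. Scores are then
discretized into a small number of levels (|D_k|) for the naive Bayes
integration.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from . import _condensed
from .errors import EvidenceError, InsufficientDataError, MissingGeneError

#: clamp |r| below 1 before atanh so identical profiles stay finite
CORRELATION_CLAMP = 1.0 - 1e-6

Pair = Tuple[str, str]


def canonical_pair(a: str, b: str) -> Pair:
    """Unordered pair as a sorted tuple; self-pairs are rejected."""
    if a == b:
        raise ValueError(f"self-pair not allowed: {a!r}")
    return (a, b) if a < b else (b, a)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ExpressionDataset:
    """A gene x condition expression matrix for one organism."""

    dataset_id: str
    organism: str
    values: pd.DataFrame  # genes in rows, conditions in columns

    def __post_init__(self) -> None:
        if self.values.shape[1] < 2:
            raise InsufficientDataError(
                f"{self.dataset_id}: need >=2 conditions, got {self.values.shape[1]}"
            )


@dataclass
class PhenotypeCollection:
    """Phenotype/disease gene-set memberships for one organism."""

    phenotypes: Dict[str, FrozenSet[str]]

    def __post_init__(self) -> None:
        self.phenotypes = {
            k: frozenset(v) for k, v in self.phenotypes.items()
        }
        for pid, genes in self.phenotypes.items():
            if not genes:
                raise ValueError(f"phenotype {pid!r} has an empty gene set")

    @property
    def n(self) -> int:
        return len(self.phenotypes)


class PairwiseEvidence:
    """One dataset's discretized pairwise scores over a fixed gene universe.

    Scores are stored condensed (one slot per unordered pair, NaN where the
    pair is unobserved). ``levels`` holds the discretized level per pair
    (-1 where unobserved) and ``level_count`` is |D_k| = len(bin_edges)+1.
    """

    def __init__(
        self,
        dataset_id: str,
        organism: str,
        genes: Sequence[str],
        values: np.ndarray,
        bin_edges: Sequence[float],
    ) -> None:
        self.dataset_id = dataset_id
        self.organism = organism
        self.genes: Tuple[str, ...] = tuple(genes)
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"{dataset_id}: duplicate gene ids")
        values = np.asarray(values, dtype=float)
        if values.shape != (_condensed.n_pairs(len(self.genes)),):
            raise ValueError(
                f"{dataset_id}: expected condensed vector of length "
                f"{_condensed.n_pairs(len(self.genes))}, got {values.shape}"
            )
        if np.any(np.isinf(values)):
            raise EvidenceError(f"{dataset_id}: non-finite score present")
        edges = tuple(float(e) for e in bin_edges)
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValueError(f"{dataset_id}: bin edges must be strictly ascending")
        if not edges:
            raise ValueError(f"{dataset_id}: need at least one bin edge")
        self.values = values
        self.bin_edges: Tuple[float, ...] = edges
        self._index = {g: i for i, g in enumerate(self.genes)}
        observed = ~np.isnan(values)
        levels = np.full(values.shape, -1, dtype=np.int16)
        # score exactly at an edge belongs to the upper bin (half-open bins)
        levels[observed] = np.searchsorted(edges, values[observed], side="right")
        self.levels = levels

    @property
    def level_count(self) -> int:
        return len(self.bin_edges) + 1

    def gene_index(self, gene: str) -> int:
        try:
            return self._index[gene]
        except KeyError:
            raise MissingGeneError(f"{self.dataset_id}: unknown gene {gene!r}") from None

    def pair_slot(self, a: str, b: str) -> int:
        return int(
            _condensed.pair_index(self.gene_index(a), self.gene_index(b), len(self.genes))
        )

    def score(self, a: str, b: str) -> float:
        return float(self.values[self.pair_slot(a, b)])

    def level(self, a: str, b: str) -> int:
        return int(self.levels[self.pair_slot(a, b)])

    def score_map(self) -> Dict[Pair, float]:
        """Observed scores as an unordered-pair dict (small datasets only)."""
        ii, jj = _condensed.pair_arrays(len(self.genes))
        out: Dict[Pair, float] = {}
        for i, j, v in zip(ii, jj, self.values):
            if not math.isnan(v):
                out[canonical_pair(self.genes[i], self.genes[j])] = float(v)
        return out


# ---------------------------------------------------------------------------
# Scorers
# ---------------------------------------------------------------------------

def _profile(dataset: ExpressionDataset, gene: str) -> np.ndarray:
    if gene not in dataset.values.index:
        raise MissingGeneError(f"{dataset.dataset_id}: unknown gene {gene!r}")
    return dataset.values.loc[gene].to_numpy(dtype=float)


def coexpression_score(dataset: ExpressionDataset, gene_a: str, gene_b: str) -> float:
    """Fisher z-transformed Pearson correlation of two condition profiles.

    r is clamped to +/-(1-1e-6) before atanh so perfectly correlated
    profiles map to a large finite value instead of infinity.
    """
    x = _profile(dataset, gene_a)
    y = _profile(dataset, gene_b)
    mask = np.isfinite(x) & np.isfinite(y)
    if mask.sum() < 2:
        raise InsufficientDataError(
            f"{dataset.dataset_id}: <2 overlapping finite conditions for "
            f"({gene_a}, {gene_b})"
        )
    x, y = x[mask], y[mask]
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        r = 0.0  # constant profile carries no co-expression information
    else:
        r = float(np.corrcoef(x, y)[0, 1])
    r = float(np.clip(r, -CORRELATION_CLAMP, CORRELATION_CLAMP))
    return math.atanh(r)


def interaction_count_score(
    records: Iterable[Tuple[Pair, str]], gene_a: str, gene_b: str
) -> int:
    """Number of experimental assay records supporting the interaction.

    Counts records, not distinct assay types: a pair with two-hybrid and
    western blot evidence receives two counts; an absent pair scores 0.
    """
    target = canonical_pair(gene_a, gene_b)
    return sum(1 for pair, _assay in records if canonical_pair(*pair) == target)


def motif_profile_score(motif_hits: pd.DataFrame, gene_a: str, gene_b: str) -> float:
    """Pearson correlation of two genes' binary motif-presence vectors.

    A constant row (all motifs hit or none) has undefined correlation and
    is scored 0 (neutral evidence).
    """
    for gene in (gene_a, gene_b):
        if gene not in motif_hits.index:
            raise MissingGeneError(f"motif matrix: unknown gene {gene!r}")
    x = motif_hits.loc[gene_a].to_numpy(dtype=float)
    y = motif_hits.loc[gene_b].to_numpy(dtype=float)
    if len(x) < 2:
        raise InsufficientDataError("motif matrix: need >=2 motifs")
    if x.std() == 0 or y.std() == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def phenotype_cooccurrence_score(
    coll: PhenotypeCollection, gene_a: str, gene_b: str
) -> float:
    """Sum over phenotypes k of I_k(a) * I_k(b) / N_k.

    N_k is the number of genes annotated to phenotype k; genes absent from
    every phenotype score 0.
    """
    canonical_pair(gene_a, gene_b)
    return sum(
        1.0 / len(genes)
        for genes in coll.phenotypes.values()
        if gene_a in genes and gene_b in genes
    )


# ---------------------------------------------------------------------------
# Discretization and dataset-level builders
# ---------------------------------------------------------------------------

def discretize(
    scores: Mapping[Pair, float],
    bin_edges: Sequence[float],
    dataset_id: str = "dataset",
    organism: str = "organism",
    genes: Sequence[str] | None = None,
) -> PairwiseEvidence:
    """Map raw pair scores to level indices over half-open bins.

    len(bin_edges)+1 levels; a score exactly on an edge goes to the upper
    bin. Non-finite scores are rejected with dataset/pair context.
    """
    if genes is None:
        genes = sorted({g for pair in scores for g in pair})
    genes = list(genes)
    n = len(genes)
    index = {g: i for i, g in enumerate(genes)}
    values = np.full(_condensed.n_pairs(n), np.nan)
    for (a, b), v in scores.items():
        if not math.isfinite(v):
            raise EvidenceError(
                f"{dataset_id}: non-finite score for pair ({a}, {b}): {v!r}"
            )
        a, b = canonical_pair(a, b)
        values[_condensed.pair_index(index[a], index[b], n)] = v
    return PairwiseEvidence(dataset_id, organism, genes, values, bin_edges)


def quantile_bin_edges(
    values: np.ndarray, quantiles: Sequence[float] = (0.5, 0.8, 0.95, 0.99)
) -> Tuple[float, ...]:
    """Empirical-quantile bin edges emphasizing the informative upper tail.

    Duplicate edges (heavily tied scores) are collapsed; at least one edge
    always remains (falling back to the median +/- epsilon if needed).
    """
    obs = values[~np.isnan(values)]
    if obs.size == 0:
        raise EvidenceError("cannot place bin edges on an empty dataset")
    edges: List[float] = []
    for q in quantiles:
        e = float(np.quantile(obs, q))
        if not edges or e > edges[-1]:
            edges.append(e)
    if not edges:  # pragma: no cover - defensive
        edges = [float(np.median(obs))]
    return tuple(edges)


def coexpression_evidence(
    dataset: ExpressionDataset,
    bin_edges: Sequence[float] | None = None,
    quantiles: Sequence[float] = (0.5, 0.8, 0.95, 0.99),
) -> PairwiseEvidence:
    """All-pairs Fisher z-correlation evidence for one expression dataset."""
    mat = dataset.values.to_numpy(dtype=float)
    genes = list(dataset.values.index)
    sd = mat.std(axis=1)
    centered = mat - mat.mean(axis=1, keepdims=True)
    safe_sd = np.where(sd == 0, 1.0, sd)
    z = centered / (safe_sd[:, None] * np.sqrt(mat.shape[1]))
    corr = z @ z.T
    corr[sd == 0, :] = 0.0
    corr[:, sd == 0] = 0.0
    np.clip(corr, -CORRELATION_CLAMP, CORRELATION_CLAMP, out=corr)
    ii, jj = _condensed.pair_arrays(len(genes))
    values = np.arctanh(corr[ii, jj])
    if bin_edges is None:
        bin_edges = quantile_bin_edges(values, quantiles)
    return PairwiseEvidence(dataset.dataset_id, dataset.organism, genes, values, bin_edges)


def phenotype_evidence(
    coll: PhenotypeCollection,
    genes: Sequence[str],
    dataset_id: str,
    organism: str,
    bin_edges: Sequence[float] = (1e-12, 0.5),
) -> PairwiseEvidence:
    """All-pairs size-normalized co-occurrence evidence.

    Default bins {0, (0, 0.5], >0.5} capture no / weak / strong shared
    phenotype membership.
    """
    genes = list(genes)
    indicator = np.zeros((len(genes), coll.n))
    weights = np.zeros(coll.n)
    gidx = {g: i for i, g in enumerate(genes)}
    for k, (pid, members) in enumerate(sorted(coll.phenotypes.items())):
        weights[k] = 1.0 / len(members)
        for g in members:
            if g in gidx:
                indicator[gidx[g], k] = 1.0
    scores = (indicator * weights) @ indicator.T
    ii, jj = _condensed.pair_arrays(len(genes))
    return PairwiseEvidence(dataset_id, organism, genes, scores[ii, jj], bin_edges)
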