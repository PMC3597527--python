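"""Functional relationship networks.

A network is a symmetric map from unordered gene pairs to the posterior
probability that the two genes co-function in the same biological process.
Internally a dense symmetric matrix over a fixed gene order; NaN marks an
undefined edge, the diagonal is always undefined (no self-edges).
"""
from __future__ import annotations

from typing import Dict, FrozenSet, Mapping, Sequence, Tuple

import numpy as np

from . import _condensed
from .errors import MissingGeneError
from .evidence import Pair, canonical_pair


class FunctionalNetwork:
    def __init__(self, organism: str, genes: Sequence[str], matrix: np.ndarray | None = None):
        self.organism = organism
        self.genes: Tuple[str, ...] = tuple(genes)
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene ids in network universe")
        n = len(self.genes)
        if matrix is None:
            matrix = np.full((n, n), np.nan)
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (n, n):
            raise ValueError(f"matrix shape {matrix.shape} != ({n}, {n})")
        if not np.allclose(matrix, matrix.T, equal_nan=True):
            raise ValueError("network matrix must be symmetric")
        finite = matrix[np.isfinite(matrix)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("edge probabilities must lie in [0, 1]")
        np.fill_diagonal(matrix, np.nan)
        self.matrix = matrix
        self._index = {g: i for i, g in enumerate(self.genes)}

    # -- construction -----------------------------------------------------
    @classmethod
    def from_edges(
        cls, organism: str, edges: Mapping[Pair, float], genes: Sequence[str] | None = None
    ) -> "FunctionalNetwork":
        if genes is None:
            genes = sorted({g for pair in edges for g in pair})
        net = cls(organism, genes)
        for (a, b), p in edges.items():
            net.set_edge(a, b, p)
        return net

    @classmethod
    def from_condensed(
        cls, organism: str, genes: Sequence[str], values: np.ndarray
    ) -> "FunctionalNetwork":
        n = len(genes)
        if values.shape != (_condensed.n_pairs(n),):
            raise ValueError("condensed vector length mismatch")
        mat = np.full((n, n), np.nan)
        ii, jj = _condensed.pair_arrays(n)
        mat[ii, jj] = values
        mat[jj, ii] = values
        return cls(organism, genes, mat)

    # -- access -----------------------------------------------------------
    @property
    def gene_universe(self) -> FrozenSet[str]:
        return frozenset(self.genes)

    def gene_index(self, gene: str) -> int:
        try:
            return self._index[gene]
        except KeyError:
            raise MissingGeneError(f"network[{self.organism}]: unknown gene {gene!r}") from None

    def edge(self, a: str, b: str) -> float:
        canonical_pair(a, b)
        return float(self.matrix[self.gene_index(a), self.gene_index(b)])

    def set_edge(self, a: str, b: str, p: float) -> None:
        canonical_pair(a, b)
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"edge probability out of [0,1]: {p}")
        i, j = self.gene_index(a), self.gene_index(b)
        self.matrix[i, j] = self.matrix[j, i] = p

    def condensed(self) -> np.ndarray:
        ii, jj = _condensed.pair_arrays(len(self.genes))
        return self.matrix[ii, jj]

    def edges(self) -> Dict[Pair, float]:
        """Defined edges as an unordered-pair dict (small networks only)."""
        ii, jj = _condensed.pair_arrays(len(self.genes))
        vals = self.matrix[ii, jj]
        ok = np.isfinite(vals)
        return {
            canonical_pair(self.genes[i], self.genes[j]): float(v)
            for i, j, v in zip(ii[ok], jj[ok], vals[ok])
        }

    def row(self, gene: str) -> np.ndarray:
        """Edge-weight vector from ``gene`` to every gene (0 where undefined/self)."""
        r = self.matrix[self.gene_index(gene)].copy()
        r[np.isnan(r)] = 0.0
        return r


def binarize_network(
    net: FunctionalNetwork, cutoff: float = 0.5
) -> Dict[str, FrozenSet[str]]:
    """Neighbor sets at a probability cutoff (edge kept when p >= cutoff)."""
    if not (0.0 < cutoff < 1.0):
        raise ValueError("cutoff must lie in (0, 1)")
    with np.errstate(invalid="ignore"):
        adj = net.matrix >= cutoff
    genes = net.genes
    return {
        g: frozenset(genes[j] for j in np.flatnonzero(adj[i]))
        for i, g in enumerate(genes)
    }


def integrate_contexts(context_networks: Sequence[FunctionalNetwork]) -> FunctionalNetwork:
    """Average edge probabilities over per-process context networks.

    Each edge averages over the contexts in which it is defined; an edge
    defined in a single context keeps that value.
    """
    from .errors import ConfigurationError

    if not context_networks:
        raise ConfigurationError("integrate_contexts: empty network list")
    organisms = {n.organism for n in context_networks}
    if len(organisms) != 1:
        raise ConfigurationError(f"mixed organisms: {sorted(organisms)}")
    genes = sorted(set().union(*(n.gene_universe for n in context_networks)))
    n = len(genes)
    total = np.zeros((n, n))
    count = np.zeros((n, n))
    for net in context_networks:
        idx = np.array([genes.index(g) for g in net.genes])
        sub = net.matrix
        ok = np.isfinite(sub)
        total[np.ix_(idx, idx)] += np.where(ok, sub, 0.0)
        count[np.ix_(idx, idx)] += ok
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return FunctionalNetwork(context_networks[0].organism, genes, mean)
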