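"""Network-row feature views for per-term classifiers.

Each gene's feature vector is its edge-weight row in the functional
relationship network (one dimension per gene in the universe, 0 at self
and for undefined edges), so the feature count equals the organism's gene
count.
"""
from __future__ import annotations

from typing import List, Optional, Sequence

import numpy as np

from .errors import MissingGeneError
from .network import FunctionalNetwork


class FeatureView:
    def __init__(self, network: FunctionalNetwork, gene_order: Optional[Sequence[str]] = None):
        self.network = network
        self.gene_order: List[str] = list(gene_order) if gene_order is not None else list(network.genes)
        missing = set(self.gene_order) - network.gene_universe
        if missing:
            raise MissingGeneError(f"genes absent from network: {sorted(missing)[:5]}")
        idx = [network.gene_index(g) for g in self.gene_order]
        mat = network.matrix[np.ix_(idx, idx)].copy()
        mat[np.isnan(mat)] = 0.0
        self._matrix = mat
        self._pos = {g: i for i, g in enumerate(self.gene_order)}

    @property
    def dim(self) -> int:
        return len(self.gene_order)

    def row(self, gene: str) -> np.ndarray:
        try:
            return self._matrix[self._pos[gene]]
        except KeyError:
            raise MissingGeneError(f"gene {gene!r} not in feature view") from None

    def rows(self, genes: Sequence[str]) -> np.ndarray:
        return np.vstack([self.row(g) for g in genes])

    def design(self, positives: Sequence[str], negatives: Sequence[str]):
        """(X, y, genes) training design with labels +1/-1."""
        genes = list(positives) + list(negatives)
        X = self.rows(genes)
        y = np.concatenate([np.ones(len(positives)), -np.ones(len(negatives))])
        return X, y, genes
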