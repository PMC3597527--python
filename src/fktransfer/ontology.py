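"""Ontology handling: a DAG of terms over is_a / part_of relations."""
from __future__ import annotations

from typing import Dict, FrozenSet, Iterable, Mapping, Set

import networkx as nx

from .errors import ConfigurationError


class OntologyDAG:
    """Acyclic term hierarchy; ``parents[t]`` are the more general terms."""

    def __init__(self, parents: Mapping[str, Iterable[str]]):
        self.parents: Dict[str, FrozenSet[str]] = {
            t: frozenset(p) for t, p in parents.items()
        }
        # close the term universe over mentioned parents
        for ps in list(self.parents.values()):
            for p in ps:
                self.parents.setdefault(p, frozenset())
        g = nx.DiGraph()
        g.add_nodes_from(self.parents)
        for t, ps in self.parents.items():
            for p in ps:
                g.add_edge(t, p)
        if not nx.is_directed_acyclic_graph(g):
            raise ConfigurationError("ontology contains a cycle")
        self._graph = g
        self.terms: FrozenSet[str] = frozenset(self.parents)
        self.roots: FrozenSet[str] = frozenset(
            t for t, ps in self.parents.items() if not ps
        )
        self._anc_cache: Dict[str, FrozenSet[str]] = {}
        self._desc_cache: Dict[str, FrozenSet[str]] = {}

    @classmethod
    def from_obo(cls, path) -> "OntologyDAG":
        """Load id / is_a / relationship: part_of from an OBO file."""
        import obonet

        graph = obonet.read_obo(path)
        parents: Dict[str, Set[str]] = {t: set() for t in graph.nodes}
        for child, parent, key in graph.edges(keys=True):
            if key in ("is_a", "part_of"):
                parents[child].add(parent)
        return cls(parents)

    def __contains__(self, term: str) -> bool:
        return term in self.terms

    def ancestors(self, term: str) -> FrozenSet[str]:
        """All more-general terms reachable from ``term`` (excluding itself)."""
        if term not in self.terms:
            raise KeyError(f"term not in ontology: {term!r}")
        if term not in self._anc_cache:
            self._anc_cache[term] = frozenset(nx.descendants(self._graph, term))
        return self._anc_cache[term]

    def descendants(self, term: str) -> FrozenSet[str]:
        if term not in self.terms:
            raise KeyError(f"term not in ontology: {term!r}")
        if term not in self._desc_cache:
            self._desc_cache[term] = frozenset(nx.ancestors(self._graph, term))
        return self._desc_cache[term]

    def relatives(self, term: str) -> FrozenSet[str]:
        """Ancestors plus descendants (used for negative-example exclusion)."""
        return self.ancestors(term) | self.descendants(term)

    def to_obo(self, path, namespace: str = "biological_process") -> None:
        with open(path, "w") as fh:
            fh.write("format-version: 1.2\n\n")
            for term in sorted(self.terms):
                fh.write("[Term]\n")
                fh.write(f"id: {term}\n")
                fh.write(f"name: {term}\n")
                fh.write(f"namespace: {namespace}\n")
                for p in sorted(self.parents[term]):
                    fh.write(f"is_a: {p} ! {p}\n")
                fh.write("\n")
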