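"""Gene Ontology DAG queries: ancestors, descendants and term levels.

The ontology is held as a :class:`networkx.DiGraph` with child -> parent
edges restricted to a configurable set of relation types ("is_a" and
"part_of" by default, the GO convention for annotation-propagation
queries).  Levels are shortest-path distances from the namespace root,
computed within a namespace only — cross-namespace paths are never
traversed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

GO_NAMESPACES = ("molecular_function", "biological_process", "cellular_component")
DEFAULT_RELATIONS = ("is_a", "part_of")


@dataclass(frozen=True)
class TermInfo:
    term_id: str
    name: str
    namespace: str
    level: int


class OntologyDag:
    """A directed acyclic graph of ontology terms.

    Parameters
    ----------
    graph
        DiGraph with one node per term (attributes ``name``,
        ``namespace``) and child -> parent edges for the selected relation
        types.
    relations
        The relation types that were retained when building the graph.
    """

    def __init__(self, graph: nx.DiGraph, relations: tuple[str, ...] = DEFAULT_RELATIONS):
        if not nx.is_directed_acyclic_graph(graph):
            raise ValueError("ontology graph contains a cycle")
        self.graph = graph
        self.relations = tuple(relations)
        self._levels: dict[str, int] | None = None

    # -- construction -------------------------------------------------

    @classmethod
    def from_obo(
        cls,
        path: str | Path,
        relations: Iterable[str] = DEFAULT_RELATIONS,
    ) -> "OntologyDag":
        """Parse an OBO 1.2 flat file.

        Obsolete terms are dropped (obonet already excludes them; the count
        of dropped edge endpoints is logged).  Only edges whose relation
        type is in ``relations`` are kept.
        """
        relations = tuple(relations)
        multi = obonet.read_obo(str(path), ignore_obsolete=True)
        graph = nx.DiGraph()
        for node, data in multi.nodes(data=True):
            graph.add_node(
                node,
                name=data.get("name", node),
                namespace=data.get("namespace", "unknown"),
            )
        dropped = 0
        for child, parent, rel in multi.edges(keys=True):
            if rel in relations:
                graph.add_edge(child, parent, relation=rel)
            else:
                dropped += 1
        if dropped:
            logger.info("dropped %d edges with relation types outside %s", dropped, relations)
        return cls(graph, relations)

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        namespace: str = "biological_process",
        names: Mapping[str, str] | None = None,
    ) -> "OntologyDag":
        """Build a DAG from (child, parent) pairs, all in one namespace."""
        graph = nx.DiGraph()
        names = dict(names or {})
        for child, parent in edges:
            for term in (child, parent):
                if term not in graph:
                    graph.add_node(term, name=names.get(term, term), namespace=namespace)
            graph.add_edge(child, parent, relation="is_a")
        return cls(graph)

    # -- queries ------------------------------------------------------

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def _require(self, term: str) -> None:
        if term not in self.graph:
            raise KeyError(f"unknown ontology term: {term!r}")

    @property
    def terms(self) -> list[str]:
        return list(self.graph.nodes)

    def namespace(self, term: str) -> str:
        self._require(term)
        return self.graph.nodes[term]["namespace"]

    def roots(self) -> dict[str, str]:
        """Map namespace -> root term (the term with no outgoing edges)."""
        roots: dict[str, str] = {}
        for node, out_degree in self.graph.out_degree():
            if out_degree == 0:
                ns = self.graph.nodes[node]["namespace"]
                if ns in roots:
                    raise ValueError(
                        f"namespace {ns!r} has multiple roots: {roots[ns]!r}, {node!r}"
                    )
                roots[ns] = node
        return roots

    def ancestors(self, term: str) -> set[str]:
        """All terms reachable by following child -> parent edges (term excluded)."""
        self._require(term)
        return set(nx.descendants(self.graph, term))

    def descendants(self, term: str) -> set[str]:
        """All terms from which ``term`` is reachable (term excluded)."""
        self._require(term)
        return set(nx.ancestors(self.graph, term))

    def term_level(self, term: str) -> int:
        """Shortest-path edge count from the term's namespace root."""
        self._require(term)
        return self._level_map()[term]

    def _level_map(self) -> dict[str, int]:
        if self._levels is None:
            levels: dict[str, int] = {}
            # BFS from each namespace root over reversed (parent -> child) edges.
            reverse = self.graph.reverse(copy=False)
            for ns, root in self.roots().items():
                for term, dist in nx.single_source_shortest_path_length(reverse, root).items():
                    if self.graph.nodes[term]["namespace"] == ns:
                        levels[term] = dist
            for term in self.graph.nodes:
                if term not in levels:
                    raise ValueError(f"term {term!r} has no path to its namespace root")
            self._levels = levels
        return self._levels

    def term_info(self, term: str) -> TermInfo:
        self._require(term)
        data = self.graph.nodes[term]
        return TermInfo(
            term_id=term,
            name=data["name"],
            namespace=data["namespace"],
            level=self.term_level(term),
        )


def write_obo(dag: OntologyDag, path: str | Path) -> None:
    """Write a minimal OBO 1.2 file (enough to round-trip through obonet)."""
    lines = ["format-version: 1.2", ""]
    for term in sorted(dag.graph.nodes):
        data = dag.graph.nodes[term]
        lines.append("[Term]")
        lines.append(f"id: {term}")
        lines.append(f"name: {data.get('name', term)}")
        lines.append(f"namespace: {data.get('namespace', 'biological_process')}")
        for _, parent, edata in dag.graph.out_edges(term, data=True):
            rel = edata.get("relation", "is_a")
            if rel == "is_a":
                lines.append(f"is_a: {parent}")
            else:
                lines.append(f"relationship: {rel} {parent}")
        lines.append("")
    Path(path).write_text("\n".join(lines))
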