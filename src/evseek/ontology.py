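"""Minimal ontology DAG with annotation propagation.

Supports the membrane-inclusion / vesicle-exclusion step of the marker
discovery workflow: a gene passes when one of its direct cellular-component
annotations lies at or below the inclusion term (e.g. ``plasma membrane``)
and none lies at or below the exclusion term (e.g. ``synaptic vesicle``).

Only ``is_a`` subsumption is traversed by default; ``part_of`` edges can be
opted in when the input file carries them. Propagation follows the GO
true-path rule: a gene annotated to a term is implicitly annotated to every
ancestor of that term.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "OntologyGraph",
    "AnnotationSet",
    "load_obo_subset",
    "load_annotations",
    "ancestors",
    "genes_annotated_under",
]


@dataclass
class OntologyGraph:
    """Acyclic term graph with child -> parent ``is_a`` edges.

    Attributes
    ----------
    graph : networkx.DiGraph
        Directed edges run child -> parent, so graph-descendants of a node
        reached by following edges are its ontological ancestors.
    names : dict
        Term id -> display name (may be empty for unnamed terms).
    """

    graph: nx.DiGraph
    names: dict[str, str] = field(default_factory=dict)

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def validate(self) -> None:
        """Raise ``ValueError`` naming a cycle member if the graph is cyclic."""
        try:
            cycle = nx.find_cycle(self.graph)
        except nx.NetworkXNoCycle:
            return
        member = cycle[0][0]
        raise ValueError(f"ontology graph contains a cycle through term {member!r}")


@dataclass
class AnnotationSet:
    """Direct gene -> term assignments (pre-propagation)."""

    pairs: dict[str, set[str]]

    @property
    def genes(self) -> set[str]:
        return set(self.pairs)

    def terms_for(self, gene: str) -> set[str]:
        return self.pairs.get(gene, set())


def load_obo_subset(path) -> OntologyGraph:
    """Parse a ``[Term]``-stanza OBO subset into an :class:`OntologyGraph`.

    Recognises ``id:``, ``name:`` and ``is_a:`` lines inside ``[Term]``
    stanzas; every other tag (including header lines and ``[Typedef]``
    stanzas) is ignored. A stanza without an ``id:`` line is a hard error
    reported with the line number of the stanza opening; a cyclic graph is a
    hard error naming one cycle member.
    """
    graph = nx.DiGraph()
    names: dict[str, str] = {}
    pending_edges: list[tuple[str, str]] = []

    in_term = False
    stanza_line = 0
    current_id: str | None = None
    current_name = ""
    current_parents: list[str] = []

    def flush() -> None:
        nonlocal current_id, current_name, current_parents
        if not in_term:
            return
        if current_id is None:
            raise ValueError(f"[Term] stanza starting at line {stanza_line} has no id: line")
        graph.add_node(current_id)
        if current_name:
            names[current_id] = current_name
        for parent in current_parents:
            pending_edges.append((current_id, parent))
        current_id, current_name, current_parents = None, "", []

    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if line.startswith("["):
                flush()
                in_term = line == "[Term]"
                stanza_line = lineno
                continue
            if not in_term or not line or line.startswith("!"):
                continue
            tag, _, value = line.partition(":")
            value = value.strip()
            if tag == "id":
                current_id = value
            elif tag == "name":
                current_name = value
            elif tag == "is_a":
                # strip trailing "! parent name" comments
                parent = value.split("!", 1)[0].strip()
                current_parents.append(parent)
            # any other tag: ignored
    flush()

    for child, parent in pending_edges:
        graph.add_node(parent)
        graph.add_edge(child, parent)

    ont = OntologyGraph(graph=graph, names=names)
    ont.validate()
    return ont


def load_annotations(path, ontology: OntologyGraph | None = None) -> AnnotationSet:
    """Read a two-column gene<TAB>term TSV ('#' comment lines allowed).

    When an ontology is supplied, annotations to terms absent from it are
    dropped with a logged warning rather than raising, mirroring how real
    association files routinely reference retired terms.
    """
    pairs: dict[str, set[str]] = {}
    dropped = 0
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"line {lineno}: expected gene<TAB>term, got {line!r}")
            gene, term = fields[0], fields[1]
            if ontology is not None and term not in ontology:
                dropped += 1
                continue
            pairs.setdefault(gene, set()).add(term)
    if dropped:
        logger.warning("dropped %d annotation(s) to terms absent from the ontology", dropped)
    return AnnotationSet(pairs=pairs)


def ancestors(ontology: OntologyGraph, term: str) -> set[str]:
    """Reflexive-transitive ``is_a`` closure of *term* (term included)."""
    if term not in ontology:
        raise KeyError(f"unknown ontology term {term!r}")
    closure = nx.descendants(ontology.graph, term)  # edges run child -> parent
    closure.add(term)
    return closure


def genes_annotated_under(
    ontology: OntologyGraph,
    annotations: AnnotationSet | Mapping[str, Iterable[str]],
    term: str,
    propagate: bool = True,
) -> set[str]:
    """Genes annotated at or below *term*.

    With ``propagate=True`` (the default, GO true-path rule) a gene counts
    when any of its direct annotations has *term* among its ancestors; with
    ``propagate=False`` only literal annotation to *term* counts.
    """
    if term not in ontology:
        raise KeyError(f"unknown ontology term {term!r}")
    pairs = annotations.pairs if isinstance(annotations, AnnotationSet) else annotations

    if not propagate:
        return {g for g, terms in pairs.items() if term in terms}

    # genes annotated to any term whose ancestor set contains `term`, i.e. to
    # `term` itself or any of its graph-ancestors (ontological descendants)
    below = nx.ancestors(ontology.graph, term)
    below.add(term)
    return {g for g, terms in pairs.items() if any(t in below for t in terms)}
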