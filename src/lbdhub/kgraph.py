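"""Typed heterogeneous knowledge graph of biomedical predications.

The graph holds subject--predicate--object assertions ("predications") of the
kind produced by large-scale text mining of the biomedical literature, e.g.

    aldosterone  INCREASES  blood pressure

Nodes are UMLS-style concepts: a CUI identifier ("C" + 7 digits, optionally a
composite "baseCUI|linkedCUI"), a free-text name, and a set of 4-letter
semantic-type codes (AAPP, GNGM, HORM, DSYN, PHSU, ...).  Edges are directed
predicates carrying the set of supporting article identifiers (PMIDs); the
number of distinct PMIDs is the edge multiplicity.

Storage is a :class:`networkx.MultiDiGraph` (edge key = predicate) wrapped in
a thin typed facade with a lazily built adjacency index keyed by
(node, predicate, direction) so that repeated walk queries stay cheap.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx

#: Wildcard predicate for degree / neighbor queries.
ANY = "ANY"

#: Traversal directions.
OUT, IN, BOTH = "out", "in", "both"

_DIRECTIONS = (OUT, IN, BOTH)


@dataclass(frozen=True)
class ConceptNode:
    """A biomedical concept: CUI, display name, UMLS semantic types."""

    cui: str
    name: str
    semtypes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.cui:
            raise ValueError("concept CUI must be non-empty")
        if not self.semtypes:
            raise ValueError(f"concept {self.cui!r} has no semantic types")

    @property
    def base_cui(self) -> str:
        """Base identifier of a composite CUI (substring before the first '|')."""
        return self.cui.split("|", 1)[0]

    @property
    def is_composite(self) -> bool:
        return "|" in self.cui


@dataclass(frozen=True)
class PredicationEdge:
    """A directed subject-PREDICATE-object assertion with supporting PMIDs."""

    subject: str
    predicate: str
    object: str
    support: frozenset[str]

    def __post_init__(self) -> None:
        if self.subject == self.object:
            raise ValueError(f"self-loop predication on {self.subject!r}")
        if not self.support:
            raise ValueError("predication must cite at least one PMID")

    @property
    def multiplicity(self) -> int:
        """Number of distinct supporting articles."""
        return len(self.support)


class KnowledgeGraph:
    """Heterogeneous information network of concepts and predications.

    Duplicate (subject, predicate, object) rows merge their PMID support;
    semantic types of a node are the union over all rows mentioning it.
    """

    def __init__(self) -> None:
        self._g = nx.MultiDiGraph()
        self._index: dict[tuple[str, str, str], tuple[str, ...]] | None = None
        #: rows dropped at load time because subject == object
        self.skipped_self_loops = 0

    # -- construction ------------------------------------------------------

    def add_concept(self, cui: str, name: str, semtypes: Iterable[str]) -> None:
        """Add a concept, merging semantic types if the CUI already exists."""
        semtypes = frozenset(semtypes)
        if not cui:
            raise ValueError("concept CUI must be non-empty")
        if not semtypes:
            raise ValueError(f"concept {cui!r} has no semantic types")
        if self._g.has_node(cui):
            data = self._g.nodes[cui]
            data["semtypes"] = data["semtypes"] | semtypes
        else:
            self._g.add_node(cui, name=name, semtypes=semtypes)
        self._index = None

    def add_predication(
        self, subject: str, predicate: str, object: str, pmids: Iterable[str]
    ) -> None:
        """Add a predication edge; duplicates merge their PMID support."""
        if subject == object:
            raise ValueError(f"self-loop predication on {subject!r}")
        for cui in (subject, object):
            if not self._g.has_node(cui):
                raise KeyError(f"unknown concept {cui!r}")
        pmids = frozenset(pmids)
        if not pmids:
            raise ValueError("predication must cite at least one PMID")
        if self._g.has_edge(subject, object, key=predicate):
            data = self._g[subject][object][predicate]
            data["support"] = data["support"] | pmids
        else:
            self._g.add_edge(subject, object, key=predicate, support=pmids)
        self._index = None

    # -- node / edge access ------------------------------------------------

    def __contains__(self, cui: str) -> bool:
        return self._g.has_node(cui)

    def node(self, cui: str) -> ConceptNode:
        if not self._g.has_node(cui):
            raise KeyError(f"unknown concept {cui!r}")
        data = self._g.nodes[cui]
        return ConceptNode(cui, data["name"], data["semtypes"])

    def nodes(self) -> Iterator[ConceptNode]:
        for cui in sorted(self._g.nodes):
            yield self.node(cui)

    def edges(self) -> Iterator[PredicationEdge]:
        for s, o, pred, data in sorted(self._g.edges(keys=True, data=True)):
            yield PredicationEdge(s, pred, o, data["support"])

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    # -- queries -----------------------------------------------------------

    def _build_index(self) -> dict[tuple[str, str, str], tuple[str, ...]]:
        index: dict[tuple[str, str, str], list[str]] = {}
        for s, o, pred in self._g.edges(keys=True):
            index.setdefault((s, pred, OUT), []).append(o)
            index.setdefault((s, ANY, OUT), []).append(o)
            index.setdefault((o, pred, IN), []).append(s)
            index.setdefault((o, ANY, IN), []).append(s)
        return {k: tuple(sorted(v)) for k, v in index.items()}

    def neighbors(self, cui: str, predicate: str = ANY, direction: str = OUT) -> tuple[str, ...]:
        """Neighbors reached along edges matching (predicate, direction).

        One entry per distinct matching edge, in sorted order.  ``direction``
        may be ``"out"``, ``"in"`` or ``"both"`` (union).
        """
        if not self._g.has_node(cui):
            raise KeyError(f"unknown concept {cui!r}")
        if direction not in _DIRECTIONS:
            raise ValueError(f"direction must be one of {_DIRECTIONS}, got {direction!r}")
        if self._index is None:
            self._index = self._build_index()
        if direction == BOTH:
            merged = self._index.get((cui, predicate, OUT), ()) + self._index.get(
                (cui, predicate, IN), ()
            )
            return tuple(sorted(merged))
        return self._index.get((cui, predicate, direction), ())

    def predicates(self, cui: str, direction: str = OUT) -> tuple[str, ...]:
        """Distinct predicates on edges incident to ``cui`` in ``direction``."""
        if not self._g.has_node(cui):
            raise KeyError(f"unknown concept {cui!r}")
        if direction == OUT:
            preds = {k for _, _, k in self._g.out_edges(cui, keys=True)}
        elif direction == IN:
            preds = {k for _, _, k in self._g.in_edges(cui, keys=True)}
        else:
            raise ValueError(f"direction must be 'out' or 'in', got {direction!r}")
        return tuple(sorted(preds))

    def degree(self, cui: str, predicate: str = ANY, direction: str = BOTH) -> int:
        """Count of distinct incident edges matching (predicate, direction).

        PMID multiplicity is *not* counted: each (subject, predicate, object)
        edge contributes one.
        """
        return len(self.neighbors(cui, predicate, direction))

    def support(self, subject: str, predicate: str, object: str) -> frozenset[str]:
        """PMID support of one edge."""
        try:
            return self._g[subject][object][predicate]["support"]
        except KeyError:
            raise KeyError(f"no edge {subject} {predicate} {object}") from None

    def filter_semtypes(self, allowed: Iterable[str]) -> set[str]:
        """CUIs of nodes whose semantic types intersect ``allowed``."""
        allowed = set(allowed)
        if not allowed:
            raise ValueError("allowed semantic-type set must be non-empty")
        return {
            cui for cui, data in self._g.nodes(data=True) if data["semtypes"] & allowed
        }

    def summary(self) -> dict:
        """Node/edge counts and per-semantic-type node counts."""
        per_type: dict[str, int] = {}
        for _, data in self._g.nodes(data=True):
            for st in data["semtypes"]:
                per_type[st] = per_type.get(st, 0) + 1
        return {
            "node_count": self.n_nodes,
            "edge_count": self.n_edges,
            "semtype_node_counts": dict(sorted(per_type.items())),
        }


# -- flat-file I/O ---------------------------------------------------------
#
# 8-column TSV, UTF-8, optional '#'-prefixed header:
#   subj_cui  subj_name  subj_semtypes  predicate  obj_cui  obj_name
#   obj_semtypes  pmid
# Multiple semantic types within one field are comma-separated.

_N_COLUMNS = 8


def load_triples(path: str | Path) -> KnowledgeGraph:
    """Read a predication-triple TSV into a :class:`KnowledgeGraph`.

    Duplicate edges merge supports; self-loop rows are skipped (the count of
    skipped rows is recorded on the returned graph as ``skipped_self_loops``).
    Malformed rows raise :class:`ValueError` naming the line number.
    """
    graph = KnowledgeGraph()
    skipped = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != _N_COLUMNS:
                raise ValueError(
                    f"{path}:{lineno}: expected {_N_COLUMNS} tab-separated "
                    f"columns, got {len(parts)}"
                )
            s_cui, s_name, s_types, pred, o_cui, o_name, o_types, pmid = parts
            if not pmid:
                raise ValueError(f"{path}:{lineno}: empty PMID")
            if s_cui == o_cui:
                skipped += 1
                continue
            graph.add_concept(s_cui, s_name, _split_types(s_types, path, lineno))
            graph.add_concept(o_cui, o_name, _split_types(o_types, path, lineno))
            graph.add_predication(s_cui, pred, o_cui, {pmid})
    graph.skipped_self_loops = skipped
    return graph


def _split_types(fieldvalue: str, path, lineno: int) -> frozenset[str]:
    types = frozenset(t for t in fieldvalue.split(",") if t)
    if not types:
        raise ValueError(f"{path}:{lineno}: empty semantic-type field")
    return types


def write_triples(graph: KnowledgeGraph, path: str | Path) -> None:
    """Write the graph back to the triple TSV dialect, one row per PMID.

    Output is deterministically sorted so that identical graphs produce
    byte-identical files regardless of construction order.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "#subj_cui\tsubj_name\tsubj_semtypes\tpredicate\tobj_cui\t"
            "obj_name\tobj_semtypes\tpmid\n"
        )
        for edge in graph.edges():
            s = graph.node(edge.subject)
            o = graph.node(edge.object)
            for pmid in sorted(edge.support):
                fh.write(
                    "\t".join(
                        (
                            s.cui,
                            s.name,
                            ",".join(sorted(s.semtypes)),
                            edge.predicate,
                            o.cui,
                            o.name,
                            ",".join(sorted(o.semtypes)),
                            pmid,
                        )
                    )
                    + "\n"
                )


def write_summary(graph: KnowledgeGraph, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(graph.summary(), fh, indent=2, sort_keys=True)
        fh.write("\n")
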