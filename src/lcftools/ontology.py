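"""OBO ontology parsing and sub-ontology extraction.

The Gene Ontology is distributed as an OBO flat file whose ``[Term]``
stanzas form a directed acyclic graph (DAG) through ``is_a`` relations:
a term may have several parents.  This module parses that format into an
:class:`OntologyGraph`, extracts the rooted molecular-function sub-DAG
(root ``GO:0003674``), and reports the in/out-degree structure of the
graph — the number of parents and children per term.

Only ``is_a`` relations define the hierarchy; ``relationship:`` lines
(``part_of`` and friends) are ignored.  Obsolete terms and terms that
cannot reach the root are excluded from extraction, with the excluded
identifiers recorded on the result.
"""

from __future__ import annotations

import gzip
import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

logger = logging.getLogger(__name__)

GO_ID_PATTERN = re.compile(r"^GO:\d{7}$")

#: Canonical root of the molecular-function domain.
MOLECULAR_FUNCTION_ROOT = "GO:0003674"


class OboParseError(ValueError):
    """Raised for a structurally invalid OBO document."""


@dataclass
class OntologyGraph:
    """A labelled ontology DAG restricted to ``is_a`` edges.

    Edges are ordered ``(child, parent)`` pairs.  ``root`` designates the
    top-level term after extraction; a freshly parsed graph has no root.
    """

    terms: set[str] = field(default_factory=set)
    names: dict[str, str] = field(default_factory=dict)
    edges: set[tuple[str, str]] = field(default_factory=set)
    namespace: dict[str, str] = field(default_factory=dict)
    obsolete: set[str] = field(default_factory=set)
    root: str | None = None
    #: is_a edges whose target was never defined by a stanza (dropped).
    dangling_edges: list[tuple[str, str]] = field(default_factory=list)
    #: terms excluded at extraction because they cannot reach the root.
    orphans: list[str] = field(default_factory=list)

    def parents_of(self, term: str) -> list[str]:
        return sorted(p for (c, p) in self.edges if c == term)

    def children_of(self, term: str) -> list[str]:
        return sorted(c for (c, p) in self.edges if p == term)

    def parent_map(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {t: [] for t in self.terms}
        for child, parent in sorted(self.edges):
            out[child].append(parent)
        return out

    def child_map(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {t: [] for t in self.terms}
        for child, parent in sorted(self.edges):
            out[parent].append(child)
        return out


@dataclass
class DegreeHistogram:
    """Frequency of the number of parents (in-degree) and children
    (out-degree) per node."""

    in_degree_counts: dict[int, int]
    out_degree_counts: dict[int, int]


def parse_obo(obo_text: str) -> OntologyGraph:
    """Parse an OBO 1.2/1.4 document into an :class:`OntologyGraph`.

    Every ``[Term]`` stanza becomes a term; every ``is_a:`` line becomes a
    (child, parent) edge; ``is_obsolete: true`` flags the term.  Edges whose
    parent is never defined by any stanza are dropped and recorded on
    ``dangling_edges``.

    Raises
    ------
    OboParseError
        If a ``[Term]`` stanza has no ``id:`` line (the error names the
        stanza ordinal) or the document has no ``[Term]`` stanza at all.
    """
    graph = OntologyGraph()
    raw_edges: list[tuple[str, str]] = []

    stanza_ordinal = 0
    in_term = False
    cur: dict[str, object] | None = None

    def flush(cur: dict[str, object] | None) -> None:
        if cur is None:
            return
        term_id = cur.get("id")
        if term_id is None:
            raise OboParseError(
                f"[Term] stanza #{cur['ordinal']} has no id: line"
            )
        term_id = str(term_id)
        graph.terms.add(term_id)
        if "name" in cur:
            graph.names[term_id] = str(cur["name"])
        if "namespace" in cur:
            graph.namespace[term_id] = str(cur["namespace"])
        if cur.get("obsolete"):
            graph.obsolete.add(term_id)
        for parent in cur["is_a"]:  # type: ignore[index]
            raw_edges.append((term_id, parent))

    for line in obo_text.splitlines():
        line = line.strip()
        if not line or line.startswith("!"):
            continue
        if line.startswith("["):
            flush(cur if in_term else None)
            cur = None
            in_term = line == "[Term]"
            if in_term:
                stanza_ordinal += 1
                cur = {"ordinal": stanza_ordinal, "is_a": []}
            continue
        if not in_term or cur is None:
            continue
        if ":" not in line:
            continue
        key, _, value = line.partition(":")
        value = value.strip()
        # strip trailing "! comment"
        if " ! " in value:
            value = value.split(" ! ", 1)[0].strip()
        if key == "id":
            cur["id"] = value
        elif key == "name":
            cur["name"] = value
        elif key == "namespace":
            cur["namespace"] = value
        elif key == "is_a":
            cur["is_a"].append(value)  # type: ignore[union-attr]
        elif key == "is_obsolete":
            cur["obsolete"] = value.lower() == "true"
    flush(cur if in_term else None)

    if not graph.terms:
        raise OboParseError("document contains no [Term] stanza with an id")

    for child, parent in raw_edges:
        if parent in graph.terms:
            graph.edges.add((child, parent))
        else:
            graph.dangling_edges.append((child, parent))
    if graph.dangling_edges:
        logger.warning(
            "dropped %d is_a edge(s) with undefined target: %s",
            len(graph.dangling_edges),
            graph.dangling_edges[:5],
        )
    return graph


def serialize_obo(graph: OntologyGraph) -> str:
    """Serialize a graph back to OBO text (stable, sorted order)."""
    lines = ["format-version: 1.2", ""]
    for term in sorted(graph.terms):
        lines.append("[Term]")
        lines.append(f"id: {term}")
        if term in graph.names:
            lines.append(f"name: {graph.names[term]}")
        if term in graph.namespace:
            lines.append(f"namespace: {graph.namespace[term]}")
        for _, parent in sorted(e for e in graph.edges if e[0] == term):
            lines.append(f"is_a: {parent}")
        if term in graph.obsolete:
            lines.append("is_obsolete: true")
        lines.append("")
    return "\n".join(lines)


def load_obo(path: str | Path) -> OntologyGraph:
    """Read an OBO file, transparently handling gzip compression."""
    path = Path(path)
    data = path.read_bytes()
    if data[:2] == b"\x1f\x8b":
        data = gzip.decompress(data)
    return parse_obo(data.decode())


def extract_subontology(
    graph: OntologyGraph,
    root_id: str = MOLECULAR_FUNCTION_ROOT,
    namespace_label: str | None = None,
) -> OntologyGraph:
    """Extract the rooted sub-DAG of non-obsolete terms below ``root_id``.

    A term is kept when it is non-obsolete, carries the requested namespace
    (when one is given), and can reach ``root_id`` by following parent
    edges through kept terms.  Terms failing only the reachability test are
    recorded as ``orphans`` on the result.
    """
    if root_id not in graph.terms:
        raise ValueError(f"root term {root_id!r} not present in ontology")

    def keep(t: str) -> bool:
        if t in graph.obsolete:
            return False
        if namespace_label is not None and graph.namespace.get(t) != namespace_label:
            return False
        return True

    candidates = {t for t in graph.terms if keep(t)}
    if root_id not in candidates:
        raise ValueError(
            f"root term {root_id!r} is obsolete or outside namespace "
            f"{namespace_label!r}"
        )

    # reachability towards the root through kept terms only
    children = {t: [] for t in candidates}
    for child, parent in graph.edges:
        if child in candidates and parent in candidates:
            children[parent].append(child)
    reachable = {root_id}
    stack = [root_id]
    while stack:
        node = stack.pop()
        for child in children[node]:
            if child not in reachable:
                reachable.add(child)
                stack.append(child)

    orphans = sorted(candidates - reachable)
    if orphans:
        logger.info(
            "%d term(s) cannot reach root %s and were excluded",
            len(orphans),
            root_id,
        )

    sub = OntologyGraph(
        terms=set(reachable),
        names={t: n for t, n in graph.names.items() if t in reachable},
        edges={
            (c, p) for (c, p) in graph.edges if c in reachable and p in reachable
        },
        namespace={
            t: n for t, n in graph.namespace.items() if t in reachable
        },
        obsolete=set(),
        root=root_id,
        orphans=orphans,
    )
    # the root must have no parents inside the extracted sub-DAG
    sub.edges = {(c, p) for (c, p) in sub.edges if c != root_id}
    if not sub.terms:
        raise ValueError("extraction produced an empty sub-ontology")
    return sub


def degree_stats(graph: OntologyGraph) -> DegreeHistogram:
    """Histogram the number of parents (in-degree) and children
    (out-degree) over all terms."""
    n_parents: Counter[str] = Counter()
    n_children: Counter[str] = Counter()
    for child, parent in graph.edges:
        n_parents[child] += 1
        n_children[parent] += 1
    in_hist: Counter[int] = Counter(n_parents.get(t, 0) for t in graph.terms)
    out_hist: Counter[int] = Counter(n_children.get(t, 0) for t in graph.terms)
    return DegreeHistogram(dict(in_hist), dict(out_hist))
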