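"""Knowledge graph loading, entity dictionary matching, and sentence graphs.

The knowledge graph is a set of entity surface forms (drugs, diseases,
targets, ...) connected by dependency edges such as "same as" or "caused by".
The model treats all dependencies as a single untyped, undirected edge kind;
relation labels are kept as metadata only.

For each sentence, tokens are matched against the graph lexicon by greedy
left-to-right longest n-gram match, and the matched nodes form a small
*sentence graph* whose adjacency (KG edges among the sentence's nodes, plus
forced self-loops) is what the graph attention layer consumes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .corpus import Sentence, Span

__all__ = [
    "EmptyGraphError",
    "EntityMatch",
    "KgParseError",
    "KnowledgeGraph",
    "SentenceGraph",
    "build_sentence_graph",
    "load_kg",
    "match_entities",
    "normalize_surface",
    "write_kg",
]

_WS = re.compile(r"\s+")


class KgParseError(ValueError):
    """Malformed knowledge-graph file; carries the offending line number."""

    def __init__(self, lineno: int, message: str):
        self.lineno = lineno
        super().__init__(f"line {lineno}: {message}")


class EmptyGraphError(ValueError):
    """The knowledge-graph file contains no valid edges or nodes."""


def normalize_surface(surface: str) -> str:
    """Normalization used for lexicon keys: lowercase, collapse whitespace."""
    return _WS.sub(" ", surface.strip().lower())


@dataclass
class KnowledgeGraph:
    """Entity nodes (surface forms) with untyped undirected dependency edges.

    Node ids are dense 0..m-1. ``graph`` is an undirected networkx graph over
    node ids with a ``relations`` set attribute per edge; no self-edges are
    stored (self-loops are forced later on sentence adjacencies). ``lexicon``
    maps normalized surface form to the lowest node id carrying it.
    """

    surface_forms: list[str]
    categories: list[str | None]
    graph: nx.Graph
    node_meta: list[dict] = field(default_factory=list)

    def __post_init__(self):
        if not self.node_meta:
            self.node_meta = [{} for _ in self.surface_forms]
        self.lexicon: dict[str, int] = {}
        for i, s in enumerate(self.surface_forms):
            self.lexicon.setdefault(normalize_surface(s), i)

    @property
    def n_nodes(self) -> int:
        return len(self.surface_forms)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def neighbors(self, node_id: int) -> list[int]:
        return sorted(self.graph.neighbors(node_id))

    def max_surface_ngram(self) -> int:
        return max((len(s.split()) for s in self.surface_forms), default=1)

    @classmethod
    def from_edges(
        cls,
        triples: list[tuple[str, str, str]],
        node_categories: dict[str, str] | None = None,
        extra_nodes: list[str] | None = None,
    ) -> "KnowledgeGraph":
        """Build a graph from (head, relation, tail) triples.

        Every distinct surface form becomes one node (in order of first
        appearance); duplicate edges are collapsed, relation labels are
        accumulated as metadata. Self-edges (head == tail after
        normalization) are dropped.
        """
        ids: dict[str, int] = {}
        surfaces: list[str] = []

        def node_of(surface: str) -> int:
            key = normalize_surface(surface)
            if key not in ids:
                ids[key] = len(surfaces)
                surfaces.append(surface)
            return ids[key]

        g = nx.Graph()
        for head, rel, tail in triples:
            h, t = node_of(head), node_of(tail)
            if h == t:
                continue
            if g.has_edge(h, t):
                g.edges[h, t]["relations"].add(rel)
            else:
                g.add_edge(h, t, relations={rel})
        for s in extra_nodes or []:
            node_of(s)
        g.add_nodes_from(range(len(surfaces)))
        cats: list[str | None] = [None] * len(surfaces)
        if node_categories:
            lookup = {normalize_surface(k): v for k, v in node_categories.items()}
            for key, i in ids.items():
                cats[i] = lookup.get(key)
        return cls(surface_forms=surfaces, categories=cats, graph=g)


def load_kg(path: str | Path, nodes_path: str | Path | None = None) -> KnowledgeGraph:
    """Load a knowledge graph from a TSV edge list.

    One edge per line, ``head<TAB>relation<TAB>tail`` (extra columns are
    ignored); ``#``-prefixed lines are comments. An optional node sidecar
    file gives ``surface_form<TAB>category`` lines, which may also introduce
    isolated nodes.
    """
    triples: list[tuple[str, str, str]] = []
    path = Path(path)
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise KgParseError(lineno, f"expected >=3 tab-separated fields, got {len(parts)}")
        head, rel, tail = (p.strip() for p in parts[:3])
        if not head or not tail:
            raise KgParseError(lineno, "empty head or tail surface form")
        triples.append((head, rel, tail))

    node_categories: dict[str, str] = {}
    extra_nodes: list[str] = []
    if nodes_path is not None:
        for lineno, raw in enumerate(
            Path(nodes_path).read_text(encoding="utf-8").splitlines(), start=1
        ):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise KgParseError(lineno, "node file needs surface_form<TAB>category")
            node_categories[parts[0].strip()] = parts[1].strip()
            extra_nodes.append(parts[0].strip())

    if not triples and not extra_nodes:
        raise EmptyGraphError(f"no valid edges or nodes in {path}")
    return KnowledgeGraph.from_edges(triples, node_categories, extra_nodes)


def write_kg(kg: KnowledgeGraph, path: str | Path, nodes_path: str | Path | None = None) -> None:
    """Serialize a graph back to the TSV edge-list (+ optional node) format."""
    lines = []
    for h, t in sorted(kg.graph.edges()):
        for rel in sorted(kg.graph.edges[h, t]["relations"]):
            lines.append(f"{kg.surface_forms[h]}\t{rel}\t{kg.surface_forms[t]}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")
    if nodes_path is not None:
        nlines = [
            f"{s}\t{c or ''}" for s, c in zip(kg.surface_forms, kg.categories)
        ]
        Path(nodes_path).write_text("\n".join(nlines) + "\n", encoding="utf-8")


@dataclass(frozen=True)
class EntityMatch:
    """A token span matched to a knowledge-graph node."""

    span: Span
    node_id: int


@dataclass
class SentenceGraph:
    """Per-sentence matched subgraph plus token-to-node alignment.

    ``node_ids`` lists the KG node indices included for this sentence;
    ``adjacency`` is a square symmetric 0/1 matrix over them with unit
    diagonal; ``alignment`` maps each token index inside a matched span to
    that match's local node index.
    """

    node_ids: list[int]
    adjacency: np.ndarray
    alignment: dict[int, int]
    matches: list[EntityMatch]

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)


def match_entities(
    sentence: Sentence,
    kg: KnowledgeGraph,
    max_ngram: int = 6,
    lowercase: bool = True,
) -> list[EntityMatch]:
    """Greedy left-to-right longest-match of token n-grams against the KG.

    Normalization is lowercase (configurable) plus single-space joining of
    the n-gram tokens. Matches never overlap; where multiple lengths match
    at one position the longest wins; ties on surface go to the lowest
    node id (lexicon keeps the first).
    """
    if max_ngram < 1:
        raise ValueError("max_ngram must be >= 1")
    toks = [t.lower() for t in sentence.tokens] if lowercase else list(sentence.tokens)
    matches: list[EntityMatch] = []
    i, n = 0, len(toks)
    while i < n:
        found = None
        for length in range(min(max_ngram, n - i), 0, -1):
            gram = " ".join(toks[i : i + length])
            key = normalize_surface(gram)
            node = kg.lexicon.get(key)
            if node is not None and not lowercase:
                # case-sensitive mode: the raw n-gram must equal the stored
                # surface exactly (modulo whitespace collapsing)
                if _WS.sub(" ", gram.strip()) != _WS.sub(" ", kg.surface_forms[node].strip()):
                    node = None
            if node is not None:
                cat = kg.categories[node]
                found = EntityMatch(Span(i, i + length, cat or "ENT"), node)
                break
        if found is not None:
            matches.append(found)
            i = found.span.end
        else:
            i += 1
    return matches


def build_sentence_graph(
    matches: list[EntityMatch],
    kg: KnowledgeGraph,
    include_neighbors: bool = False,
    use_edges: bool = True,
) -> SentenceGraph:
    """Assemble the adjacency structure the graph attention layer consumes.

    The node set is the matched nodes (in match order, duplicates collapsed),
    optionally extended with their first-order KG neighbors
    (``include_neighbors=True``). ``adjacency[i, j] = 1`` iff a KG edge links
    the two nodes, with the diagonal forced to 1 (self-loops). With
    ``use_edges=False`` the adjacency is the identity over the node set: the
    "concept-only" ablation, which keeps matched concepts but ignores their
    dependencies.
    """
    node_ids: list[int] = []
    local: dict[int, int] = {}
    for m in matches:
        if m.node_id not in local:
            local[m.node_id] = len(node_ids)
            node_ids.append(m.node_id)
    if include_neighbors:
        extra = sorted(
            {nb for m in matches for nb in kg.graph.neighbors(m.node_id)} - set(local)
        )
        for nb in extra:
            local[nb] = len(node_ids)
            node_ids.append(nb)

    m_s = len(node_ids)
    adjacency = np.eye(m_s, dtype=np.int8)
    if use_edges:
        for a in range(m_s):
            for b in range(a + 1, m_s):
                if kg.graph.has_edge(node_ids[a], node_ids[b]):
                    adjacency[a, b] = adjacency[b, a] = 1

    alignment: dict[int, int] = {}
    for m in matches:
        for tok in range(m.span.start, m.span.end):
            alignment[tok] = local[m.node_id]
    return SentenceGraph(node_ids=node_ids, adjacency=adjacency, alignment=alignment, matches=matches)
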