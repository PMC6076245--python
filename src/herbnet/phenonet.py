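"""Phenotype concept hierarchy: parsing, DAG construction and Wu-Palmer similarity.

The phenotype network is a rooted DAG of biomedical concepts (CUI-like string
identifiers) built from broader/narrower (RB/RN) relation rows of an
MRREL-style table.  Hierarchy edges are weighted with the Wu-Palmer semantic
similarity of their endpoints,

    sim(c1, c2) = 2 * depth(lcs) / (path(c1, lcs) + path(c2, lcs) + 2 * depth(lcs)),

where ``lcs`` is the lowest common subsumer (deepest common ancestor), depth
counts nodes on the shortest root path (depth(root) = 1) and path counts edges
on the shortest descending path.  The node-counting depth convention keeps the
root's edges at positive weight.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

logger = logging.getLogger(__name__)

VIRTUAL_ROOT = "__ROOT__"

__all__ = [
    "HierarchyEdge",
    "PhenotypeNetwork",
    "read_relations",
    "read_universe",
    "build_network",
    "weight_edges",
    "write_network",
    "read_network",
    "VIRTUAL_ROOT",
]


@dataclass(frozen=True, order=True)
class HierarchyEdge:
    """A directed hierarchy edge: ``parent`` is the broader concept."""

    parent: str
    child: str

    def __post_init__(self) -> None:
        if not self.parent or not self.child:
            raise ValueError("concept IDs must be non-empty")
        if self.parent == self.child:
            raise ValueError(f"self-relation {self.parent!r} is not a hierarchy edge")


class FormatError(ValueError):
    """Raised when an input file does not match the expected dialect."""


class EmptyInputError(ValueError):
    """Raised when parsing yields zero usable records."""


def read_relations(path: str | Path, *, rb_second_is_broader: bool = True) -> list[HierarchyEdge]:
    """Parse an MRREL-style relations TSV into canonical parent->child edges.

    Each row is ``concept1 <tab> relation <tab> concept2`` with relation RB
    (broader) or RN (narrower).  Under the default convention an RB row states
    that ``concept2`` is broader than ``concept1`` (parent = concept2); RN is
    the inverse statement.  Setting ``rb_second_is_broader=False`` flips both.
    Unknown relations and self-relations are skipped and counted; duplicates
    are merged.
    """
    edges: set[HierarchyEdge] = set()
    skipped = 0
    dropped_self = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0].strip().upper() in {"CUI1", "CONCEPT1"}:
                continue
            if len(parts) < 3:
                raise FormatError(
                    f"{path}:{lineno}: expected 3 tab-separated columns, got {len(parts)}"
                )
            c1, rel, c2 = parts[0].strip(), parts[1].strip().upper(), parts[2].strip()
            if rel not in {"RB", "RN"}:
                skipped += 1
                continue
            if c1 == c2:
                dropped_self += 1
                continue
            broader_is_second = (rel == "RB") == rb_second_is_broader
            parent, child = (c2, c1) if broader_is_second else (c1, c2)
            edges.add(HierarchyEdge(parent=parent, child=child))
    if skipped:
        logger.info("read_relations: skipped %d rows with unknown relation types", skipped)
    if dropped_self:
        logger.info("read_relations: dropped %d self-relations", dropped_self)
    if not edges:
        raise EmptyInputError(f"no usable RB/RN relations in {path}")
    return sorted(edges)


def read_universe(path: str | Path) -> list[str]:
    """Read the phenotype universe: one concept ID per line, order preserved."""
    seen: set[str] = set()
    universe: list[str] = []
    with open(path) as fh:
        for line in fh:
            cid = line.strip()
            if cid and cid not in seen:
                seen.add(cid)
                universe.append(cid)
    if not universe:
        raise EmptyInputError(f"empty phenotype universe file {path}")
    return universe


@dataclass
class PhenotypeNetwork:
    """Rooted DAG of phenotype concepts with Wu-Palmer edge weights.

    ``graph`` holds parent->child hierarchy edges.  ``weights`` maps each
    hierarchy edge (both orientations) to its similarity score in (0, 1];
    it is populated by :func:`weight_edges`.
    """

    graph: nx.DiGraph
    root: str
    weights: dict[tuple[str, str], float] = field(default_factory=dict)
    _depth: dict[str, int] = field(default_factory=dict, repr=False)

    @property
    def concepts(self) -> list[str]:
        return sorted(self.graph.nodes)

    def __contains__(self, concept: str) -> bool:
        return concept in self.graph

    def _require(self, concept: str) -> None:
        if concept not in self.graph:
            raise KeyError(f"unknown concept {concept!r}")

    def depth(self, concept: str) -> int:
        """Number of nodes on the shortest root path, inclusive; depth(root) = 1."""
        self._require(concept)
        if not self._depth:
            self._depth = {
                n: d + 1 for n, d in nx.single_source_shortest_path_length(self.graph, self.root).items()
            }
        return self._depth[concept]

    def ancestors(self, concept: str) -> set[str]:
        """All hierarchy ancestors of ``concept``, including itself."""
        self._require(concept)
        return nx.ancestors(self.graph, concept) | {concept}

    def lcs(self, c1: str, c2: str) -> str:
        """Lowest common subsumer: deepest common ancestor, lexicographic tie-break."""
        common = self.ancestors(c1) & self.ancestors(c2)
        return min(common, key=lambda c: (-self.depth(c), c))

    def path_down(self, ancestor: str, concept: str) -> int:
        """Edge count of the shortest descending hierarchy path ancestor -> concept."""
        return nx.shortest_path_length(self.graph, ancestor, concept)

    def wup_similarity(self, c1: str, c2: str) -> float:
        """Wu-Palmer similarity in (0, 1]; 1 iff ``c1 == c2``.

        The subsumer is the common ancestor yielding the maximal score.  On a
        tree this is exactly the lowest common subsumer; in a multi-parent DAG
        with shortest-path depths a proper ancestor can sit deeper than its
        descendant, in which case scoring through the deepest ancestor would
        break the identity sim(c, c) = 1, so the score-maximizing subsumer is
        the consistent generalization.
        """
        self._require(c1)
        self._require(c2)
        common = self.ancestors(c1) & self.ancestors(c2)
        best = 0.0
        for anc in common:
            d = self.depth(anc)
            p1 = self.path_down(anc, c1)
            p2 = self.path_down(anc, c2)
            best = max(best, 2.0 * d / (p1 + p2 + 2.0 * d))
        return best

    def edge_weight(self, u: str, v: str) -> float:
        return self.weights[(u, v)]


def _break_cycles(edges: Iterable[HierarchyEdge]) -> nx.DiGraph:
    """Drop back-edges found by a deterministic DFS ordered by concept ID."""
    graph = nx.DiGraph()
    for e in sorted(edges):
        graph.add_edge(e.parent, e.child)
    WHITE, GREY, BLACK = 0, 1, 2
    color = {n: WHITE for n in graph.nodes}
    dropped: list[tuple[str, str]] = []
    for start in sorted(graph.nodes):
        if color[start] != WHITE:
            continue
        stack: list[tuple[str, Iterable[str]]] = [(start, iter(sorted(graph.successors(start))))]
        color[start] = GREY
        while stack:
            node, children = stack[-1]
            child = next(children, None)
            if child is None:
                color[node] = BLACK
                stack.pop()
                continue
            if color[child] == GREY:
                dropped.append((node, child))
            elif color[child] == WHITE:
                color[child] = GREY
                stack.append((child, iter(sorted(graph.successors(child)))))
    for u, v in dropped:
        graph.remove_edge(u, v)
        logger.info("build_network: dropped back-edge %s -> %s to break a cycle", u, v)
    return graph


def build_network(edges: Iterable[HierarchyEdge]) -> PhenotypeNetwork:
    """Assemble a rooted DAG from hierarchy edges.

    Cycles are broken deterministically (the back-edge first met by a DFS
    ordered by concept ID is dropped).  If several concepts are parentless a
    virtual root is inserted above all of them.
    """
    edges = list(edges)
    if not edges:
        raise EmptyInputError("cannot build a network from zero edges")
    graph = _break_cycles(edges)
    roots = sorted(n for n in graph.nodes if graph.in_degree(n) == 0)
    if len(roots) == 1:
        root = roots[0]
    else:
        root = VIRTUAL_ROOT
        for r in roots:
            graph.add_edge(root, r)
    return PhenotypeNetwork(graph=graph, root=root)


def weight_edges(network: PhenotypeNetwork) -> PhenotypeNetwork:
    """Attach Wu-Palmer weights to every hierarchy edge, stored symmetrically.

    For a parent at depth ``d`` and its direct child the similarity reduces to
    ``2d / (1 + 2d)`` whenever the parent is the pair's lowest common subsumer,
    so deeper edges carry larger weights and propagation favours specific
    concepts over broad ones.
    """
    weights: dict[tuple[str, str], float] = {}
    for u, v in network.graph.edges:
        w = network.wup_similarity(u, v)
        weights[(u, v)] = w
        weights[(v, u)] = w
    network.weights = weights
    return network


def write_network(network: PhenotypeNetwork, path: str | Path) -> None:
    """Serialize as an edge-list TSV: parent, child, weight."""
    with open(path, "w") as fh:
        fh.write("parent\tchild\tweight\n")
        for u, v in sorted(network.graph.edges):
            w = network.weights.get((u, v), float("nan"))
            fh.write(f"{u}\t{v}\t{w:.10g}\n")


def read_network(path: str | Path) -> PhenotypeNetwork:
    """Reload a network serialized by :func:`write_network`."""
    graph = nx.DiGraph()
    weights: dict[tuple[str, str], float] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("parent\t"):
            raise FormatError(f"{path}: missing network header")
        for line in fh:
            u, v, w = line.rstrip("\n").split("\t")
            graph.add_edge(u, v)
            weights[(u, v)] = weights[(v, u)] = float(w)
    roots = [n for n in graph.nodes if graph.in_degree(n) == 0]
    if len(roots) != 1:
        raise FormatError(f"{path}: serialized network must have exactly one root")
    return PhenotypeNetwork(graph=graph, root=roots[0], weights=weights)
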