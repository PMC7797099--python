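"""DAG-to-tree transformation and lowest-common-function queries.

A GO sub-DAG is not directly usable as a classification hierarchy because
terms may have several parents.  This module derives a spanning
arborescence (every non-root node keeps exactly one of its DAG parents)
under three strategies:

``DFS``
    keeps the first-discovery parent of a depth-first traversal with
    lexicographic child order, realised as the deepest already-placed
    parent; this maximises node depth and therefore annotation
    specificity.
``BFS``
    keeps the shallowest parent, giving every node its shortest-path
    distance from the root.
``RND``
    picks uniformly at random among the parents (seeded).

Two-parent nodes where one parent is an ancestor of the other are resolved
to the deeper parent under the depth-maximising strategies (DFS, RND) —
the single non-redundant attachment point; a ``two_parent_rule`` flag
offers the shallower reading for sensitivity analysis.  BFS always takes
the shallowest parent so that its depths stay shortest-path distances.

The resulting :class:`FunctionTree` supports lowest-common-ancestor
queries, called the lowest common function (LCF) in this functional
setting: the most specific function consistent with all evidence.
"""

from __future__ import annotations

import random
from collections import Counter, deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .ontology import OntologyGraph

STRATEGIES = ("DFS", "BFS", "RND")


@dataclass
class FunctionTree:
    """A rooted functional hierarchy: one parent per non-root node."""

    root: str
    parent: dict[str, str]  # non-root node -> parent
    depth: dict[str, int]
    strategy: str = "DFS"
    seed: int | None = None

    @property
    def nodes(self) -> set[str]:
        return set(self.depth)

    def __contains__(self, node: str) -> bool:
        return node in self.depth

    def children_map(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {n: [] for n in self.depth}
        for child, parent in sorted(self.parent.items()):
            out[parent].append(child)
        return out

    def path_to_root(self, node: str) -> list[str]:
        """Nodes from ``node`` up to and including the root."""
        if node not in self.depth:
            raise KeyError(f"unknown node {node!r}")
        path = [node]
        while path[-1] != self.root:
            path.append(self.parent[path[-1]])
        return path

    def is_ancestor(self, anc: str, node: str) -> bool:
        """True when ``anc`` is an ancestor of ``node`` (or equal)."""
        while True:
            if node == anc:
                return True
            if node == self.root:
                return False
            node = self.parent[node]

    def descendants(self, node: str) -> set[str]:
        children = self.children_map()
        out: set[str] = set()
        stack = [node]
        while stack:
            for child in children[stack.pop()]:
                out.add(child)
                stack.append(child)
        return out


@dataclass
class StrategyComparison:
    """Per-strategy depth summaries over the same node set."""

    entries: list[dict] = field(default_factory=list)

    def by_label(self, label: str) -> dict:
        for entry in self.entries:
            if entry["label"] == label:
                return entry
        raise KeyError(label)


def _toposort(graph: OntologyGraph) -> list[str]:
    """Topological order (parents before children), lexicographic ties.

    Raises on cycles (listing one) and on nodes unreachable from the root.
    """
    if graph.root is None:
        raise ValueError("graph has no designated root; extract one first")
    parents = graph.parent_map()
    children = graph.child_map()
    indeg = {t: len(ps) for t, ps in parents.items()}
    if indeg.get(graph.root, 0) != 0:
        raise ValueError(f"root {graph.root!r} has parents in the sub-DAG")

    import heapq

    ready = [t for t, d in indeg.items() if d == 0]
    heapq.heapify(ready)
    order: list[str] = []
    while ready:
        node = heapq.heappop(ready)
        order.append(node)
        for child in children[node]:
            indeg[child] -= 1
            if indeg[child] == 0:
                heapq.heappush(ready, child)
    if len(order) != len(graph.terms):
        stuck = sorted(t for t, d in indeg.items() if d > 0)
        # distinguish a cycle from disconnection
        cycle = _find_cycle(parents, stuck)
        if cycle:
            raise ValueError(f"ontology contains a cycle: {' -> '.join(cycle)}")
        raise ValueError(f"nodes unreachable from root: {stuck}")
    unreachable = sorted(t for t in graph.terms if t not in set(order))
    if unreachable:
        raise ValueError(f"nodes unreachable from root: {unreachable}")
    return order


def _find_cycle(parents: dict[str, list[str]], nodes: Iterable[str]) -> list[str]:
    nodes = set(nodes)
    for start in sorted(nodes):
        path, seen = [start], {start}
        node = start
        while True:
            nxt = [p for p in parents.get(node, []) if p in nodes]
            if not nxt:
                break
            node = nxt[0]
            if node in seen:
                return path[path.index(node):] + [node] if node in path else [node]
            seen.add(node)
            path.append(node)
    return []


def resolve_parents(
    node: str,
    parents: list[str],
    partial_tree: FunctionTree,
    strategy: str = "DFS",
    rng: random.Random | None = None,
    two_parent_rule: str = "deeper",
) -> str:
    """Choose the single tree parent for a multi-parent node.

    Rules, in order: a single parent is kept as-is; BFS takes the
    shallowest placed parent (lexicographic tie-break) so depths remain
    shortest-path distances; for DFS/RND a two-parent node where one
    parent is an ancestor of the other attaches to the deeper parent (or
    the shallower one under ``two_parent_rule="shallower"``); otherwise
    DFS takes the deepest placed parent (lexicographic tie-break) and RND
    draws uniformly with the supplied seeded ``rng``.
    """
    if not parents:
        raise ValueError(f"node {node!r} has no parents to resolve")
    for p in parents:
        if p not in partial_tree.depth:
            raise RuntimeError(
                f"internal ordering error: parent {p!r} of {node!r} not placed"
            )
    if len(parents) == 1:
        return parents[0]
    depth = partial_tree.depth
    if strategy == "BFS":
        return min(parents, key=lambda p: (depth[p], p))
    if len(parents) == 2:
        a, b = parents
        if partial_tree.is_ancestor(a, b) or partial_tree.is_ancestor(b, a):
            shallow, deep = sorted([a, b], key=lambda p: (depth[p], p))
            return deep if two_parent_rule == "deeper" else shallow
    if strategy == "DFS":
        # first-discovery parent of a lexicographic DFS = deepest placed,
        # ties to the lexicographically smallest identifier
        return min(parents, key=lambda p: (-depth[p], p))
    if strategy == "RND":
        if rng is None:
            raise ValueError("RND strategy requires an rng")
        return rng.choice(sorted(parents))
    raise ValueError(f"unknown strategy {strategy!r}")


def build_tree(
    graph: OntologyGraph,
    strategy: str = "DFS",
    seed: int = 0,
    two_parent_rule: str = "deeper",
) -> FunctionTree:
    """Derive a spanning arborescence of a rooted sub-DAG.

    Nodes are placed in topological order (lexicographic tie-break), so
    every DAG parent of a node is placed — with its final depth — before
    the node itself; each node's parent is then chosen by
    :func:`resolve_parents`.  Deterministic given (strategy, seed).
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"strategy must be one of {STRATEGIES}")
    order = _toposort(graph)
    assert order[0] == graph.root
    rng = random.Random(seed)
    parent_map = graph.parent_map()
    tree = FunctionTree(
        root=graph.root,  # type: ignore[arg-type]
        parent={},
        depth={graph.root: 0},
        strategy=strategy,
        seed=seed,
    )
    for node in order[1:]:
        chosen = resolve_parents(
            node, sorted(parent_map[node]), tree, strategy, rng, two_parent_rule
        )
        tree.parent[node] = chosen
        tree.depth[node] = tree.depth[chosen] + 1
    return tree


def depth_histogram(tree: FunctionTree) -> dict[int, int]:
    """Node count per distance-from-root level."""
    return dict(Counter(tree.depth.values()))


def mean_depth(tree: FunctionTree, include_root: bool = False) -> float:
    """Mean distance from the root, excluding the root itself by default."""
    depths = [d for n, d in tree.depth.items() if include_root or n != tree.root]
    if not depths:
        return 0.0
    return sum(depths) / len(depths)


def compare_strategies(
    graph: OntologyGraph,
    rnd_replicates: int = 10,
    base_seed: int = 1,
) -> StrategyComparison:
    """Build DFS, BFS and ``rnd_replicates`` seeded RND trees and report
    mean depth (root excluded), max depth and the full depth histogram."""
    comparison = StrategyComparison()
    jobs = [("DFS", "DFS", base_seed), ("BFS", "BFS", base_seed)]
    jobs += [
        (f"RND_{i + 1}", "RND", base_seed + i) for i in range(rnd_replicates)
    ]
    for label, strategy, seed in jobs:
        tree = build_tree(graph, strategy=strategy, seed=seed)
        comparison.entries.append(
            {
                "label": label,
                "strategy": strategy,
                "seed": seed,
                "mean_depth": mean_depth(tree),
                "max_depth": max(tree.depth.values()),
                "histogram": depth_histogram(tree),
            }
        )
    return comparison


def lca(tree: FunctionTree, nodes: Iterable[str]) -> str:
    """Lowest common ancestor — here, the lowest common function (LCF):
    the deepest node that is ancestor-or-self of every input node."""
    nodes = list(nodes)
    if not nodes:
        raise ValueError("lca of an empty node set is undefined")
    for n in nodes:
        if n not in tree.depth:
            raise KeyError(f"unknown node {n!r}")
    cur = nodes[0]
    for other in nodes[1:]:
        a, b = cur, other
        while tree.depth[a] > tree.depth[b]:
            a = tree.parent[a]
        while tree.depth[b] > tree.depth[a]:
            b = tree.parent[b]
        while a != b:
            a = tree.parent[a]
            b = tree.parent[b]
        cur = a
        if cur == tree.root:
            break
    return cur


# --- serialization -----------------------------------------------------

def write_tree_tsv(tree: FunctionTree, path: str | Path) -> None:
    """Write the tree as TSV with columns node, parent, depth (root first,
    parent of the root = itself)."""
    lines = [f"{tree.root}\t{tree.root}\t0"]
    for node in sorted(tree.parent):
        lines.append(f"{node}\t{tree.parent[node]}\t{tree.depth[node]}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_tree_tsv(path: str | Path) -> FunctionTree:
    parent: dict[str, str] = {}
    root: str | None = None
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ValueError(f"malformed tree TSV at line {lineno}: {line!r}")
        node, par = fields[0], fields[1]
        if node == par:
            if root is not None and root != node:
                raise ValueError("multiple self-parent (root) rows")
            root = node
        else:
            parent[node] = par
    if root is None:
        raise ValueError("no self-parent (root) row found")
    tree = FunctionTree(root=root, parent=parent, depth={})
    _recompute_depths(tree)
    return tree


def _recompute_depths(tree: FunctionTree) -> None:
    tree.depth = {tree.root: 0}
    children: dict[str, list[str]] = {}
    for child, par in tree.parent.items():
        children.setdefault(par, []).append(child)
    queue = deque([tree.root])
    while queue:
        node = queue.popleft()
        for child in children.get(node, []):
            tree.depth[child] = tree.depth[node] + 1
            queue.append(child)
    missing = set(tree.parent) - set(tree.depth)
    if missing:
        raise ValueError(f"orphan parent references for nodes: {sorted(missing)}")


def write_branches(tree: FunctionTree, path: str | Path) -> None:
    """Export one row per leaf: its root path, most specific term first."""
    leaves = sorted(tree.nodes - set(tree.parent.values()) - {tree.root})
    with open(path, "w") as fh:
        for leaf in leaves:
            fh.write("\t".join(tree.path_to_root(leaf)) + "\n")


def read_branches(path: str | Path) -> FunctionTree:
    """Reconstruct a tree from a branches file (each row a root path,
    most specific term first)."""
    parent: dict[str, str] = {}
    root: str | None = None
    for line in Path(path).read_text().splitlines():
        fields = [f for f in line.rstrip("\n").split("\t") if f]
        if not fields:
            continue
        if root is None:
            root = fields[-1]
        elif fields[-1] != root:
            raise ValueError("branches disagree on the root term")
        for child, par in zip(fields, fields[1:]):
            if parent.setdefault(child, par) != par:
                raise ValueError(f"conflicting parents for {child!r}")
    if root is None:
        raise ValueError("empty branches file")
    tree = FunctionTree(root=root, parent=parent, depth={})
    _recompute_depths(tree)
    return tree
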