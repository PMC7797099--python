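"""Shared fixtures and independent brute-force oracles.

The oracles deliberately re-derive every quantity from first principles
(ancestor-set intersections, exhaustive k-mer scans, quadratic common-
substring search) so the implementation under test never checks itself.
"""

from __future__ import annotations

import pytest

import lcftools as L


# --- brute-force oracles ----------------------------------------------

def ancestor_set(tree: L.FunctionTree, node: str) -> set[str]:
    out = {node}
    while node != tree.root:
        node = tree.parent[node]
        out.add(node)
    return out


def oracle_lca(tree: L.FunctionTree, nodes) -> str:
    common = None
    for n in nodes:
        anc = ancestor_set(tree, n)
        common = anc if common is None else common & anc
    return max(common, key=lambda n: tree.depth[n])


def oracle_kmer_index(records, tree, k, alphabet):
    """Exhaustive scan: every k-mer maps to the LCA of the representative
    terms of all sequences containing it (strand-aware for DNA)."""
    from collections import defaultdict

    containing = defaultdict(set)
    allowed = set("ACGT") if alphabet == "dna" else set("ACDEFGHIKLMNPQRSTVWY")
    for rec in records:
        seq = rec.sequence.upper()
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if set(kmer) <= allowed:
                if alphabet == "dna":
                    kmer = min(kmer, L.reverse_complement(kmer))
                containing[kmer].add(rec.representative)
    return {kmer: oracle_lca(tree, terms) for kmer, terms in containing.items()}

def oracle_path_score_assign(hits: dict[str, int], tree: L.FunctionTree):
    """Enumerate score(v) over ALL tree nodes; return LCA of maximisers
    among nodes with hit support on their root path."""
    scores = {}
    for node in tree.nodes:
        s = sum(hits.get(a, 0) for a in ancestor_set(tree, node))
        if s > 0:
            scores[node] = s
    if not scores:
        return None
    best = max(scores.values())
    tied = [n for n, s in scores.items() if s == best]
    return oracle_lca(tree, tied)


def oracle_longest_common_substring(a: str, b: str) -> int:
    """Quadratic DP over suffix match lengths."""
    best = 0
    prev = [0] * (len(b) + 1)
    for i in range(1, len(a) + 1):
        cur = [0] * (len(b) + 1)
        for j in range(1, len(b) + 1):
            if a[i - 1] == b[j - 1]:
                cur[j] = prev[j - 1] + 1
                best = max(best, cur[j])
        prev = cur
    return best


# --- shared fixtures ---------------------------------------------------

DIAMOND_OBO = """\
format-version: 1.2

[Term]
id: R
name: root
namespace: molecular_function

[Term]
id: A
name: a
namespace: molecular_function
is_a: R

[Term]
id: B
name: b
namespace: molecular_function
is_a: R
is_a: A
"""


@pytest.fixture
def diamond_graph() -> L.OntologyGraph:
    """R -> A, R -> B, A -> B: the canonical two-parent case."""
    graph = L.parse_obo(DIAMOND_OBO)
    return L.extract_subontology(graph, "R", "molecular_function")


@pytest.fixture
def small_tree() -> L.FunctionTree:
    """DFS tree of a 30-term synthetic ontology with multi-parent nodes."""
    _, graph = L.make_ontology(
        L.FixtureSpec(terms=30, seed=11, multi_parent_fraction=0.25)
    )
    sub = L.extract_subontology(graph, graph.root, "molecular_function")
    return L.build_tree(sub, "DFS")


def random_rooted_dag(seed: int, terms: int = 25) -> L.OntologyGraph:
    _, graph = L.make_ontology(
        L.FixtureSpec(
            terms=terms, seed=seed, multi_parent_fraction=0.3
        )
    )
    return L.extract_subontology(graph, graph.root, "molecular_function")
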