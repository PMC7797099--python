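"""Deterministic synthetic ontologies and labelled sequence sets.

Every stage of the pipeline is testable without downloads: this module
generates small GO-like ontologies (rooted DAGs with a configurable
multi-parent fraction, serialised as valid OBO) and random reference
sequences labelled with their terms.  A ``disjoint_kmers`` mode
guarantees pairwise-disjoint k-mer sets across terms, which makes exact
origin recovery provable for noise-free reads.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .ontology import MOLECULAR_FUNCTION_ROOT, OntologyGraph, parse_obo, serialize_obo
from .refdb import SequenceRecord, canonical_kmer
from .tree_builder import FunctionTree


@dataclass
class FixtureSpec:
    """Parameters of a synthetic ontology fixture."""

    terms: int = 50
    #: None picks min(5, terms - 1)
    depth_target: int | None = None
    multi_parent_fraction: float = 0.15
    seed: int = 0
    root_id: str = MOLECULAR_FUNCTION_ROOT
    namespace: str = "molecular_function"


def _term_ids(n: int, root_id: str) -> list[str]:
    """GO-style sequential identifiers, skipping the root accession."""
    root_acc = int(root_id[3:]) if root_id.startswith("GO:") else -1
    ids, acc = [], 1
    while len(ids) < n:
        if acc != root_acc:
            ids.append(f"GO:{acc:07d}")
        acc += 1
    return ids


def make_ontology(spec: FixtureSpec) -> tuple[str, OntologyGraph]:
    """Generate a rooted DAG and its OBO serialisation.

    A backbone chain realises the depth target; remaining terms attach to
    uniformly drawn existing nodes; with probability
    ``multi_parent_fraction`` a term receives one extra parent drawn from
    strictly shallower nodes (which keeps the graph acyclic).
    Deterministic under the seed.
    """
    if spec.terms < 1:
        raise ValueError("spec.terms must be >= 1")
    depth_target = (
        min(5, spec.terms - 1) if spec.depth_target is None else spec.depth_target
    )
    if depth_target > spec.terms - 1:
        raise ValueError(
            f"depth target {depth_target} infeasible with "
            f"{spec.terms} term(s)"
        )
    rng = random.Random(spec.seed)
    graph = OntologyGraph(root=spec.root_id)
    graph.terms.add(spec.root_id)
    graph.names[spec.root_id] = "molecular_function"
    graph.namespace[spec.root_id] = spec.namespace

    depth = {spec.root_id: 0}
    others = _term_ids(spec.terms - 1, spec.root_id)
    placed = [spec.root_id]

    for i, term in enumerate(others):
        if i < depth_target:  # backbone chain realising the depth target
            primary = others[i - 1] if i > 0 else spec.root_id
        else:
            primary = rng.choice(placed)
        graph.terms.add(term)
        graph.names[term] = f"synthetic term {term}"
        graph.namespace[term] = spec.namespace
        graph.edges.add((term, primary))
        depth[term] = depth[primary] + 1
        if rng.random() < spec.multi_parent_fraction:
            shallower = [
                p for p in placed if depth[p] < depth[term] and p != primary
            ]
            if shallower:
                graph.edges.add((term, rng.choice(shallower)))
        placed.append(term)
    return serialize_obo(graph), graph


def _random_seq(rng: random.Random, length: int, alphabet: str) -> str:
    letters = "ACGT" if alphabet == "dna" else "ACDEFGHIKLMNPQRSTVWY"
    return "".join(rng.choice(letters) for _ in range(length))


def _kmer_set(seq: str, k: int, alphabet: str) -> set[str]:
    kmers = {seq[i : i + k] for i in range(len(seq) - k + 1)}
    if alphabet == "dna":
        kmers = {canonical_kmer(km) for km in kmers}
    return kmers


def make_sequences(
    tree: FunctionTree,
    per_term: int = 1,
    length_range: tuple[int, int] = (150, 300),
    alphabet: str = "dna",
    seed: int = 0,
    disjoint_kmers: bool = False,
    k: int = 31,
    terms: list[str] | None = None,
    shared_motif: str | None = None,
    shared_motif_terms: list[str] | None = None,
) -> list[SequenceRecord]:
    """Generate ``per_term`` random labelled sequences per term.

    ``disjoint_kmers`` enforces pairwise-disjoint k-mer sets across terms
    (rejection sampling; collisions are astronomically rare for random
    sequences, so this is a guarantee, not a bottleneck).
    ``shared_motif`` plants a common motif at the start of the first
    sequence of each term in ``shared_motif_terms``, so the motif's index
    entry must resolve to the LCA of those terms.
    """
    if per_term < 1:
        raise ValueError("per_term must be >= 1")
    if disjoint_kmers and length_range[0] < k:
        raise ValueError("minimum length below k in disjoint_kmers mode")
    rng = random.Random(seed)
    chosen_terms = sorted(terms) if terms is not None else sorted(tree.nodes)
    taken_kmers: dict[str, set[str]] = {}
    records: list[SequenceRecord] = []
    for term in chosen_terms:
        if term not in tree:
            raise KeyError(f"term {term!r} not in tree")
        term_kmers: set[str] = set()
        for i in range(per_term):
            length = rng.randint(*length_range)
            for _attempt in range(1000):
                seq = _random_seq(rng, length, alphabet)
                if not disjoint_kmers:
                    break
                kmers = _kmer_set(seq, k, alphabet)
                clash = any(
                    kmers & other
                    for t, other in taken_kmers.items()
                    if t != term
                )
                if not clash:
                    term_kmers |= kmers
                    break
            else:  # pragma: no cover - unreachable in practice
                raise RuntimeError("could not generate disjoint sequences")
            seqid = f"{term.replace(':', '_')}_s{i + 1}"
            records.append(SequenceRecord(seqid, seq, [term], term))
        if disjoint_kmers:
            taken_kmers[term] = term_kmers
    if shared_motif is not None:
        for term in shared_motif_terms or []:
            rec = next(r for r in records if r.terms == [term])
            rec.sequence = shared_motif + rec.sequence[len(shared_motif):]
    return records


def write_fasta(records: list[SequenceRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


def labels_of(records: list[SequenceRecord]) -> dict[str, str]:
    return {r.id: r.terms[0] for r in records}
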