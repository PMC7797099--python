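"""Read classification to the lowest common function (LCF).

Two classification engines are provided, mirroring the two families of
taxonomic classifiers being re-purposed:

* **k-mer / path-weight** (Kraken-style): each read k-mer is looked up in
  the k-mer → LCF index, producing hit counts on tree nodes; each
  root-to-leaf path is scored by the sum of hits on it and the read is
  assigned to the deepest node maximising that path score.  Ties among
  maximal-scoring nodes resolve to their LCA, preserving the
  lowest-common-function semantics.  Works on DNA against a DNA index or
  on six-frame translations against a protein index.
* **maximal exact match** (Kaiju-MEM-style): the read's six translated
  frames, split at stop codons, are searched for the longest exact
  substring match against the protein references; the read is assigned
  to the LCA of the representative terms of all references achieving the
  best match length, provided it reaches ``min_match`` residues
  (default 11, Kaiju's default).

Paired-end mates are pooled: k-mer hit counts are summed over mates
before path scoring; MEM takes the maximum match over both mates.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio.Seq import Seq

from .refdb import KmerIndex, SequenceRecord
from .tree_builder import FunctionTree, lca

IUPAC_DNA = set("ACGTRYSWKMBDHVN")


@dataclass
class ClassificationResult:
    """Per-read assignment with its supporting evidence."""

    read_id: str
    status: str  # "classified" | "unclassified"
    assigned: str | None = None
    #: k-mer mode: node -> k-mer hit count; MEM mode: term -> best match length
    hit_counts: dict[str, int] = field(default_factory=dict)
    mode: str = "kmer_dna"  # kmer_dna | kmer_translated | mem

    @property
    def classified(self) -> bool:
        return self.status == "classified"


def six_frame_translate(read: str) -> list[str]:
    """The six standard-code translations of a DNA read.

    Frames +1, +2, +3 of the read then +1, +2, +3 of its reverse
    complement; trailing partial codons are dropped; stop codons are
    emitted as ``*``; ambiguous codons translate to ``X`` (or to the
    residue when the ambiguity does not change it)."""
    read = read.upper()
    bad = set(read) - IUPAC_DNA
    if bad:
        raise ValueError(f"non-IUPAC DNA symbols in read: {sorted(bad)}")
    frames = []
    for strand in (read, str(Seq(read).reverse_complement())):
        for offset in range(3):
            sub = strand[offset:]
            sub = sub[: len(sub) - len(sub) % 3]
            frames.append(str(Seq(sub).translate()) if sub else "")
    return frames


def split_fragments(frames: Iterable[str], min_len: int = 1) -> list[str]:
    """Split translated frames at stop codons; drop short fragments."""
    fragments = []
    for frame in frames:
        for frag in frame.split("*"):
            if len(frag) >= min_len:
                fragments.append(frag)
    return fragments


def _read_kmers_dna(read: str, k: int) -> Iterable[str]:
    from .refdb import _clean_kmers

    return _clean_kmers(read.upper(), k, "dna")


def _hit_counts(
    read_or_frames: str | Sequence[str], index: KmerIndex
) -> Counter[str]:
    """Count index hits per tree node for one read (any mode)."""
    hits: Counter[str] = Counter()
    if index.alphabet == "dna":
        if not isinstance(read_or_frames, str):
            raise ValueError("DNA index expects a single read string")
        for kmer in _read_kmers_dna(read_or_frames, index.k):
            node = index.entries.get(kmer)
            if node is not None:
                hits[node] += 1
    else:
        if isinstance(read_or_frames, str):
            frames = six_frame_translate(read_or_frames)
        else:
            frames = list(read_or_frames)
        from .refdb import _clean_kmers

        for frag in split_fragments(frames, min_len=index.k):
            for kmer in _clean_kmers(frag, index.k, "protein"):
                node = index.entries.get(kmer)
                if node is not None:
                    hits[node] += 1
    return hits


def _assign_from_hits(
    hits: Counter[str], tree: FunctionTree
) -> tuple[str | None, dict[str, int]]:
    """Path-weight decision: score(v) = sum of hits on the root-to-v
    path; return the maximiser (ties -> LCA of the tied nodes)."""
    if not hits:
        return None, {}
    # the maximum path score is always achieved at a hit node, and every
    # tied non-hit node is a descendant of a tied hit node, which leaves
    # the LCA of the tied set unchanged — so only hit nodes are scored
    scores: dict[str, int] = {}
    for node in hits:
        scores[node] = sum(hits.get(p, 0) for p in tree.path_to_root(node))
    best = max(scores.values())
    tied = [n for n, s in scores.items() if s == best]
    return lca(tree, tied), dict(hits)


def classify_kmer(
    read_or_frames: str | Sequence[str],
    index: KmerIndex,
    tree: FunctionTree,
    read_id: str = "read",
) -> ClassificationResult:
    """Kraken-style k-mer classification of one read (or frame set)."""
    hits = _hit_counts(read_or_frames, index)
    mode = "kmer_dna" if index.alphabet == "dna" else "kmer_translated"
    assigned, counts = _assign_from_hits(hits, tree)
    if assigned is None:
        return ClassificationResult(read_id, "unclassified", mode=mode)
    return ClassificationResult(read_id, "classified", assigned, counts, mode)


# --- maximal exact match engine ---------------------------------------


class MemIndex:
    """Seed index over protein references for maximal-exact-match search.

    Seeds of length ``min_match`` are exhaustive for the decision rule:
    every qualifying match (>= min_match residues) contains a seed at its
    start, and shorter matches never change the unclassified outcome.
    """

    def __init__(self, records: list[SequenceRecord], min_match: int = 11):
        if min_match < 1:
            raise ValueError("min_match must be >= 1")
        self.min_match = min_match
        self.records = records
        self.seeds: dict[str, list[tuple[int, int]]] = {}
        for ri, rec in enumerate(records):
            seq = rec.sequence.upper()
            for pos in range(len(seq) - min_match + 1):
                self.seeds.setdefault(seq[pos : pos + min_match], []).append(
                    (ri, pos)
                )

    def best_matches(self, fragment: str) -> dict[int, int]:
        """Best exact match length per reference index (only >= min_match)."""
        best: dict[int, int] = {}
        m = self.min_match
        frag = fragment.upper()
        for qpos in range(len(frag) - m + 1):
            for ri, rpos in self.seeds.get(frag[qpos : qpos + m], ()):
                seq = self.records[ri].sequence.upper()
                length = m
                while (
                    qpos + length < len(frag)
                    and rpos + length < len(seq)
                    and frag[qpos + length] == seq[rpos + length]
                ):
                    length += 1
                if length > best.get(ri, 0):
                    best[ri] = length
        return best


def classify_mem(
    read: str,
    records: list[SequenceRecord],
    tree: FunctionTree,
    min_match: int = 11,
    read_id: str = "read",
    mem_index: MemIndex | None = None,
) -> ClassificationResult:
    """Kaiju-MEM-style classification of a DNA read against protein
    references."""
    index = mem_index or MemIndex(records, min_match)
    fragments = split_fragments(six_frame_translate(read), min_len=index.min_match)
    best: dict[int, int] = {}
    for frag in fragments:
        for ri, length in index.best_matches(frag).items():
            if length > best.get(ri, 0):
                best[ri] = length
    return _mem_result(best, index.records, tree, read_id)


def _mem_result(
    best: dict[int, int],
    records: list[SequenceRecord],
    tree: FunctionTree,
    read_id: str,
) -> ClassificationResult:
    if not best:
        return ClassificationResult(read_id, "unclassified", mode="mem")
    top = max(best.values())
    terms = set()
    hit_counts: dict[str, int] = {}
    for ri, length in best.items():
        term = records[ri].representative
        if term is None:
            raise ValueError(f"record {records[ri].id!r} has no representative")
        hit_counts[term] = max(hit_counts.get(term, 0), length)
        if length == top:
            terms.add(term)
    return ClassificationResult(
        read_id, "classified", lca(tree, sorted(terms)), hit_counts, "mem"
    )


def classify_pair(
    mate1: str,
    mate2: str | None,
    mode: str,
    index_or_records,
    tree: FunctionTree,
    read_id: str = "pair",
    min_match: int = 11,
    mem_index: MemIndex | None = None,
) -> ClassificationResult:
    """Classify a read pair as one fragment.

    k-mer modes pool the hit counts of both mates before path scoring;
    MEM mode takes the maximum match over mates (achieving references at
    that maximum are unioned).  A missing mate degrades to single-read
    classification.
    """
    if mode in ("kmer_dna", "kmer_translated"):
        index: KmerIndex = index_or_records
        hits = _hit_counts(mate1, index)
        if mate2 is not None:
            hits += _hit_counts(mate2, index)
        assigned, counts = _assign_from_hits(hits, tree)
        if assigned is None:
            return ClassificationResult(read_id, "unclassified", mode=mode)
        return ClassificationResult(read_id, "classified", assigned, counts, mode)
    if mode == "mem":
        records: list[SequenceRecord] = index_or_records
        index_m = mem_index or MemIndex(records, min_match)
        best: dict[int, int] = {}
        for mate in (mate1, mate2):
            if mate is None:
                continue
            frags = split_fragments(
                six_frame_translate(mate), min_len=index_m.min_match
            )
            for frag in frags:
                for ri, length in index_m.best_matches(frag).items():
                    if length > best.get(ri, 0):
                        best[ri] = length
        return _mem_result(best, index_m.records, tree, read_id)
    raise ValueError(f"unknown mode {mode!r}")


def write_classifications(
    results: Iterable[ClassificationResult],
    path: str | Path,
    taxid_map=None,
) -> None:
    """Per-read TSV mirroring Kraken's output shape:
    read_id, C/U flag, assigned term, assigned taxid, evidence summary."""
    with open(path, "w") as fh:
        for res in results:
            flag = "C" if res.classified else "U"
            term = res.assigned or "-"
            taxid = (
                str(taxid_map.to_taxid[res.assigned])
                if taxid_map is not None and res.assigned
                else "-"
            )
            evidence = ",".join(
                f"{n}:{c}" for n, c in sorted(res.hit_counts.items())
            )
            fh.write(f"{res.read_id}\t{flag}\t{term}\t{taxid}\t{evidence}\n")
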