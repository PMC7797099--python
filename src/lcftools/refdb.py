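"""Reference database preparation and the k-mer → LCF index.

A functional reference set is a collection of protein or DNA sequences,
each annotated with one or more GO terms.  Preparation mirrors what a
Kraken-style database build needs:

* when a sequence carries several terms, a single *representative* term
  is selected, prioritising the most specific (deepest) one;
* identical sequences can be collapsed (optionally also sequences fully
  contained in a longer one), which combats root-ward classification
  bias caused by redundant near-identical references;
* protein references can be reverse-translated to DNA using a
  most-frequent-codon table, so DNA-DNA classifiers can consume them.

The index itself maps every k-mer of the reference set to the lowest
common function (LCF) — the LCA over the functional tree — of all
sequences containing that k-mer.  DNA k-mers are canonicalised over
strands (the lexicographic minimum of a k-mer and its reverse
complement); protein k-mers are not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio.Seq import Seq
from Bio import SeqIO

from .tree_builder import FunctionTree, lca

logger = logging.getLogger(__name__)

DNA_ALPHABET = set("ACGT")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")

#: Default k-mer sizes: Kraken-family convention for DNA; smaller for
#: protein where the alphabet is larger and reads are shorter after
#: translation.
DEFAULT_K = {"dna": 31, "protein": 10}

#: Most frequent codon per residue (E. coli K-12 codon usage), used for
#: deterministic reverse translation.  Swappable per call.
PREFERRED_CODONS = {
    "A": "GCG", "R": "CGC", "N": "AAC", "D": "GAT", "C": "TGC",
    "Q": "CAG", "E": "GAA", "G": "GGC", "H": "CAT", "I": "ATT",
    "L": "CTG", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCG",
    "S": "AGC", "T": "ACC", "W": "TGG", "Y": "TAT", "V": "GTG",
    "*": "TAA",
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class SequenceRecord:
    """A reference sequence with its GO term annotations."""

    id: str
    sequence: str
    terms: list[str]
    representative: str | None = None


def load_records(
    fasta: str | Path, labels: dict[str, str] | dict[str, list[str]]
) -> list[SequenceRecord]:
    """Read FASTA and attach term labels (seqid → term or term list)."""
    records = []
    for rec in SeqIO.parse(str(fasta), "fasta"):
        if rec.id not in labels:
            raise ValueError(f"sequence {rec.id!r} has no term label")
        terms = labels[rec.id]
        if isinstance(terms, str):
            terms = [terms]
        records.append(SequenceRecord(rec.id, str(rec.seq).upper(), list(terms)))
    return records


def select_representative_term(terms: Iterable[str], tree: FunctionTree) -> str:
    """Pick the most specific (deepest) term; ties break to the
    lexicographically smallest identifier."""
    terms = list(terms)
    if not terms:
        raise ValueError("no terms to select from")
    for t in terms:
        if t not in tree:
            raise KeyError(f"term {t!r} not in tree")
    return min(terms, key=lambda t: (-tree.depth[t], t))


def assign_representatives(
    records: list[SequenceRecord], tree: FunctionTree
) -> list[SequenceRecord]:
    for rec in records:
        rec.representative = select_representative_term(rec.terms, tree)
    return records


def collapse_redundant(
    records: list[SequenceRecord], mode: str = "exact"
) -> tuple[list[SequenceRecord], list[tuple[str, str]]]:
    """Remove redundant sequences.

    ``exact`` drops byte-identical duplicates, keeping the first by input
    order.  ``containment`` additionally drops sequences that are
    substrings of a longer kept sequence, keeping the longest.  Returns
    (kept records, list of (removed id, kept id) pairs).
    """
    if mode not in ("exact", "containment"):
        raise ValueError(f"unknown mode {mode!r}")
    removed: list[tuple[str, str]] = []
    seen: dict[str, SequenceRecord] = {}
    kept: list[SequenceRecord] = []
    for rec in records:
        if rec.sequence in seen:
            removed.append((rec.id, seen[rec.sequence].id))
        else:
            seen[rec.sequence] = rec
            kept.append(rec)
    if mode == "containment":
        by_len = sorted(kept, key=lambda r: -len(r.sequence))
        final: list[SequenceRecord] = []
        for rec in by_len:
            host = next(
                (k for k in final if rec.sequence in k.sequence), None
            )
            if host is not None:
                removed.append((rec.id, host.id))
            else:
                final.append(rec)
        order = {id(r): i for i, r in enumerate(kept)}
        kept = sorted(final, key=lambda r: order[id(r)])
    return kept, removed


def translate(dna: str) -> str:
    """Standard-code translation of a DNA string (length a multiple of 3)."""
    return str(Seq(dna).translate())


def reverse_translate(
    protein: str, codon_choice: dict[str, str] | None = None
) -> str:
    """Deterministically back-translate a protein to DNA, one codon per
    residue from ``codon_choice`` (default: bundled most-frequent-codon
    table).  Translating the result under the standard code reproduces
    the input."""
    table = codon_choice or PREFERRED_CODONS
    codons = []
    for pos, residue in enumerate(protein.upper()):
        if residue not in table:
            raise ValueError(
                f"unknown residue {residue!r} at position {pos}"
            )
        codons.append(table[residue])
    return "".join(codons)


def reverse_complement(dna: str) -> str:
    return dna.translate(_COMPLEMENT)[::-1]


def canonical_kmer(kmer: str) -> str:
    """Lexicographic minimum of a DNA k-mer and its reverse complement."""
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


def _clean_kmers(sequence: str, k: int, alphabet: str) -> Iterable[str]:
    """Yield k-mers free of ambiguity symbols (canonicalised for DNA)."""
    allowed = DNA_ALPHABET if alphabet == "dna" else PROTEIN_ALPHABET
    n = len(sequence)
    # track the rightmost disallowed symbol to skip ambiguous windows fast
    last_bad = -1
    for i in range(n):
        if sequence[i] not in allowed:
            last_bad = i
        start = i - k + 1
        if start >= 0 and last_bad < start:
            kmer = sequence[start : i + 1]
            yield canonical_kmer(kmer) if alphabet == "dna" else kmer


@dataclass
class KmerIndex:
    """k-mer → LCF lookup over a functional tree."""

    k: int
    alphabet: str  # "dna" | "protein"
    entries: dict[str, str] = field(default_factory=dict)
    tree: FunctionTree | None = None
    skipped: list[str] = field(default_factory=list)  # too-short sequence ids

    def lookup(self, kmer: str) -> str | None:
        if self.alphabet == "dna":
            kmer = canonical_kmer(kmer)
        return self.entries.get(kmer)

    def save_tsv(self, path: str | Path, taxid_map=None) -> None:
        """Persist as sorted TSV (k-mer, term or taxid) with a header."""
        with open(path, "w") as fh:
            fh.write(f"#k={self.k}\talphabet={self.alphabet}\n")
            for kmer in sorted(self.entries):
                value = self.entries[kmer]
                if taxid_map is not None:
                    value = str(taxid_map.to_taxid[value])
                fh.write(f"{kmer}\t{value}\n")

    @classmethod
    def load_tsv(cls, path: str | Path, tree: FunctionTree | None = None):
        lines = Path(path).read_text().splitlines()
        header = dict(
            part.split("=") for part in lines[0].lstrip("#").split("\t")
        )
        index = cls(k=int(header["k"]), alphabet=header["alphabet"], tree=tree)
        for line in lines[1:]:
            if line.strip():
                kmer, value = line.split("\t")
                index.entries[kmer] = value
        return index


def build_kmer_index(
    records: list[SequenceRecord],
    tree: FunctionTree,
    k: int,
    alphabet: str = "dna",
) -> KmerIndex:
    """Index every reference k-mer to the LCF of the representative terms
    of all sequences containing it.

    Sequences shorter than ``k`` contribute nothing (logged); k-mers with
    ambiguity symbols are skipped; DNA k-mers are strand-canonical.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if alphabet not in ("dna", "protein"):
        raise ValueError(f"unknown alphabet {alphabet!r}")
    index = KmerIndex(k=k, alphabet=alphabet, tree=tree)
    for rec in records:
        if rec.representative is None:
            raise ValueError(f"record {rec.id!r} has no representative term")
        if rec.representative not in tree:
            raise KeyError(f"term {rec.representative!r} not in tree")
        if len(rec.sequence) < k:
            index.skipped.append(rec.id)
            continue
        term = rec.representative
        # a sequence may contain a k-mer several times; LCA is idempotent
        for kmer in _clean_kmers(rec.sequence.upper(), k, alphabet):
            cur = index.entries.get(kmer)
            if cur is None:
                index.entries[kmer] = term
            elif cur != term:
                index.entries[kmer] = lca(tree, [cur, term])
    if index.skipped:
        logger.warning(
            "%d sequence(s) shorter than k=%d skipped: %s",
            len(index.skipped), k, index.skipped[:5],
        )
    return index
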