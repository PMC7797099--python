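"""NCBI-taxonomy-style export of the functional hierarchy.

Kraken, Kraken 2 and Kaiju build their databases from NCBI taxonomy dump
files (``nodes.dmp`` / ``names.dmp``, tab-pipe-delimited) and from
reference sequences whose headers or mapping files carry taxon
identifiers.  Writing the functional tree in exactly that dialect is what
lets those taxonomic classifiers be re-purposed for functional (GO term)
classification: each GO term becomes a "taxon".

Taxon identifiers default to the numeric GO accession (``GO:0003674`` →
3674), which is collision-free within GO and human-auditable; non-GO
fixture identifiers fall back to sequential assignment above the current
maximum.  The root's parent is itself (NCBI convention), ranks are all
``no rank`` (functional levels have no Linnaean ranks) and names carry
the ``scientific name`` class so name-class-filtering tools accept them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

from Bio import SeqIO

from .ontology import GO_ID_PATTERN
from .tree_builder import FunctionTree, _recompute_depths

logger = logging.getLogger(__name__)


@dataclass
class TaxidMap:
    """Bijection between tree nodes and positive integer taxids."""

    to_taxid: dict[str, int] = field(default_factory=dict)
    to_term: dict[int, str] = field(default_factory=dict)

    def add(self, term: str, taxid: int) -> None:
        if taxid in self.to_term or term in self.to_taxid:
            raise ValueError(f"duplicate mapping for {term!r} / {taxid}")
        self.to_taxid[term] = taxid
        self.to_term[taxid] = term

    def __len__(self) -> int:
        return len(self.to_taxid)


def assign_taxids(tree: FunctionTree) -> TaxidMap:
    """Map every tree node to a positive integer taxid.

    GO-style identifiers take the integer value of their 7-digit accession
    suffix; anything else (or a collision, or an accession of 0) gets the
    smallest unused integer above the maximum already assigned.
    """
    mapping = TaxidMap()
    fallback: list[str] = []
    for term in sorted(tree.nodes):
        if GO_ID_PATTERN.match(term):
            taxid = int(term[3:])
            if taxid > 0 and taxid not in mapping.to_term:
                mapping.add(term, taxid)
                continue
        fallback.append(term)
    next_id = max(mapping.to_term, default=0) + 1
    for term in fallback:
        mapping.add(term, next_id)
        next_id += 1
    return mapping


def write_taxonomy(
    tree: FunctionTree,
    taxid_map: TaxidMap,
    names: dict[str, str] | None = None,
    out_dir: str | Path = ".",
) -> tuple[Path, Path]:
    """Write ``nodes.dmp`` and ``names.dmp`` in the NCBI dump dialect.

    Row formats (bit-exact, one row per node, sorted by taxid)::

        nodes.dmp: <taxid>\\t|\\t<parent_taxid>\\t|\\tno rank\\t|
        names.dmp: <taxid>\\t|\\t<name>\\t|\\t\\t|\\tscientific name\\t|

    The root's parent is itself.  A node absent from ``taxid_map`` is an
    error.  Missing names default to the term identifier.
    """
    names = names or {}
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    unmapped = sorted(n for n in tree.nodes if n not in taxid_map.to_taxid)
    if unmapped:
        raise ValueError(f"nodes without a taxid: {unmapped}")

    nodes_rows, names_rows = [], []
    for term in sorted(tree.nodes, key=lambda t: taxid_map.to_taxid[t]):
        taxid = taxid_map.to_taxid[term]
        parent_term = tree.parent.get(term, term)  # root: self-parent
        parent_taxid = taxid_map.to_taxid[parent_term]
        nodes_rows.append(f"{taxid}\t|\t{parent_taxid}\t|\tno rank\t|")
        names_rows.append(
            f"{taxid}\t|\t{names.get(term, term)}\t|\t\t|\tscientific name\t|"
        )
    nodes_path = out_dir / "nodes.dmp"
    names_path = out_dir / "names.dmp"
    nodes_path.write_text("\n".join(nodes_rows) + "\n")
    names_path.write_text("\n".join(names_rows) + "\n")
    return nodes_path, names_path


def _default_term_for_taxid(taxid: int) -> str:
    return f"GO:{taxid:07d}" if taxid <= 9_999_999 else str(taxid)


def read_taxonomy(
    nodes_dmp: str | Path,
    names_dmp: str | Path | None = None,
    term_for_taxid: Callable[[int], str] = _default_term_for_taxid,
) -> tuple[FunctionTree, TaxidMap, dict[str, str]]:
    """Read ``nodes.dmp`` (and optionally ``names.dmp``) back into a tree.

    The single self-parent row identifies the root; depths are recomputed.
    ``term_for_taxid`` reconstructs term identifiers from taxids (default:
    7-digit GO accession formatting).  Returns (tree, taxid map, names).
    """
    rows: list[tuple[int, int]] = []
    for lineno, line in enumerate(Path(nodes_dmp).read_text().splitlines(), 1):
        if not line.strip():
            continue
        fields = line.split("\t|\t")
        if len(fields) < 2:
            raise ValueError(f"malformed nodes.dmp row {lineno}: {line!r}")
        rows.append((int(fields[0]), int(fields[1].rstrip("\t|"))))

    known = {t for t, _ in rows}
    roots = [t for t, p in rows if t == p]
    if len(roots) != 1:
        raise ValueError(f"expected exactly one self-parent (root) row, got {roots}")
    for lineno, (taxid, parent) in enumerate(rows, 1):
        if parent not in known:
            raise ValueError(
                f"nodes.dmp row {lineno}: parent taxid {parent} is undefined"
            )

    mapping = TaxidMap()
    for taxid, _ in rows:
        mapping.add(term_for_taxid(taxid), taxid)
    root_term = mapping.to_term[roots[0]]
    parent_map = {
        mapping.to_term[t]: mapping.to_term[p] for t, p in rows if t != p
    }
    tree = FunctionTree(root=root_term, parent=parent_map, depth={})
    _recompute_depths(tree)

    names: dict[str, str] = {}
    if names_dmp is not None:
        for line in Path(names_dmp).read_text().splitlines():
            if not line.strip():
                continue
            fields = line.split("\t|\t")
            taxid = int(fields[0])
            if taxid in mapping.to_term and (
                len(fields) < 4 or fields[3].rstrip("\t|") == "scientific name"
            ):
                names[mapping.to_term[taxid]] = fields[1]
    return tree, mapping, names


def label_sequences(
    fasta_in: str | Path,
    seq2term: dict[str, str],
    taxid_map: TaxidMap,
    dialect: str = "kraken_header",
    fasta_out: str | Path | None = None,
    tsv_out: str | Path | None = None,
) -> None:
    """Emit classifier-consumable sequence labels.

    ``kraken_header`` rewrites each header to
    ``>seqid|kraken:taxid|<taxid> <original description>`` (Kraken library
    convention); ``mapping_file`` writes a two-column ``seqid\\ttaxid``
    TSV.  Sequence bodies are unchanged.  Unlabelled sequences are an
    error listing the offending ids.
    """
    if dialect not in ("kraken_header", "mapping_file"):
        raise ValueError(f"unknown dialect {dialect!r}")
    records = list(SeqIO.parse(str(fasta_in), "fasta"))
    if not records:
        logger.warning("empty FASTA %s: writing empty outputs", fasta_in)
    missing = [r.id for r in records if r.id not in seq2term]
    if missing:
        raise ValueError(f"sequences without a term label: {missing}")
    unmapped = sorted(
        {seq2term[r.id] for r in records} - set(taxid_map.to_taxid)
    )
    if unmapped:
        raise ValueError(f"terms without a taxid: {unmapped}")

    if dialect == "kraken_header":
        out = Path(fasta_out if fasta_out is not None else "labeled.fasta")
        with open(out, "w") as fh:
            for rec in records:
                taxid = taxid_map.to_taxid[seq2term[rec.id]]
                desc = rec.description[len(rec.id):].strip()
                header = f">{rec.id}|kraken:taxid|{taxid}"
                if desc:
                    header += f" {desc}"
                fh.write(header + "\n")
                fh.write(str(rec.seq) + "\n")
    else:
        out = Path(tsv_out if tsv_out is not None else "seqid2taxid.map")
        with open(out, "w") as fh:
            for rec in records:
                fh.write(f"{rec.id}\t{taxid_map.to_taxid[seq2term[rec.id]]}\n")


def read_seq_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column ``seqid\\tterm`` TSV."""
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        seqid, term = line.split("\t")[:2]
        out[seqid] = term
    return out


def write_seq_labels(labels: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for seqid in sorted(labels):
            fh.write(f"{seqid}\t{labels[seqid]}\n")
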