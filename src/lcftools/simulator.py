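"""wgsim-like paired-end read simulation from labelled references.

Reads are simulated the way classification benchmarks build their truth
sets: paired 125 bp reads are drawn from reference DNA at a chosen fold
coverage, each base independently substituted (to one of the three other
bases) with a fixed per-base probability — no indels, no quality model.
The origin of every read is encoded in its identifier::

    <seqid>|go:<TERM>|<serial>/<1|2>

so downstream evaluation can compare the assigned term to the term of
origin.  References shorter than the read length, or with a high
fraction of ambiguous bases, are filtered out first (with a per-reason
skip report).  Simulation is fully deterministic under a seed.
"""

from __future__ import annotations

import gzip
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .refdb import SequenceRecord, reverse_complement

logger = logging.getLogger(__name__)

READ_ID_RE = re.compile(r"^(?P<seqid>.+)\|go:(?P<term>[^|]+)\|(?P<serial>\d+)/(?P<mate>[12])$")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class ReadPair:
    id1: str
    seq1: str
    id2: str
    seq2: str
    origin_seqid: str
    origin_term: str
    #: fragment coordinates on the source sequence (known truth for
    #: alignment-free error-rate auditing)
    start: int = 0
    insert: int = 0


@dataclass
class SkipReport:
    short: list[str] = field(default_factory=list)
    ambiguous: list[str] = field(default_factory=list)

    def counts(self) -> dict[str, int]:
        return {"short": len(self.short), "ambiguous": len(self.ambiguous)}


@dataclass
class SimulatedReadSet:
    pairs: list[ReadPair]
    read_length: int
    substitution_rate: float
    coverage: float
    insert_size: int
    seed: int

    def __len__(self) -> int:
        return len(self.pairs)

    def manifest(self) -> dict:
        return {
            "n_pairs": len(self.pairs),
            "read_length": self.read_length,
            "substitution_rate": self.substitution_rate,
            "coverage": self.coverage,
            "insert_size": self.insert_size,
            "seed": self.seed,
        }


def parse_read_id(read_id: str) -> tuple[str, str, int, int]:
    """Decode a simulated read id into (seqid, term, serial, mate)."""
    m = READ_ID_RE.match(read_id)
    if m is None:
        raise ValueError(f"read id {read_id!r} does not follow the grammar")
    return (
        m.group("seqid"),
        m.group("term"),
        int(m.group("serial")),
        int(m.group("mate")),
    )


def eligible_sequences(
    records: list[SequenceRecord],
    read_length: int = 125,
    max_ambiguous_fraction: float = 0.10,
) -> tuple[list[SequenceRecord], SkipReport]:
    """Filter references usable for simulation.

    Sequences shorter than ``read_length`` are skipped (reason "short");
    sequences whose non-ACGT fraction exceeds ``max_ambiguous_fraction``
    are skipped (reason "ambiguous")."""
    report = SkipReport()
    kept = []
    for rec in records:
        seq = rec.sequence.upper()
        if len(seq) < read_length:
            report.short.append(rec.id)
            continue
        n_ambiguous = sum(1 for b in seq if b not in "ACGT")
        if n_ambiguous / len(seq) > max_ambiguous_fraction:
            report.ambiguous.append(rec.id)
            continue
        kept.append(rec)
    return kept, report


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each base independently with probability ``rate``,
    choosing uniformly among the three other bases."""
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < rate
    if hit.any():
        idx = np.searchsorted(_BASES, arr[hit])
        shift = rng.integers(1, 4, size=int(hit.sum()))
        arr[hit] = _BASES[(idx + shift) % 4]
    return arr.tobytes().decode()


def pairs_per_sequence(length: int, coverage: float, read_length: int) -> int:
    """Pair count giving the requested fold coverage:
    max(1, round(coverage * length / (2 * read_length)))."""
    return max(1, round(coverage * length / (2 * read_length)))


def simulate_reads(
    records: list[SequenceRecord],
    read_length: int = 125,
    substitution_rate: float = 0.05,
    coverage: float = 10.0,
    insert_size: int = 300,
    seed: int = 0,
) -> SimulatedReadSet:
    """Simulate paired-end reads from (pre-filtered) labelled references.

    Per sequence, ``pairs_per_sequence`` fragments are drawn with a
    uniform start; mate 1 is the forward prefix of the fragment, mate 2
    the reverse complement of its suffix.  Inserts longer than the
    sequence are clamped (with a warning).  Records must carry their
    origin term as ``representative`` (falling back to the sole entry of
    ``terms``).
    """
    if insert_size < read_length:
        raise ValueError("insert_size must be >= read_length")
    rng = np.random.default_rng(seed)
    pairs: list[ReadPair] = []
    clamped = 0
    for rec in records:
        seq = rec.sequence.upper()
        term = rec.representative or (rec.terms[0] if rec.terms else None)
        if term is None:
            raise ValueError(f"record {rec.id!r} has no origin term")
        insert = insert_size
        if insert > len(seq):
            insert = max(read_length, len(seq))
            clamped += 1
        n_pairs = pairs_per_sequence(len(seq), coverage, read_length)
        starts = rng.integers(0, len(seq) - insert + 1, size=n_pairs)
        for serial, start in enumerate(starts, 1):
            fragment = seq[start : start + insert]
            m1 = _mutate(fragment[:read_length], substitution_rate, rng)
            m2 = _mutate(
                reverse_complement(fragment[-read_length:]),
                substitution_rate,
                rng,
            )
            pairs.append(
                ReadPair(
                    id1=f"{rec.id}|go:{term}|{serial}/1",
                    seq1=m1,
                    id2=f"{rec.id}|go:{term}|{serial}/2",
                    seq2=m2,
                    origin_seqid=rec.id,
                    origin_term=term,
                    start=int(start),
                    insert=insert,
                )
            )
    if clamped:
        logger.warning(
            "insert size exceeded %d sequence(s); clamped to sequence length",
            clamped,
        )
    return SimulatedReadSet(
        pairs=pairs,
        read_length=read_length,
        substitution_rate=substitution_rate,
        coverage=coverage,
        insert_size=insert_size,
        seed=seed,
    )


def write_fastq(
    readset: SimulatedReadSet,
    out_dir: str | Path,
    prefix: str = "sim",
    compress: bool = False,
) -> tuple[Path, Path]:
    """Write mate FASTQ files (constant 'I' qualities) and a JSON run
    manifest echoing the simulation parameters."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    suffix = ".fastq.gz" if compress else ".fastq"
    p1 = out_dir / f"{prefix}_1{suffix}"
    p2 = out_dir / f"{prefix}_2{suffix}"
    opener = gzip.open if compress else open
    with opener(p1, "wt") as f1, opener(p2, "wt") as f2:
        for pair in readset.pairs:
            q = "I" * len(pair.seq1)
            f1.write(f"@{pair.id1}\n{pair.seq1}\n+\n{q}\n")
            q = "I" * len(pair.seq2)
            f2.write(f"@{pair.id2}\n{pair.seq2}\n+\n{q}\n")
    (out_dir / f"{prefix}_manifest.json").write_text(
        json.dumps(readset.manifest(), indent=2) + "\n"
    )
    return p1, p2
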