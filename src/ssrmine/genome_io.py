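"""Reading, filtering and profiling genome assemblies in FASTA format.

Sequences are streamed as plain ``(sequence_id, residues)`` pairs with
residues folded to uppercase; soft-masked (lowercase) bases are treated as
ordinary sequence. Any symbol outside {A,C,G,T} is kept in coordinates but
is excluded from GC computation and is opaque to the repeat scanner.
"""

from __future__ import annotations

import gzip
import io
import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator

from Bio.SeqIO.FastaIO import SimpleFastaParser

Record = tuple[str, str]

_GC = frozenset("GC")
_ACGT = frozenset("ACGT")


class FastaParseError(ValueError):
    pass


@dataclass(frozen=True)
class GenomeProfile:
    """Size and composition summary of a (length-filtered) assembly.

    ``gc_fraction`` is the proportion of G+C among A/C/G/T bases only;
    it is None when the assembly holds no unambiguous base. ``n_filtered``
    counts contigs removed by the minimum-length filter.
    """

    assembly_id: str
    n_sequences: int
    total_length: int
    gc_fraction: float | None
    n_filtered: int = 0

    @property
    def size_mb(self) -> float:
        """Assembly length in megabases (1 Mb = 10^6 bp exactly)."""
        return self.total_length / 1e6


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="ascii")
    return open(path, encoding="ascii")


def read_fasta(path: str | Path) -> Iterator[Record]:
    """Stream (id, residues) pairs from a FASTA file, plain or gzipped.

    The sequence id is the first whitespace-delimited token of the header;
    residues are uppercased. Sequence data appearing before any header is a
    parse error naming the offending line. An empty file yields nothing.
    """
    with _open_text(path) as handle:
        lines = iter(handle)
        head: list[str] = []
        for lineno, line in enumerate(lines, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaParseError(
                        f"{path}: line {lineno}: sequence data before any FASTA header"
                    )
                head.append(line)
                break
        for title, seq in SimpleFastaParser(itertools.chain(head, lines)):
            yield title.split()[0] if title.split() else "", seq.upper()


def write_fasta(records: Iterable[Record], path: str | Path, width: int = 60) -> None:
    with open(path, "w", encoding="ascii") as out:
        for seq_id, residues in records:
            out.write(f">{seq_id}\n")
            for i in range(0, len(residues), width):
                out.write(residues[i : i + width] + "\n")


def filter_contigs(
    records: Iterable[Record], min_contig_len: int = 0
) -> Iterator[Record]:
    """Drop contigs shorter than ``min_contig_len`` bp."""
    for seq_id, residues in records:
        if len(residues) >= min_contig_len:
            yield seq_id, residues


def profile_genome(
    records: Iterable[Record],
    min_contig_len: int = 0,
    assembly_id: str = "assembly",
) -> GenomeProfile:
    """Length-filter and profile an assembly.

    Contigs shorter than ``min_contig_len`` are excluded from every
    statistic. GC is computed over A/C/G/T only (Ns and other ambiguity
    codes count toward neither numerator nor denominator).
    """
    if min_contig_len < 0:
        raise ValueError("min_contig_len must be >= 0")
    n_seq = n_filtered = total = gc = acgt = 0
    for seq_id, residues in records:
        if len(residues) < min_contig_len:
            n_filtered += 1
            continue
        n_seq += 1
        total += len(residues)
        gc += sum(residues.count(b) for b in "GC")
        acgt += sum(residues.count(b) for b in "ACGT")
    return GenomeProfile(
        assembly_id=assembly_id,
        n_sequences=n_seq,
        total_length=total,
        gc_fraction=(gc / acgt) if acgt else None,
        n_filtered=n_filtered,
    )
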