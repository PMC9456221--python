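"""Detection of perfect microsatellite tracts in genome sequences.

A perfect SSR is a maximal uninterrupted repetition of an atomic 1-6 bp
motif; the final unit may be partial. A tract is reported once, at its
smallest period, and only when it contains at least the per-period minimum
number of COMPLETE units: 12 for mononucleotides, 7 for dinucleotides, 5
for trinucleotides and 4 for tetra-, penta- and hexanucleotides. Any
symbol outside {A,C,G,T} terminates a run.

Algorithm
---------
For each period p, the boolean match vector m[j] = (s[j] == s[j+p], s[j] in
{A,C,G,T}) is computed with numpy; every maximal run of True of length r
corresponds to a maximal p-periodic tract of length r + p. A tract is kept
at period p iff p is the smallest period of the whole tract, which both
guarantees the motif is atomic and suppresses candidates contained in a
smaller-period tract (a substring of a q-periodic string is q-periodic).
Tracts of different periods that overlap without containment are all
reported. Output order is (start, end); the scanner is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

from .genome_io import GenomeProfile, Record
from .motif_algebra import canonical_representative

#: Minimum complete repeat units per period 1..6.
DEFAULT_MIN_UNITS = (12, 7, 5, 4, 4, 4)

_ACGT_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)
_GC_CODES = np.frombuffer(b"GC", dtype=np.uint8)


@dataclass(frozen=True)
class ScanThresholds:
    """Per-period minimum complete-unit counts and the maximum period."""

    min_units: tuple[int, ...] = DEFAULT_MIN_UNITS
    max_period: int = 6

    def __post_init__(self) -> None:
        if self.max_period < 1 or self.max_period > len(self.min_units):
            raise ValueError("max_period must be in 1..len(min_units)")
        if any(u < 1 for u in self.min_units):
            raise ValueError("all min_units entries must be >= 1")

    def min_units_for(self, period: int) -> int:
        return self.min_units[period - 1]


DEFAULT_THRESHOLDS = ScanThresholds()


@dataclass(frozen=True)
class SSRLocus:
    """One perfect repeat tract. Coordinates are 0-based half-open."""

    sequence_id: str
    start: int
    end: int
    period: int
    motif_observed: str
    motif_class: str
    gc_count: int

    @property
    def tract_length(self) -> int:
        return self.end - self.start

    @property
    def complete_units(self) -> int:
        return self.tract_length // self.period


def _true_runs(mask: np.ndarray) -> Iterator[tuple[int, int]]:
    """(start, stop) of maximal runs of True; stop is exclusive."""
    if mask.size == 0:
        return
    padded = np.diff(np.r_[False, mask, False].astype(np.int8))
    starts = np.flatnonzero(padded == 1)
    stops = np.flatnonzero(padded == -1)
    yield from zip(starts.tolist(), stops.tolist())


def _smallest_period(arr: np.ndarray, start: int, end: int, upto: int) -> int:
    """Smallest q <= upto with arr[start:end] q-periodic; upto if none smaller."""
    for q in range(1, upto):
        if np.array_equal(arr[start : end - q], arr[start + q : end]):
            return q
    return upto


def scan_sequence(
    sequence_id: str,
    residues: str,
    thresholds: ScanThresholds = DEFAULT_THRESHOLDS,
    strand: str = "revcomp",
) -> list[SSRLocus]:
    """All perfect SSR tracts in one sequence, sorted by (start, end)."""
    arr = np.frombuffer(residues.encode("ascii"), dtype=np.uint8)
    n = arr.size
    is_acgt = np.isin(arr, _ACGT_CODES)
    is_gc = np.isin(arr, _GC_CODES)
    gc_cum = np.r_[0, np.cumsum(is_gc)]
    loci: list[SSRLocus] = []
    for p in range(1, thresholds.max_period + 1):
        if n <= p:
            break
        need = thresholds.min_units_for(p)
        match = (arr[:-p] == arr[p:]) & is_acgt[:-p]
        for j0, j1 in _true_runs(match):
            start, end = j0, j1 + p  # tract = matches plus the final p bases
            if (end - start) // p < need:
                continue
            if _smallest_period(arr, start, end, p) != p:
                continue
            motif = residues[start : start + p]
            loci.append(
                SSRLocus(
                    sequence_id=sequence_id,
                    start=start,
                    end=end,
                    period=p,
                    motif_observed=motif,
                    motif_class=canonical_representative(motif, strand),
                    gc_count=int(gc_cum[end] - gc_cum[start]),
                )
            )
    loci.sort(key=lambda l: (l.start, l.end))
    return loci


def scan_genome(
    records: Iterable[Record],
    thresholds: ScanThresholds = DEFAULT_THRESHOLDS,
    min_contig_len: int = 0,
    assembly_id: str = "assembly",
    strand: str = "revcomp",
) -> tuple[GenomeProfile, list[SSRLocus]]:
    """Scan every retained contig; loci follow input sequence order.

    Single streaming pass: the profile and the scan share one traversal,
    so gzipped multi-hundred-Mb assemblies never need to be held whole.
    """
    n_seq = n_filtered = total = gc = acgt = 0
    loci: list[SSRLocus] = []
    for seq_id, residues in records:
        if len(residues) < min_contig_len:
            n_filtered += 1
            continue
        n_seq += 1
        total += len(residues)
        gc += sum(residues.count(b) for b in "GC")
        acgt += sum(residues.count(b) for b in "ACGT")
        loci.extend(scan_sequence(seq_id, residues, thresholds, strand))
    profile = GenomeProfile(
        assembly_id=assembly_id,
        n_sequences=n_seq,
        total_length=total,
        gc_fraction=(gc / acgt) if acgt else None,
        n_filtered=n_filtered,
    )
    return profile, loci


# ---------------------------------------------------------------------------
# serialization

TSV_COLUMNS = (
    "sequence_id",
    "start_1based",
    "end",
    "tract_length",
    "period",
    "motif_observed",
    "motif_class",
    "complete_units",
    "gc_count",
)


def loci_to_rows(loci: Iterable[SSRLocus]) -> Iterator[dict]:
    """TSV rows with 1-based inclusive coordinates."""
    for l in loci:
        yield {
            "sequence_id": l.sequence_id,
            "start_1based": l.start + 1,
            "end": l.end,
            "tract_length": l.tract_length,
            "period": l.period,
            "motif_observed": l.motif_observed,
            "motif_class": l.motif_class,
            "complete_units": l.complete_units,
            "gc_count": l.gc_count,
        }


def loci_to_bed(loci: Iterable[SSRLocus]) -> Iterator[str]:
    """BED6 lines: name = class.period, score = tract length, strand '.'."""
    for l in loci:
        yield (
            f"{l.sequence_id}\t{l.start}\t{l.end}\t"
            f"{l.motif_class}.{l.period}\t{l.tract_length}\t."
        )
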