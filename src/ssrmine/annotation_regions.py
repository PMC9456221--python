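"""Genomic compartments from GFF3 annotations, and SSR-to-region assignment.

Compartments are derived per sequence from gene/exon/CDS rows:

* exon, CDS - the merged annotated intervals;
* intron    - gene minus exon;
* intergenic - complement of the merged gene spans over [0, L)
  ("complement" convention, sequence ends included), or strictly the gaps
  between two adjacent genes ("between" convention).

All interval lists are 0-based half-open, sorted and merged. A locus is
assigned every compartment it overlaps by at least one base, so a single
tract spanning an exon/intron boundary carries both labels and compartment
percentages need not sum to 100.
"""

from __future__ import annotations

import gzip
import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .ssr_scanner import SSRLocus

logger = logging.getLogger(__name__)

Interval = tuple[int, int]
IntervalList = list[Interval]

COMPARTMENTS = ("CDS", "exon", "intron", "intergenic")
INTERGENIC_CONVENTIONS = ("complement", "between")


class GFFParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# interval arithmetic (sorted, half-open)


def merge(intervals: Iterable[Interval]) -> IntervalList:
    """Sort and merge overlapping or touching intervals; drop empty ones."""
    out: IntervalList = []
    for s, e in sorted(i for i in intervals if i[1] > i[0]):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def subtract(a: Sequence[Interval], b: Sequence[Interval]) -> IntervalList:
    """Set difference a \\ b for sorted, merged interval lists."""
    out: IntervalList = []
    bi = 0
    for s, e in a:
        cur = s
        while bi < len(b) and b[bi][1] <= cur:
            bi += 1
        j = bi
        while j < len(b) and b[j][0] < e:
            bs, be = b[j]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if be >= e:
                break
            j += 1
        if cur < e:
            out.append((cur, e))
    return out


def intersect(a: Sequence[Interval], b: Sequence[Interval]) -> IntervalList:
    """Set intersection of sorted, merged interval lists."""
    out: IntervalList = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return out


def complement_intervals(a: Sequence[Interval], length: int) -> IntervalList:
    """[0, length) minus a."""
    return subtract([(0, length)], list(a))


def total_bp(intervals: Iterable[Interval]) -> int:
    return sum(e - s for s, e in intervals)


def overlaps(intervals: Sequence[Interval], start: int, end: int) -> bool:
    """Does [start, end) overlap any interval by >= 1 bp? (binary search)"""
    if not intervals or end <= start:
        return False
    i = bisect_right([s for s, _ in intervals], start)
    if i and intervals[i - 1][1] > start:
        return True
    return i < len(intervals) and intervals[i][0] < end


# ---------------------------------------------------------------------------
# GFF3


def parse_gff(path: str | Path) -> dict[tuple[str, str], IntervalList]:
    """Extract merged gene/exon/CDS intervals from a GFF3 file.

    Returns ``{(sequence_id, feature_type): merged intervals}`` with
    feature types normalized to "gene"/"exon"/"CDS" (matched
    case-insensitively) and coordinates converted from 1-based inclusive
    to 0-based half-open. Other feature types are ignored. Rows with
    end < start are rejected with a logged warning; structurally
    unparseable lines raise with the line number.
    """
    wanted = {"gene": "gene", "exon": "exon", "cds": "CDS"}
    raw: dict[tuple[str, str], IntervalList] = {}
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt", encoding="ascii") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise GFFParseError(
                    f"{path}: line {lineno}: expected >= 8 tab-separated fields, got {len(fields)}"
                )
            ftype = wanted.get(fields[2].lower())
            if ftype is None:
                continue
            try:
                start1, end1 = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise GFFParseError(
                    f"{path}: line {lineno}: non-integer coordinates {fields[3]!r}, {fields[4]!r}"
                ) from exc
            if end1 < start1:
                logger.warning(
                    "%s: line %d: end < start (%d < %d); row rejected",
                    path, lineno, end1, start1,
                )
                continue
            raw.setdefault((fields[0], ftype), []).append((start1 - 1, end1))
    return {key: merge(ivs) for key, ivs in raw.items()}


# ---------------------------------------------------------------------------
# compartments


@dataclass
class CompartmentMap:
    """Per-sequence sorted/merged interval lists for each compartment."""

    seq_lengths: dict[str, int]
    gene: dict[str, IntervalList] = field(default_factory=dict)
    exon: dict[str, IntervalList] = field(default_factory=dict)
    cds: dict[str, IntervalList] = field(default_factory=dict)
    intron: dict[str, IntervalList] = field(default_factory=dict)
    intergenic: dict[str, IntervalList] = field(default_factory=dict)

    def compartment(self, name: str) -> dict[str, IntervalList]:
        return {
            "gene": self.gene,
            "exon": self.exon,
            "CDS": self.cds,
            "intron": self.intron,
            "intergenic": self.intergenic,
        }[name]

    def compartment_bp(self, name: str) -> int:
        return sum(total_bp(ivs) for ivs in self.compartment(name).values())


def derive_compartments(
    features: dict[tuple[str, str], IntervalList],
    seq_lengths: dict[str, int],
    intergenic_convention: str = "complement",
) -> CompartmentMap:
    """Build the compartment map from parsed features.

    ``intron = gene - exon`` per sequence; intergenic per the chosen
    convention. Features extending past the sequence end are clipped with
    a warning. Sequences without genes are wholly intergenic.
    """
    if intergenic_convention not in INTERGENIC_CONVENTIONS:
        raise ValueError(
            f"unknown intergenic convention {intergenic_convention!r}; "
            f"expected one of {INTERGENIC_CONVENTIONS}"
        )
    cmap = CompartmentMap(seq_lengths=dict(seq_lengths))

    def clipped(seq_id: str, ftype: str) -> IntervalList:
        ivs = features.get((seq_id, ftype), [])
        length = seq_lengths[seq_id]
        out: IntervalList = []
        for s, e in ivs:
            if e > length:
                logger.warning(
                    "%s: %s interval (%d, %d) exceeds sequence length %d; clipped",
                    seq_id, ftype, s, e, length,
                )
                e = length
            if s < length and s < e:
                out.append((s, e))
        return out

    for seq_id, length in seq_lengths.items():
        gene = clipped(seq_id, "gene")
        exon = clipped(seq_id, "exon")
        cds = clipped(seq_id, "CDS")
        cmap.gene[seq_id] = gene
        cmap.exon[seq_id] = exon
        cmap.cds[seq_id] = cds
        cmap.intron[seq_id] = subtract(gene, exon)
        if intergenic_convention == "complement":
            cmap.intergenic[seq_id] = complement_intervals(gene, length)
        else:
            inter = complement_intervals(gene, length)
            if gene:
                gmin, gmax = gene[0][0], gene[-1][1]
                inter = [(s, e) for s, e in inter if s >= gmin and e <= gmax]
            else:
                inter = []
            cmap.intergenic[seq_id] = inter
    return cmap


@dataclass(frozen=True)
class RegionAssignment:
    """Compartment labels of one locus; multi-label under >= 1 bp overlap."""

    locus: SSRLocus
    compartments: frozenset[str]


def assign_loci(
    loci: Iterable[SSRLocus], cmap: CompartmentMap
) -> list[RegionAssignment]:
    """Label every locus with each compartment it overlaps by >= 1 bp.

    Loci on sequences absent from the annotation default to intergenic
    (logged once per sequence).
    """
    noted: set[str] = set()
    out: list[RegionAssignment] = []
    for locus in loci:
        sid = locus.sequence_id
        if sid not in cmap.seq_lengths:
            if sid not in noted:
                logger.info("sequence %s not annotated; loci labelled intergenic", sid)
                noted.add(sid)
            out.append(RegionAssignment(locus, frozenset({"intergenic"})))
            continue
        labels = {
            name
            for name in COMPARTMENTS
            if overlaps(cmap.compartment(name).get(sid, []), locus.start, locus.end)
        }
        out.append(RegionAssignment(locus, frozenset(labels)))
    return out
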