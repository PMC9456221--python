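"""Seeded synthetic genomes with planted microsatellites and annotations.

The generator emulates the inputs of a genome-wide SSR survey without any
download: multi-contig FASTA with a controllable background base
composition (default GC 0.44, matching an AT-rich weevil genome) and
optional N runs, perfect SSR tracts planted at known coordinates with
chosen motif classes and lengths, and a minimal gene/exon/CDS GFF3 whose
intron/intergenic derivation is known exactly.

The background is made SSR-free by rejection-repair: bases are drawn
i.i.d., the scanner is run, and every tract it finds is redrawn until the
scan is clean. Planted loci are separated by at least two background
bases, and after planting the full sequence is re-scanned and junctions
repaired until the scan reproduces the planted truth exactly - so the
emitted truth coordinates are authoritative by construction.

Everything is reproducible from (spec, seed) alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .annotation_regions import CompartmentMap, derive_compartments, merge
from .genome_io import Record
from .motif_algebra import canonical_representative
from .ssr_scanner import (
    DEFAULT_THRESHOLDS,
    ScanThresholds,
    SSRLocus,
    scan_sequence,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class GenerationError(RuntimeError):
    pass


@dataclass(frozen=True)
class PlantedSSR:
    """One tract to plant: motif as written, tract length in bp, how many
    copies, and the compartment the copies must fall in (None = anywhere)."""

    motif: str
    tract_length: int
    count: int = 1
    compartment: str | None = None


@dataclass(frozen=True)
class GeneModel:
    """Layout of the synthetic annotation, lengths in bp."""

    genes_per_contig: int = 2
    exons_per_gene: int = 3
    exon_len: tuple[int, int] = (150, 400)
    intron_len: tuple[int, int] = (200, 600)
    min_intergenic: int = 300
    cds_margin: int = 30  # exon bp outside CDS at each gene end (UTR-like)


@dataclass(frozen=True)
class SyntheticSpec:
    seed: int = 0
    n_contigs: int = 4
    contig_length: int = 50_000
    background_gc: float = 0.44
    n_runs: tuple[int, int] = (0, 0)  # (count per contig, run length)
    planted: tuple[PlantedSSR, ...] = ()
    gene_model: GeneModel | None = GeneModel()
    thresholds: ScanThresholds = DEFAULT_THRESHOLDS


@dataclass
class SyntheticTruth:
    """Ground truth emitted with a generated dataset."""

    loci: list[SSRLocus]
    compartments: CompartmentMap
    locus_compartments: dict[tuple[str, int, int], str | None]
    spec: SyntheticSpec


# ---------------------------------------------------------------------------
# background


def generate_background(
    length: int,
    gc: float = 0.44,
    seed: int | np.random.Generator = 0,
    thresholds: ScanThresholds = DEFAULT_THRESHOLDS,
    max_passes: int = 50,
) -> str:
    """An SSR-free random sequence with expected GC fraction ``gc``."""
    if not 0.0 < gc < 1.0:
        raise ValueError("background_gc must be in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    arr = rng.choice(_BASES, size=length, p=probs)
    for _ in range(max_passes):
        found = scan_sequence("bg", arr.tobytes().decode("ascii"), thresholds)
        if not found:
            return arr.tobytes().decode("ascii")
        for locus in found:
            arr[locus.start : locus.end] = rng.choice(
                _BASES, size=locus.end - locus.start, p=probs
            )
    raise GenerationError(
        f"could not make a {length} bp background SSR-free in {max_passes} passes; "
        "try a shorter length or another seed"
    )


def _tract(motif: str, tract_length: int) -> str:
    reps = -(-tract_length // len(motif))
    return (motif * reps)[:tract_length]


# ---------------------------------------------------------------------------
# planting


def plant_ssrs(
    background: str,
    plants: list[tuple[str, int]],
    seed: int | np.random.Generator = 0,
    thresholds: ScanThresholds = DEFAULT_THRESHOLDS,
    sequence_id: str = "synthetic",
    allowed: list[tuple[int, int]] | None = None,
    existing: list[SSRLocus] | None = None,
    max_repair_passes: int = 50,
) -> tuple[str, list[SSRLocus]]:
    """Overwrite background stretches with perfect tracts; return truth.

    ``plants`` is a list of (motif, tract_length). Each tract replaces
    background bases at a uniformly drawn position, >= 2 bp away from any
    other tract; with ``allowed`` intervals given, a tract must fall
    entirely inside one of them. ``existing`` loci already present in the
    background are protected and expected by the verification scan. After
    placement the sequence is re-scanned and any background base adjacent
    to a mismatching tract is redrawn until the scan equals the planted
    truth exactly.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    existing = existing or []
    n = len(background)
    if sum(t for _, t in plants) >= n // 2:
        raise GenerationError("total planted bp must be under half the background")
    arr = np.frombuffer(background.encode("ascii"), dtype=np.uint8).copy()
    gc = np.count_nonzero(np.isin(arr, np.frombuffer(b"GC", dtype=np.uint8)))

    placed: list[tuple[int, int, str]] = []  # (start, end, motif)
    occupied = [(l.start, l.end) for l in existing]
    for motif, tract_length in plants:
        ok = False
        for _ in range(10_000):
            if allowed is not None:
                weights = np.array([e - s for s, e in allowed], dtype=float)
                fits = [i for i, (s, e) in enumerate(allowed) if e - s >= tract_length]
                if not fits:
                    break
                i = int(rng.choice(fits, p=weights[fits] / weights[fits].sum()))
                s0, e0 = allowed[i]
                start = int(rng.integers(s0, e0 - tract_length + 1))
            else:
                start = int(rng.integers(0, n - tract_length + 1))
            end = start + tract_length
            taken = occupied + [(ps, pe) for ps, pe, _ in placed]
            if all(end + 2 <= ps or pe + 2 <= start for ps, pe in taken):
                placed.append((start, end, motif))
                ok = True
                break
        if not ok:
            raise GenerationError(
                f"could not place a {tract_length} bp tract without overlap"
            )
    for start, end, motif in placed:
        arr[start:end] = np.frombuffer(
            _tract(motif, end - start).encode("ascii"), dtype=np.uint8
        )

    truth = sorted(
        (
            SSRLocus(
                sequence_id=sequence_id,
                start=start,
                end=end,
                period=len(motif),
                motif_observed=motif,
                motif_class=canonical_representative(motif),
                gc_count=sum(1 for b in _tract(motif, end - start) if b in "GC"),
            )
            for start, end, motif in placed
        ),
        key=lambda l: (l.start, l.end),
    )
    expected = sorted(
        [(l.start, l.end, l.period) for l in truth]
        + [(l.start, l.end, l.period) for l in existing]
    )
    planted_mask = np.zeros(n, dtype=bool)
    for start, end, _ in placed:
        planted_mask[start:end] = True
    for l in existing:
        planted_mask[l.start : l.end] = True

    probs = None
    for _ in range(max_repair_passes):
        seq = arr.tobytes().decode("ascii")
        got = [(l.start, l.end, l.period) for l in scan_sequence(sequence_id, seq, thresholds)]
        if got == expected:
            return seq, truth
        # redraw mutable (non-planted) bases in the symmetric difference
        bad = np.zeros(n, dtype=bool)
        for s, e, _ in set(got) ^ set(expected):
            bad[max(0, s - 1) : min(n, e + 1)] = True
        bad &= ~planted_mask
        if not bad.any():
            raise GenerationError("planted tracts interact irreparably; use another seed")
        if probs is None:
            acgt = np.count_nonzero(np.isin(arr[~planted_mask], _BASES))
            g = gc / acgt if acgt else 0.44
            probs = np.array([(1 - g) / 2, g / 2, g / 2, (1 - g) / 2])
        idx = np.flatnonzero(bad)
        arr[idx] = rng.choice(_BASES, size=idx.size, p=probs)
    raise GenerationError("junction repair did not converge; use another seed")


# ---------------------------------------------------------------------------
# annotation


def generate_annotation(
    contig_lengths: dict[str, int],
    gene_model: GeneModel,
    seed: int | np.random.Generator = 0,
) -> tuple[str, CompartmentMap]:
    """A minimal gene/exon/CDS GFF3 and its compartment truth.

    Genes are laid left to right with alternating exon/intron structure
    and at least ``min_intergenic`` bp between and around them. CDS spans
    the exons minus a UTR-like margin at each gene end. The returned text
    round-trips through ``parse_gff`` + ``derive_compartments``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lines = ["##gff-version 3"]
    features: dict[tuple[str, str], list[tuple[int, int]]] = {}

    def emit(seq_id: str, ftype: str, start0: int, end0: int, attrs: str) -> None:
        features.setdefault((seq_id, ftype if ftype != "CDS" else "CDS"), []).append(
            (start0, end0)
        )
        lines.append(
            f"{seq_id}\tssrmine_sim\t{ftype}\t{start0 + 1}\t{end0}\t.\t+\t.\t{attrs}"
        )

    for seq_id, length in contig_lengths.items():
        cursor = gene_model.min_intergenic
        for g in range(gene_model.genes_per_contig):
            exons: list[tuple[int, int]] = []
            pos = cursor + int(rng.integers(0, gene_model.min_intergenic))
            for e in range(gene_model.exons_per_gene):
                if e > 0:
                    pos += int(rng.integers(*gene_model.intron_len))
                elen = int(rng.integers(*gene_model.exon_len))
                exons.append((pos, pos + elen))
                pos += elen
            gene_start, gene_end = exons[0][0], exons[-1][1]
            if gene_end + gene_model.min_intergenic > length:
                break  # contig full; keep what fits
            gid = f"{seq_id}.g{g + 1}"
            emit(seq_id, "gene", gene_start, gene_end, f"ID={gid}")
            cds_lo = gene_start + gene_model.cds_margin
            cds_hi = gene_end - gene_model.cds_margin
            for k, (s, e) in enumerate(exons, start=1):
                emit(seq_id, "exon", s, e, f"ID={gid}.e{k};Parent={gid}")
                cs, ce = max(s, cds_lo), min(e, cds_hi)
                if cs < ce:
                    emit(seq_id, "CDS", cs, ce, f"ID={gid}.c{k};Parent={gid}")
            cursor = gene_end + gene_model.min_intergenic
    merged = {key: merge(ivs) for key, ivs in features.items()}
    cmap = derive_compartments(merged, contig_lengths)
    return "\n".join(lines) + "\n", cmap


# ---------------------------------------------------------------------------
# full dataset


def generate_dataset(
    spec: SyntheticSpec,
) -> tuple[list[Record], str, SyntheticTruth]:
    """Generate contigs, GFF3 text and planted truth from a spec + seed."""
    rng = np.random.default_rng(spec.seed)
    contig_ids = [f"contig{i + 1}" for i in range(spec.n_contigs)]
    lengths = {cid: spec.contig_length for cid in contig_ids}

    if spec.gene_model is not None:
        gff_text, cmap = generate_annotation(lengths, spec.gene_model, rng)
    else:
        gff_text, cmap = "##gff-version 3\n", derive_compartments({}, lengths)

    # expand plant requests and deal them round-robin across contigs
    requests: list[PlantedSSR] = []
    for p in spec.planted:
        requests.extend(replace(p, count=1) for _ in range(p.count))
    per_contig: dict[str, list[PlantedSSR]] = {cid: [] for cid in contig_ids}
    for i, req in enumerate(requests):
        per_contig[contig_ids[i % spec.n_contigs]].append(req)

    records: list[Record] = []
    loci: list[SSRLocus] = []
    locus_compartments: dict[tuple[str, int, int], str | None] = {}
    for cid in contig_ids:
        background = generate_background(
            spec.contig_length, spec.background_gc, rng, spec.thresholds
        )
        seq = background
        # group by target compartment so `allowed` windows are honoured
        by_comp: dict[str | None, list[PlantedSSR]] = {}
        for req in per_contig[cid]:
            by_comp.setdefault(req.compartment, []).append(req)
        placed_here: list[SSRLocus] = []
        for comp, reqs in by_comp.items():
            if comp is None:
                allowed = None
            else:
                allowed = cmap.compartment(comp).get(cid, [])
                if not allowed:
                    raise GenerationError(f"no {comp} interval on {cid} to plant into")
            seq, truth = plant_ssrs(
                seq,
                [(r.motif, r.tract_length) for r in reqs],
                rng,
                spec.thresholds,
                sequence_id=cid,
                allowed=allowed,
                existing=placed_here,
            )
            for l in truth:
                locus_compartments[(cid, l.start, l.end)] = comp
            placed_here.extend(truth)
        # N runs last: placed in background gaps, never touching a tract
        if spec.n_runs[0] > 0 and spec.n_runs[1] > 0:
            seq = _insert_n_runs(seq, placed_here, spec.n_runs, rng, spec.thresholds, cid)
        placed_here.sort(key=lambda l: (l.start, l.end))
        loci.extend(placed_here)
        records.append((cid, seq))

    # planting happened per compartment group; re-verify each contig whole
    for cid, seq in records:
        got = [
            (l.start, l.end, l.period)
            for l in scan_sequence(cid, seq, spec.thresholds)
        ]
        want = [(l.start, l.end, l.period) for l in loci if l.sequence_id == cid]
        if got != want:
            raise GenerationError(
                f"{cid}: planted groups interact; use another seed (got {len(got)}, want {len(want)})"
            )
    return records, gff_text, SyntheticTruth(loci, cmap, locus_compartments, spec)


def _insert_n_runs(
    seq: str,
    placed: list[SSRLocus],
    n_runs: tuple[int, int],
    rng: np.random.Generator,
    thresholds: ScanThresholds,
    cid: str,
) -> str:
    count, run_len = n_runs
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    n = arr.size
    forbidden = np.zeros(n, dtype=bool)
    for l in placed:
        forbidden[max(0, l.start - 2) : min(n, l.end + 2)] = True
    for _ in range(count):
        for _attempt in range(1000):
            start = int(rng.integers(0, n - run_len + 1))
            if not forbidden[start : start + run_len].any():
                arr[start : start + run_len] = ord("N")
                forbidden[max(0, start - 2) : min(n, start + run_len + 2)] = True
                break
        else:
            raise GenerationError("could not place an N run clear of planted tracts")
    out = arr.tobytes().decode("ascii")
    got = [(l.start, l.end, l.period) for l in scan_sequence(cid, out, thresholds)]
    want = [(l.start, l.end, l.period) for l in sorted(placed, key=lambda l: (l.start, l.end))]
    if got != want:
        raise GenerationError("N runs disturbed the planted truth; use another seed")
    return out


def write_truth_tsv(truth: SyntheticTruth, path) -> None:
    with open(path, "w", encoding="ascii") as out:
        out.write(
            "sequence_id\tstart\tend\tperiod\tmotif_observed\tmotif_class\t"
            "tract_length\tgc_count\tcompartment\n"
        )
        for l in truth.loci:
            comp = truth.locus_compartments.get((l.sequence_id, l.start, l.end))
            out.write(
                f"{l.sequence_id}\t{l.start}\t{l.end}\t{l.period}\t{l.motif_observed}\t"
                f"{l.motif_class}\t{l.tract_length}\t{l.gc_count}\t{comp or ''}\n"
            )
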