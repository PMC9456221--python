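"""Survey summary tables: per-type, per-motif and per-region SSR metrics.

Definitions (1 Mb = 10^6 bp exactly):

* relative frequency - loci per Mb of assembly;
* relative density   - SSR base pairs per Mb of assembly;
* SSR content        - percent of assembly length covered by tracts;
* GC of a locus set  - 100 * sum(GC bases) / sum(tract lengths),
  i.e. length-weighted over tracts.

All metrics are computed as exact ratios of integer counts over integer
base pairs; rounding to two decimals is presentation-only, applied by the
TSV writers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .annotation_regions import CompartmentMap, RegionAssignment, COMPARTMENTS
from .genome_io import GenomeProfile
from .ssr_scanner import SSRLocus

DENOMINATOR_MODES = ("assembly_mb", "compartment_mb")


def type_metrics(
    n_loci: int, total_bp: int, size_mb: float, n_all_loci: int, gc_bp: int | None = None
) -> dict:
    """The shared metric arithmetic behind every summary row.

    Works equally on loci aggregated by the scanner and on printed
    integer counts transcribed from a survey table.
    """
    if size_mb <= 0:
        raise ValueError("size_mb must be positive")
    return {
        "n_loci": n_loci,
        "total_bp": total_bp,
        "mean_len": total_bp / n_loci if n_loci else 0.0,
        "freq_per_mb": n_loci / size_mb,
        "density_bp_per_mb": total_bp / size_mb,
        "pct_of_loci": 100.0 * n_loci / n_all_loci if n_all_loci else 0.0,
        "gc_pct": (100.0 * gc_bp / total_bp) if (gc_bp is not None and total_bp) else None,
    }


def gc_of_loci(loci: Sequence[SSRLocus]) -> float | None:
    """Length-weighted GC percentage of a locus set; None when empty."""
    bp = sum(l.tract_length for l in loci)
    if not bp:
        return None
    return 100.0 * sum(l.gc_count for l in loci) / bp


@dataclass(frozen=True)
class AssemblySummary:
    """Whole-assembly SSR overview (one survey-table row)."""

    profile: GenomeProfile
    n_loci: int
    total_ssr_bp: int
    freq_per_mb: float
    density_bp_per_mb: float
    ssr_content_pct: float
    mean_len: float
    gc_pct: float | None

    def to_row(self) -> dict:
        return {
            "assembly_id": self.profile.assembly_id,
            "size_mb": self.profile.size_mb,
            "n_loci": self.n_loci,
            "freq_per_mb": self.freq_per_mb,
            "density_bp_per_mb": self.density_bp_per_mb,
            "ssr_content_pct": self.ssr_content_pct,
            "mean_len": self.mean_len,
            "gc_pct": self.gc_pct,
        }


def summarize_by_type(
    loci: Sequence[SSRLocus], profile: GenomeProfile, max_period: int = 6
) -> tuple[pd.DataFrame, AssemblySummary]:
    """Per-period metric table plus the whole-assembly summary.

    Periods with no loci appear as zero rows, so the table always has
    ``max_period`` rows and the conservation identities
    sum(n_loci) = assembly n_loci and sum(total_bp) = assembly SSR bp
    hold by construction.
    """
    size_mb = profile.size_mb
    n_all = len(loci)
    rows = []
    for p in range(1, max_period + 1):
        sub = [l for l in loci if l.period == p]
        rows.append(
            {
                "period": p,
                **type_metrics(
                    len(sub),
                    sum(l.tract_length for l in sub),
                    size_mb,
                    n_all,
                    sum(l.gc_count for l in sub),
                ),
            }
        )
    table = pd.DataFrame(rows)
    total_bp = int(table["total_bp"].sum())
    assembly = AssemblySummary(
        profile=profile,
        n_loci=n_all,
        total_ssr_bp=total_bp,
        freq_per_mb=n_all / size_mb,
        density_bp_per_mb=total_bp / size_mb,
        ssr_content_pct=100.0 * total_bp / profile.total_length if profile.total_length else 0.0,
        mean_len=total_bp / n_all if n_all else 0.0,
        gc_pct=gc_of_loci(loci),
    )
    return table, assembly


def summarize_by_motif(
    loci: Sequence[SSRLocus], profile: GenomeProfile
) -> pd.DataFrame:
    """Per-motif-class metric table, sorted by (period, representative).

    ``pct_of_loci`` is against all loci in the assembly;
    ``pct_of_period`` against loci of the same period. Ranking reports
    ("top motif" per period) should sort on n_loci with lexicographic
    representative tie-break, which the row order makes stable.
    """
    size_mb = profile.size_mb
    n_all = len(loci)
    per_period: dict[int, int] = {}
    groups: dict[tuple[int, str], list[SSRLocus]] = {}
    for l in loci:
        per_period[l.period] = per_period.get(l.period, 0) + 1
        groups.setdefault((l.period, l.motif_class), []).append(l)
    rows = []
    for (period, rep), sub in sorted(groups.items()):
        metrics = type_metrics(
            len(sub),
            sum(l.tract_length for l in sub),
            size_mb,
            n_all,
            sum(l.gc_count for l in sub),
        )
        rows.append(
            {
                "motif_class": rep,
                "period": period,
                **metrics,
                "pct_of_period": 100.0 * len(sub) / per_period[period],
            }
        )
    columns = [
        "motif_class", "period", "n_loci", "total_bp", "mean_len",
        "freq_per_mb", "density_bp_per_mb", "pct_of_loci", "gc_pct",
        "pct_of_period",
    ]
    return pd.DataFrame(rows, columns=columns)


def top_motifs(motif_table: pd.DataFrame) -> pd.DataFrame:
    """Most frequent class per period (count-ranked, lexicographic ties)."""
    if motif_table.empty:
        return motif_table
    ordered = motif_table.sort_values(
        ["period", "n_loci", "motif_class"], ascending=[True, False, True]
    )
    return ordered.groupby("period", as_index=False).head(1).reset_index(drop=True)


def summarize_by_region(
    assignments: Sequence[RegionAssignment],
    cmap: CompartmentMap,
    profile: GenomeProfile,
    denominator_mode: str = "assembly_mb",
) -> pd.DataFrame:
    """Per-compartment x period metric table.

    ``period = 0`` rows hold the compartment totals. Because assignment
    is multi-label, compartment percentages need not sum to 100 across
    compartments. ``denominator_mode`` selects the Mb denominator for
    frequency/density: the whole assembly (default) or the compartment's
    own span.
    """
    if denominator_mode not in DENOMINATOR_MODES:
        raise ValueError(
            f"unknown denominator mode {denominator_mode!r}; expected one of {DENOMINATOR_MODES}"
        )
    n_all = len(assignments)
    rows = []
    for comp in COMPARTMENTS:
        if denominator_mode == "assembly_mb":
            denom_mb = profile.size_mb
        else:
            denom_mb = cmap.compartment_bp(comp) / 1e6
        members = [a.locus for a in assignments if comp in a.compartments]
        periods = sorted({l.period for l in members})
        for p in [0, *periods]:
            sub = members if p == 0 else [l for l in members if l.period == p]
            if denom_mb > 0:
                metrics = type_metrics(
                    len(sub),
                    sum(l.tract_length for l in sub),
                    denom_mb,
                    n_all,
                    sum(l.gc_count for l in sub),
                )
            else:  # empty compartment under compartment_mb: counts only
                metrics = {
                    "n_loci": len(sub),
                    "total_bp": sum(l.tract_length for l in sub),
                    "mean_len": 0.0,
                    "freq_per_mb": None,
                    "density_bp_per_mb": None,
                    "pct_of_loci": 100.0 * len(sub) / n_all if n_all else 0.0,
                    "gc_pct": None,
                }
            rows.append({"compartment": comp, "period": p, **metrics})
    columns = [
        "compartment", "period", "n_loci", "total_bp", "mean_len",
        "freq_per_mb", "density_bp_per_mb", "pct_of_loci", "gc_pct",
    ]
    return pd.DataFrame(rows, columns=columns)


def check_conservation(
    type_table: pd.DataFrame, assembly: AssemblySummary
) -> None:
    """Raise if the per-type table does not add up to the assembly totals."""
    if int(type_table["n_loci"].sum()) != assembly.n_loci:
        raise AssertionError("per-type locus counts do not sum to assembly total")
    if int(type_table["total_bp"].sum()) != assembly.total_ssr_bp:
        raise AssertionError("per-type SSR bp do not sum to assembly total")


def round_for_display(table: pd.DataFrame, decimals: int = 2) -> pd.DataFrame:
    """Presentation rounding of the float metric columns."""
    out = table.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].round(decimals)
    return out
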