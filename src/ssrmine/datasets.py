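"""Packaged reference tables (transcribed published survey values)."""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    ref = resources.files("ssrmine.data").joinpath(name)
    with ref.open("r") as handle:
        return pd.read_csv(handle, sep="\t", comment="#")


def load_weevil_survey_table() -> pd.DataFrame:
    """Whole-assembly SSR overview for twelve weevil draft genomes.

    Columns: assembly_id, common_name, size_mb, n_loci, freq_per_mb,
    density_bp_per_mb, ssr_content_pct. Values transcribed from the
    published survey; the derived columns can be recomputed from
    (size_mb, n_loci) and the per-type counts.
    """
    return _load("table1_weevils.tsv")


def load_rpw_type_counts() -> pd.DataFrame:
    """Per-period locus counts and tract bp for the two red palm weevil
    assemblies (adult female, larva); transcribed integers from which the
    published mean lengths, frequencies, densities and shares derive.
    """
    return _load("table2_rpw_types.tsv")
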