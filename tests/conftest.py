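from __future__ import annotations

import numpy as np
import pytest

from ssrmine.synthetic_data import GeneModel, PlantedSSR, SyntheticSpec, generate_dataset


def random_sequence(rng: np.random.Generator, length: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=length))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20220930)


@pytest.fixture(scope="session")
def small_dataset():
    """A small annotated synthetic genome with planted loci in every
    compartment, shared across tests that only read it."""
    spec = SyntheticSpec(
        seed=42,
        n_contigs=3,
        contig_length=30_000,
        planted=(
            PlantedSSR("A", 14, 4, "intergenic"),
            PlantedSSR("AT", 18, 6, "intron"),
            PlantedSSR("AAG", 18, 4, "exon"),
            PlantedSSR("ACGT", 20, 3, None),
            PlantedSSR("AACCG", 25, 2, "CDS"),
        ),
        n_runs=(2, 60),
        gene_model=GeneModel(),
    )
    return generate_dataset(spec)


def write_fasta_text(path, text: str) -> str:
    path.write_text(text, encoding="ascii")
    return str(path)
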