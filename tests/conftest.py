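from __future__ import annotations

from typing import Dict

import pytest

from mitoload.codon_alignment import (
    HEAVY_STRAND_GENES,
    SupergeneAlignment,
    genetic_code,
)
from mitoload.synthetic_data import (
    SimulationParams,
    SimulatedDataset,
    scaled_gene_codons,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def code():
    return genetic_code(2)


def make_dataset(
    seed: int,
    n_samples: int = 10,
    codons: int = 1200,
    theta: float = 0.05,
    omega: float = 0.2,
    kappa: float = 8.0,
    n_demes: int = 1,
    split_depth: float = 5.0,
) -> SimulatedDataset:
    params = SimulationParams(
        n_samples=n_samples,
        gene_codons=scaled_gene_codons(codons),
        theta=theta,
        omega=omega,
        kappa=kappa,
        n_demes=n_demes,
        split_depth=split_depth,
        seed=seed,
    )
    return simulate_dataset(params)


def dataset_supergene(ds: SimulatedDataset) -> SupergeneAlignment:
    """Assemble the supergene directly from simulated genes (no indels, so
    the sequences are already aligned)."""
    rows: Dict[str, str] = {}
    for i, sid in enumerate(ds.sample_ids):
        rows[sid] = "".join(ds.genes[g][i] for g in HEAVY_STRAND_GENES)
    return SupergeneAlignment.from_rows(rows, species=ds.params.species)


@pytest.fixture
def small_dataset():
    return make_dataset(seed=11, n_samples=6, codons=400, theta=0.03)
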