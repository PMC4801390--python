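"""Shared fixtures: seeded random records, reads, and small cohorts."""
from __future__ import annotations

import numpy as np
import pytest

from radcap import digest, popsim
from radcap.seqio import QualityRead, SequenceRecord


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture
def random_records(rng) -> list[SequenceRecord]:
    """1,000 seeded FASTA records with assorted lengths."""
    return [
        SequenceRecord(f"rec{i}", random_seq(rng, int(rng.integers(1, 400))))
        for i in range(1000)
    ]


@pytest.fixture
def random_reads(rng) -> list[QualityRead]:
    """500 seeded FASTQ reads with random qualities."""
    reads = []
    for i in range(500):
        n = int(rng.integers(30, 160))
        reads.append(
            QualityRead(
                f"read{i}",
                random_seq(rng, n),
                [int(q) for q in rng.integers(0, 42, size=n)],
            )
        )
    return reads


@pytest.fixture(scope="session")
def small_cohort():
    """60 kb ancestor with densified SbfI sites, 2 pops x 2 individuals."""
    anc = popsim.simulate_ancestor(60_000, 0.45, seed=1)
    anc, _ = popsim.embed_motifs(anc, digest.SBFI.recognition, 12, seed=2, min_gap=800)
    model = popsim.PopulationModel(
        n_pops=2, n_per_pop=2, theta_within=0.001, d_between=0.005
    )
    return popsim.simulate_cohort(anc, model, seed=3)
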