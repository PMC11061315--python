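"""Shared fixtures: a compact synthetic universe reused across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from ragath import cleavage, io, motif, profiles, synthetic

GUIDE = "ATGCATGCATGCATGCATGC"


@pytest.fixture(scope="session")
def engine() -> cleavage.CleavageEngineParams:
    return cleavage.CleavageEngineParams(guide=GUIDE)


@pytest.fixture(scope="session")
def runoff_substrate(engine) -> cleavage.DnaSubstrate:
    rng = np.random.default_rng(101)
    seq = (
        synthetic.random_dna(rng, 60)
        + engine.tam_consensus
        + engine.guide
        + synthetic.random_dna(rng, 60)
    )
    return cleavage.DnaSubstrate(seq, 60)


@pytest.fixture(scope="session")
def defense_db() -> profiles.ProfileDB:
    return profiles.make_profile_db(4, 120, seed=11, name="defense")


@pytest.fixture(scope="session")
def housekeeping_db() -> profiles.ProfileDB:
    return profiles.make_profile_db(4, 120, seed=13, name="housekeeping")


@pytest.fixture(scope="session")
def seed_alignment() -> io.SeedAlignment:
    """12-sequence seed alignment of a 73-nt structured RNA motif."""
    rng = np.random.default_rng(7)
    consensus = synthetic.random_dna(rng, 73)
    rows = [
        synthetic.mutate_dna(np.random.default_rng(700 + i), consensus, 0.08)
        .replace("T", "U")
        for i in range(12)
    ]
    structure = "." * 5 + "((((....))))" + "." * (73 - 17)
    return io.SeedAlignment(
        [f"seq{i}" for i in range(12)], rows, structure, name="ragath18"
    )


@pytest.fixture(scope="session")
def motif_model(seed_alignment) -> motif.StructuredMotifModel:
    return motif.build_model(seed_alignment)


@pytest.fixture(scope="session")
def motif_consensus_dna(seed_alignment) -> str:
    """The DNA-alphabet consensus the seed alignment was derived from."""
    rng = np.random.default_rng(7)
    return synthetic.random_dna(rng, 73)
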