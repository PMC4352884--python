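import numpy as np
import pytest

from replicomb import (
    CombingNoise,
    GenomeSpec,
    KineticProfile,
    Molecule,
    Track,
    simulate_genome_sphase,
)


@pytest.fixture(scope="session")
def genome():
    return GenomeSpec()


@pytest.fixture(scope="session")
def small_genome():
    return GenomeSpec(names=("A",), lengths_kb=(1000.0,))


@pytest.fixture(scope="session")
def default_profile():
    return KineticProfile()


@pytest.fixture(scope="session")
def default_sim(genome, default_profile):
    """One seeded whole-genome S-phase, shared across read-only tests."""
    return simulate_genome_sphase(genome, default_profile, seed=42)


def make_molecule(length, tracks, molecule_id="m", **kw):
    return Molecule(molecule_id, length, [Track(*t) for t in tracks], **kw)


@pytest.fixture
def pulse_chase_molecule():
    """One active replicon: BrdU core with EdU flanks, unlabeled beyond."""
    return make_molecule(
        200.0,
        [(50.0, 60.0, "BrdU"), (42.0, 50.0, "EdU"), (60.0, 68.0, "EdU")],
    )
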