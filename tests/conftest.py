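import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from protmodel.seqio import (
    AlignedFamily,
    ProteinSequence,
    ProteinSequenceSet,
)
from protmodel.profile import fit_column_profile
from protmodel.synthetic import (
    SyntheticFamilySpec,
    consensus_wt,
    labeled_variants,
    make_profile,
    sample_family,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


@pytest.fixture
def toy_msa() -> AlignedFamily:
    """Small hand-written alignment: width 4, depth 4, one gappy column."""
    return AlignedFamily(
        members=ProteinSequenceSet.from_strings(
            ["ACDW", "ACDW", "AC-W", "GCDW"], ids=["m0", "m1", "m2", "m3"]
        )
    )


@pytest.fixture
def toy_profile(toy_msa):
    return fit_column_profile(toy_msa, alpha=1.0)


@pytest.fixture(scope="session")
def synth_spec() -> SyntheticFamilySpec:
    return SyntheticFamilySpec(width=12, depth=60, concentration=0.5, seed=42)


@pytest.fixture(scope="session")
def synth_profile(synth_spec):
    return make_profile(synth_spec)


@pytest.fixture(scope="session")
def synth_family(synth_spec, synth_profile):
    return sample_family(synth_profile, synth_spec.depth, seed=synth_spec.seed)


@pytest.fixture(scope="session")
def synth_wt(synth_profile) -> ProteinSequence:
    return consensus_wt(synth_profile)


@pytest.fixture(scope="session")
def synth_variants(synth_profile, synth_wt):
    return labeled_variants(synth_profile, synth_wt, m=40, noise_sd=0.0, seed=7)


PDB_LINES = [
    "ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N",
    "ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C",
    "ATOM      3  CA ACYS A   2      12.000   7.000  -4.000  0.50  0.00           C",
    "ATOM      4  CA BCYS A   2      12.100   7.100  -4.100  0.50  0.00           C",
    "ATOM      5  CA  ASP A   3      13.000   8.000  -3.000  1.00  0.00           C",
    "HETATM    6  O   HOH A   4      14.000   9.000  -2.000  1.00  0.00           O",
    "END",
]


@pytest.fixture
def pdb_text() -> str:
    """Synthetic three-residue (ALA-CYS-ASP) chain A with a duplicated
    altloc CA and one HETATM water."""
    return "\n".join(PDB_LINES)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
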