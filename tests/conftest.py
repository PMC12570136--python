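import numpy as np
import pytest

from rnpdyn.synthetic import (
    FluctuationSpec,
    GeneratorConfig,
    build_toy_complex,
    generate_fluctuating_trajectory,
)

THREE_ATOM_PDB = """\
ATOM      1  N   GLY A   1       1.000   2.000   3.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       2.000   2.000   3.000  1.00  0.00           C
ATOM      3  C   GLY A   1       3.000   2.000   3.000  1.00  0.00           C
END
"""

TWO_CHAIN_PDB = """\
ATOM      1  CA  TYR A  10       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CB  TYR A  10       1.500   0.000   0.000  1.00  0.00           C
ATOM      3  CA  ALA A  11       3.800   0.000   0.000  1.00  0.00           C
ATOM      4  P     U B   1       0.000  10.000   0.000  1.00  0.00           P
ATOM      5  N1    U B   1       1.000  10.000   0.000  1.00  0.00           N
END
"""


@pytest.fixture(scope="session")
def toy_complex():
    return build_toy_complex(12, 4, seed=7)


@pytest.fixture(scope="session")
def toy_topology(toy_complex):
    return toy_complex[0]


@pytest.fixture(scope="session")
def toy_reference(toy_complex):
    return toy_complex[1]


@pytest.fixture()
def small_trajectory(toy_complex):
    topology, reference = toy_complex
    spec = FluctuationSpec(sigmas=np.full(topology.n_atoms, 0.02))
    return generate_fluctuating_trajectory(
        reference, spec, GeneratorConfig(seed=3, n_frames=30), topology
    )
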