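import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from importlib.resources import files

from plascomp.repeats import load_descriptors
from plascomp.simulate import SimConfig, generate_query

# the three iteron 17-mer units (middle copy differs from the flanks at
# one position) and fixed spacers whose boundary bases cannot extend the
# repeat unit
ITERON_UNIT_A = "TCGTGCTATCAGGAGTA"
ITERON_UNIT_B = "TCGTGCTATCGGGAGTA"
ITERON_SPACERS = ["GATCCAT", "ACGGTC"]


@pytest.fixture(scope="session")
def descriptors():
    return load_descriptors(files("plascomp").joinpath("data/elements_synthetic.toml"))


@pytest.fixture(scope="session")
def small_plasmid():
    """A 12-gene circular plasmid with known run geometry."""
    return generate_query(SimConfig(seed=7, n_genes=12))
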