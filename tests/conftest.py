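import numpy as np
import pytest

from dupfam.io_formats import Region, RegionSet, SequenceRecord
from dupfam.simulate import FamilySimConfig, simulate_gene_family


@pytest.fixture
def family_alignment():
    """Small gene-family alignment: 2 species x 4 paralogs, no conversion."""
    return simulate_gene_family(FamilySimConfig(root_length=1000, seed=11))


@pytest.fixture
def amplicon_reference():
    rng = np.random.default_rng(42)
    bases = np.array(list("ACGT"))
    return SequenceRecord("amplicon", "".join(bases[rng.integers(0, 4, 240)]))


@pytest.fixture
def paralog_regions():
    return RegionSet(
        [
            Region("chrSim", 10_000, 20_000, "A1"),
            Region("chrSim", 30_000, 36_000, "C1"),
        ]
    )
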