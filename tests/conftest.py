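import numpy as np
import pytest

import matesim as ms
from matesim.experiment import run_reduced_comparison

#: seed of the reduced-scale comparison study used by the directional tests
STUDY_SEED = 11
STUDY_REPLICATES = 20


@pytest.fixture(scope="session")
def paper_layout() -> ms.GenomeLayout:
    """The full 38 x 120 block / 33-marker dog-genome layout."""
    return ms.default_genome_layout()


@pytest.fixture(scope="session")
def tiny_layout() -> ms.GenomeLayout:
    """A 3-chromosome toy layout (markers on the first two chromosomes)."""
    return ms.build_genome_layout(3, 8, 500_000, [2, 1, 0])


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def reduced_study():
    """Paired reduced-scale comparison of the headline mate-choice models.

    One shared run feeds every directional test: six models at default
    settings plus the two marker-panel models with the mating cap tightened
    to 5, 20 replicates, 40 mate-choice generations at N=200.
    """
    return run_reduced_comparison(base_seed=STUDY_SEED, n_replicates=STUDY_REPLICATES)
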