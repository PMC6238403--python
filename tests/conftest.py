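import numpy as np
import pytest

from ltrcensus.simulate import PlantSpec, build_element_library, plant_copies


@pytest.fixture(scope="session")
def small_library():
    """3 clades (one per superfamily) x 3 well-separated families."""
    return build_element_library(3, 3, clade_divergence=0.3, family_divergence=0.25,
                                 seed=101, species=("SpA", "SpB"))


@pytest.fixture(scope="session")
def clean_genome(small_library):
    """Zero-mutation plants: every full copy is structurally detectable."""
    library, _panel = small_library
    spec = PlantSpec(n_contigs=2, contig_length=300_000, copies_per_family=3, seed=7)
    genome, truth = plant_copies(library, spec)
    return genome, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
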