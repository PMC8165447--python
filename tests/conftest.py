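import numpy as np
import pytest

from famscan import synthgen


@pytest.fixture(scope="session")
def small_family():
    """A compact synthetic family with every planted structure: all three
    subfamilies, one tandem and one segmental duplicate pair, one 70%%
    identity decoy pair, and background genes."""
    spec = synthgen.FamilySpec(
        n_pcf=3, n_cin=2, n_cyc=1, n_background=8,
        tandem_separations_bp=(50_000,), n_segmental_pairs=1,
        low_identity_fractions=(0.70,),
    )
    return synthgen.generate_family_genome(3, spec, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
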