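import numpy as np
import pytest

from mulescan.synthetic import ElementTemplate, build_element, generate_genome


@pytest.fixture(scope="session")
def muta_core():
    """One concrete element built from the default template."""
    return build_element(ElementTemplate(), np.random.default_rng(11))


@pytest.fixture(scope="session")
def small_genome():
    """Compact planted genome: 2 scaffolds, 7 full copies, no derivatives."""
    return generate_genome(n_scaffolds=2, scaffold_len=60_000,
                           n_full_copies=7, n_derivatives=0,
                           window=2000, seed=101)


@pytest.fixture(scope="session")
def derivative_genome():
    """Planted genome with a mixed derivative census (perfect and
    imperfect TSDs, pack content)."""
    return generate_genome(n_scaffolds=4, scaffold_len=120_000,
                           n_full_copies=2, n_derivatives=12,
                           derivative_tsd_frac=0.6, pack_frac=0.4,
                           seed=202)


def random_dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))
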