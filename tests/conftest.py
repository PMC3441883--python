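import numpy as np
import pytest

from afgp_rescue.synthetic import (
    GeneSpec,
    LocusSpec,
    degrade_to_scaffold,
    generate_locus,
)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def seven_gene_truth():
    """A compact 7-gene locus used by several modules' tests."""
    spec = LocusSpec(
        [GeneSpec(n_units=u) for u in (20, 35, 50, 141, 30, 45, 25)],
        intergenic_len_range=(2000, 4000),
    )
    return generate_locus(spec, np.random.default_rng(1))


@pytest.fixture(scope="session")
def seven_gene_scaffold(seven_gene_truth):
    return degrade_to_scaffold(seven_gene_truth, flank_keep=150)
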