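import numpy as np
import pandas as pd
import pytest

from parallevo import SpecimenModel, SpecimenTable, sample_specimens


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def tiny_specimens() -> SpecimenTable:
    """Two lineages, two traits, hand-checkable means."""
    rows = [
        ("a1", "L1", "ancestor", 1.0, 1.0),
        ("a2", "L1", "ancestor", 3.0, 3.0),
        ("d1", "L1", "descendant", 2.0, 0.0),
        ("d2", "L1", "descendant", 4.0, 2.0),
        ("a3", "L2", "ancestor", 0.0, 0.0),
        ("d3", "L2", "descendant", 3.0, 4.0),
    ]
    return SpecimenTable(pd.DataFrame(
        rows, columns=["specimen_id", "lineage_id", "role", "t1", "t2"]))


@pytest.fixture
def noisy_specimens() -> SpecimenTable:
    """Five lineages, six traits, moderate within-group noise."""
    gen = np.random.default_rng(7)
    anc = gen.standard_normal((5, 6))
    model = SpecimenModel(ancestor_means=anc,
                          descendant_means=anc + gen.standard_normal((5, 6)),
                          sd=0.3, n_specimens=12)
    return sample_specimens(model, seed=11)
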