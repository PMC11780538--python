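import numpy as np
import pandas as pd
import pytest

from shearsig.datatypes import CountMatrix, SampleAnnotation
from shearsig.simulate import SimConfig, simulate


@pytest.fixture(scope="session")
def small_sim():
    """A small default-structure simulation shared by read-only tests."""
    cfg = SimConfig(
        n_genes=400,
        planted_variable=(40, 2.5),
        planted_blocks=((0, 15, 2.0), (1, 15, 2.0), (2, 15, 2.0), (3, 15, 2.0)),
        shear_response=(0.1, {"LSS": 1.0, "HSS": 2.0}),
        library_size_range=(3.6e5, 4.4e5),
        seed=7,
    )
    cm, ann, truth = simulate(cfg)
    return cfg, cm, ann, truth


@pytest.fixture
def toy_counts():
    genes = ["gA", "gB", "gC"]
    samples = ["s1", "s2"]
    return CountMatrix(genes, samples, np.array([[1, 2], [0, 5], [10, 0]]))


@pytest.fixture
def four_donor_annotation():
    rows = []
    for grp, prefix in (("control", "CTR"), ("PAH", "PAH")):
        for d in range(1, 5):
            donor = f"{prefix}{d:02d}"
            for cond in ("Static", "LSS", "HSS"):
                rows.append({"sample_id": f"{donor}_{cond}", "donor_id": donor,
                             "group": grp, "condition": cond})
    return SampleAnnotation(pd.DataFrame(rows))
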