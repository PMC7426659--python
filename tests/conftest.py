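import numpy as np
import pandas as pd
import pytest

from qmprofiler import SimConfig, generate_truth
from qmprofiler.simulate import CommunityTruth


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(n_subjects=8, n_replicates=2, n_taxa=12, seed=11)


@pytest.fixture(scope="session")
def small_truth(small_config) -> CommunityTruth:
    return generate_truth(small_config)


@pytest.fixture()
def two_taxon_truth() -> CommunityTruth:
    """Hand-built truth: two taxa with equal intact cells, k = (1, 2)."""
    taxa = pd.Index(["A", "B"], name="taxon")
    subjects = pd.Index(["s01"], name="subject")
    intact = pd.DataFrame({"s01": [5e9, 5e9]}, index=taxa)
    extra = pd.DataFrame({"s01": [0.0, 0.0]}, index=taxa)
    cfg = SimConfig(n_subjects=1, n_replicates=1, n_taxa=2, extracellular_mean=0.0,
                    extracellular_sd=0.0, seed=0)
    return CommunityTruth(
        taxa=taxa,
        copy_numbers=pd.Series([1.0, 2.0], index=taxa),
        subjects=subjects,
        intact=intact,
        extracellular=extra,
        loads=intact.sum(axis=0),
        enterotype=pd.Series(["Bacteroides"], index=subjects),
        moisture=pd.Series([25.0], index=subjects),
        extracellular_fraction=pd.Series([0.0], index=subjects),
        config=cfg,
        seed=0,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
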