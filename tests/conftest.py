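import numpy as np
import pandas as pd
import pytest

from channelscreen import synthetic_data as sim
from channelscreen.types import ExpressionMatrix, REGIONS, SampleMetadata


@pytest.fixture(scope="session")
def small_cohort():
    """300-gene tumor/control cohort with 15 planted genes (seeded)."""
    cfg = sim.ScreenSimConfig(n_genes=300, replicates_per_isolate=2, seed=11)
    return sim.simulate_expression(cfg)


@pytest.fixture()
def tiny_matrix():
    df = pd.DataFrame(
        [[10.0, 20.0, 1.0], [5.0, 4.0, 6.0], [0.0, 1.0, 2.0]],
        index=["gA", "gB", "gC"],
        columns=["s1", "s2", "s3"],
    )
    return ExpressionMatrix(df, "counts")


@pytest.fixture()
def flat_region_means():
    means = pd.DataFrame(1.0, index=["g1", "g2", "g3"], columns=list(REGIONS))
    means.loc["g1", ["LE", "IT"]] = 10.0
    return means


def make_metadata(samples, groups, isolates=None):
    table = pd.DataFrame({"group": groups}, index=pd.Index(samples, name="sample_id"))
    if isolates is not None:
        table["isolate_id"] = isolates
    return SampleMetadata(table)
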