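import logging

import numpy as np
import pandas as pd
import pytest

from fragbeta.datamodel import CommunityMatrix

logging.getLogger("fragbeta").setLevel(logging.ERROR)


@pytest.fixture
def toy_cm():
    """3 sites x 4 species with distinct totals and a shared gradient feel."""
    counts = pd.DataFrame(
        [[10, 5, 1, 0], [2, 8, 4, 1], [0, 1, 9, 6]],
        index=["s1", "s2", "s3"],
        columns=["spA", "spB", "spC", "spD"],
    )
    return CommunityMatrix(counts)


@pytest.fixture
def grouped_cm():
    """6 sites in 2 fragments, including a perfect indicator species."""
    rng = np.random.default_rng(7)
    counts = pd.DataFrame(
        rng.poisson(4, (6, 10)) + 1,
        index=[f"s{i}" for i in range(6)],
        columns=[f"sp{j}" for j in range(10)],
    )
    counts["ind_north"] = [5, 6, 7, 0, 0, 0]   # only in group N
    group = pd.Series(["N", "N", "N", "S", "S", "S"], index=counts.index)
    return CommunityMatrix(counts, group)
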