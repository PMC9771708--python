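from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ventnet import PresenceMatrix
from ventnet.simnet import DissimilarityMatrix


@pytest.fixture
def identity_matrix_2x2() -> PresenceMatrix:
    return PresenceMatrix(("s1", "s2"), ("spA", "spB"), np.eye(2, dtype=int))


@pytest.fixture
def toy_matrix() -> PresenceMatrix:
    """Four sites, two assemblage blocks with one bridging species."""
    values = np.array(
        [
            [1, 1, 1, 0, 0],
            [1, 1, 0, 0, 0],
            [0, 0, 1, 1, 1],
            [0, 0, 0, 1, 1],
        ]
    )
    return PresenceMatrix(
        ("n1", "n2", "s1", "s2"), ("a", "b", "c", "d", "e"), values
    )


@pytest.fixture
def k4_dissimilarity() -> DissimilarityMatrix:
    """Complete 4-site network with hand-chosen dissimilarities."""
    ids = ("A", "B", "C", "D")
    D = np.zeros((4, 4))
    for (u, v), d in {
        ("A", "B"): 0.9,
        ("C", "D"): 0.8,
        ("A", "C"): 0.7,
        ("B", "D"): 0.6,
        ("A", "D"): 0.5,
        ("B", "C"): 0.4,
    }.items():
        i, j = ids.index(u), ids.index(v)
        D[i, j] = D[j, i] = d
    return DissimilarityMatrix(ids, D)


@pytest.fixture
def small_metadata() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "site_id": ["s1", "s2", "s3"],
            "name": ["one", "two", "three"],
            "latitude": [10.0, 11.0, 30.0],
            "longitude": [120.0, 121.0, 140.0],
            "depth_m": [1000.0, 1200.0, 2500.0],
            "tectonic_setting": [
                "back-arc spreading center",
                "back-arc spreading center",
                "arc volcano",
            ],
            "region": ["west", "west", "east"],
        }
    )
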