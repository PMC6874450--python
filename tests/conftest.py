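import numpy as np
import pandas as pd
import pytest

from immunoflux.proteomics import ChannelSample, ProteinQuantTable


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def two_plexes():
    """Two tiny 4-channel plexes sharing three proteins; plex B scaled 3x.

    Channel c1 of each plex carries the reference; donors d1/d2 (young) sit
    in plex A, d3/d4 (old) in plex B; dX appears in both plexes so cross-plex
    concordance after normalization can be checked exactly.
    """
    proteins = ["P1", "P2", "P3"]
    a = pd.DataFrame(
        {
            "c1": [100.0, 50.0, 10.0],  # reference
            "c2": [200.0, 50.0, 20.0],
            "c3": [150.0, 25.0, 10.0],
            "c4": [100.0, 100.0, 40.0],  # dX
        },
        index=proteins,
    )
    b = a * 3.0
    b.columns = ["c1", "c2", "c3", "c4"]
    map_a = {
        "c1": ChannelSample("ref", "young", "reference"),
        "c2": ChannelSample("d1", "young", "biological"),
        "c3": ChannelSample("d2", "young", "biological"),
        "c4": ChannelSample("dX", "old", "biological"),
    }
    map_b = {
        "c1": ChannelSample("ref", "young", "reference"),
        "c2": ChannelSample("d3", "old", "biological"),
        "c3": ChannelSample("d4", "old", "biological"),
        "c4": ChannelSample("dX", "old", "technical_duplicate"),
    }
    return [
        ProteinQuantTable(plex_id="A", intensities=a, sample_map=map_a),
        ProteinQuantTable(plex_id="B", intensities=b, sample_map=map_b),
    ]
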