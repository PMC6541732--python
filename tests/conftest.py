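import numpy as np
import pandas as pd
import pytest

from cliffcensus.grid_io import GridCensus


@pytest.fixture
def small_census() -> GridCensus:
    """Three-cell census with counts 5, 0, 12 (total 17)."""
    return GridCensus(
        pd.DataFrame(
            {"cell_id": ["A1", "A2", "A3"], "visual_units": [5, 0, 12], "included": [True] * 3}
        )
    )


@pytest.fixture
def poisson_census() -> GridCensus:
    """147-cell Poisson(5) census, fixed seed."""
    rng = np.random.default_rng(11)
    counts = rng.poisson(5.0, 147)
    return GridCensus(
        pd.DataFrame(
            {"cell_id": [f"C{i:03d}" for i in range(147)], "visual_units": counts}
        )
    )


def make_census(counts, included=None) -> GridCensus:
    counts = list(counts)
    if included is None:
        included = [True] * len(counts)
    return GridCensus(
        pd.DataFrame(
            {
                "cell_id": [f"C{i:03d}" for i in range(len(counts))],
                "visual_units": counts,
                "included": included,
            }
        )
    )
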