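import numpy as np
import pandas as pd
import pytest

from mycodiv import FeatureTable, SampleMetadata, SoilTable, TaxonomyMap


@pytest.fixture
def toy_table():
    """3 features x 2 samples with counts {{5,0},{1,2},{0,7}}."""
    return FeatureTable(pd.DataFrame(
        [[5, 0], [1, 2], [0, 7]],
        index=["f1", "f2", "f3"], columns=["S1", "S2"],
    ))


@pytest.fixture
def toy_meta():
    return SampleMetadata(pd.DataFrame(
        {"group": ["A", "B"], "replicate": [1, 1]}, index=["S1", "S2"],
    ))


@pytest.fixture
def toy_taxonomy():
    return TaxonomyMap({
        "f1": ("Fungi", "Ascomycota"),
        "f2": ("Fungi", "Ascomycota", "Sordariomycetes"),
        "f3": ("Fungi", "Basidiomycota"),
    })


@pytest.fixture
def random_table():
    rng = np.random.default_rng(42)
    counts = rng.integers(0, 50, size=(30, 9))
    counts[:, counts.sum(axis=0) == 0] += 1
    return FeatureTable(pd.DataFrame(
        counts,
        index=[f"f{i}" for i in range(30)],
        columns=[f"s{i}" for i in range(9)],
    ))


@pytest.fixture
def grouped_meta():
    """9 samples in 3 groups of 3 (matches random_table)."""
    return SampleMetadata(pd.DataFrame(
        {"group": [f"G{i // 3}" for i in range(9)],
         "replicate": [i % 3 + 1 for i in range(9)]},
        index=[f"s{i}" for i in range(9)],
    ))


@pytest.fixture
def small_soil():
    """6 observations x 4 indicators, generic positive values."""
    rng = np.random.default_rng(7)
    data = pd.DataFrame(
        rng.uniform(1.0, 10.0, size=(6, 4)),
        index=[f"O{i}" for i in range(6)],
        columns=["w", "x", "y", "z"],
    )
    return SoilTable(data)
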