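import numpy as np
import pandas as pd
import pytest

from chromoglyph import from_coordinates, make_test_annotation, make_test_genome


@pytest.fixture
def simple_table() -> pd.DataFrame:
    """Three well-formed 100 kb bins on chr1 at distinct points."""
    return pd.DataFrame(
        {
            "chrom": ["chr1", "chr1", "chr1"],
            "start": [0, 100_000, 200_000],
            "end": [100_000, 200_000, 300_000],
            "x": [0.0, 1.0, 2.0],
            "y": [0.0, 0.0, 1.0],
            "z": [0.0, 0.0, 0.0],
        }
    )


@pytest.fixture
def genome() -> pd.DataFrame:
    """Seeded 30-bin two-chromosome territory structure."""
    return make_test_genome(
        [("chr1", 2_000_000), ("chr2", 1_000_000)], resolution=100_000, seed=7
    )


@pytest.fixture
def annotation() -> pd.DataFrame:
    return make_test_annotation(
        [("chr1", 2_000_000), ("chr2", 1_000_000)], n_features=200, seed=7
    )


def random_structure(seed: int, max_bins: int = 2000) -> pd.DataFrame:
    """Random multi-chromosome bin table (uniform coordinate cloud)."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(100, max_bins + 1))
    n_chrom = int(rng.integers(1, 4))
    splits = np.sort(rng.choice(np.arange(1, n), size=n_chrom - 1, replace=False))
    parts = np.split(np.arange(n), splits)
    tables = [
        from_coordinates(
            rng.normal(scale=5.0, size=(len(part), 3)),
            chrom=f"chr{i + 1}",
            resolution=int(rng.choice([50_000, 100_000])),
        )
        for i, part in enumerate(parts)
    ]
    return pd.concat(tables, ignore_index=True)


def random_intervals(seed: int, n: int = 50, genome_span: int = 10**8) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    chroms = [f"chr{int(c)}" for c in rng.integers(1, 5, size=n)]
    starts = rng.integers(0, genome_span, size=n)
    lengths = rng.integers(1, 500_000, size=n)
    return pd.DataFrame(
        {"chrom": chroms, "start": starts, "end": starts + lengths}
    )
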