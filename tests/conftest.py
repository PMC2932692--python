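import numpy as np
import pandas as pd
import pytest

from tilechip.models import GeneModel, GenomeLayout
from tilechip.synth import SimulationConfig


def make_track(chroms, starts, values, probe_length=50):
    starts = np.asarray(starts, dtype=np.int64)
    return pd.DataFrame(
        {
            "chrom": chroms,
            "start": starts,
            "end": starts + probe_length,
            "probe_id": [f"p{i}" for i in range(len(starts))],
            "value": np.asarray(values, dtype=float),
        }
    )


@pytest.fixture
def two_chrom_layout():
    return GenomeLayout(lengths={"chr1": 100_000, "X": 100_000}, focal="X")


@pytest.fixture
def small_config():
    """Desk-scale simulation: 2 autosome-like chromosomes + X, 60 genes."""
    return SimulationConfig(
        seed=11,
        chrom_lengths={"chrA": 400_000, "chrB": 400_000, "chrX": 400_000},
        x_like="chrX",
        n_genes=60,
    )


@pytest.fixture
def random_track():
    rng = np.random.default_rng(42)
    n = 400
    starts = np.sort(rng.choice(np.arange(0, 20_000, 10), size=n, replace=False))
    return make_track(["chr1"] * n, starts, rng.normal(0, 1, n), probe_length=8)
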