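import numpy as np
import pandas as pd
import pytest

from tilescan import SimulationConfig, TilingArray, generate_experiment


@pytest.fixture(scope="session")
def small_experiment():
    """A small spiked experiment shared across detection/motif tests."""
    cfg = SimulationConfig(
        n_promoters=400, fraction_spiked=0.05, fraction_direct=0.5, seed=7
    )
    return cfg, *generate_experiment(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_array(m, a=None, gc=None, spacing=100, array_id="toy", promoter_id="P0"):
    """Build a single-promoter TilingArray from an M (and optional A) vector."""
    m = np.asarray(m, dtype=float)
    n = len(m)
    a = np.full(n, 10.0) if a is None else np.asarray(a, dtype=float)
    gc = np.full(n, 0.5) if gc is None else np.asarray(gc, dtype=float)
    starts = np.arange(n) * spacing
    df = pd.DataFrame(
        {
            "probe_id": [f"{promoter_id}_{i:03d}" for i in range(n)],
            "chrom": "chr1",
            "start": starts,
            "end": starts + 50,
            "gc": gc,
            "cy5_log": a + m / 2,
            "cy3_log": a - m / 2,
            "promoter_id": promoter_id,
        }
    )
    return TilingArray(array_id, df)
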