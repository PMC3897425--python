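import numpy as np
import pandas as pd
import pytest

from pscc.simulator import SimConfig, generate_panel


@pytest.fixture(scope="session")
def small_experiment():
    """A shared 3000-window, 20-control synthetic experiment at 2x."""
    cfg = SimConfig(n_windows=3000, n_chroms=3, n_controls=20, seed=42)
    rng = np.random.default_rng(42)
    windows, gc, bias, controls = generate_panel(cfg, rng)
    return cfg, windows, gc, bias, controls


def make_windows(n: int, width: int = 1000, chrom: str = "chr1") -> pd.DataFrame:
    """Uniform toy window table for constructed-data tests."""
    starts = np.arange(n) * width
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": starts + width,
            "n_sim": 0,
            "partial": False,
        }
    )
    return df
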