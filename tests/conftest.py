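import numpy as np
import pandas as pd
import pytest

from clonoscape.synthetic import SimConfig


@pytest.fixture
def small_config() -> SimConfig:
    """Fast config with every noise source enabled."""
    return SimConfig(
        seed=11,
        n_real_cells=300,
        n_noise_barcodes=1200,
        n_samples=3,
        n_clonotypes=150,
        umi_error_rate=0.03,
        multiplet_rate=0.05,
        tag_noise_rate=0.02,
    )


@pytest.fixture
def clean_config() -> SimConfig:
    """Zero-noise config: every stage should recover ground truth exactly."""
    return SimConfig(
        seed=5,
        n_real_cells=300,
        n_noise_barcodes=1200,
        n_samples=3,
        n_clonotypes=150,
        umi_error_rate=0.0,
        multiplet_rate=0.0,
        tag_noise_rate=0.0,
    )


def make_molecules(rows) -> pd.DataFrame:
    """Molecule table from (cell_label, umi, feature, reads) tuples."""
    return pd.DataFrame(rows, columns=["cell_label", "umi", "feature", "reads"])


@pytest.fixture
def molecules_factory():
    return make_molecules
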