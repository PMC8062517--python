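import numpy as np
import pytest

from connectisim import (
    CommunityGeneratorConfig,
    OTUAbundanceTable,
    generate_master_distribution,
)


@pytest.fixture
def tiny_table() -> OTUAbundanceTable:
    """Hand-built 4-OTU x 2-replicate table with known counts."""
    return OTUAbundanceTable(
        otu_ids=["a", "b", "c", "d"],
        counts=np.array([[50, 10], [50, 30], [0, 60], [0, 0]]),
        replicate_ids=["R1", "R2"],
    )


@pytest.fixture(scope="session")
def default_table() -> OTUAbundanceTable:
    """One default-calibration community table shared across tests."""
    return generate_master_distribution(CommunityGeneratorConfig(), seed=11)


@pytest.fixture(scope="session")
def small_sim():
    """A small bead simulation (biased_positive, 20k cells) shared across
    readout tests."""
    from connectisim.pipeline import RunConfig, run_single_repeat

    cfg = RunConfig(master_seed=5, n_repeats=1, n_cells=20_000)
    return run_single_repeat(cfg, "biased_positive", 0)
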