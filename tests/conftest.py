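import numpy as np
import pytest

import cytocba as c


@pytest.fixture(scope="session")
def config():
    return c.PipelineConfig.default()


@pytest.fixture(scope="session")
def positive_result(config):
    """A saturating-titre assay run through the full pipeline."""
    run = c.simulate_assay(
        c.SimulationParams(seed=1, antibody_titer=10.0), "titin", "pos_serum")
    return c.run_assay(run, config)


@pytest.fixture(scope="session")
def negative_result(config):
    """A titre-zero assay run through the full pipeline."""
    run = c.simulate_assay(
        c.SimulationParams(seed=1, antibody_titer=0.0), "titin", "neg_serum")
    return c.run_assay(run, config)


@pytest.fixture
def small_table():
    """A tiny hand-written event table (3 events)."""
    return c.EventTable(
        sample_id="tiny", cell_line="parental", antigen="titin",
        serum_id="s1", dilution=500,
        intensities=np.array([
            [50_000.0, 20_000.0, 40.0, 120.0, 55.0],
            [60_000.0, 25_000.0, 55.0, 300.0, 70.0],
            [45_000.0, 18_000.0, 35.0, 90.0, 40.0],
        ]),
    )
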