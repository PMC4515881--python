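import numpy as np
import pandas as pd
import pytest

from spikequant import OtuTable, SampleMetadata


@pytest.fixture
def small_table():
    """2 OTUs x 2 samples raw table."""
    counts = pd.DataFrame(
        [[5, 0], [3, 7]], index=["OTU1", "OTU2"], columns=["s1", "s2"]
    )
    return OtuTable(counts=counts, state="raw")


@pytest.fixture
def random_raw_table():
    """20-OTU x 6-sample raw table with taxonomy, fixed seed."""
    rng = np.random.default_rng(1234)
    counts = pd.DataFrame(
        rng.integers(0, 500, size=(20, 6)),
        index=[f"OTU{i}" for i in range(20)],
        columns=[f"s{j}" for j in range(6)],
    )
    genera = ["Leuconostoc", "Bacillus", "Paenibacillus", "Pseudomonas"]
    taxonomy = {
        f"OTU{i}": f"Bacteria;Firmicutes;Bacilli;Order;Family;{genera[i % 4]}"
        for i in range(20)
    }
    return OtuTable(counts=counts, taxonomy=taxonomy, state="raw")


@pytest.fixture
def spike_metadata():
    """Metadata for a one-OTU dilution series: 4 spiked samples + 1 control."""
    levels = {"d1": 8.5, "d2": 85.0, "d3": 850.0, "d4": 8500.0, "c1": 0.0}
    return {
        sid: SampleMetadata(
            sample_id=sid,
            group="control" if lvl == 0 else "spiked",
            spike_spores_per_sample=lvl,
        )
        for sid, lvl in levels.items()
    }
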