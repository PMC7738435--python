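import numpy as np
import pytest
from hypothesis import settings

from egmb import OtuTable, ReactorConfig, SampleMetadata, to_relative_abundance

settings.register_profile("suite", derandomize=True, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def expI_cfg() -> ReactorConfig:
    """Experiment-I operating point: 150 mL, 3 mL exchanged every 2 d."""
    return ReactorConfig(
        vc_ml=150.0, exchange_volume_ml=3.0, exchange_interval_d=2.0,
        cf_g_per_l=6.2, cc_g_per_l=10.0,
    )


@pytest.fixture
def small_table() -> OtuTable:
    """3 OTUs x 2 samples with mixed lineages."""
    return OtuTable(
        otu_ids=("OTU1", "OTU2", "OTU3"),
        taxonomy=(
            "Bacteria;Bacteroidetes;Bacteroidia;Bacteroidales;Tannerellaceae;Parabacteroides",
            "Archaea;Euryarchaeota;Methanomicrobia;Methanosarcinales;Methanosaetaceae;Methanosaeta",
            "",
        ),
        counts=np.array([[10, 5], [30, 15], [60, 80]]),
        sample_ids=("s1", "s2"),
    )


@pytest.fixture
def small_rel(small_table):
    return to_relative_abundance(small_table)


@pytest.fixture
def small_metadata() -> list[SampleMetadata]:
    return [
        SampleMetadata("s1", "reactor", 40.0, "grpA", "control"),
        SampleMetadata("s2", "reactor", 40.0, "grpA", "control"),
    ]
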