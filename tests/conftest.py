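import logging

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

logging.getLogger("seedmrm").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def bundled_panel():
    from seedmrm import panel

    return panel.load_panel()


@pytest.fixture(scope="session")
def pep2prot(bundled_panel):
    _, peptides = bundled_panel
    return {p.sequence: p.protein.short_name for p in peptides}


@pytest.fixture()
def small_config():
    """A reduced two-protein design for fast end-to-end tests."""
    from seedmrm import simdata

    return simdata.SimConfig(
        genotypes=("WT", "ftsh4-1"),
        timepoints=("0", "24"),
        n_replicates=3,
        n_fractions=4,
        anchors={
            "P1": {"WT": {"0": 0.5, "24": 1.0}, "ftsh4": {"0": 0.5, "24": 0.4}},
            "P2": {"WT": {"0": 0.2, "24": 0.8}, "ftsh4": {"0": 0.2, "24": 0.8}},
        },
        mw_kda={"P1": 50.0, "P2": 30.0},
        peptides={
            "P1": ["AVDSLVPIGR", "TTIAIDTILNQK", "LLEFYER"],
            "P2": ["SFEQIEVER", "AIYTVGNWIR"],
        },
    )
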