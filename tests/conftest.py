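"""Shared fixtures: one synthetic study generated once per session."""

import pytest

from pennid.pipeline import run_study
from pennid.simdata import (PanelConfig, ReadSimConfig, make_reference_panel,
                            paper_scenarios)

MASTER_SEED = 7
STUDY_COVERAGE = 1000.0
STUDY_ERROR_RATE = 0.001


@pytest.fixture(scope="session")
def panel_cfg():
    return PanelConfig(seed=MASTER_SEED)


@pytest.fixture(scope="session")
def panel(panel_cfg):
    return make_reference_panel(panel_cfg)


@pytest.fixture(scope="session")
def scenarios():
    return paper_scenarios()


@pytest.fixture(scope="session")
def read_cfg():
    return ReadSimConfig(coverage=STUDY_COVERAGE, error_rate=STUDY_ERROR_RATE,
                         seed=MASTER_SEED)


@pytest.fixture(scope="session")
def study(panel_cfg, read_cfg):
    """End-to-end run of the 13 study scenarios at the study conditions."""
    calls, frame, scenarios_, panel_ = run_study(panel_cfg, read_cfg)
    return {"calls": calls, "frame": frame, "scenarios": scenarios_,
            "panel": panel_}
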