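"""Shared fixtures: expensive batch-culture runs are computed once per
session and reused by the simulator, analysis, proximal and acceptance
tests (every run is deterministic, so sharing is safe)."""
import pytest

import protistph as pp

FIG3_TYPES = ("phytoplankton", "zooplankton", "GNCM", "pSNCM", "CM")


@pytest.fixture(scope="session")
def constants15():
    return pp.equilibrium_constants(15.0, 35.0)


@pytest.fixture(scope="session")
def fig3_runs():
    """The five functional types under default conditions."""
    return {
        ft: pp.run_scenario(pp.Scenario(config=pp.make_config(ft), name=ft))
        for ft in FIG3_TYPES
    }


@pytest.fixture(scope="session")
def fig5_runs():
    """The five CM-variant scenarios."""
    return {s.name: pp.run_scenario(s) for s in pp.scenario_presets("fig5")}


@pytest.fixture(scope="session")
def cm_run(fig3_runs):
    return fig3_runs["CM"]
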