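import pytest

from phthalscreen.synth import SimulationConfig, default_panel, make_study_fixture


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    return SimulationConfig(panel=default_panel())


@pytest.fixture(scope="session")
def study(tmp_path_factory, sim_config):
    """The default synthetic study fixture, generated once per session."""
    outdir = tmp_path_factory.mktemp("study")
    manifest = make_study_fixture(sim_config, outdir)
    return manifest


def panel_subsets(config):
    natives = [a for a in config.panel if not a.is_decoy and not a.labelled]
    decoys = [a for a in config.panel if a.is_decoy]
    labelled = [a for a in config.panel if a.labelled]
    return natives, decoys, labelled


def candidate_matches(analyte, candidates, status, rt_tol=0.3):
    """True if a candidate of the given status sits on this analyte."""
    return any(
        abs(c.mz - analyte.anion_mz) <= 5e-6 * analyte.anion_mz
        and abs(c.rt_min - analyte.rt_min) <= rt_tol
        and c.status == status
        for c in candidates
    )
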