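import pytest

from numtscreen.screen import screen_dataset
from numtscreen.simulate import SimConfig, asl_scenario_config, simulate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic study: three groups plus NUMTs of every
    lesion class, with truth labels."""
    return simulate_dataset(SimConfig(seed=11))


@pytest.fixture(scope="session")
def asl_dataset():
    """Two-group scenario with a 5'-hot rate profile straddling the
    3.5% species boundary."""
    return simulate_dataset(asl_scenario_config(seed=11))


@pytest.fixture(scope="session")
def default_screen(default_dataset):
    """Screen report + per-haplotype flags for the default fixture."""
    ds = default_dataset
    return screen_dataset(ds.records, ds.group_ancestors, ds.panel, ds.decoys)


@pytest.fixture(scope="session")
def truth_classes(default_dataset):
    return {r.id: r.cls for r in default_dataset.truth.rows}
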