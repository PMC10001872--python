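import numpy as np
import pytest

import dietrisk as dr


@pytest.fixture(scope="session")
def tox():
    """Bundled toxicological reference table (FAO/WHO MACs, USEPA RfD/SF)."""
    return dr.load_tox_table()


@pytest.fixture(scope="session")
def nepal_spec():
    """Bundled survey summary targets (7 provinces + pooled national)."""
    return dr.read_summary_targets()


@pytest.fixture(scope="session")
def groups():
    """Bundled population groups (assumption-based Nepal defaults)."""
    return dr.read_groups()


@pytest.fixture(scope="session")
def national_group(groups):
    return next(g for g in groups if g.name == "national")


@pytest.fixture
def point_group():
    """Fully degenerate group: IR 0.1 kg/day, BW 50 kg, ef·ed/at = 1."""
    return dr.PopulationGroup(name="pt", ir=0.1, bw=50.0, ef=365, ed=30)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
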