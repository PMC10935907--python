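import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from clonekinetics import CellRecord, ColonyDataset, LineageTree


def make_cell(colony, cell_id, parent, birth, division, last):
    return CellRecord(
        colony_id=colony,
        cell_id=cell_id,
        parent_id=parent,
        birth_time=birth,
        division_time=division,
        last_observed_time=last,
    )


@pytest.fixture
def expanding_tree():
    """Three divisions, last at 80 h of a 100-h window; leaves P/D/U."""
    colony = "exp1"
    cells = (
        make_cell(colony, "f", None, 0.0, 20.0, 20.0),
        make_cell(colony, "c2", "f", 20.0, 40.0, 40.0),
        make_cell(colony, "c3", "f", 20.0, None, 100.0),  # D (80 h)
        make_cell(colony, "c4", "c2", 40.0, 80.0, 80.0),
        make_cell(colony, "c5", "c2", 40.0, None, 100.0),  # D (60 h)
        make_cell(colony, "c6", "c4", 80.0, None, 100.0),  # U (20 h)
        make_cell(colony, "c7", "c4", 80.0, None, 100.0),  # U
    )
    return LineageTree(colony_id=colony, cells=cells, observation_end=100.0)


@pytest.fixture
def differentiating_tree():
    """A single terminal division at 24 h; both daughters differentiate."""
    colony = "dif1"
    cells = (
        make_cell(colony, "f", None, 0.0, 24.0, 24.0),
        make_cell(colony, "d1", "f", 24.0, None, 100.0),
        make_cell(colony, "d2", "f", 24.0, None, 100.0),
    )
    return LineageTree(colony_id=colony, cells=cells, observation_end=100.0)


@pytest.fixture
def unclassified_tree():
    """A founder lost before dividing: nothing to classify."""
    colony = "un1"
    cells = (make_cell(colony, "f", None, 0.0, None, 30.0),)
    return LineageTree(colony_id=colony, cells=cells, observation_end=100.0)


@pytest.fixture
def demo_dataset(expanding_tree, differentiating_tree, unclassified_tree):
    return ColonyDataset(
        trees=(expanding_tree, differentiating_tree, unclassified_tree),
        donor_id="demo",
        frame_interval=1.0 / 3.0,
    )
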