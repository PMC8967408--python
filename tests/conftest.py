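import numpy as np
import pytest

from histogrowth.lineage import (FATE_CENSORED, FATE_DIVIDED, FATE_EXTRUDED,
                                 CellTrackRecord, LineageForest)
from histogrowth.sim import default_config, simulate


def make_cell(cid, parent, t0, t1, fate, is_sop=False, **kw):
    return CellTrackRecord(cell_id=cid, parent_id=parent, birth_time=t0,
                           end_time=t1, end_fate=fate, is_sop=is_sop, **kw)


@pytest.fixture(scope="session")
def base_result():
    """One base-case simulation shared by read-only tests."""
    return simulate(default_config(seed=1))


@pytest.fixture(scope="session")
def base_forest(base_result):
    return base_result.forest


@pytest.fixture
def tiny_forest():
    """One founder dividing into two censored daughters."""
    return LineageForest(records=[
        make_cell("a", None, 0.0, 2.7, FATE_DIVIDED),
        make_cell("b", "a", 2.7, 10.0, FATE_CENSORED),
        make_cell("c", "a", 2.7, 10.0, FATE_CENSORED),
    ], movie_end=10.0)
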