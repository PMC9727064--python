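import numpy as np
import pytest

from chipdili.dili_classify import truth_label
from chipdili.mos_scoring import load_mos_table
from chipdili.panel_io import load_panel, table1_panel_path


@pytest.fixture(scope="session")
def benchmark_panel():
    """The bundled 27-drug panel."""
    return load_panel(table1_panel_path())


@pytest.fixture(scope="session")
def benchmark_labels(benchmark_panel):
    return {r.name: truth_label(r.garside_rank) for r in benchmark_panel}


@pytest.fixture(scope="session")
def benchmark_ranks(benchmark_panel):
    return {r.name: r.garside_rank for r in benchmark_panel}


@pytest.fixture(scope="session")
def published_mos():
    """The bundled published MOS table, keyed drug -> scope."""
    return load_mos_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
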