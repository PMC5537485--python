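import numpy as np
import pandas as pd
import pytest

import priorscan as ps


@pytest.fixture(scope="session")
def small_config():
    """Compact study conditions for fast unit tests: 2,000 variants."""
    return ps.SimulationConfig(m=2000, n_ref=400, seed=11,
                               n_causal_t=20)


@pytest.fixture(scope="session")
def small_panel(small_config):
    return ps.simulate_panel(small_config)


@pytest.fixture(scope="session")
def small_compendium(small_config, small_panel):
    return ps.simulate_compendium(small_panel, small_config)


@pytest.fixture(scope="session")
def toy_panel():
    """Three-variant panel with hand-listed dosages on one chromosome."""
    variants = pd.DataFrame({
        "snp": ["v1", "v2", "v3"],
        "chr": [1, 1, 1],
        "pos": [100, 200, 300],
        "a1": ["A", "C", "A"],
        "a2": ["G", "T", "C"],
    })
    dosages = np.array([
        [0, 1, 2],
        [1, 1, 1],
        [2, 0, 0],
        [1, 2, 1],
        [0, 0, 1],
        [2, 2, 2],
    ], dtype=float)
    return ps.LDPanel(variants, dosages)


def make_table(records, **kw):
    """SumStatTable from a list of dicts with sensible defaults."""
    rows = []
    for i, rec in enumerate(records):
        row = {"snp": f"s{i}", "chr": 1, "pos": 100 * (i + 1),
               "a1": "A", "a2": "G", "n": 10_000, "z": 1.0}
        row.update(rec)
        rows.append(row)
    return ps.SumStatTable(pd.DataFrame(rows), **kw)
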