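import numpy as np
import pandas as pd
import pytest

from blastpte.tables import AbundanceTable


@pytest.fixture
def two_group_design():
    """Two groups x two animals x two technical runs."""
    rows = {}
    for g in ("ctrl", "exp"):
        for b in (1, 2):
            for t in (1, 2):
                rows[f"{g}_b{b}_t{t}"] = {
                    "group": g,
                    "biological_replicate": b,
                    "technical_replicate": t,
                }
    return pd.DataFrame(rows).T


@pytest.fixture
def small_table(two_group_design):
    runs = list(two_group_design.index)
    rng = np.random.default_rng(42)
    ints = pd.DataFrame(
        rng.lognormal(mean=10, sigma=0.3, size=(6, len(runs))),
        index=[f"P{i}" for i in range(6)],
        columns=runs,
    )
    return AbundanceTable(ints, two_group_design)
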