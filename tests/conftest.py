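import numpy as np
import pandas as pd
import pytest

import cephpls as c


@pytest.fixture(scope="session")
def single_mv_model():
    """Two LVs, one reflective MV each: the degenerate model whose path
    coefficient must equal the raw Pearson correlation."""
    blocks = (c.BlockSpec("A", ("x",)), c.BlockSpec("B", ("y",)))
    inner = c.InnerSpec(("A", "B"), (("A", "B"),))
    return blocks, inner


@pytest.fixture(scope="session")
def correlated_pair():
    rng = np.random.default_rng(20170605)
    x = rng.standard_normal(500)
    y = 0.6 * x + 0.8 * rng.standard_normal(500)
    return pd.DataFrame({"x": x, "y": y})


@pytest.fixture(scope="session")
def printed_tables():
    return c.load_printed_tables()


@pytest.fixture(scope="session")
def table4(printed_tables):
    t4 = printed_tables["table4"]
    return pd.DataFrame(
        np.asarray(t4["matrix"], dtype=float),
        index=t4["order"],
        columns=t4["order"],
    )


@pytest.fixture(scope="session")
def reflective_three_lv_spec():
    """Well-separated reflective three-LV structure (loadings >= 0.9)."""
    return c.LatentSimSpec(
        blocks=(
            c.SimBlock("A", ("a1", "a2", "a3"), loadings=(0.95, 0.9, 0.92)),
            c.SimBlock("B", ("b1", "b2", "b3"), loadings=(0.9, 0.93, 0.91)),
            c.SimBlock("C", ("c1", "c2", "c3"), loadings=(0.94, 0.9, 0.9)),
        ),
        inner=c.InnerSpec(("A", "B", "C"), (("A", "C"), ("B", "C"))),
        paths={("A", "C"): 0.6, ("B", "C"): 0.5},
        n=1500,
    )
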