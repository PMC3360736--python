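import numpy as np
import pandas as pd
import pytest

import drynet
from drynet.deg_screen import ExpressionSet


@pytest.fixture
def rng():
    return np.random.default_rng(20120525)


@pytest.fixture
def small_config():
    """A small planted compendium: 2 modules of 50 among 300 genes."""
    return drynet.SimulationConfig(n_genes=300, module_sizes=(50, 50), seed=11)


def make_expression_set(ctrl_rows, stress_rows, genes=None, set_id="set1"):
    """ExpressionSet from explicit per-gene replicate values."""
    ctrl = np.atleast_2d(np.asarray(ctrl_rows, dtype=float))
    strs = np.atleast_2d(np.asarray(stress_rows, dtype=float))
    genes = genes or [f"g{i}" for i in range(ctrl.shape[0])]
    cols = [f"{set_id}.c{i+1}" for i in range(ctrl.shape[1])] + [
        f"{set_id}.s{i+1}" for i in range(strs.shape[1])
    ]
    design = pd.DataFrame(
        {
            "set": set_id,
            "condition": ["control"] * ctrl.shape[1] + ["stress"] * strs.shape[1],
            "replicate": list(range(1, ctrl.shape[1] + 1))
            + list(range(1, strs.shape[1] + 1)),
        },
        index=pd.Index(cols, name="sample"),
    )
    matrix = pd.DataFrame(
        np.hstack([ctrl, strs]), index=pd.Index(genes, name="gene"), columns=cols
    )
    return ExpressionSet(matrix=matrix, design=design, set_id=set_id)
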