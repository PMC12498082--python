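import dendropy
import numpy as np
import pandas as pd
import pytest

from elevtrait.simulate import (SimulationConfig, simulate_dataset,
                                simulate_yule_tree)


@pytest.fixture(scope="session")
def sister_tree():
    """((A:0.4,B:0.4):0.6,C:1.0); — sisters share 0.6 of unit depth."""
    return dendropy.Tree.get(data="((A:0.4,B:0.4):0.6,C:1.0);",
                             schema="newick")


@pytest.fixture(scope="session")
def star_tree_40():
    nwk = "(" + ",".join(f"sp{i}:1.0" for i in range(40)) + ");"
    return dendropy.Tree.get(data=nwk, schema="newick")


@pytest.fixture(scope="session")
def yule_tree_60():
    return simulate_yule_tree(60, 1.0, seed=11)


@pytest.fixture(scope="session")
def small_dataset():
    """One small synthetic dataset shared by pipeline-level tests."""
    cfg = SimulationConfig(
        n_species=40, n_localities=600, seed=77,
        beta_true={"Height": -25.0, "Storage tissue": 15.0},
        optimum_intercept=4400.0, optimum_noise_sd=250.0,
    )
    return simulate_dataset(cfg)


def tip_labels(tree):
    return sorted(l.taxon.label for l in tree.leaf_node_iter())
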