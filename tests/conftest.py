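import io
import warnings

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from airway_biogeo.core_io import CountTable, Phylogeny, PipelineConfig
from airway_biogeo.simulate import SimulationParams, simulate_cohort

warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", category=RuntimeWarning)
warnings.filterwarnings("ignore", module="statsmodels")


@pytest.fixture(scope="session")
def toy_phylogeny() -> Phylogeny:
    """Four-tip balanced tree with unit branch lengths."""
    return Phylogeny(TreeNode.read(io.StringIO("((A:1,B:1):1,(C:1,D:1):1);")))


@pytest.fixture(scope="session")
def small_cohort():
    """One default-design synthetic cohort at reduced taxon count."""
    return simulate_cohort(SimulationParams(seed=3, n_taxa=120))


@pytest.fixture(scope="session")
def small_config() -> PipelineConfig:
    return PipelineConfig(seed=5, n_rarefactions=3, mantel_permutations=199)


def make_count_table(counts: dict, meta_rows: list[dict]) -> CountTable:
    """Helper: CountTable from {sample_id: {taxon: count}} plus metadata."""
    frame = pd.DataFrame(counts).T.fillna(0).astype(np.int64)
    frame = frame.sort_index(axis=0).sort_index(axis=1)
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    meta["squamous_pct"] = meta.get("squamous_pct", np.nan)
    meta["is_control"] = meta.get("is_control", False)
    return CountTable(frame, meta.loc[frame.index])


def random_binary_tree(n_tips: int, rng: np.random.Generator) -> TreeNode:
    """Random binary tree with uniform branch lengths, independent of the
    package's own coalescent generator (test oracle input)."""
    nodes = [TreeNode(name=f"T{i}") for i in range(n_tips)]
    for node in nodes:
        node.length = float(rng.uniform(0.05, 2.0))
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[i], nodes[j]
        parent = TreeNode(children=[a, b])
        parent.length = float(rng.uniform(0.05, 2.0))
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)]
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return root
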