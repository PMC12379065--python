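import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ccne.datasets import BackgroundNetwork, ExpressionDataset

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_dataset(
    n_genes=6,
    cells_per_stage=(10, 12),
    seed=0,
    with_ties=False,
    gene_prefix="G",
):
    """Random staged dataset (lognormal values; optional exact ties)."""
    rng = np.random.default_rng(seed)
    n_cells = sum(cells_per_stage)
    values = rng.lognormal(mean=0.0, sigma=0.6, size=(n_genes, n_cells))
    if with_ties:
        # duplicate ~30% of entries within rows to exercise tie handling
        for row in values:
            idx = rng.choice(n_cells, size=max(2, n_cells // 3), replace=False)
            row[idx] = row[idx[0]]
    genes = [f"{gene_prefix}{i:02d}" for i in range(n_genes)]
    cells = [f"c{i:03d}" for i in range(n_cells)]
    stages = [f"t{j}" for j in range(len(cells_per_stage))]
    stage_of_cell = {}
    pos = 0
    for stage, size in zip(stages, cells_per_stage):
        for c in cells[pos : pos + size]:
            stage_of_cell[c] = stage
        pos += size
    return ExpressionDataset(
        values=values,
        gene_ids=genes,
        cell_ids=cells,
        stage_of_cell=stage_of_cell,
        stage_order=stages,
    )


def random_background(gene_ids, p=0.5, seed=0):
    import networkx as nx

    rng = np.random.default_rng(seed)
    g = nx.Graph()
    g.add_nodes_from(gene_ids)
    ids = list(gene_ids)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if rng.random() < p:
                g.add_edge(ids[i], ids[j])
    return BackgroundNetwork(g)


@pytest.fixture
def small_dataset():
    return make_dataset(n_genes=6, cells_per_stage=(10, 12), seed=1)


@pytest.fixture
def small_background(small_dataset):
    return random_background(small_dataset.gene_ids, p=0.6, seed=2)
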