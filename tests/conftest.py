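import numpy as np
import pytest
from hypothesis import settings

from postrest import SimulationSpec
from postrest.graph_build import SparseGraph

settings.register_profile("fixed", derandomize=True, max_examples=30, deadline=None)
settings.load_profile("fixed")


@pytest.fixture(scope="session")
def tiny_spec():
    """A desk-scale study: 6 subjects, 20 ROIs, 120 volumes, planted effect."""
    return SimulationSpec(
        n_rois=20,
        n_subjects=6,
        n_volumes=120,
        n_communities=4,
        hub_neighbors=tuple(range(1, 9)),
        seed=1234,
    )


@pytest.fixture(scope="session")
def tiny_study_dir(tiny_spec, tmp_path_factory):
    from postrest import simulate_study

    path = tmp_path_factory.mktemp("study")
    simulate_study(tiny_spec, path, force=True)
    return path


def random_connected_graph(rng: np.random.Generator, n_nodes: int | None = None) -> SparseGraph:
    """Random connected weighted graph on <= 8 nodes for oracle batteries."""
    n = n_nodes or int(rng.integers(3, 9))
    while True:
        p = rng.uniform(0.35, 0.9)
        mask = rng.random((n, n)) < p
        mask = np.triu(mask, k=1)
        ii, jj = np.nonzero(mask)
        if ii.size < n - 1:
            continue
        w = rng.uniform(0.05, 1.0, size=ii.size)
        g = SparseGraph(
            n_nodes=n,
            edges=np.column_stack([ii, jj]),
            weights=w,
            target_density=ii.size / (n * (n - 1) / 2),
        )
        from postrest import is_connected

        if is_connected(g):
            return g
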