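import numpy as np
import pytest

from icmspsych import synthetic
from icmspsych.core_io import ArrayGridMap
from icmspsych.spatial import AdjacencyGraph


@pytest.fixture
def cfg():
    return synthetic.SyntheticConfig()


@pytest.fixture
def standard_grid():
    return synthetic.make_standard_grid()


def path_graph(n: int) -> AdjacencyGraph:
    """1 x n path graph (single array, one row)."""
    nodes = tuple((0, 0, c) for c in range(n))
    edges = np.array([(i, i + 1) for i in range(n - 1)], dtype=int)
    return AdjacencyGraph(nodes=nodes, edges=edges)


def lattice_graph(rows: int, cols: int, holes=(), scheme="rook") -> AdjacencyGraph:
    """Full rows x cols lattice on one array, with optional holes removed."""
    from icmspsych.spatial import build_adjacency
    wired = np.zeros((1, 6, 10), dtype=bool)
    wired[0, :rows, :cols] = True
    for (r, c) in holes:
        wired[0, r, c] = False
    category = np.full(wired.shape, None, dtype=object)
    grid = ArrayGridMap(wired=wired, category=category)
    return build_adjacency(grid, scheme=scheme)


@pytest.fixture
def small_magnitude_frame(cfg):
    """30-electrode default-noise synthetic dataset with ground truth."""
    from icmspsych.core_io import trials_to_frame
    trials, labels = synthetic.gen_magnitude_dataset(cfg, seed=11)
    return trials_to_frame(trials), labels
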