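import numpy as np
import pytest
from hypothesis import settings
from shapely.geometry import Polygon

from neomap.areal_data import AdjacencyGraph, GeoLayer, make_weights, queen_contiguity

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def grid_layer(nrow: int, ncol: int) -> GeoLayer:
    """Raster of unit-square polygons, row-major ids."""
    ids, geoms = [], []
    for r in range(nrow):
        for c in range(ncol):
            ids.append(f"G{r}{c}")
            geoms.append(Polygon([(c, r), (c + 1, r), (c + 1, r + 1), (c, r + 1)]))
    return GeoLayer(ids, geoms, lonlat=False)


def cycle_graph(n: int) -> AdjacencyGraph:
    return AdjacencyGraph(
        [f"C{i}" for i in range(n)],
        [{(i - 1) % n, (i + 1) % n} for i in range(n)],
    )


@pytest.fixture
def ring4() -> AdjacencyGraph:
    return cycle_graph(4)


@pytest.fixture
def grid33():
    layer = grid_layer(3, 3)
    return layer, queen_contiguity(layer)


@pytest.fixture
def grid66_weights():
    layer = grid_layer(6, 6)
    return make_weights(queen_contiguity(layer), "row")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)


def random_connected_graph(n: int, rng: np.random.Generator) -> AdjacencyGraph:
    """Random spanning tree plus extra edges: always connected."""
    neighbors = [set() for _ in range(n)]
    order = rng.permutation(n)
    for k in range(1, n):
        i, j = int(order[k]), int(order[rng.integers(0, k)])
        neighbors[i].add(j)
        neighbors[j].add(i)
    for _ in range(n):
        i, j = rng.integers(0, n, 2)
        if i != j:
            neighbors[int(i)].add(int(j))
            neighbors[int(j)].add(int(i))
    return AdjacencyGraph([f"N{i}" for i in range(n)], neighbors)
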