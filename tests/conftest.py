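import numpy as np
import pytest

from micromorph.tracing import CellTrace, Node, ROOT_PARENT


def make_path(points, cell_id="path") -> CellTrace:
    """Unbranched trace through the given 3-D points."""
    nodes = [Node(1, ROOT_PARENT, *map(float, points[0]), 1.0, 1)]
    for i, p in enumerate(points[1:], start=2):
        nodes.append(Node(i, i - 1, *map(float, p), 0.5, 0))
    return CellTrace(nodes, cell_id=cell_id)


def make_y(stem=5.0, left=3.0, right=4.0) -> CellTrace:
    """Y-shaped trace: a stem along +x splitting into two daughters."""
    s2 = np.sqrt(2) / 2
    nodes = [
        Node(1, ROOT_PARENT, 0.0, 0.0, 0.0, 1.0, 1),
        Node(2, 1, stem, 0.0, 0.0, 0.5, 0),
        Node(3, 2, stem + left * s2, left * s2, 0.0, 0.5, 0),
        Node(4, 2, stem + right * s2, -right * s2, 0.0, 0.5, 0),
    ]
    return CellTrace(nodes, cell_id="Y")


def random_tree(rng, n_nodes=40, spread=12.0) -> CellTrace:
    """Random rooted tree: each new node attaches to a random earlier node."""
    nodes = [Node(1, ROOT_PARENT, 0.0, 0.0, 0.0, 1.0, 1)]
    for i in range(2, n_nodes + 1):
        parent = int(rng.integers(1, i))
        base = next(n for n in nodes if n.id == parent)
        off = rng.normal(0, spread / 3, size=3)
        nodes.append(
            Node(i, parent, base.x + off[0], base.y + off[1], base.z + off[2],
                 0.5, 0)
        )
    return CellTrace(nodes, cell_id="rand")


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def straight3():
    return make_path([(0, 0, 0), (4, 0, 0), (10, 0, 0)])


@pytest.fixture
def y_trace():
    return make_y()
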