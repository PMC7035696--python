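import pytest

from bicliq.datasets import worked_example, worked_example_path


@pytest.fixture(scope="session")
def example_graph():
    """The bundled 5x4, 10-edge example graph."""
    return worked_example()


@pytest.fixture(scope="session")
def example_path():
    return worked_example_path()


# Ground truth for the example graph, frozen from the brute-force closure
# oracle (subsets of the 4-vertex right side): label sets of the three
# maximal bicliques.
EXAMPLE_BICLIQUES = frozenset(
    {
        (frozenset({"u1", "u2"}), frozenset({"v1", "v2", "v4"})),
        (frozenset({"u1", "u2", "u3", "u4", "u5"}), frozenset({"v4"})),
        (frozenset({"u3"}), frozenset({"v3", "v4"})),
    }
)


def label_set(collection):
    """Order-free {(left labels, right labels)} view of a collection."""
    return frozenset(
        (frozenset(l), frozenset(r))
        for l, r in (collection.labels(b) for b in collection)
    )
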