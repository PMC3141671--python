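import numpy as np
import pytest

from dupetime import (
    BackboneSpec,
    EventModel,
    RootedTree,
    kcna_backbone_spec,
    kcna_event_model,
)


@pytest.fixture(scope="session")
def backbone() -> BackboneSpec:
    return kcna_backbone_spec()

@pytest.fixture(scope="session")
def events() -> EventModel:
    return kcna_event_model()


@pytest.fixture(scope="session")
def single_arrangement(backbone) -> BackboneSpec:
    arr_id = next(iter(backbone.arrangements))
    return BackboneSpec({arr_id: backbone.arrangements[arr_id]})


@pytest.fixture
def three_taxon_tree() -> RootedTree:
    return RootedTree.from_newick("((A:0.1,B:0.2):0.05,C:0.25);")


def random_binary_newick(rng: np.random.Generator, n_leaves: int) -> str:
    """Random rooted binary topology with unit branch lengths."""
    nodes = [f"L{i}" for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a}:1,{b}:1)")
    return nodes[0] + ";"
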