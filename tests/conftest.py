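import numpy as np
import pytest

from orchidedge.io import read_newick
from orchidedge.simulate import SimulationConfig, make_fixture


@pytest.fixture
def three_tip_tree():
    return read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def small_bundle():
    """A 12-taxon end-to-end fixture shared across integration tests."""
    config = SimulationConfig(
        n_taxa=12, marker_length=400, accessions_per_species=2, seed=7
    )
    return make_fixture(config)


def random_tree(rng: np.random.Generator, n_tips: int):
    """Random binary tree with uniform random branch lengths, built by
    sequentially joining subtrees (independent of the package's own
    Yule simulator)."""
    parts = [f"t{i}:{rng.uniform(0.1, 2.0):.6f}" for i in range(n_tips)]
    while len(parts) > 1:
        i, j = sorted(rng.choice(len(parts), size=2, replace=False))
        b = parts.pop(j)
        a = parts.pop(i)
        parts.append(f"({a},{b}):{rng.uniform(0.1, 2.0):.6f}")
    newick = parts[0]
    newick = newick[: newick.rfind(":")] + ";"
    return read_newick(newick)
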