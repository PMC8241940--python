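import numpy as np
import pytest

from sagscreen.taxonomy import RankConfig, TaxonPath


@pytest.fixture
def cfg() -> RankConfig:
    return RankConfig()


def make_random_taxonomy(rng: np.random.Generator, n_nodes: int = 50, max_depth: int = 5):
    """A random rooted taxonomy as a list of root-to-node name paths.

    Node names are globally unique so that equal names imply equal nodes,
    matching the name-based path model.
    """
    paths: list[tuple[str, ...]] = [()]
    for i in range(n_nodes):
        parent = paths[rng.integers(len(paths))]
        if len(parent) >= max_depth:
            parent = ()
        paths.append(parent + (f"n{i}",))
    return [TaxonPath(p) for p in paths if p]


def brute_force_lca(paths: list[TaxonPath]) -> TaxonPath:
    """Oracle: intersect the ancestor sets of all paths, take the deepest."""
    def ancestors(p: TaxonPath) -> set[tuple[str, ...]]:
        return {p.names[:d] for d in range(len(p.names) + 1)}

    common = ancestors(paths[0])
    for p in paths[1:]:
        common &= ancestors(p)
    return TaxonPath(max(common, key=len))
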