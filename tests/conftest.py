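import numpy as np
import pytest

from phyloscape import Grid, OccurrenceMatrix, Phylogeny, parse_newick


@pytest.fixture
def small_tree():
    """The worked 3-species tree: ((A:1,B:1):1,C:2); total length 5."""
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def small_occ(small_tree):
    """A in c1; B in c1,c2; C in c2 (two extra empty cells)."""
    g = Grid.regular(2, 2)
    recs = [
        (g.cell_ids[0], "A"),
        (g.cell_ids[0], "B"),
        (g.cell_ids[1], "B"),
        (g.cell_ids[1], "C"),
    ]
    return OccurrenceMatrix.from_records(recs, g, small_tree)


def random_tree(n_tips: int, rng: np.random.Generator) -> Phylogeny:
    """Random topology with random (non-ultrametric) branch lengths:
    grow by splitting a uniformly chosen current tip."""
    parent = [-1, 0, 0]
    while sum(1 for i in range(len(parent)) if i not in parent) < n_tips:
        tips = [i for i in range(len(parent)) if i not in parent]
        split = tips[rng.integers(len(tips))]
        parent += [split, split]
    n = len(parent)
    length = rng.uniform(0.1, 2.0, size=n)
    length[0] = 0.0
    labels: list = [None] * n
    k = 0
    for i in range(n):
        if i not in parent:
            k += 1
            labels[i] = f"t{k}"
    return Phylogeny(np.array(parent), length, labels)


def pd_bruteforce(tree: Phylogeny, present) -> float:
    """Edge-union oracle: walk each present tip's path to the root and sum
    the lengths of the union of visited edges (root edge included)."""
    tip_nodes = {tree.labels[i]: int(i) for i in tree.tip_indices}
    edges = set()
    for sp in present:
        node = tip_nodes[sp]
        while node >= 0:
            edges.add(node)
            node = int(tree.parent[node])
    return float(sum(tree.length[e] for e in edges))


def random_occurrences(grid: Grid, species, rng, p=0.3) -> OccurrenceMatrix:
    """Bernoulli presence matrix, resampled so every species has >= 1 cell."""
    M = rng.random((grid.n_cells, len(species))) < p
    for j in range(len(species)):
        if not M[:, j].any():
            M[rng.integers(grid.n_cells), j] = True
    return OccurrenceMatrix(grid, list(species), M)
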