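"""Shared fixtures: packaged data accessors and a random-tree factory."""

from __future__ import annotations

import numpy as np
import pytest

from opsin_dollo import fixtures
from opsin_dollo.trees import CladeTree, builtin_tree


@pytest.fixture(scope="session")
def nephrozoa():
    return builtin_tree("nephrozoa")


@pytest.fixture(scope="session")
def xenambulacraria():
    return builtin_tree("xenambulacraria")


@pytest.fixture(scope="session")
def both_trees(nephrozoa, xenambulacraria):
    return {"nephrozoa": nephrozoa, "xenambulacraria": xenambulacraria}


@pytest.fixture(scope="session")
def main_matrix():
    return fixtures.opsin_matrix_main()


@pytest.fixture(scope="session")
def absent_matrix():
    return fixtures.opsin_matrix_xenopsin_absent()


@pytest.fixture(scope="session")
def configs():
    return {name: fixtures.packaged_configs(name) for name in ("nephrozoa", "xenambulacraria")}


def random_binary_tree(rng: np.random.Generator, n_leaves: int) -> CladeTree:
    """Random rooted binary tree with leaves L1..Ln (labelled internals)."""
    subtrees = [f"L{i + 1}" for i in range(n_leaves)]
    idx = 0
    while len(subtrees) > 1:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        right = subtrees.pop(j)
        left = subtrees.pop(i)
        idx += 1
        subtrees.append(f"({left},{right})I{idx}")
    return CladeTree.from_newick(subtrees[0] + ";")
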