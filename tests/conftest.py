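from __future__ import annotations

import string

import numpy as np
import pytest

from hybcoal.profiles import TreeProfile
from hybcoal.treeio import read_tree_profile


def random_rooted_newick(m: int, rng: np.random.Generator, lengths: bool = False) -> str:
    """Uniform random coalescent-shaped rooted binary tree on m named taxa."""
    labels = list(string.ascii_lowercase[:m])
    nodes = list(labels)
    depth = 0.0
    while len(nodes) > 1:
        depth += float(rng.exponential(1.0))
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[int(i)], nodes[int(j)]
        merged = f"({a},{b})"
        nodes = [x for k, x in enumerate(nodes) if k not in (int(i), int(j))] + [merged]
    return nodes[0] + ";"


def random_profile_newicks(m: int, n: int, rng: np.random.Generator) -> list[str]:
    return [random_rooted_newick(m, rng) for _ in range(n)]


def profile_from_newicks(newicks: list[str]) -> TreeProfile:
    import tempfile, os

    with tempfile.NamedTemporaryFile("w", suffix=".nwk", delete=False) as fh:
        fh.write("\n".join(newicks) + "\n")
        path = fh.name
    try:
        return read_tree_profile(path, schema="newick")
    finally:
        os.unlink(path)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
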