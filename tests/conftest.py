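"""Shared fixtures and independent tree helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from migratree import _tree


def random_topology_newick(labels, rng) -> str:
    """Random binary topology by sequential random joining (test oracle side).

    Independent of the package's own tree generators: repeatedly joins two
    uniformly chosen subtrees until one remains.  Branch lengths are drawn
    Uniform(0.1, 1.0).
    """
    frags = [str(lab) for lab in labels]
    while len(frags) > 1:
        i, j = sorted(rng.choice(len(frags), size=2, replace=False))
        a, b = frags[i], frags[j]
        la, lb = rng.uniform(0.1, 1.0, size=2)
        joined = f"({a}:{la:.4f},{b}:{lb:.4f})"
        frags = [f for k, f in enumerate(frags) if k not in (i, j)]
        frags.append(joined)
    return frags[0] + ";"


def random_tree(n_taxa, rng):
    labels = [f"t{k}" for k in range(n_taxa)]
    return _tree.parse_newick(random_topology_newick(labels, rng))


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def five_taxon_tree():
    return _tree.parse_newick("((A:1,B:2):1,(C:1,(D:1,E:1):1):2);")


@pytest.fixture
def quartet_pair():
    t1 = _tree.parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
    t2 = _tree.parse_newick("((A:1,C:1):1,(B:1,D:1):1);")
    return t1, t2
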