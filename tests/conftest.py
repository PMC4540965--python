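"""Shared fixtures and independent brute-force oracles.

The parsimony oracle enumerates every internal-node state assignment
directly, with no reference to the package's reconstruction algorithm, so
it can serve as an independent check of the Fitch-Hartigan counts.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from coevotrace.parsimony import parse_newick


@pytest.fixture
def quartet_tree():
    return parse_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def balanced8_tree():
    """Balanced 8-leaf tree: two clades of four."""
    return parse_newick(
        "(((L1:1,L2:1):1,(L3:1,L4:1):1):1,((R1:1,R2:1):1,(R3:1,R4:1):1):1);"
    )


def brute_force_parsimony(tree, column: dict) -> int:
    """Exhaustive minimum change count over all ancestral assignments.

    Missing leaves (absent from ``column`` or gapped) may take any observed
    state; edges between two missing-capable nodes contribute the best case.
    Enumerates observed states only (sufficient for uniform-cost parsimony).
    """
    nodes = list(tree.preorder_node_iter())
    internal = [nd for nd in nodes if not nd.is_leaf()]
    leaves = [nd for nd in nodes if nd.is_leaf()]
    observed = sorted(
        {column[l.taxon.label] for l in leaves
         if column.get(l.taxon.label) not in (None, "-", "?", "X", ".")}
    )
    if not observed:
        return 0
    missing_leaves = [
        l for l in leaves if column.get(l.taxon.label) in (None, "-", "?", "X", ".")
    ]
    free = internal + missing_leaves  # nodes whose state is unconstrained
    fixed = {
        id(l): column[l.taxon.label] for l in leaves if l not in missing_leaves
    }
    edges = [
        (nd.parent_node, nd) for nd in nodes if nd.parent_node is not None
    ]
    best = None
    for combo in itertools.product(observed, repeat=len(free)):
        assign = dict(fixed)
        for nd, state in zip(free, combo):
            assign[id(nd)] = state
        cost = sum(1 for p, c in edges if assign[id(p)] != assign[id(c)])
        best = cost if best is None else min(best, cost)
    return best


def random_tree_newick(rng: np.random.Generator, n_leaves: int) -> str:
    """Random rooted binary topology with unit branch lengths."""
    nodes = [f"L{i}:1" for i in range(n_leaves)]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b}):1")
    return f"({nodes[0]},{nodes[1]});"
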