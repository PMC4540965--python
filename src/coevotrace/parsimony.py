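"""Small parsimony on phylogenetic trees for single/double change counting.

Covariation alone cannot distinguish a burst of correlated (double) changes
from independently occurring single changes amplified by the tree.  This
module places changes on branches with maximum parsimony so a column pair
can be decomposed into branches carrying a change at exactly one site
(single) or at both sites (double), and into the two aggregate parsimony
scores: MP_ind (total changes with the two sites treated independently) and
MP_dep (branches with any change when the pair is one joint character).

Ancestral states are reconstructed with the Fitch-Hartigan vote-counting
algorithm, which returns the exact minimum on multifurcating trees and
reduces to classic Fitch on binary trees.  Ties are broken deterministically
top-down: a node takes its parent's state when that state is in its optimal
set, otherwise the alphabetically smallest member.  Gaps and unknown symbols
are missing data and impose no constraint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Hashable, Mapping

import dendropy

GAP = "-"
MISSING_SYMBOLS = {GAP, "?", "X", "."}

__all__ = [
    "PairChangeCounts",
    "read_newick",
    "parse_newick",
    "validate_tree_against_ids",
    "total_tree_length",
    "fitch_count",
    "fitch_assign",
    "pair_branch_changes",
    "single_double_ratio",
    "site_rate_proxy",
]


@dataclass(frozen=True)
class PairChangeCounts:
    """Parsimony decomposition of a column pair.

    ``n_single_branches``/``n_double_branches`` classify branches by whether
    exactly one or both sites change on them (per-site reconstructions);
    ``mp_ind`` is the sum of the two independent Fitch minima; ``mp_dep`` is
    the number of branches with any change under joint-character parsimony.
    """

    n_single_branches: int
    n_double_branches: int
    mp_ind: int
    mp_dep: int


def parse_newick(newick: str) -> dendropy.Tree:
    """Parse a Newick string into a rooted dendropy tree."""
    try:
        tree = dendropy.Tree.get(
            data=newick, schema="newick", rooting="force-rooted",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise ValueError(f"Newick parse failure: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = {x for x in labels if labels.count(x) > 1}
    if dupes:
        raise ValueError(f"duplicate leaf labels: {sorted(dupes)}")
    return tree


def read_newick(path: str | Path) -> dendropy.Tree:
    return parse_newick(Path(path).read_text())


def validate_tree_against_ids(tree: dendropy.Tree, ids: list[str]) -> None:
    """Require the tree's leaf label set to equal the alignment's id set."""
    leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    ids_set = set(ids)
    missing = sorted(ids_set - leaves)
    extra = sorted(leaves - ids_set)
    if missing or extra:
        raise ValueError(
            f"tree/alignment leaf mismatch: missing from tree {missing}, "
            f"not in alignment {extra}"
        )


def total_tree_length(tree: dendropy.Tree) -> float:
    return sum(
        e.length or 0.0 for e in tree.preorder_edge_iter() if e.head_node is not tree.seed_node
    )


def _leaf_state(column: Mapping[str, Hashable], label: str) -> Hashable | None:
    state = column.get(label)
    if state is None or state in MISSING_SYMBOLS:
        return None
    return state


def _hartigan_bottom_up(
    tree: dendropy.Tree, column: Mapping[str, Hashable]
) -> tuple[int, dict]:
    """Bottom-up pass: minimal change count and per-node optimal state sets.

    Nodes whose subtree has no observed state get an empty set (wildcard).
    """
    optimal: dict = {}
    cost = 0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            state = _leaf_state(column, node.taxon.label)
            optimal[id(node)] = frozenset() if state is None else frozenset([state])
            continue
        votes: dict[Hashable, int] = {}
        n_voting = 0
        for child in node.child_nodes():
            child_set = optimal[id(child)]
            if not child_set:
                continue  # wildcard subtree: no constraint, no cost
            n_voting += 1
            for s in child_set:
                votes[s] = votes.get(s, 0) + 1
        if not votes:
            optimal[id(node)] = frozenset()
            continue
        m = max(votes.values())
        cost += n_voting - m
        optimal[id(node)] = frozenset(s for s, v in votes.items() if v == m)
    return cost, optimal


def fitch_count(tree: dendropy.Tree, column: Mapping[str, Hashable]) -> int:
    """Minimum number of state changes of a single character on the tree.

    ``column`` maps leaf labels to states; gaps/unknowns are missing data
    and contribute no constraint.
    """
    cost, _ = _hartigan_bottom_up(tree, column)
    return cost


def fitch_assign(
    tree: dendropy.Tree, column: Mapping[str, Hashable]
) -> dict[dendropy.Node, Hashable]:
    """One deterministic most-parsimonious ancestral reconstruction.

    Top-down, each node takes its parent's state if it lies in the node's
    optimal set, otherwise the alphabetically (or tuple-lexicographically)
    smallest member.  Leaves with missing data inherit the parent's state so
    their terminal branches carry no change.  Returns a state for every
    node; ``None`` throughout if the column has no observed states.
    """
    _, optimal = _hartigan_bottom_up(tree, column)
    assignment: dict[dendropy.Node, Hashable] = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        parent_state = assignment.get(parent) if parent is not None else None
        node_set = optimal[id(node)]
        if not node_set:  # wildcard (missing leaf or all-missing subtree)
            assignment[node] = parent_state
        elif parent_state is not None and parent_state in node_set:
            assignment[node] = parent_state
        else:
            assignment[node] = min(node_set)
    return assignment


def _implied_changes(
    tree: dendropy.Tree, assignment: Mapping[dendropy.Node, Hashable]
) -> list[dendropy.Node]:
    """Nodes whose branch (edge to parent) carries a change."""
    changed = []
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            continue
        a, b = assignment[parent], assignment[node]
        if a is not None and b is not None and a != b:
            changed.append(node)
    return changed


def pair_branch_changes(
    tree: dendropy.Tree,
    colA: Mapping[str, Hashable],
    colB: Mapping[str, Hashable],
) -> PairChangeCounts:
    """Decompose a column pair into single- and double-change branches.

    Branch classification uses the per-site deterministic reconstructions: a
    branch is a double-change branch iff both sites change on it, and a
    single-change branch iff exactly one does.  ``mp_ind`` is the sum of the
    two independent minima; ``mp_dep`` is the joint-character minimum, i.e.
    the number of branches on which the joint state changes at all.
    """
    count_a, _ = _hartigan_bottom_up(tree, colA)
    count_b, _ = _hartigan_bottom_up(tree, colB)
    assign_a = fitch_assign(tree, colA)
    assign_b = fitch_assign(tree, colB)

    changed_a = set(id(n) for n in _implied_changes(tree, assign_a))
    changed_b = set(id(n) for n in _implied_changes(tree, assign_b))
    n_double = len(changed_a & changed_b)
    n_single = len(changed_a ^ changed_b)

    joint: dict[str, tuple] = {}
    for leaf in tree.leaf_node_iter():
        a = _leaf_state(colA, leaf.taxon.label)
        b = _leaf_state(colB, leaf.taxon.label)
        if a is not None and b is not None:
            joint[leaf.taxon.label] = (a, b)
    mp_dep, _ = _hartigan_bottom_up(tree, joint)

    return PairChangeCounts(
        n_single_branches=n_single,
        n_double_branches=n_double,
        mp_ind=count_a + count_b,
        mp_dep=mp_dep,
    )


def single_double_ratio(counts: PairChangeCounts) -> float | None:
    """Ratio of single- to double-change branches.

    Returns ``+inf`` when there are singles but no doubles (ranked last when
    selecting the smallest ratio) and ``None`` when there are no changes at
    all (excluded from ranking).
    """
    if counts.n_double_branches > 0:
        return counts.n_single_branches / counts.n_double_branches
    if counts.n_single_branches > 0:
        return math.inf
    return None


def site_rate_proxy(tree: dendropy.Tree, column: Mapping[str, Hashable]) -> float:
    """Parsimony-based evolutionary rate proxy: Fitch changes per unit tree
    length.  A stand-in when no externally estimated (e.g. ML) rates are
    supplied."""
    length = total_tree_length(tree)
    if length <= 0:
        raise ValueError("total tree length must be > 0 for a rate proxy")
    return fitch_count(tree, column) / length
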