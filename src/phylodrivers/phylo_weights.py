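"""Phylogenetic leaf weights and weighted ancestral state
reconstruction with branch-midpoint transitions.

Leaf weighting apportions the total tree weight T (the sum of all
branch lengths) from the root down: the root receives T, and each node
receives A*B/C where A is the branch length into the node plus the
total branch length of its subtree, B is the parent's weight and C the
sum of the A values over the parent's children. Children's weights
therefore sum to their parent's, so leaf weights sum to T; densely
sampled clades are down-weighted.

Ancestral reconstruction is a weighted two-pass consensus: a bottom-up
pass sums descendant leaf weights per residue and normalizes, a
top-down pass multiplies each interior node's vector elementwise with
its parent's bottom-up vector and renormalizes (the root keeps its
bottom-up vector), and each node is assigned the arg-max residue when
its weight exceeds 0.5, otherwise the undefined state. A transition is
recorded at the midpoint of every branch whose child has a defined
residue differing from the nearest defined ancestor's residue
(undefined spans are bridged; the transition is attributed to the
branch entering the first defined descendant).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import GAP, GeneTree, Msa

#: sentinel residue code for "no consensus residue"
UNDEFINED = -1

_N_STATES = 20  # canonical amino acids


@dataclass
class LeafWeights:
    """Per-leaf weights plus the total tree weight T."""

    weights: dict[str, float]
    node_weights: np.ndarray
    total_tree_weight: float

    def __getitem__(self, leaf_id: str) -> float:
        return self.weights[leaf_id]


def leaf_weights(tree: GeneTree) -> LeafWeights:
    """Root-to-tip recursive leaf weighting.

    When all of a parent's child A values are zero (an all-zero-length
    clade) the parent's weight is split equally among the children.
    """
    n = tree.n_nodes
    a = tree.brlen + tree.subtree_length  # A per node
    w = np.zeros(n, dtype=float)
    w[0] = tree.total_length
    for i in tree.preorder:
        kids = tree.children[i]
        if not kids:
            continue
        c = sum(a[k] for k in kids)
        if c == 0:
            share = w[i] / len(kids)
            for k in kids:
                w[k] = share
        else:
            for k in kids:
                w[k] = a[k] * w[i] / c
    weights = {tree.labels[i]: float(w[i]) for i in tree.leaf_nodes}
    return LeafWeights(weights, w, tree.total_length)


@dataclass
class AncestralAssignment:
    """Per-node consensus residue codes for one site (UNDEFINED = -1)."""

    site_column: int
    residues: np.ndarray  # int8, length n_nodes

    def residue_of(self, node: int) -> int:
        return int(self.residues[node])


@dataclass(frozen=True)
class Transition:
    """A consensus-residue change placed at a branch midpoint."""

    site_column: int
    parent: int
    child: int
    from_state: int
    to_state: int


def _leaf_state_matrix(tree: GeneTree, msa: Msa, column: int) -> np.ndarray:
    """Residue code per tree node (leaves only; gap/unknown -> -1)."""
    states = np.full(tree.n_nodes, -1, dtype=np.int8)
    for lab, node in tree.leaf_index.items():
        code = msa.row(lab)[column]
        if code < GAP:
            states[node] = code
    return states


def reconstruct_ancestral_states(
    tree: GeneTree,
    msa: Msa,
    column: int,
    weights: LeafWeights,
    threshold: float = 0.5,
) -> tuple[np.ndarray, AncestralAssignment]:
    """Weighted two-pass reconstruction for one alignment column.

    Returns the final per-node character weight vectors (n_nodes x 20,
    rows summing to 1 where defined, all-zero where no descendant
    carries a residue) and the per-node assignment. Leaves with a gap
    at the column carry no character and end up UNDEFINED.
    """
    n = tree.n_nodes
    leaf_states = _leaf_state_matrix(tree, msa, column)
    up = np.zeros((n, _N_STATES), dtype=float)
    for i in tree.postorder:
        if tree.is_leaf[i]:
            s = leaf_states[i]
            if s >= 0:
                up[i, s] = weights.node_weights[i]
        else:
            for c in tree.children[i]:
                up[i] += up[c]
    # raw sums kept; normalize copies
    totals = up.sum(axis=1)
    up_norm = np.zeros_like(up)
    defined = totals > 0
    up_norm[defined] = up[defined] / totals[defined, None]

    final = up_norm.copy()
    for i in tree.preorder:
        p = tree.parent[i]
        if p == -1 or tree.is_leaf[i]:
            continue
        prod = up_norm[i] * up_norm[p]
        t = prod.sum()
        if t > 0:
            final[i] = prod / t
        # disjoint supports: keep the bottom-up vector (no information
        # from the parent can be combined)
    residues = np.full(n, UNDEFINED, dtype=np.int8)
    # ties at the threshold (e.g. an exact 0.5/0.5 root split) are
    # undefined; the 1e-12 guard keeps float summation order from
    # flipping mathematically exact ties either way
    for i in range(n):
        j = int(np.argmax(final[i]))
        if final[i, j] > threshold + 1e-12:
            residues[i] = j
    return final, AncestralAssignment(column, residues)


def nearest_defined_ancestor(tree: GeneTree, residues: np.ndarray, node: int) -> int:
    """Residue of the nearest strict ancestor with a defined assignment,
    or UNDEFINED if none exists."""
    p = int(tree.parent[node])
    while p != -1:
        if residues[p] != UNDEFINED:
            return int(residues[p])
        p = int(tree.parent[p])
    return UNDEFINED


def extract_transitions(tree: GeneTree, assignment: AncestralAssignment) -> list[Transition]:
    """Branch-midpoint transitions for one site.

    For every node with a defined residue, the nearest defined strict
    ancestor is found (bridging undefined spans); a differing residue
    yields one transition on the branch entering the node.
    """
    residues = assignment.residues
    out = []
    for i in range(1, tree.n_nodes):
        r = residues[i]
        if r == UNDEFINED:
            continue
        anc = nearest_defined_ancestor(tree, residues, i)
        if anc != UNDEFINED and anc != r:
            out.append(
                Transition(assignment.site_column, int(tree.parent[i]), int(i),
                           int(anc), int(r))
            )
    return out


def reconstruct_all_sites(
    tree: GeneTree,
    msa: Msa,
    columns,
    weights: LeafWeights,
) -> tuple[dict[int, AncestralAssignment], dict[int, list[Transition]]]:
    """Assignments and transitions for a set of columns."""
    assignments: dict[int, AncestralAssignment] = {}
    transitions: dict[int, list[Transition]] = {}
    for col in columns:
        _, asg = reconstruct_ancestral_states(tree, msa, col, weights)
        assignments[col] = asg
        transitions[col] = extract_transitions(tree, asg)
    return assignments, transitions
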