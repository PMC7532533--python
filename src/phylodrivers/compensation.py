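"""Compensatory mutation ensembles.

For a driver state (an alignment column plus residue) present in at
least four leaves, a compensatory ensemble is a minimal set of other
residue states such that

1. every leaf carrying the driver state also carries a member state
   whose transition precedes that lineage's driver emergence
   (coverage),
2. the probability that the observed precedence pattern arose with
   driver and members placed independently — a binomial upper tail over
   the driver's transition events with success probability F, the
   fraction of the tree occupied by the member states — is below 1%,
3. every member's transitions occur at >= 2 independent nodes of the
   tree (a pooled-count variant is available behind a flag), and
4. at least two driver-bearing leaves descend from each such node;
5. each individual state belongs to at most one ensemble per gene.

The binomial tail uses N_total, the number of transitions to the driver
state across the whole ancestral record, and N_pair, the number of
those transitions strictly descendant of a member-state transition
(two transitions at the same branch midpoint have no resolvable
order, so same-branch events count toward construction and coverage
but not toward confirmed precedence).
Ensembles are searched in order of increasing co-occurrence
probability; ensembles two or more larger than the smallest accepted
one are not reported.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .io_formats import GeneTree
from .phylo_weights import (
    UNDEFINED,
    AncestralAssignment,
    Transition,
    nearest_defined_ancestor,
)

logger = logging.getLogger(__name__)

State = tuple[int, int]  # (alignment column, residue code)


def cooccurrence_probability(n_total: int, n_pair: int, f: float) -> float:
    """Binomial upper tail: P(X >= n_pair), X ~ Binomial(n_total, F).

    The probability that at least ``n_pair`` of the ``n_total`` driver
    transitions fall on member-occupied parts of the tree if placed
    independently at rate F.
    """
    if not (0 <= n_pair <= n_total):
        raise ValueError(f"need 0 <= n_pair <= n_total, got {n_pair}, {n_total}")
    if not (0.0 <= f <= 1.0):
        raise ValueError(f"F must lie in [0, 1], got {f}")
    if n_pair == 0:
        return 1.0
    # direct summation, smallest terms last are avoided by summing from
    # the far tail inward; exact integer binomial coefficients
    total = 0.0
    for k in range(n_total, n_pair - 1, -1):
        total += math.comb(n_total, k) * f**k * (1.0 - f) ** (n_total - k)
    return min(total, 1.0)


def candidate_compensators(
    driver_transitions: list[Transition],
    all_transitions: dict[int, list[Transition]],
    tree: GeneTree,
    driver_column: int,
) -> set[State]:
    """States with a transition on the same branch as, or any ancestral
    branch of, at least one driver transition. The driver's own column
    is excluded."""
    out: set[State] = set()
    driver_children = [t.child for t in driver_transitions]
    for col, trans in all_transitions.items():
        if col == driver_column:
            continue
        for t in trans:
            for dc in driver_children:
                # branch into t.child is the same branch as, or ancestral
                # to, the branch into dc iff t.child is an
                # ancestor-or-self of dc
                if tree.is_ancestor_or_self(t.child, dc):
                    out.add((col, t.to_state))
                    break
    return out


def _occupancy(tree: GeneTree, assignment: AncestralAssignment, residue: int):
    """Per-branch occupancy of a residue state and per-branch
    applicability, under the half-branch convention.

    A branch (into node i) is applicable when node i has a defined
    assignment. Its occupancy is 1 when both the node and its effective
    parent (nearest defined ancestor, bridging undefined spans) carry
    the state, 0.5 when exactly one of them does, 0 otherwise.
    """
    res = assignment.residues
    occ = np.zeros(tree.n_nodes)
    applicable = np.zeros(tree.n_nodes, dtype=bool)
    for i in range(1, tree.n_nodes):
        if res[i] == UNDEFINED:
            continue
        applicable[i] = True
        anc = nearest_defined_ancestor(tree, res, i)
        here = res[i] == residue
        above = anc == residue
        if here and above:
            occ[i] = 1.0
        elif here or above:
            occ[i] = 0.5
    return occ, applicable


def branch_state_fraction(
    tree: GeneTree, assignment: AncestralAssignment, residue: int
) -> float | None:
    """Fraction of applicable branch length occupied by a residue state.

    Branches where the state holds at both endpoints count fully,
    transition branches count half; the denominator is the total length
    of branches with a defined assignment at the site. ``None`` when
    that length is zero.
    """
    occ, applicable = _occupancy(tree, assignment, residue)
    denom = float(tree.brlen[applicable].sum())
    if denom == 0:
        return None
    return float((occ * tree.brlen).sum() / denom)


def _ensemble_fraction(
    tree: GeneTree,
    assignments: dict[int, AncestralAssignment],
    members: tuple[State, ...],
) -> float | None:
    """F for a member set: union of occupied branches (per-branch
    occupancy is the max over members), over branches applicable for at
    least one member."""
    occ = np.zeros(tree.n_nodes)
    applicable = np.zeros(tree.n_nodes, dtype=bool)
    for col, residue in members:
        o, a = _occupancy(tree, assignments[col], residue)
        occ = np.maximum(occ, o)
        applicable |= a
    denom = float(tree.brlen[applicable].sum())
    if denom == 0:
        return None
    return float((occ * tree.brlen).sum() / denom)


@dataclass
class CompensatoryEnsemble:
    driver_column: int
    driver_residue: int
    members: tuple[State, ...]
    n_total: int
    n_pair: int
    fraction: float
    p_cooccur: float
    member_nodes: tuple[int, ...] = field(default=())

    @property
    def size(self) -> int:
        return len(self.members)


class _DriverContext:
    """Precomputed geometry for one driver state."""

    def __init__(
        self,
        gene_family,
        driver_column: int,
        driver_residue: int,
        assignments: dict[int, AncestralAssignment],
        transitions: dict[int, list[Transition]],
    ):
        tree = gene_family.tree
        msa = gene_family.msa
        self.tree = tree
        self._msa = msa
        self.assignments = assignments
        self.driver_column = driver_column
        self.driver_residue = driver_residue
        self.driver_leaves = [
            node
            for lab, node in tree.leaf_index.items()
            if msa.row(lab)[driver_column] == driver_residue
        ]
        self.driver_transitions = [
            t for t in transitions.get(driver_column, []) if t.to_state == driver_residue
        ]
        self.n_total = len(self.driver_transitions)
        # leaves below each node, as sets, computed lazily
        self._leafsets: dict[int, set[int]] = {}
        # driver transition node whose emergence each driver leaf
        # descends from (the leaf itself when none is found, e.g. for a
        # root-ancestral driver state)
        self.emergence_of: dict[int, int] = {}
        dchildren = [t.child for t in self.driver_transitions]
        for leaf in self.driver_leaves:
            anchor = leaf
            for dc in dchildren:
                if tree.is_ancestor_or_self(dc, leaf):
                    anchor = dc
                    break
            self.emergence_of[leaf] = anchor

    def leaves_below(self, node: int) -> set[int]:
        if node not in self._leafsets:
            self._leafsets[node] = set(self.tree.subtree_leaves(node))
        return self._leafsets[node]

    def member_geometry(self, state: State, transitions_of):
        """(covered driver leaves, transition nodes, driver transitions
        on/below a member transition) for one candidate state.

        A member covers a driver leaf only when the leaf carries the
        member residue AND one of the member's transitions lies on the
        same or an ancestral branch of the driver emergence that leaf
        descends from — mere presence of the residue via an unrelated
        transition elsewhere does not compensate that lineage.
        """
        col, residue = state
        nodes = tuple(t.child for t in transitions_of(col) if t.to_state == residue)
        covered = set()
        for leaf in self.driver_leaves:
            if not self._carries(leaf, col, residue):
                continue
            anchor = self.emergence_of[leaf]
            if any(self.tree.is_ancestor_or_self(m, anchor) for m in nodes):
                covered.add(leaf)
        # N_pair counts driver transitions strictly DESCENDANT of a
        # member transition: two transitions at the midpoint of the
        # same branch have no resolvable order, so a same-branch event
        # can cover lineages (construction allows "the same or a prior
        # branch") but cannot confirm precedence
        paired = set()
        for t in self.driver_transitions:
            for mnode in nodes:
                if mnode != t.child and self.tree.is_ancestor_or_self(mnode, t.child):
                    paired.add(t.child)
                    break
        return covered, nodes, paired

    def _carries(self, leaf: int, col: int, residue: int) -> bool:
        lab = self.tree.labels[leaf]
        return self._msa_code(lab, col) == residue

    def _msa_code(self, lab, col):
        return self._msa.row(lab)[col]


def build_ensembles(
    gene_family,
    driver_column: int,
    driver_residue: int,
    assignments: dict[int, AncestralAssignment],
    transitions: dict[int, list[Transition]],
    p_max: float = 0.01,
    min_driver_leaves: int = 4,
    exhaustive_limit: int = 15,
    excluded_states: set[State] | None = None,
    per_member_nodes: bool = True,
) -> CompensatoryEnsemble | None:
    """Search for the best compensatory ensemble of one driver state.

    Candidates already consumed by another ensemble may be passed in
    ``excluded_states``. Returns the minimum-probability ensemble
    satisfying all criteria whose size is at most the smallest
    qualifying size plus one, or ``None`` with the failing reason
    logged. ``per_member_nodes=False`` relaxes the
    two-independent-appearances criterion from every member on its own
    to the pool of all member transitions.
    """
    tree = gene_family.tree
    msa = gene_family.msa
    ctx = _DriverContext(gene_family, driver_column, driver_residue, assignments, transitions)
    if len(ctx.driver_leaves) < min_driver_leaves:
        logger.info(
            "driver col %d res %d skipped: only %d leaves (< %d)",
            driver_column, driver_residue, len(ctx.driver_leaves), min_driver_leaves,
        )
        return None
    if ctx.n_total == 0:
        logger.info("driver col %d res %d: no transitions in the ancestral record",
                    driver_column, driver_residue)
        return None

    candidates = candidate_compensators(
        ctx.driver_transitions, transitions, tree, driver_column
    )
    if excluded_states:
        candidates -= excluded_states
    if not candidates:
        logger.info("driver col %d res %d: no candidate compensators",
                    driver_column, driver_residue)
        return None

    # precompute per-candidate geometry; drop candidates covering no
    # driver leaf (they cannot help criterion 1)
    geom = {}
    for st in sorted(candidates):
        covered, nodes, paired = ctx.member_geometry(st, lambda c: transitions.get(c, []))
        if covered:
            geom[st] = (covered, nodes, paired)
    if not geom:
        logger.info("driver col %d res %d: no candidate covers any driver leaf",
                    driver_column, driver_residue)
        return None

    driver_leafset = set(ctx.driver_leaves)

    def evaluate(members: tuple[State, ...]) -> CompensatoryEnsemble | None:
        covered: set[int] = set()
        paired: set[int] = set()
        qual_nodes: list[int] = []
        for st in members:
            c, nodes, p = geom[st]
            covered |= c
            paired |= p
            qual_nodes.extend(nodes)
        if covered != driver_leafset:
            return None
        # criteria 3/4: the members' transitions occur at >= 2
        # independent nodes, and at least two driver-bearing sequences
        # descend from EACH of those nodes — a member with a stray
        # transition in a driver-free part of the tree disqualifies
        # the ensemble
        node_set = set(qual_nodes)
        if len(node_set) < 2:
            return None
        if any(len(ctx.leaves_below(nd) & driver_leafset) < 2 for nd in node_set):
            return None
        if per_member_nodes and any(len(set(geom[st][1])) < 2 for st in members):
            return None
        good_nodes = sorted(node_set)
        f = _ensemble_fraction(tree, assignments, members)
        if f is None:
            return None
        p = cooccurrence_probability(ctx.n_total, len(paired), f)
        return CompensatoryEnsemble(
            driver_column, driver_residue, members, ctx.n_total, len(paired), f, p,
            tuple(sorted(good_nodes)),
        )

    pool = sorted(geom)
    best: list[CompensatoryEnsemble] = []
    if len(pool) <= exhaustive_limit:
        for size in range(1, len(pool) + 1):
            for combo in itertools.combinations(pool, size):
                ens = evaluate(combo)
                if ens is not None and ens.p_cooccur < p_max:
                    best.append(ens)
            if best and size >= min(e.size for e in best) + 1:
                break
    else:
        # greedy: grow toward coverage, choosing at each step the
        # candidate that yields the lowest probability of the partial
        # ensemble, preferring coverage gain
        members: list[State] = []
        covered: set[int] = set()
        remaining = set(pool)
        while covered != driver_leafset and remaining:
            scored = []
            for st in remaining:
                gain = len(geom[st][0] - covered)
                if gain == 0:
                    continue
                trial = tuple(members + [st])
                f = _ensemble_fraction(tree, assignments, trial)
                paired = set()
                for s2 in trial:
                    paired |= geom[s2][2]
                p = cooccurrence_probability(ctx.n_total, len(paired), f or 1.0)
                scored.append((p, -gain, st))
            if not scored:
                break
            scored.sort()
            _, _, chosen = scored[0]
            members.append(chosen)
            covered |= geom[chosen][0]
            remaining.discard(chosen)
        ens = evaluate(tuple(members)) if members else None
        if ens is not None and ens.p_cooccur < p_max:
            best.append(ens)
        # single-member full-coverage alternatives
        for st in pool:
            if geom[st][0] == driver_leafset:
                ens = evaluate((st,))
                if ens is not None and ens.p_cooccur < p_max:
                    best.append(ens)

    if not best:
        logger.info("driver col %d res %d: no ensemble satisfies all criteria",
                    driver_column, driver_residue)
        return None
    min_size = min(e.size for e in best)
    best = [e for e in best if e.size <= min_size + 1]
    best.sort(key=lambda e: (e.p_cooccur, e.size, e.members))
    return best[0]


def build_all_ensembles(
    gene_family,
    drivers: list[tuple[int, int]],
    assignments: dict[int, AncestralAssignment],
    transitions: dict[int, list[Transition]],
    p_max: float = 0.01,
    min_driver_leaves: int = 4,
    per_member_nodes: bool = True,
) -> dict[tuple[int, int], CompensatoryEnsemble]:
    """Build ensembles for all drivers of a gene, enforcing that each
    individual state occurs in at most one ensemble.

    Drivers are resolved in order of increasing co-occurrence
    probability of their best ensemble; later drivers are rebuilt with
    already-consumed states excluded.
    """
    first = {}
    for d in drivers:
        ens = build_ensembles(gene_family, d[0], d[1], assignments, transitions,
                              p_max, min_driver_leaves,
                              per_member_nodes=per_member_nodes)
        if ens is not None:
            first[d] = ens
    consumed: set[State] = set()
    out: dict[tuple[int, int], CompensatoryEnsemble] = {}
    for d in sorted(first, key=lambda d: first[d].p_cooccur):
        ens = first[d]
        if consumed & set(ens.members):
            ens = build_ensembles(gene_family, d[0], d[1], assignments, transitions,
                                  p_max, min_driver_leaves,
                                  excluded_states=consumed,
                                  per_member_nodes=per_member_nodes)
        if ens is not None:
            out[d] = ens
            consumed |= set(ens.members)
    return out
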