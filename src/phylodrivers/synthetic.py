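"""Synthetic gene families with planted driver/compensator events.

Everything the pipeline consumes can be generated here: a rooted
pure-birth (Yule) tree over labeled major clades, a protein alignment
evolved on it under a uniform (Jukes-Cantor-style) 20-state
substitution process with planted state transitions, a taxon
annotation table, a tumor mutation table with configurable marginal
frequencies and pairwise co-occurrence odds, and a structure hit
table. Ground-truth event logs are first-class outputs so tests never
re-derive truth from the simulator's internals.

All generators are deterministic functions of their seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io_formats import (
    AA_ALPHABET,
    GAP,
    GeneFamily,
    GeneTree,
    Msa,
    MutationRecord,
    TaxonAnnotation,
)

logger = logging.getLogger(__name__)

#: default apportioning of leaves to the six major clades; roughly the
#: mix of a deep eukaryote-heavy ortholog set (mostly metazoan, with
#: fungi/plants present so that "deep" sites exist, and a small
#: prokaryotic outgroup)
DEFAULT_CLADE_FRACTIONS = {
    "vertebrate": 0.30,
    "invertebrate": 0.25,
    "protist": 0.15,
    "fungus": 0.125,
    "plant": 0.125,
    "prokaryote": 0.05,
}


@dataclass(frozen=True)
class PlantedEvent:
    """A state transition forced onto a branch: the residue at
    ``site`` changes from ``anc`` to ``der`` on the branch entering
    ``node`` and propagates to all descendants."""

    site: int  # alignment column (gapless simulation: ref pos - 1)
    node: int  # child node index of the branch carrying the event
    anc: str
    der: str
    role: str  # "driver" | "compensator"


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic gene family.

    ``subst_rate`` is the expected number of substitutions per site
    per unit branch length; with Yule trees of total length
    ~(n-1)/birth_rate the default 0.1 gives each site a handful
    (~5) of substitutions across the tree — the conserved-but-
    informative regime of deep ortholog alignments, with enough
    homoplasy to exercise the reconstruction without saturating the
    columns.
    """

    seed: int = 0
    n_leaves: int = 48
    birth_rate: float = 1.0
    seq_length: int = 40
    subst_rate: float = 0.1
    clade_fractions: dict = field(default_factory=lambda: dict(DEFAULT_CLADE_FRACTIONS))
    gene: str = "GENE1"


# ---------------------------------------------------------------------------
# tree simulation


class _SimNode:
    __slots__ = ("label", "children", "brlen")

    def __init__(self, label=None):
        self.label = label
        self.children: list[_SimNode] = []
        self.brlen = 0.0

    def newick(self) -> str:
        if not self.children:
            return f"{self.label}:{self.brlen:.10f}"
        inner = ",".join(c.newick() for c in self.children)
        return f"({inner}):{self.brlen:.10f}"


def simulate_tree(n_leaves: int, birth_rate: float, rng: np.random.Generator) -> GeneTree:
    """Rooted ultrametric pure-birth (Yule) tree.

    Lineages split at total rate k * birth_rate; a final exponential
    waiting time is drawn after the last split so every pendant branch
    has positive length. Leaves are labeled ``L0001..L<n>`` in the
    order they are created.
    """
    if n_leaves < 4:
        raise ValueError("need at least 4 leaves")
    root = _SimNode()
    first, second = _SimNode(), _SimNode()
    root.children = [first, second]
    # active lineages with their birth time
    t = 0.0
    active: list[tuple[_SimNode, float]] = [(first, 0.0), (second, 0.0)]
    while len(active) < n_leaves:
        k = len(active)
        t += rng.exponential(1.0 / (birth_rate * k))
        i = int(rng.integers(k))
        node, born = active[i]
        node.brlen = t - born
        a, b = _SimNode(), _SimNode()
        node.children = [a, b]
        active[i] = (a, t)
        active.append((b, t))
    t += rng.exponential(1.0 / (birth_rate * len(active)))
    for j, (node, born) in enumerate(active):
        node.brlen = t - born
    # label leaves in creation order
    for j, (node, _) in enumerate(active):
        node.label = f"L{j + 1:04d}"
    inner = ",".join(c.newick() for c in root.children)
    return GeneTree.from_newick(f"({inner});")


# ---------------------------------------------------------------------------
# alignment simulation


@dataclass
class EventLog:
    """Ground-truth substitution events: (site, child node, from, to)."""

    events: list[tuple[int, int, str, str]] = field(default_factory=list)

    def at_site(self, site: int) -> list[tuple[int, int, str, str]]:
        return [e for e in self.events if e[0] == site]

    def branches_at_site(self, site: int) -> set[int]:
        return {e[1] for e in self.events if e[0] == site}


def simulate_alignment(
    tree: GeneTree,
    seq_length: int,
    subst_rate: float,
    rng: np.random.Generator,
    planted: list[PlantedEvent] | None = None,
    root_sequence: str | None = None,
    gap_fraction: float = 0.0,
    reference_id: str | None = None,
) -> tuple[Msa, EventLog]:
    """Evolve a protein alignment on a tree and log every event.

    Sites evolve independently under a uniform 20-state process: on a
    branch of length b each site substitutes with probability
    1 - exp(-subst_rate * b), the new residue uniform over the other
    19. Planted events overwrite the state on their branch and
    propagate; random substitutions at planted sites are suppressed so
    the planted history is the complete history of those sites.
    ``gap_fraction`` masks that fraction of leaf cells (never at
    planted sites, never in the reference row).
    """
    planted = planted or []
    _validate_planted(tree, planted)
    planted_sites = {e.site for e in planted}
    by_branch: dict[int, list[PlantedEvent]] = {}
    for e in planted:
        by_branch.setdefault(e.node, []).append(e)

    aa = np.frombuffer(AA_ALPHABET.encode(), dtype=np.uint8)
    code_of = {ch: i for i, ch in enumerate(AA_ALPHABET)}

    if root_sequence is None:
        root = rng.integers(0, 20, size=seq_length)
    else:
        root = np.array([code_of[c] for c in root_sequence], dtype=np.int64)
    for e in planted:
        root[e.site] = code_of[e.anc]

    states = np.zeros((tree.n_nodes, seq_length), dtype=np.int64)
    states[0] = root
    log = EventLog()
    free = np.array([s not in planted_sites for s in range(seq_length)])
    for i in tree.preorder:
        p = tree.parent[i]
        if p == -1:
            continue
        seq = states[p].copy()
        pmut = 1.0 - np.exp(-subst_rate * tree.brlen[i])
        hit = (rng.random(seq_length) < pmut) & free
        for s in np.nonzero(hit)[0]:
            old = seq[s]
            new = int(rng.integers(19))
            if new >= old:
                new += 1
            seq[s] = new
            log.events.append((int(s), int(i), AA_ALPHABET[old], AA_ALPHABET[new]))
        for e in by_branch.get(int(i), []):
            old = seq[e.site]
            seq[e.site] = code_of[e.der]
            log.events.append((e.site, int(i), AA_ALPHABET[old], e.der))
        states[i] = seq

    ids = tree.leaf_labels
    matrix = np.empty((len(ids), seq_length), dtype=np.uint8)
    for r, lab in enumerate(ids):
        matrix[r] = states[tree.leaf_index[lab]]
    if reference_id is None:
        reference_id = ids[0]
    if gap_fraction > 0:
        mask = rng.random(matrix.shape) < gap_fraction
        ref_row = ids.index(reference_id)
        mask[ref_row, :] = False
        for s in planted_sites:
            mask[:, s] = False
        matrix[mask] = GAP
    return Msa(ids, matrix, reference_id), log


def _validate_planted(tree: GeneTree, planted: list[PlantedEvent]) -> None:
    """When compensator events are planted, every driver event must be
    preceded by one: some compensator sits on the same branch as, or an
    ancestor branch of, the driver's branch."""
    drivers = [e for e in planted if e.role == "driver"]
    comps = [e for e in planted if e.role == "compensator"]
    if not comps:
        return
    for d in drivers:
        if not any(tree.is_ancestor_or_self(c.node, d.node) for c in comps):
            raise ValueError(
                f"driver event on node {d.node} is not preceded by any compensator"
            )


# ---------------------------------------------------------------------------
# taxa


def simulate_taxa(
    tree: GeneTree,
    clade_fractions: dict[str, float] | None = None,
) -> TaxonAnnotation:
    """Assign leaves to major clades in contiguous preorder blocks
    (mimicking taxonomic clustering in a rooted tree) and give each
    leaf its own species with a four-level taxonomy path."""
    fractions = clade_fractions or DEFAULT_CLADE_FRACTIONS
    leaves = [tree.labels[i] for i in tree.preorder if tree.is_leaf[i]]
    n = len(leaves)
    clades = list(fractions)
    counts = [int(round(fractions[c] * n)) for c in clades]
    while sum(counts) < n:
        counts[0] += 1
    while sum(counts) > n:
        counts[int(np.argmax(counts))] -= 1
    species, clade, path = {}, {}, {}
    k = 0
    for cl, cnt in zip(clades, counts):
        for j in range(cnt):
            sid = leaves[k]
            sp = f"{cl}_sp{j + 1}"
            species[sid] = sp
            clade[sid] = cl
            path[sid] = ("cellular", cl, f"{cl}_genus{j // 3 + 1}", sp)
            k += 1
    return TaxonAnnotation(species, clade, path)


# ---------------------------------------------------------------------------
# planting helpers


def plant_compensated_driver(
    tree: GeneTree,
    rng: np.random.Generator,
    n_comp_events: int = 2,
    drivers_per_comp: int = 2,
    max_fraction_each: float = 0.15,
    consensus_margin: float = 0.55,
    driver_site: int = 0,
    comp_site: int = 1,
) -> list[PlantedEvent] | None:
    """Choose branches for a single-state compensator preceding a set
    of driver events so that the planted configuration satisfies the
    ensemble criteria by construction.

    The compensator state arises ``n_comp_events`` times independently
    (disjoint subtrees, each occupying at most ``max_fraction_each`` of
    total branch length so F stays small); inside each compensator
    subtree, ``drivers_per_comp`` driver events are planted on leaf
    branches, giving at least two driver-bearing sequences per
    compensator node and at least four driver leaves overall. Placements
    are rejected when, at any node above a planted event, the leaf
    weight carrying the derived state exceeds ``consensus_margin`` of
    the subtree weight: such a node would itself be assigned the
    derived state by the weighted consensus, flattening clustered
    events onto a shared ancestral branch. (At fractions near one half
    the top-down pass pulls ancestors toward the surrounding ancestral
    residue, so a margin slightly above 0.5 suffices.) Returns ``None`` when the
    tree admits no such configuration.
    """
    from .phylo_weights import leaf_weights as _leaf_weights

    w = _leaf_weights(tree).node_weights
    total = tree.total_length
    sub_w = np.zeros(tree.n_nodes)
    for i in tree.postorder:
        sub_w[i] = w[i] if tree.is_leaf[i] else sum(sub_w[c] for c in tree.children[i])

    def ancestors(node):
        p = int(tree.parent[node])
        while p != -1:
            yield p
            p = int(tree.parent[p])

    comp_cands = [
        c
        for c in range(1, tree.n_nodes)
        if len(tree.subtree_leaves(c)) >= 2 * drivers_per_comp
        and (tree.subtree_length[c] + 0.5 * tree.brlen[c]) / total <= max_fraction_each
    ]
    comp_cands = list(rng.permutation(comp_cands)) if comp_cands else []

    def pick_driver_leaves(c):
        # one leaf per distinct child subtree first, for dispersion
        leaves = tree.subtree_leaves(int(c))
        rng.shuffle(leaves)
        picked = []
        used_children = set()
        for lf in leaves:
            # which child subtree of c contains lf
            a = lf
            while int(tree.parent[a]) != int(c):
                a = int(tree.parent[a])
            if a in used_children:
                continue
            used_children.add(a)
            picked.append(lf)
            if len(picked) == drivers_per_comp:
                return picked
        for lf in leaves:
            if lf not in picked:
                picked.append(lf)
                if len(picked) == drivers_per_comp:
                    return picked
        return None

    def weight_ok(state_nodes):
        # at every node strictly above a planted event, the derived
        # state's leaf weight must stay a clear minority
        carrier = np.zeros(tree.n_nodes)
        for s in state_nodes:
            carrier[s] = sub_w[s]
        checked = set()
        for s in state_nodes:
            for a in ancestors(s):
                if a in checked:
                    continue
                checked.add(a)
                mass = sum(carrier[s2] for s2 in state_nodes
                           if tree.is_ancestor_or_self(a, s2))
                if sub_w[a] > 0 and mass / sub_w[a] > consensus_margin:
                    return False
        return True

    for i, c1 in enumerate(comp_cands):
        for c2 in comp_cands[i + 1:]:
            c1i, c2i = int(c1), int(c2)
            if tree.is_ancestor_or_self(c1i, c2i) or tree.is_ancestor_or_self(c2i, c1i):
                continue
            d1 = pick_driver_leaves(c1i)
            d2 = pick_driver_leaves(c2i)
            if d1 is None or d2 is None:
                continue
            if not weight_ok([c1i, c2i]):
                continue  # compensator transitions would flatten
            if not weight_ok(d1 + d2):
                continue  # driver transitions would flatten
            events = [
                PlantedEvent(comp_site, c1i, "L", "I", "compensator"),
                PlantedEvent(comp_site, c2i, "L", "I", "compensator"),
            ]
            for d in d1 + d2:
                events.append(PlantedEvent(driver_site, int(d), "A", "V", "driver"))
            return events
    return None


def plant_independent_driver(
    tree: GeneTree,
    rng: np.random.Generator,
    n_driver_events: int = 3,
    min_leaves_per_event: int = 2,
    consensus_margin: float = 0.55,
    driver_site: int = 0,
) -> list[PlantedEvent] | None:
    """Plant driver events on random disjoint branches with no
    compensator: the null configuration in which any apparent
    compensatory signal among the freely evolving background sites is
    coincidental.

    Each event subtends at least ``min_leaves_per_event`` leaves (so
    the driver is eligible for ensemble construction) and placements
    that would flatten under the weighted consensus are rejected as in
    :func:`plant_compensated_driver`.
    """
    from .phylo_weights import leaf_weights as _leaf_weights

    w = _leaf_weights(tree).node_weights
    sub_w = np.zeros(tree.n_nodes)
    for i in tree.postorder:
        sub_w[i] = w[i] if tree.is_leaf[i] else sum(sub_w[c] for c in tree.children[i])

    cands = [
        c
        for c in range(1, tree.n_nodes)
        if len(tree.subtree_leaves(c)) >= min_leaves_per_event
    ]
    order = list(rng.permutation(cands))
    for _ in range(50):
        picked: list[int] = []
        for d in order:
            d = int(d)
            if all(
                not tree.is_ancestor_or_self(d, q)
                and not tree.is_ancestor_or_self(q, d)
                for q in picked
            ):
                picked.append(d)
            if len(picked) == n_driver_events:
                break
        if len(picked) < n_driver_events:
            return None
        ok = True
        for d in picked:
            a = int(tree.parent[d])
            while a != -1 and ok:
                mass = sum(sub_w[q] for q in picked if tree.is_ancestor_or_self(a, q))
                if sub_w[a] > 0 and mass / sub_w[a] > consensus_margin:
                    ok = False
                a = int(tree.parent[a])
        if ok:
            return [
                PlantedEvent(driver_site, int(d), "A", "V", "driver") for d in picked
            ]
        order = list(rng.permutation(cands))
    return None


# ---------------------------------------------------------------------------
# tumor tables


@dataclass(frozen=True)
class TumorMutationSpec:
    pos: int
    ref: str
    alt: str
    frequency: float
    snp: bool = False
    mut_class: str = "missense"


def _pair_joint(p1: float, p2: float, odds: float) -> float:
    """P(both) for given marginals and odds multiplier (Plackett)."""
    if odds <= 0:
        raise ValueError(f"odds multiplier must be positive, got {odds}")
    if odds == 1.0:
        return p1 * p2
    s = 1.0 + (p1 + p2) * (odds - 1.0)
    disc = s * s - 4.0 * odds * (odds - 1.0) * p1 * p2
    if disc < 0:
        raise ValueError("infeasible marginals/odds combination")
    p11 = (s - np.sqrt(disc)) / (2.0 * (odds - 1.0))
    lo, hi = max(0.0, p1 + p2 - 1.0), min(p1, p2)
    if not (lo - 1e-12 <= p11 <= hi + 1e-12):
        raise ValueError(
            f"odds multiplier {odds} infeasible for marginals {p1}, {p2}"
        )
    return float(np.clip(p11, lo, hi))


def simulate_tumor_table(
    gene: str,
    mutations: list[TumorMutationSpec],
    n_tumors: int,
    rng: np.random.Generator,
    pair_odds: dict[tuple[int, int], float] | None = None,
) -> list[MutationRecord]:
    """Per-tumor Bernoulli presence draws with optional pairwise
    co-occurrence odds multipliers (mutations indexed by their position
    in ``mutations``; each mutation may belong to at most one pair)."""
    pair_odds = pair_odds or {}
    paired = [i for pair in pair_odds for i in pair]
    if len(set(paired)) != len(paired):
        raise ValueError("each mutation may enter at most one odds pair")
    present = np.zeros((n_tumors, len(mutations)), dtype=bool)
    in_pair = set(paired)
    for j, m in enumerate(mutations):
        if j not in in_pair:
            present[:, j] = rng.random(n_tumors) < m.frequency
    for (i, j), odds in pair_odds.items():
        p1, p2 = mutations[i].frequency, mutations[j].frequency
        p11 = _pair_joint(p1, p2, odds)
        u = rng.random(n_tumors)
        # sample the 2x2 cell by inverse CDF: [11, 10, 01, 00]
        c = np.cumsum([p11, p1 - p11, p2 - p11])
        both = u < c[0]
        only1 = (u >= c[0]) & (u < c[1])
        only2 = (u >= c[1]) & (u < c[2])
        present[:, i] = both | only1
        present[:, j] = both | only2
    records = []
    for t in range(n_tumors):
        sample = f"TUMOR{t + 1:05d}"
        for j, m in enumerate(mutations):
            if present[t, j]:
                records.append(
                    MutationRecord(gene, sample, m.ref, m.pos, m.alt, m.snp, m.mut_class)
                )
        if not present[t].any():
            # keep the sample in the table so tumor counts are correct
            records.append(MutationRecord(gene, sample, "A", 1, "A", False, "other"))
    return records


# ---------------------------------------------------------------------------
# structure hit tables


def simulate_hit_table(
    gene: str,
    protein_length: int,
    n_hits: int,
    rng: np.random.Generator,
):
    """Random structure hits: footprints uniform within the protein,
    bit scores proportional to footprint length with noise."""
    from .structure_cover import StructureHit

    hits = []
    for k in range(n_hits):
        start = int(rng.integers(1, max(2, protein_length - 5)))
        end = int(rng.integers(start, protein_length + 1))
        flen = end - start + 1
        bits = float(max(20.0, flen * rng.uniform(0.5, 2.5)))
        hits.append(StructureHit(gene, f"PDB{k + 1:04d}_A", start, end, bits))
    return hits


# ---------------------------------------------------------------------------
# whole families


@dataclass
class SimulatedFamily:
    family: GeneFamily
    log: EventLog
    planted: list[PlantedEvent]
    tumor_records: list[MutationRecord]


def simulate_family(
    config: SimulationConfig,
    planted: list[PlantedEvent] | None = None,
    plant_compensation: bool = False,
) -> SimulatedFamily:
    """One complete synthetic gene family.

    With ``plant_compensation`` a compensator/driver event set
    satisfying the ensemble criteria is planted (sites 0 and 1);
    otherwise only the given ``planted`` events (possibly none) are
    applied. The tumor table marks the planted driver state as the most
    recurrent mutation so the selection stage recovers it.
    """
    rng = np.random.default_rng(config.seed)
    tree = simulate_tree(config.n_leaves, config.birth_rate, rng)
    if plant_compensation:
        if planted is not None:
            raise ValueError("pass either planted events or plant_compensation")
        planted = plant_compensated_driver(tree, rng)
        if planted is None:
            raise ValueError(
                f"tree from seed {config.seed} admits no plantable configuration"
            )
    planted = planted or []
    msa, log = simulate_alignment(
        tree, config.seq_length, config.subst_rate, rng, planted=planted
    )
    taxa = simulate_taxa(tree, config.clade_fractions)
    family = GeneFamily(config.gene, msa, tree, taxa)

    # tumor table: the planted driver (if any) dominates; background
    # mutations fill out the rank distribution
    ref = msa.reference_row
    specs = []
    pair_odds = {}
    driver_events = [e for e in planted if e.role == "driver"]
    if driver_events:
        e = driver_events[0]
        specs.append(
            TumorMutationSpec(e.site + 1, AA_ALPHABET[ref[e.site]], e.der, 0.08)
        )
    n_background = 6
    for b in range(n_background):
        pos = int((b + 2) * config.seq_length / (n_background + 3)) + 1
        ref_aa = AA_ALPHABET[ref[pos - 1]]
        alt = "W" if ref_aa != "W" else "Y"
        specs.append(TumorMutationSpec(pos, ref_aa, alt, 0.01 + 0.005 * b))
    records = simulate_tumor_table(config.gene, specs, 400, rng, pair_odds)
    return SimulatedFamily(family, log, planted, records)
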