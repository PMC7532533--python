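"""Calibration and recovery studies on synthetic families.

These drive both the test suite and the reproduction script: a null
study (driver events placed independently of all other sites) measuring
how often the ensemble search reports a spurious compensatory ensemble,
a recovery study (planted compensator configurations satisfying the
ensemble criteria) measuring how often the planted member set is
returned, and a tumor-table null for the association score.

Study conditions: 48-leaf Yule trees (birth rate 1), 40-column
alignments at substitution rate 0.1 per site per unit branch length;
tumor null tables use two mutations at 0.5% marginal frequency in 1000
tumors — the rare-co-occurrence regime of real tumor mutation tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .association import association_score, cosmic_pair_counts
from .compensation import build_ensembles
from .io_formats import GeneFamily
from .phylo_weights import leaf_weights, reconstruct_all_sites
from .synthetic import (
    SimulationConfig,
    TumorMutationSpec,
    plant_independent_driver,
    simulate_alignment,
    simulate_family,
    simulate_taxa,
    simulate_tree,
    simulate_tumor_table,
)

#: the planted driver state in all planted/null studies: column 0,
#: residue V; the planted compensator state: column 1, residue I
DRIVER_STATE = (0, 17)
COMPENSATOR_STATE = (1, 7)


@dataclass
class StudyResult:
    n_replicates: int
    n_hits: int

    @property
    def rate(self) -> float:
        return self.n_hits / self.n_replicates


def null_ensemble_study(
    n_replicates: int = 200,
    seed: int = 0,
    n_leaves: int = 48,
    seq_length: int = 40,
    subst_rate: float = 0.1,
    p_max: float = 0.01,
) -> StudyResult:
    """Fraction of independently placed drivers that acquire a
    compensatory ensemble with p < p_max (spurious-detection rate)."""
    tested = hits = 0
    stream = seed
    while tested < n_replicates:
        rng = np.random.default_rng(stream)
        stream += 1
        tree = simulate_tree(n_leaves, 1.0, rng)
        events = plant_independent_driver(tree, rng)
        if events is None:
            continue
        msa, _ = simulate_alignment(tree, seq_length, subst_rate, rng, planted=events)
        fam = GeneFamily("NULL", msa, tree, simulate_taxa(tree))
        lw = leaf_weights(tree)
        asg, trans = reconstruct_all_sites(tree, msa, range(msa.n_columns), lw)
        ens = build_ensembles(fam, *DRIVER_STATE, asg, trans, p_max=p_max)
        tested += 1
        if ens is not None:
            hits += 1
    return StudyResult(tested, hits)


def recovery_study(
    n_replicates: int = 100,
    seed: int = 0,
    n_leaves: int = 48,
    seq_length: int = 40,
    subst_rate: float = 0.1,
) -> StudyResult:
    """Fraction of planted single-compensator configurations for which
    the search returns exactly the planted member set."""
    tested = hits = 0
    stream = seed
    while tested < n_replicates:
        cfg = SimulationConfig(
            seed=stream, n_leaves=n_leaves, seq_length=seq_length,
            subst_rate=subst_rate,
        )
        stream += 1
        try:
            sim = simulate_family(cfg, plant_compensation=True)
        except ValueError:
            continue
        fam = sim.family
        lw = leaf_weights(fam.tree)
        asg, trans = reconstruct_all_sites(fam.tree, fam.msa, range(fam.msa.n_columns), lw)
        ens = build_ensembles(fam, *DRIVER_STATE, asg, trans)
        tested += 1
        if ens is not None and set(ens.members) == {COMPENSATOR_STATE}:
            hits += 1
    return StudyResult(tested, hits)


def association_null_study(
    n_replicates: int = 200,
    seed: int = 0,
    n_tumors: int = 1000,
    frequency: float = 0.005,
) -> StudyResult:
    """Fraction of independent (odds multiplier 1) tumor-table pairs
    whose association score magnitude stays within 1."""
    rng = np.random.default_rng(seed)
    specs = [
        TumorMutationSpec(5, "A", "V", frequency),
        TumorMutationSpec(9, "A", "L", frequency),
    ]
    scored = within = 0
    for _ in range(n_replicates):
        recs = simulate_tumor_table("G", specs, n_tumors, rng)
        exp, obs, n = cosmic_pair_counts(recs, "G", (5, "V"), (9, "L"))
        score = association_score(exp, obs) if exp > 0 else None
        if score is None:
            continue
        scored += 1
        if abs(score) <= 1.0:
            within += 1
    return StudyResult(scored, within)
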