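"""End-to-end per-gene orchestration.

Stages run in a fixed order — driver selection, conservation,
leaf weights + ancestral reconstruction, clade statistics,
compensatory ensembles, pair association, structure coverage — and
every stage writes a deterministic TSV report. Genes are processed
independently; the one-ensemble-per-state rule is enforced within a
gene.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import association_quadrants, score_gene_pairs
from .clade_stats import (
    bootstrap_clade_means,
    clade_driver_frequency,
    find_target_clade,
    species_harbors,
)
from .compensation import build_all_ensembles
from .conservation import conservation_table
from .driver_select import compute_ranks, select_drivers
from .io_formats import (
    AA_ALPHABET,
    GeneFamily,
    MAJOR_CLADES,
    MutationRecord,
    check_reference_residues,
)
from .phylo_weights import leaf_weights, reconstruct_all_sites
from .structure_cover import best_pair_structure, best_structure_per_site, score_hits

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Thresholds of the analysis, defaulting to the published
    protocol: driver rank < 20, at most 5 more-frequent distinct
    missense mutations, up to 9 drivers per gene, ensemble
    co-occurrence probability < 1%, driver in at least 4 leaves,
    structure Local Score >= 1.9, 1000 bootstrap resamples."""

    rank_threshold: int = 20
    missense_threshold: int = 5
    max_drivers_per_gene: int = 9
    p_max: float = 0.01
    min_driver_leaves: int = 4
    local_score_min: float = 1.9
    bootstrap_b: int = 1000
    seed: int = 0
    obs_mode: str = "floor"


def run_gene(
    family: GeneFamily,
    tumor_records: list[MutationRecord],
    hits: list | None = None,
    config: RunConfig | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Run the full analysis for one gene; optionally write reports.

    Returns a bundle dict with every stage's table plus summary
    counts. Writing the same bundle twice produces byte-identical
    files.
    """
    config = config or RunConfig()
    msa, tree, taxa, refmap = family.msa, family.tree, family.taxa, family.refmap
    bundle: dict = {"gene": family.gene, "config": asdict(config), "version": __version__}

    # --- driver selection ------------------------------------------------
    records, flagged = check_reference_residues(tumor_records, msa, refmap)
    bundle["n_records"] = len(records)
    bundle["n_flagged_records"] = len(flagged)
    candidates = compute_ranks(records, family.gene)
    drivers = select_drivers(
        candidates,
        config.rank_threshold,
        config.missense_threshold,
        config.max_drivers_per_gene,
    )
    bundle["candidates"] = candidates
    bundle["drivers"] = drivers
    driver_tbl = pd.DataFrame(
        [
            {
                "gene": c.gene, "ref": c.ref_aa, "pos": c.pos, "alt": c.alt_aa,
                "class": c.mut_class, "count": c.tumor_count, "rank": c.rank,
                "n_more_frequent_missense": c.n_more_frequent_missense,
                "selected": c in drivers,
            }
            for c in candidates
        ]
    )
    bundle["driver_table"] = driver_tbl

    # --- conservation ----------------------------------------------------
    vert_rows = [
        msa.row_index(sid) for sid in msa.ids if taxa.clade.get(sid) == "vertebrate"
    ] or None
    cons = conservation_table(msa, taxa, refmap, vert_rows)
    bundle["conservation"] = cons

    # --- weights + ancestry ----------------------------------------------
    weights = leaf_weights(tree)
    bundle["leaf_weights"] = weights
    mapped_columns = [refmap.column_of(p) for p in range(1, refmap.reference_length + 1)]
    assignments, transitions = reconstruct_all_sites(tree, msa, mapped_columns, weights)
    bundle["assignments"] = assignments
    bundle["transitions"] = transitions
    trans_rows = []
    for col in mapped_columns:
        for t in transitions[col]:
            trans_rows.append(
                {
                    "column": col, "ref_pos": refmap.position_of(col),
                    "parent": t.parent, "child": t.child,
                    "from": AA_ALPHABET[t.from_state], "to": AA_ALPHABET[t.to_state],
                }
            )
    bundle["transition_table"] = pd.DataFrame(trans_rows)

    # --- clade statistics -------------------------------------------------
    code_of = {ch: i for i, ch in enumerate(AA_ALPHABET)}
    driver_states = [(refmap.column_of(d.pos), code_of[d.alt_aa]) for d in drivers]
    rng = np.random.default_rng(config.seed)
    clade_rows = []
    for d, (col, res) in zip(drivers, driver_states):
        freqs = []
        for clade in MAJOR_CLADES:
            f = clade_driver_frequency(msa, taxa, weights, clade, col, res)
            if f is not None:
                clade_rows.append(
                    {"pos": d.pos, "alt": d.alt_aa, "clade": clade, "frequency": f}
                )
                freqs.append(f)
        if freqs:
            p25, p50, p75 = bootstrap_clade_means(freqs, config.bootstrap_b, rng)
            clade_rows.append(
                {"pos": d.pos, "alt": d.alt_aa, "clade": "all(bootstrap)",
                 "frequency": p50, "p25": p25, "p75": p75}
            )
    bundle["clade_table"] = pd.DataFrame(clade_rows)

    target_rows = []
    species_paths = {sp: taxa.species_path(sp) for sp in taxa.all_species()}
    for d, (col, res) in zip(drivers, driver_states):
        harb = {
            sp for sp in taxa.all_species() if species_harbors(msa, taxa, sp, col, res)
        }
        if not harb:
            continue
        tc = find_target_clade(species_paths, harb)
        target_rows.append(
            {"pos": d.pos, "alt": d.alt_aa, "target_clade": ";".join(tc.clade),
             "rule": tc.rule, "n_species": tc.n_species}
        )
    bundle["target_clades"] = pd.DataFrame(target_rows)

    # --- compensatory ensembles -------------------------------------------
    ensembles = build_all_ensembles(
        family,
        driver_states,
        assignments,
        transitions,
        config.p_max,
        config.min_driver_leaves,
    )
    bundle["ensembles"] = ensembles
    ens_rows = []
    for (col, res), ens in sorted(ensembles.items()):
        ens_rows.append(
            {
                "driver_pos": refmap.position_of(col),
                "driver_alt": AA_ALPHABET[res],
                "members": ";".join(
                    f"{refmap.position_of(c)}{AA_ALPHABET[r]}" for c, r in ens.members
                ),
                "n_total": ens.n_total, "n_pair": ens.n_pair,
                "F": ens.fraction, "p": ens.p_cooccur,
            }
        )
    bundle["ensemble_table"] = pd.DataFrame(ens_rows)

    # --- association -------------------------------------------------------
    driver_letter_states = [(d.pos, d.alt_aa) for d in drivers]
    assoc = score_gene_pairs(family, records, weights, driver_letter_states,
                             config.obs_mode)
    quadrants = association_quadrants(assoc)
    bundle["associations"] = assoc
    bundle["quadrants"] = {q: len(v) for q, v in quadrants.items()}
    bundle["association_table"] = pd.DataFrame(
        [
            {
                "gene": a.gene, "pos1": a.state1[0], "res1": a.state1[1],
                "pos2": a.state2[0], "res2": a.state2[1],
                "exp_cosmic": a.exp_cosmic, "obs_cosmic": a.obs_cosmic,
                "exp_msa": a.exp_msa, "obs_msa": a.obs_msa,
                "score_cosmic": a.score_cosmic, "score_msa": a.score_msa,
                "kept": a.kept, "quadrant": a.quadrant,
            }
            for a in assoc
        ]
    )

    # --- structures ---------------------------------------------------------
    if hits:
        scored = score_hits(hits, refmap.reference_length)
        site_rows = []
        for d in drivers:
            choice = best_structure_per_site(scored, d.pos)
            if choice is not None:
                site_rows.append(
                    {"pos": d.pos, "alt": d.alt_aa, "structure": choice.structure_id,
                     "global": choice.global_score, "local": choice.local_score}
                )
        pair_rows = []
        for (col, res), ens in sorted(ensembles.items()):
            dpos = refmap.position_of(col)
            for c, r in ens.members:
                mpos = refmap.position_of(c)
                hitpass = best_pair_structure(scored, dpos, mpos, config.local_score_min)
                if hitpass is not None:
                    hit, passing = hitpass
                    pair_rows.append(
                        {"driver_pos": dpos, "member_pos": mpos,
                         "structure": hit.structure_id, "local": hit.local_score,
                         "passing": passing}
                    )
        bundle["site_structures"] = pd.DataFrame(site_rows)
        bundle["pair_structures"] = pd.DataFrame(pair_rows)

    if outdir is not None:
        write_bundle(bundle, outdir)
    return bundle


_TABLES = (
    ("driver_table", "drivers.tsv"),
    ("conservation", "conservation.tsv"),
    ("transition_table", "transitions.tsv"),
    ("clade_table", "clade_frequencies.tsv"),
    ("target_clades", "target_clades.tsv"),
    ("ensemble_table", "ensembles.tsv"),
    ("association_table", "associations.tsv"),
    ("site_structures", "site_structures.tsv"),
    ("pair_structures", "pair_structures.tsv"),
)


def write_bundle(bundle: dict, outdir: str | Path) -> None:
    """Write every stage table plus a run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for key, fname in _TABLES:
        if key in bundle:
            df: pd.DataFrame = bundle[key]
            df.to_csv(outdir / fname, sep="\t", index=False, float_format="%.10g")
    manifest = {
        "gene": bundle["gene"],
        "version": bundle["version"],
        "config": bundle["config"],
        "counts": {
            "records": bundle["n_records"],
            "flagged_records": bundle["n_flagged_records"],
            "candidates": len(bundle["candidates"]),
            "drivers": len(bundle["drivers"]),
            "ensembles": len(bundle["ensembles"]),
            "kept_associations": sum(1 for a in bundle["associations"] if a.kept),
            "quadrants": bundle["quadrants"],
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
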