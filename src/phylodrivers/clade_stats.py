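"""Clade-level prevalence of driver states, bootstrap summaries,
species mode residues, and target-clade identification.

A species "harbors" a driver state when its mode residue (the most
frequent residue over all its sequences, ties broken toward the human
reference residue) at the driver's column equals the driver residue.
The target clade of a driver summarizes where it occurs: the largest
taxonomic group in which more than half of the species harbor the
state, or the smallest group containing more than 90% of all harboring
species, whichever holds fewer species.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io_formats import GAP, Msa, TaxonAnnotation
from .phylo_weights import LeafWeights


def species_mode_residue(
    msa: Msa, taxa: TaxonAnnotation, species: str, column: int
) -> int:
    """Most frequent residue code (gaps included) among the species'
    rows at a column; ties break toward the human-reference residue at
    that column, then toward the lowest code."""
    rows = [sid for sid in taxa.rows_of_species(species) if sid in msa._row_of]
    if not rows:
        raise ValueError(f"species {species!r} has no alignment rows")
    codes = [int(msa.row(sid)[column]) for sid in rows]
    counts = np.bincount(codes, minlength=GAP + 2)
    top = counts.max()
    cands = sorted(int(c) for c in np.nonzero(counts == top)[0])
    ref_code = int(msa.reference_row[column])
    if ref_code in cands:
        return ref_code
    return cands[0]


def species_harbors(
    msa: Msa,
    taxa: TaxonAnnotation,
    species: str,
    column: int,
    residue: int,
    rule: str = "mode",
) -> bool:
    """Whether a species harbors a residue state at a column, by mode
    residue (default) or by any of its sequences."""
    if rule == "mode":
        return species_mode_residue(msa, taxa, species, column) == residue
    if rule == "any":
        return any(
            msa.row(sid)[column] == residue
            for sid in taxa.rows_of_species(species)
            if sid in msa._row_of
        )
    raise ValueError(f"unknown harbor rule {rule!r}")


def clade_driver_frequency(
    msa: Msa,
    taxa: TaxonAnnotation,
    weights: LeafWeights,
    clade: str,
    column: int,
    residue: int,
) -> float | None:
    """Leaf-weighted frequency of a residue state among a clade's rows:
    weight carrying the state over weight non-gap at the column.
    ``None`` when no clade row is non-gap there."""
    num = den = 0.0
    for sid, wt in weights.weights.items():
        if taxa.clade.get(sid) != clade or sid not in msa._row_of:
            continue
        code = msa.row(sid)[column]
        if code >= GAP:
            continue
        den += wt
        if code == residue:
            num += wt
    if den == 0:
        return None
    return num / den


def bootstrap_clade_means(
    frequencies: Sequence[float],
    b: int = 1000,
    seed: int | np.random.Generator = 0,
    percentiles: Sequence[float] = (25, 50, 75),
) -> tuple[float, ...]:
    """Bootstrap-with-replacement percentiles of the mean of a
    frequency set: resample B times, take each resample's mean, return
    the requested percentiles of those means."""
    freqs = np.asarray(frequencies, dtype=float)
    if freqs.size == 0:
        raise ValueError("need at least one frequency value")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, freqs.size, size=(b, freqs.size))
    means = freqs[idx].mean(axis=1)
    return tuple(float(np.percentile(means, p)) for p in percentiles)


@dataclass(frozen=True)
class TargetClade:
    clade: tuple[str, ...]  # taxonomy-path prefix naming the group
    rule: str  # "majority" or "ninety-percent"
    n_species: int


def _taxonomy_nodes(paths: Mapping[str, tuple[str, ...]]):
    """All taxonomy-path prefixes with their species sets."""
    nodes: dict[tuple[str, ...], set[str]] = {}
    for species, path in paths.items():
        for i in range(1, len(path) + 1):
            nodes.setdefault(tuple(path[:i]), set()).add(species)
    return nodes


def find_target_clade(
    species_paths: Mapping[str, tuple[str, ...]],
    harboring_species: set[str],
) -> TargetClade:
    """Target clade of a driver given every species' taxonomy path and
    the set of harboring species.

    clade_A = the largest group (most species) where harboring species
    are a strict majority; clade_B = the smallest group containing
    more than 90% of all harboring species. The one with fewer species
    wins (ties go to the 90%-cover rule); when no group has a
    harboring majority, clade_B is returned.
    """
    if not harboring_species:
        raise ValueError("no harboring species")
    nodes = _taxonomy_nodes(species_paths)
    n_harb = len(harboring_species)

    # ties between nested groups with identical species sets resolve
    # toward the shallower node for the "largest" rule and the deeper
    # (more specific) node for the "smallest" rule
    clade_a = None
    best_a_key = None
    for path, members in sorted(nodes.items()):
        if len(harboring_species & members) * 2 > len(members):
            key = (-len(members), len(path), path)
            if best_a_key is None or key < best_a_key:
                clade_a, best_a_key = path, key
    clade_b = None
    best_b_key = None
    for path, members in sorted(nodes.items()):
        if len(harboring_species & members) > 0.9 * n_harb:
            key = (len(members), -len(path), path)
            if best_b_key is None or key < best_b_key:
                clade_b, best_b_key = path, key
    # clade_b always exists: the root prefix covers all harboring species
    if clade_a is None or len(nodes[clade_b]) <= len(nodes[clade_a]):
        return TargetClade(clade_b, "ninety-percent", len(nodes[clade_b]))
    return TargetClade(clade_a, "majority", len(nodes[clade_a]))


def species_frequency_histogram(
    drivers: Sequence[tuple[int, int]],
    msa: Msa,
    taxa: TaxonAnnotation,
    bins: int = 10,
    rule: str = "mode",
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Histogram of drivers binned by the fraction of species (with the
    site present) harboring the state.

    Drivers whose state is found in zero species fall in the zero bin.
    Returns (counts, bin_edges, per-driver fractions).
    """
    fractions = []
    for column, residue in drivers:
        n_present = n_harb = 0
        for sp in taxa.all_species():
            rows = [sid for sid in taxa.rows_of_species(sp) if sid in msa._row_of]
            if not rows:
                continue
            if all(msa.row(sid)[column] >= GAP for sid in rows):
                continue
            n_present += 1
            if species_harbors(msa, taxa, sp, column, residue, rule):
                n_harb += 1
        fractions.append(n_harb / n_present if n_present else 0.0)
    edges = np.linspace(0.0, 1.0, bins + 1)
    counts, _ = np.histogram(fractions, bins=edges)
    return counts, edges, fractions
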