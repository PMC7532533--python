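"""Column conservation (homogeneity), the tree-building site filter and
deep/shallow site classification.

Homogeneity is a sum-of-pairs column score rescaled linearly so that a
column of residues drawn from the background amino-acid distribution
scores ~0 in expectation and a perfectly uniform column scores 1:

    H = (S - S_rand) / (S_hom - S_rand)

with S the sum-of-pairs substitution-matrix score of the column, S_hom
the score of a homogeneous column of the same depth (by default filled
with the column's consensus residue) and S_rand the analytic expectation
of the score for residues drawn i.i.d. from the background frequencies.
H may fall below 0 for anti-conserved columns and is not clamped.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .io_formats import AA_ALPHABET, GAP, Msa, TaxonAnnotation

UNDEFINED = None

_N_AA = len(AA_ALPHABET)


def load_matrix(name: str = "BLOSUM62") -> np.ndarray:
    """A 20x20 substitution matrix in AA_ALPHABET order."""
    m = substitution_matrices.load(name)
    out = np.zeros((_N_AA, _N_AA))
    for i, a in enumerate(AA_ALPHABET):
        for j, b in enumerate(AA_ALPHABET):
            out[i, j] = m[a, b]
    return out


_BLOSUM62 = load_matrix("BLOSUM62")


def background_frequencies(msa: Msa, row_subset: Sequence[int] | None = None) -> np.ndarray:
    """Empirical amino-acid frequencies of the given rows over the whole
    alignment (gaps and unknowns excluded). Falls back to uniform when
    the rows carry no residues."""
    sub = msa.matrix if row_subset is None else msa.matrix[list(row_subset)]
    counts = np.bincount(sub[sub < GAP].ravel(), minlength=_N_AA).astype(float)
    total = counts.sum()
    if total == 0:
        return np.full(_N_AA, 1.0 / _N_AA)
    return counts / total


def sum_of_pairs(column_codes: np.ndarray, matrix: np.ndarray) -> float:
    """Sum-of-pairs substitution score over the non-gap residues of a
    column (gap/unknown rows contribute nothing)."""
    res = column_codes[column_codes < GAP]
    counts = np.bincount(res, minlength=_N_AA).astype(float)
    # pair counts: off-diagonal c_a*c_b, diagonal c_a choose 2
    s = 0.5 * (counts @ matrix @ counts - (np.diag(matrix) * counts).sum())
    return float(s)


def site_homogeneity(
    msa: Msa,
    column: int,
    row_subset: Sequence[int] | None = None,
    matrix: np.ndarray | None = None,
    background: np.ndarray | None = None,
    hom_residue: str = "consensus",
) -> float | None:
    """Homogeneity of one alignment column over a row subset.

    Returns ``None`` (undefined, distinct from 0) when fewer than two
    rows carry a residue at the column. ``hom_residue`` selects the
    residue filling the hypothetical homogeneous column: the column's
    consensus (default, giving H = 1 for any uniform column) or
    ``"max_self"``, the alphabet residue with the highest self-score.
    """
    if matrix is None:
        matrix = _BLOSUM62
    if background is None:
        background = background_frequencies(msa, row_subset)
    col = msa.column(column) if row_subset is None else msa.matrix[list(row_subset), column]
    res = col[col < GAP]
    n = len(res)
    if n < 2:
        return None
    npairs = n * (n - 1) / 2.0
    s = sum_of_pairs(col, matrix)
    if hom_residue == "consensus":
        counts = np.bincount(res, minlength=_N_AA)
        top = counts.max()
        # most frequent residue; ties toward the higher self-score
        cands = np.nonzero(counts == top)[0]
        consensus = cands[np.argmax(np.diag(matrix)[cands])]
        s_hom = npairs * matrix[consensus, consensus]
    elif hom_residue == "max_self":
        s_hom = npairs * np.diag(matrix).max()
    else:
        raise ValueError(f"unknown hom_residue {hom_residue!r}")
    s_rand = npairs * float(background @ matrix @ background)
    denom = s_hom - s_rand
    if denom == 0:
        return 1.0 if s == s_hom else 0.0
    return float((s - s_rand) / denom)


def homogeneity_track(
    msa: Msa,
    row_subset: Sequence[int] | None = None,
    matrix: np.ndarray | None = None,
    hom_residue: str = "consensus",
) -> list[float | None]:
    """Per-column homogeneity over the whole alignment; undefined
    columns are ``None``."""
    background = background_frequencies(msa, row_subset)
    return [
        site_homogeneity(msa, j, row_subset, matrix, background, hom_residue)
        for j in range(msa.n_columns)
    ]


def neighborhood_homogeneity(track: Sequence[float | None], column: int) -> float | None:
    """Mean homogeneity over the site and its three flanking sites on
    each side; edge columns average over whatever neighbors exist.
    Undefined when no column in the window has a defined value."""
    lo = max(0, column - 3)
    hi = min(len(track), column + 4)
    vals = [track[j] for j in range(lo, hi) if track[j] is not None]
    if not vals:
        return None
    return float(np.mean(vals))


def tree_site_filter(
    msa: Msa,
    max_gap_fraction: float = 0.5,
    min_homogeneity: float = 0.1,
    matrix: np.ndarray | None = None,
) -> list[int]:
    """Columns suitable for tree building: gap fraction <= 50% and
    homogeneity >= 0.1, both computed over all rows. Columns whose
    homogeneity is undefined (fewer than two residues) are excluded."""
    track = homogeneity_track(msa, matrix=matrix)
    kept = []
    gapped = (msa.matrix >= GAP).mean(axis=0)
    for j in range(msa.n_columns):
        if gapped[j] > max_gap_fraction:
            continue
        h = track[j]
        if h is None or h < min_homogeneity:
            continue
        kept.append(j)
    return kept


def classify_site_depth(msa: Msa, taxa: TaxonAnnotation, column: int) -> str:
    """"deep" if at least one fungal or plant row carries a residue at
    the column, "shallow" otherwise."""
    for sid, clade in taxa.clade.items():
        if clade in ("fungus", "plant") and sid in msa._row_of:
            if msa.row(sid)[column] < GAP:
                return "deep"
    return "shallow"


def conservation_table(
    msa: Msa,
    taxa: TaxonAnnotation,
    refmap,
    row_subset: Sequence[int] | None = None,
):
    """Per-column conservation report as a DataFrame: column, ref_pos,
    homogeneity, neighborhood homogeneity, depth class."""
    import pandas as pd

    track = homogeneity_track(msa, row_subset)
    rows = []
    for j in range(msa.n_columns):
        rows.append(
            {
                "column": j,
                "ref_pos": refmap.position_of(j),
                "homogeneity": track[j],
                "neighborhood_homogeneity": neighborhood_homogeneity(track, j),
                "depth_class": classify_site_depth(msa, taxa, j),
            }
        )
    return pd.DataFrame(rows)
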