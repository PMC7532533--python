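"""Pairwise association of mutation states in tumors and in the
leaf-weighted alignment.

For a residue pair, expected and observed co-occurrence counts are
computed in two datasets: tumor samples (counts of samples carrying
each state and both states) and the alignment (leaf weights
renormalized over the sequences non-gap at both columns). The signed
association score, analogous to a log-odds ratio, is a Poisson tail
log-probability:

    Score = -ln(1 - PCDF(exp, obs))   if obs > exp
             ln(PCDF(exp, obs))       if obs < exp
             0                        if obs = exp

with PCDF the Poisson CDF with mean ``exp`` evaluated at ``obs``.
Scores of magnitude <= 1 mean the pair is seen about as often as
expected and are discarded. The tail is evaluated in log space so that
strongly associated pairs (tail probabilities ~1e-30 and below) score
correctly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import poisson

from .io_formats import GAP, Msa, MutationRecord, encode_residues
from .phylo_weights import LeafWeights


def cosmic_pair_counts(
    records: Iterable[MutationRecord],
    gene: str,
    state1: tuple[int, str],
    state2: tuple[int, str],
) -> tuple[float, float, int]:
    """Expected and observed tumor pair counts for two mutation states.

    A state is (reference position, alternate residue). Returns
    (exp, obs, n_tumors) with exp = f1 * f2 * N and obs the number of
    tumor samples carrying both states. N counts the distinct samples
    of the gene's table.
    """
    tumors: set[str] = set()
    has1: set[str] = set()
    has2: set[str] = set()
    for r in records:
        if r.gene != gene:
            continue
        tumors.add(r.sample_id)
        if (r.pos, r.alt_aa) == state1:
            has1.add(r.sample_id)
        if (r.pos, r.alt_aa) == state2:
            has2.add(r.sample_id)
    n = len(tumors)
    if n == 0:
        return 0.0, 0.0, 0
    f1 = len(has1) / n
    f2 = len(has2) / n
    exp = f1 * f2 * n
    obs = len(has1 & has2)
    return exp, float(obs), n


def msa_pair_counts(
    msa: Msa,
    weights: LeafWeights,
    state1: tuple[int, int],
    state2: tuple[int, int],
) -> tuple[float, float, int] | None:
    """Expected and observed leaf-weighted pair counts in the alignment.

    A state is (alignment column, residue code). Over the weighted
    sequences non-gap at both columns, with weights renormalized to sum
    to 1: obs = (sum of weights carrying both residues) * n_nz and
    exp = (sum carrying residue1) * (sum carrying residue2) * n_nz,
    where n_nz is the number of nonzero-weighted qualifying sequences.
    Both may be non-integer. ``None`` when no sequence qualifies.
    """
    (c1, r1), (c2, r2) = state1, state2
    w, a1, a2 = [], [], []
    for sid, wt in weights.weights.items():
        if sid not in msa._row_of:
            continue
        row = msa.row(sid)
        if row[c1] >= GAP or row[c2] >= GAP:
            continue
        w.append(wt)
        a1.append(row[c1] == r1)
        a2.append(row[c2] == r2)
    w = np.asarray(w, dtype=float)
    if w.size == 0 or w.sum() == 0:
        return None
    n_nz = int((w > 0).sum())
    w = w / w.sum()
    a1 = np.asarray(a1)
    a2 = np.asarray(a2)
    obs = float(w[a1 & a2].sum() * n_nz)
    exp = float(w[a1].sum() * w[a2].sum() * n_nz)
    return exp, obs, n_nz


def association_score(exp: float, obs: float, obs_mode: str = "floor") -> float | None:
    """Signed Poisson-tail association score.

    ``obs_mode`` controls how a non-integer observed count enters the
    Poisson CDF: ``floor`` (default), ``round``, or ``continuous``
    (regularized incomplete-gamma interpolation of the CDF). Returns
    ``None`` (undefined) when exp <= 0.
    """
    if exp <= 0:
        return None
    if obs == exp:
        return 0.0
    if obs_mode == "floor":
        k = math.floor(obs)
    elif obs_mode == "round":
        k = round(obs)
    elif obs_mode == "continuous":
        from scipy.special import gammaincc, gammainc

        if obs > exp:
            # -ln P(X > obs) with continuous tail
            tail = gammainc(obs + 1.0, exp)
            return -math.log(tail) if tail > 0 else math.inf
        cdf = gammaincc(obs + 1.0, exp)
        return math.log(cdf) if cdf > 0 else -math.inf
    else:
        raise ValueError(f"unknown obs_mode {obs_mode!r}")
    if obs > exp:
        # 1 - PCDF(exp, k) = P(X > k); logsf avoids catastrophic
        # cancellation for deep upper tails
        return -_log_poisson_sf(k, exp)
    if k == 0:
        return -exp  # ln P(X = 0) exactly
    return float(poisson.logcdf(k, exp))


def _log_poisson_sf(k: int, lam: float) -> float:
    """ln P(X > k) for X ~ Poisson(lam), valid past double underflow.

    scipy's survival function is accurate down to ~1e-308; beyond that
    the tail is summed directly in log space (the underflow regime has
    k >> lam, where the series converges geometrically).
    """
    val = float(poisson.logsf(k, lam))
    if np.isfinite(val):
        return val
    from scipy.special import gammaln, logsumexp

    i = np.arange(k + 1, k + 202)
    log_terms = i * math.log(lam) - lam - gammaln(i + 1)
    return float(logsumexp(log_terms))


@dataclass
class AssociationRecord:
    gene: str
    state1: tuple[int, str]
    state2: tuple[int, str]
    exp_cosmic: float
    obs_cosmic: float
    exp_msa: float | None
    obs_msa: float | None
    score_cosmic: float | None
    score_msa: float | None

    @property
    def kept(self) -> bool:
        """A pair is kept when both scores are defined and have
        magnitude above 1 ("about as frequent as expected" pairs are
        discarded)."""
        return (
            self.score_cosmic is not None
            and self.score_msa is not None
            and abs(self.score_cosmic) > 1.0
            and abs(self.score_msa) > 1.0
        )

    @property
    def quadrant(self) -> str | None:
        if not self.kept:
            return None
        return ("+" if self.score_cosmic > 0 else "-") + (
            "+" if self.score_msa > 0 else "-"
        )


def association_quadrants(records: Sequence[AssociationRecord]) -> dict[str, list[AssociationRecord]]:
    """Kept pairs grouped by the signs of (tumor score, MSA score),
    each quadrant sorted by decreasing combined magnitude."""
    out: dict[str, list[AssociationRecord]] = {"++": [], "--": [], "+-": [], "-+": []}
    for r in records:
        q = r.quadrant
        if q is not None:
            out[q].append(r)
    for q in out:
        out[q].sort(key=lambda r: -(abs(r.score_cosmic) + abs(r.score_msa)))
    return out


def score_gene_pairs(
    gene_family,
    records: list[MutationRecord],
    weights: LeafWeights,
    driver_states: Sequence[tuple[int, str]],
    obs_mode: str = "floor",
) -> list[AssociationRecord]:
    """Score every residue pair with at least one selected driver state
    that co-occurs in at least one tumor or one alignment row.

    States are (reference position, residue letter); positions are
    mapped to alignment columns through the family's reference map.
    """
    gene = gene_family.gene
    msa = gene_family.msa
    refmap = gene_family.refmap
    driver_set = set(driver_states)

    # partner states observed in tumors
    tumor_states: set[tuple[int, str]] = set()
    for r in records:
        if r.gene == gene and r.mut_class == "missense" and r.pos in refmap:
            tumor_states.add((r.pos, r.alt_aa))
    # partner states observed in the alignment at mapped columns
    msa_states: set[tuple[int, str]] = set()
    code_of = {pos: refmap.column_of(pos) for pos, _ in driver_set}
    from .io_formats import AA_ALPHABET

    for pos in {p for p, _ in tumor_states} | {p for p, _ in driver_set}:
        col = refmap.column_of(pos)
        for code in np.unique(msa.matrix[:, col]):
            if code < GAP:
                msa_states.add((pos, AA_ALPHABET[code]))

    universe = tumor_states | msa_states
    out = []
    seen = set()
    for d in sorted(driver_set):
        for other in sorted(universe):
            if other == d:
                continue
            if other[0] == d[0]:
                continue  # same site cannot co-occur in one sequence
            key = tuple(sorted((d, other)))
            if key in seen:
                continue
            seen.add(key)
            exp_c, obs_c, n = cosmic_pair_counts(records, gene, d, other)
            s1 = (refmap.column_of(d[0]), encode_residues(d[1])[0])
            s2 = (refmap.column_of(other[0]), encode_residues(other[1])[0])
            mc = msa_pair_counts(msa, weights, s1, s2)
            if obs_c == 0 and (mc is None or mc[1] == 0):
                continue  # appears in neither dataset as a pair
            score_c = association_score(exp_c, obs_c, obs_mode) if n else None
            if mc is None:
                exp_m = obs_m = score_m = None
            else:
                exp_m, obs_m, _ = mc
                score_m = association_score(exp_m, obs_m, obs_mode)
            out.append(
                AssociationRecord(gene, d, other, exp_c, obs_c, exp_m, obs_m,
                                  score_c, score_m)
            )
    return out
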