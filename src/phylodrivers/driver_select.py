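"""Ranking of tumor mutations and driver-candidate selection.

Every distinct non-SNP mutation of a gene is ranked as 1 + the number of
distinct mutations observed in strictly more tumor samples; ties share a
rank. Driver candidates are the missense mutations with rank below a
threshold (default 20) observed less frequently than at most 5 distinct
missense mutations, truncated to at most 9 per gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .io_formats import MutationRecord


@dataclass(frozen=True)
class DriverCandidate:
    gene: str
    ref_aa: str
    pos: int
    alt_aa: str
    mut_class: str
    tumor_count: int
    rank: int
    n_more_frequent_missense: int

    @property
    def state(self) -> tuple[int, str]:
        """(reference position, alternate residue) — the driver state."""
        return (self.pos, self.alt_aa)


def compute_ranks(records: Iterable[MutationRecord], gene: str) -> list[DriverCandidate]:
    """Rank the distinct non-SNP mutations of one gene by tumor count.

    Tumor count is the number of distinct tumor samples carrying the
    mutation (duplicate (mutation, sample) rows collapse). SNP-flagged
    mutations are excluded before ranking.
    """
    samples: dict[tuple[str, int, str, str], set[str]] = {}
    for r in records:
        if r.gene != gene or r.snp:
            continue
        key = (r.ref_aa, r.pos, r.alt_aa, r.mut_class)
        samples.setdefault(key, set()).add(r.sample_id)
    counts = {k: len(v) for k, v in samples.items()}
    out = []
    for (ref, pos, alt, mclass), c in counts.items():
        n_greater = sum(1 for v in counts.values() if v > c)
        n_missense_greater = sum(
            1 for k2, v in counts.items() if v > c and k2[3] == "missense"
        )
        out.append(
            DriverCandidate(
                gene=gene,
                ref_aa=ref,
                pos=pos,
                alt_aa=alt,
                mut_class=mclass,
                tumor_count=c,
                rank=1 + n_greater,
                n_more_frequent_missense=n_missense_greater,
            )
        )
    out.sort(key=_selection_order)
    return out


def _selection_order(c: DriverCandidate):
    # deterministic: count desc, rank asc, position asc, alt residue
    return (-c.tumor_count, c.rank, c.pos, c.alt_aa)


def select_drivers(
    candidates: Sequence[DriverCandidate],
    rank_threshold: int = 20,
    missense_threshold: int = 5,
    max_per_gene: int = 9,
    strict_rank: bool = True,
) -> list[DriverCandidate]:
    """Apply the driver-candidate thresholds to ranked candidates.

    Keeps missense candidates with rank below ``rank_threshold``
    (strictly, unless ``strict_rank`` is False, which admits equality)
    and with at most ``missense_threshold`` distinct more-frequent
    missense mutations, sorted by tumor count descending and truncated
    to ``max_per_gene``. Nonsense and other classes are never selected.
    """
    ok = []
    for c in candidates:
        if c.mut_class != "missense":
            continue
        rank_ok = c.rank < rank_threshold if strict_rank else c.rank <= rank_threshold
        if rank_ok and c.n_more_frequent_missense <= missense_threshold:
            ok.append(c)
    ok.sort(key=_selection_order)
    return ok[:max_per_gene]
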