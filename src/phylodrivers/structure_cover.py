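"""Structure coverage scoring from tabular search hits.

Each hit of the human reference protein against a structure database
gets a Global Score (bit score / full protein length) and a Local
Score (bit score / query footprint length). Per site, the covering
structure maximizing Global^2 + Local^2 is chosen; per
driver/compensator pair, the covering structure with the highest Local
Score, reported as passing when Local >= 1.9.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: 12-column tabular search output (outfmt-6 dialect)
HIT_COLUMNS = [
    "query", "subject", "identity", "length", "mismatches", "gaps",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


@dataclass(frozen=True)
class StructureHit:
    gene: str
    structure_id: str
    qstart: int  # 1-based closed footprint on the reference
    qend: int
    bitscore: float
    global_score: float = float("nan")
    local_score: float = float("nan")

    def covers(self, pos: int) -> bool:
        return self.qstart <= pos <= self.qend

    @property
    def footprint_length(self) -> int:
        return self.qend - self.qstart + 1


def read_hit_table(path: str | Path) -> list[StructureHit]:
    """Read a 12-column tabular hit file (no header)."""
    df = pd.read_csv(path, sep="\t", names=HIT_COLUMNS, comment="#")
    return [
        StructureHit(
            gene=str(r.query),
            structure_id=str(r.subject),
            qstart=int(r.qstart),
            qend=int(r.qend),
            bitscore=float(r.bitscore),
        )
        for r in df.itertuples(index=False)
    ]


def score_hits(hits: Sequence[StructureHit], protein_length: int) -> list[StructureHit]:
    """Attach Global and Local Scores; zero-length or inverted
    footprints are dropped with a log message."""
    if protein_length <= 0:
        raise ValueError("protein_length must be positive")
    out = []
    for h in hits:
        flen = h.qend - h.qstart + 1
        if flen <= 0:
            logger.info("dropping hit %s with empty footprint", h.structure_id)
            continue
        out.append(
            StructureHit(
                h.gene, h.structure_id, h.qstart, h.qend, h.bitscore,
                global_score=h.bitscore / protein_length,
                local_score=h.bitscore / flen,
            )
        )
    return out


@dataclass(frozen=True)
class SiteStructureChoice:
    position: int
    structure_id: str
    global_score: float
    local_score: float

    @property
    def combined(self) -> float:
        return self.global_score**2 + self.local_score**2


def best_structure_per_site(
    scored_hits: Sequence[StructureHit], position: int
) -> SiteStructureChoice | None:
    """Among hits covering the position, the one maximizing
    Global^2 + Local^2; ties break toward higher Local Score, then
    lexicographic structure id."""
    covering = [h for h in scored_hits if h.covers(position)]
    if not covering:
        return None
    best = sorted(
        covering,
        key=lambda h: (-(h.global_score**2 + h.local_score**2), -h.local_score,
                       h.structure_id),
    )[0]
    return SiteStructureChoice(position, best.structure_id, best.global_score,
                               best.local_score)


def best_pair_structure(
    scored_hits: Sequence[StructureHit],
    pos1: int,
    pos2: int,
    local_min: float = 1.9,
) -> tuple[StructureHit, bool] | None:
    """The covering hit with the highest Local Score encompassing both
    positions, plus whether it passes the Local Score threshold.
    ``None`` when no single hit covers both sites (e.g., a pair split
    across separate domain structures)."""
    covering = [h for h in scored_hits if h.covers(pos1) and h.covers(pos2)]
    if not covering:
        return None
    best = sorted(covering, key=lambda h: (-h.local_score, h.structure_id))[0]
    return best, best.local_score >= local_min
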