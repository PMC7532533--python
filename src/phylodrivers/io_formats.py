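"""Input parsing, validation and coordinate plumbing.

Conventions used throughout the package:

* reference protein positions are 1-based over the ungapped human
  reference row (the tumor-table convention);
* alignment columns are 0-based;
* offset-rule intervals are closed on both ends.

Residues are stored as small integer codes: ``0..19`` the canonical
amino acids in :data:`AA_ALPHABET` order, :data:`GAP` for the gap
character and :data:`UNKNOWN` for everything else (B, Z, X, U, ...).
The unknown code is treated like a gap by every counting operation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
GAP = 20
UNKNOWN = 21
GAP_CHARS = "-."

_CODE_OF = {aa: i for i, aa in enumerate(AA_ALPHABET)}
_CHAR_OF = list(AA_ALPHABET) + ["-", "X"]

MAJOR_CLADES = (
    "vertebrate",
    "invertebrate",
    "protist",
    "fungus",
    "plant",
    "prokaryote",
)


def encode_residues(seq: str) -> np.ndarray:
    """Encode an aligned residue string into integer codes (uppercased)."""
    out = np.empty(len(seq), dtype=np.uint8)
    for i, ch in enumerate(seq.upper()):
        if ch in _CODE_OF:
            out[i] = _CODE_OF[ch]
        elif ch in GAP_CHARS:
            out[i] = GAP
        else:
            out[i] = UNKNOWN
    return out


def decode_residues(codes: np.ndarray) -> str:
    return "".join(_CHAR_OF[c] for c in codes)


class MsaError(ValueError):
    pass


class Msa:
    """A protein multiple sequence alignment with one designated
    human reference row.

    Parameters
    ----------
    ids : sequence of row identifiers (unique, ordered).
    matrix : uint8 array of shape (n_rows, n_columns) of residue codes.
    reference_id : identifier of the human reference row.
    """

    def __init__(self, ids: Sequence[str], matrix: np.ndarray, reference_id: str):
        ids = list(ids)
        matrix = np.asarray(matrix, dtype=np.uint8)
        if matrix.ndim != 2 or matrix.shape[0] != len(ids):
            raise MsaError("matrix shape does not match row ids")
        if len(set(ids)) != len(ids):
            raise MsaError("duplicate sequence ids in alignment")
        if reference_id not in ids:
            raise MsaError(f"reference row {reference_id!r} not in alignment")
        self.ids = ids
        self.matrix = matrix
        self.reference_id = reference_id
        self._row_of = {sid: i for i, sid in enumerate(ids)}

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def row_index(self, seq_id: str) -> int:
        return self._row_of[seq_id]

    def row(self, seq_id: str) -> np.ndarray:
        return self.matrix[self._row_of[seq_id]]

    @property
    def reference_row(self) -> np.ndarray:
        return self.row(self.reference_id)

    def column(self, j: int) -> np.ndarray:
        return self.matrix[:, j]

    def __repr__(self) -> str:  # pragma: no cover
        return f"Msa({self.n_rows} rows x {self.n_columns} columns, ref={self.reference_id!r})"


def read_msa(fasta_path: str | Path, reference_id: str) -> Msa:
    """Read an aligned FASTA file into an :class:`Msa`.

    Residues are uppercased; characters outside the 20 canonical amino
    acids are mapped to the explicit unknown code. A ragged alignment,
    an empty file or a missing reference row is fatal.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise MsaError(f"no sequences in {fasta_path}")
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise MsaError(f"ragged alignment in {fasta_path}: lengths {sorted(lengths)}")
    ids = [r.id for r in records]
    matrix = np.stack([encode_residues(str(r.seq)) for r in records])
    return Msa(ids, matrix, reference_id)


def write_msa(msa: Msa, fasta_path: str | Path) -> None:
    records = [
        SeqRecord(Seq(decode_residues(msa.matrix[i])), id=sid, description="")
        for i, sid in enumerate(msa.ids)
    ]
    SeqIO.write(records, str(fasta_path), "fasta")


class TreeError(ValueError):
    pass


class GeneTree:
    """A rooted gene tree with branch lengths, flattened to arrays.

    Nodes are indexed ``0..n_nodes-1`` in preorder (root first).
    ``parent[i]`` is the parent index (-1 for the root) and ``brlen[i]``
    the length of the branch above node ``i`` (0.0 for the root).
    """

    def __init__(self, dtree: dendropy.Tree):
        nodes = list(dtree.preorder_node_iter())
        index = {id(n): i for i, n in enumerate(nodes)}
        n = len(nodes)
        self.n_nodes = n
        self.parent = np.full(n, -1, dtype=np.int64)
        self.brlen = np.zeros(n, dtype=float)
        self.children: list[list[int]] = [[] for _ in range(n)]
        self.labels: list[str | None] = [None] * n
        for i, node in enumerate(nodes):
            if node.parent_node is not None:
                p = index[id(node.parent_node)]
                self.parent[i] = p
                self.children[p].append(i)
                bl = node.edge.length
                if bl is None:
                    bl = 0.0
                if bl < 0:
                    raise TreeError(f"negative branch length {bl} in tree")
                self.brlen[i] = bl
            if node.taxon is not None:
                self.labels[i] = node.taxon.label
            elif node.label is not None:
                self.labels[i] = node.label
        self.is_leaf = np.array([len(c) == 0 for c in self.children])
        self.leaf_nodes = np.nonzero(self.is_leaf)[0]
        self.leaf_index = {}
        for i in self.leaf_nodes:
            lab = self.labels[i]
            if lab is None:
                raise TreeError("unlabeled leaf in tree")
            if lab in self.leaf_index:
                raise TreeError(f"duplicate leaf label {lab!r}")
            self.leaf_index[lab] = int(i)
        # preorder by construction; postorder is its reverse for this layout
        self.preorder = np.arange(n)
        self.postorder = self.preorder[::-1].copy()
        if len(self.children[0]) > 2:
            logger.info("tree root is multifurcating (%d children); accepted as-is",
                        len(self.children[0]))
        # subtree branch-length totals (branches strictly below each node)
        sub = np.zeros(n, dtype=float)
        for i in self.postorder:
            for c in self.children[i]:
                sub[i] += sub[c] + self.brlen[c]
        self.subtree_length = sub
        self._dtree = dtree

    @property
    def total_length(self) -> float:
        """Sum of all branch lengths (the total tree weight T)."""
        return float(self.brlen.sum())

    @property
    def leaf_labels(self) -> list[str]:
        return [self.labels[i] for i in self.leaf_nodes]

    def subtree_leaves(self, node: int) -> list[int]:
        """Leaf node indices below (or at) ``node``."""
        out, stack = [], [node]
        while stack:
            i = stack.pop()
            if self.is_leaf[i]:
                out.append(i)
            else:
                stack.extend(self.children[i])
        return out

    def is_ancestor_or_self(self, a: int, b: int) -> bool:
        """True if node ``a`` lies on the root path of node ``b`` (or a == b)."""
        while b != -1:
            if b == a:
                return True
            b = int(self.parent[b])
        return False

    def as_newick(self) -> str:
        return self._dtree.as_string(schema="newick", suppress_rooting=True).strip()

    @classmethod
    def from_newick(cls, newick: str) -> "GeneTree":
        dtree = dendropy.Tree.get(data=newick, schema="newick")
        return cls(dtree)


def read_tree(newick_path: str | Path, msa: Msa | None = None) -> GeneTree:
    """Read a rooted Newick tree and validate it against an alignment.

    Leaves absent from the alignment are fatal; alignment rows absent
    from the tree are allowed (they participate in coordinate mapping
    only) and are reported with a warning.
    """
    dtree = dendropy.Tree.get(path=str(newick_path), schema="newick")
    tree = GeneTree(dtree)
    if msa is not None:
        missing = [lab for lab in tree.leaf_labels if lab not in msa._row_of]
        if missing:
            raise TreeError(f"tree leaves absent from alignment: {missing}")
        extra = [sid for sid in msa.ids if sid not in tree.leaf_index]
        if extra:
            logger.warning(
                "%d alignment rows absent from tree (coordinate-only rows): %s",
                len(extra), extra[:5],
            )
    return tree


@dataclass
class TaxonAnnotation:
    """Per-sequence taxonomy: species, major clade and the ordered
    taxonomy path from the root of the classification to the species."""

    species: dict[str, str]
    clade: dict[str, str]
    path: dict[str, tuple[str, ...]]

    def __post_init__(self):
        for sid, cl in self.clade.items():
            if cl not in MAJOR_CLADES:
                raise ValueError(f"unknown major clade {cl!r} for {sid!r}")
        for sid, p in self.path.items():
            if not p:
                raise ValueError(f"empty taxonomy path for {sid!r}")

    def rows_of_species(self, species: str) -> list[str]:
        return [sid for sid, sp in self.species.items() if sp == species]

    def all_species(self) -> list[str]:
        seen, out = set(), []
        for sp in self.species.values():
            if sp not in seen:
                seen.add(sp)
                out.append(sp)
        return out

    def species_path(self, species: str) -> tuple[str, ...]:
        for sid, sp in self.species.items():
            if sp == species:
                return self.path[sid]
        raise KeyError(species)


def read_taxa(tsv_path: str | Path) -> TaxonAnnotation:
    """Read a taxon annotation TSV: seq_id, species, clade, taxonomy_path
    (path elements separated by ``;``, root first)."""
    df = pd.read_csv(tsv_path, sep="\t", dtype=str)
    required = {"seq_id", "species", "clade", "taxonomy_path"}
    if not required.issubset(df.columns):
        raise ValueError(f"taxa table missing columns {required - set(df.columns)}")
    species = dict(zip(df["seq_id"], df["species"]))
    clade = dict(zip(df["seq_id"], df["clade"]))
    path = {
        sid: tuple(p.split(";"))
        for sid, p in zip(df["seq_id"], df["taxonomy_path"])
    }
    return TaxonAnnotation(species, clade, path)


def write_taxa(taxa: TaxonAnnotation, tsv_path: str | Path) -> None:
    rows = [
        {
            "seq_id": sid,
            "species": taxa.species[sid],
            "clade": taxa.clade[sid],
            "taxonomy_path": ";".join(taxa.path[sid]),
        }
        for sid in taxa.species
    ]
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)


@dataclass(frozen=True)
class MutationRecord:
    """One tumor-table row: a protein-level mutation observed in one
    tumor sample, in reference coordinates."""

    gene: str
    sample_id: str
    ref_aa: str
    pos: int
    alt_aa: str
    snp: bool = False
    mut_class: str = "missense"

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.mut_class == "missense" and self.ref_aa == self.alt_aa:
            raise ValueError("missense record with ref == alt")


def read_mutation_table(tsv_path: str | Path) -> list[MutationRecord]:
    """Read a tumor mutation TSV (gene, sample_id, ref_aa, pos, alt_aa,
    snp, class)."""
    df = pd.read_csv(tsv_path, sep="\t", dtype=str)
    records = []
    for row in df.itertuples(index=False):
        records.append(
            MutationRecord(
                gene=row.gene,
                sample_id=row.sample_id,
                ref_aa=row.ref_aa,
                pos=int(row.pos),
                alt_aa=row.alt_aa,
                snp=str(getattr(row, "snp", "False")).lower() in ("1", "true", "yes"),
                mut_class=getattr(row, "mut_class", None) or getattr(row, "_6", "missense"),
            )
        )
    return records


def write_mutation_table(records: Iterable[MutationRecord], tsv_path: str | Path) -> None:
    rows = [
        {
            "gene": r.gene,
            "sample_id": r.sample_id,
            "ref_aa": r.ref_aa,
            "pos": r.pos,
            "alt_aa": r.alt_aa,
            "snp": r.snp,
            "mut_class": r.mut_class,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)


@dataclass(frozen=True)
class OffsetRule:
    """Remap a closed position interval of one gene by a signed offset.

    ``end=None`` means the interval is open-ended (``pos >= start``),
    matching rules written as "pos 136-end".
    """

    gene: str
    start: int
    end: int | None
    offset: int

    def contains(self, pos: int) -> bool:
        return pos >= self.start and (self.end is None or pos <= self.end)


def read_offset_rules(yaml_path: str | Path) -> list[OffsetRule]:
    """Load offset rules from YAML: a mapping gene -> list of
    ``{start, end, offset}`` entries (end omitted or ``end`` for open)."""
    with open(yaml_path) as fh:
        raw = yaml.safe_load(fh) or {}
    rules = []
    for gene, entries in raw.items():
        for e in entries:
            end = e.get("end")
            if end in (None, "end"):
                end = None
            rules.append(OffsetRule(gene, int(e["start"]), end if end is None else int(end),
                                    int(e["offset"])))
    validate_offset_rules(rules)
    return rules


def validate_offset_rules(rules: Sequence[OffsetRule]) -> None:
    """Reject overlapping intervals for any one gene."""
    by_gene: dict[str, list[OffsetRule]] = {}
    for r in rules:
        by_gene.setdefault(r.gene, []).append(r)
    for gene, rs in by_gene.items():
        rs = sorted(rs, key=lambda r: r.start)
        for a, b in zip(rs, rs[1:]):
            a_end = a.end if a.end is not None else float("inf")
            if b.start <= a_end:
                raise ValueError(f"overlapping offset intervals for gene {gene!r}")


def apply_offsets(
    records: Iterable[MutationRecord],
    rules: Sequence[OffsetRule],
    reference_length: int | None = None,
) -> list[MutationRecord]:
    """Shift tumor-record positions by their gene's offset rules.

    Records falling in no rule interval pass through unchanged. When a
    ``reference_length`` is given, shifted positions outside
    ``[1, reference_length]`` are dropped (the count is logged).
    """
    validate_offset_rules(rules)
    by_gene: dict[str, list[OffsetRule]] = {}
    for r in rules:
        by_gene.setdefault(r.gene, []).append(r)
    out, dropped = [], 0
    for rec in records:
        pos = rec.pos
        for rule in by_gene.get(rec.gene, []):
            if rule.contains(rec.pos):
                pos = rec.pos + rule.offset
                break
        if pos < 1 or (reference_length is not None and pos > reference_length):
            dropped += 1
            continue
        if pos != rec.pos:
            rec = MutationRecord(rec.gene, rec.sample_id, rec.ref_aa, pos,
                                 rec.alt_aa, rec.snp, rec.mut_class)
        out.append(rec)
    if dropped:
        logger.info("apply_offsets: dropped %d records outside the reference", dropped)
    return out


class ReferenceMap:
    """Bijection between 1-based ungapped reference positions and
    0-based alignment columns."""

    def __init__(self, pos_to_col: Mapping[int, int]):
        items = sorted(pos_to_col.items())
        positions = [p for p, _ in items]
        columns = [c for _, c in items]
        if positions != list(range(1, len(positions) + 1)):
            raise ValueError("reference positions must be contiguous from 1")
        if any(b <= a for a, b in zip(columns, columns[1:])):
            raise ValueError("columns must be strictly increasing")
        self._pos_to_col = dict(items)
        self._col_to_pos = {c: p for p, c in items}

    def __len__(self) -> int:
        return len(self._pos_to_col)

    @property
    def reference_length(self) -> int:
        return len(self._pos_to_col)

    def column_of(self, pos: int) -> int:
        return self._pos_to_col[pos]

    def position_of(self, column: int) -> int | None:
        return self._col_to_pos.get(column)

    def __contains__(self, pos: int) -> bool:
        return pos in self._pos_to_col

    def items(self):
        return self._pos_to_col.items()


def build_reference_map(msa: Msa) -> ReferenceMap:
    """Map each ungapped residue of the reference row to its column."""
    ref = msa.reference_row
    cols = np.nonzero(ref < GAP)[0]
    return ReferenceMap({i + 1: int(c) for i, c in enumerate(cols)})


def check_reference_residues(
    records: Iterable[MutationRecord], msa: Msa, refmap: ReferenceMap
) -> tuple[list[MutationRecord], list[MutationRecord]]:
    """Split records into (consistent, flagged) by comparing each
    record's reference residue with the reference row at the mapped
    column; out-of-range positions are flagged too."""
    ref = msa.reference_row
    ok, flagged = [], []
    for rec in records:
        if rec.pos not in refmap:
            flagged.append(rec)
            continue
        col = refmap.column_of(rec.pos)
        if decode_residues(ref[col:col + 1]) == rec.ref_aa:
            ok.append(rec)
        else:
            flagged.append(rec)
    if flagged:
        logger.info("reference-residue check: %d records flagged and excluded",
                    len(flagged))
    return ok, flagged


@dataclass
class GeneFamily:
    """Everything the pipeline needs about one gene: alignment, rooted
    tree, taxon annotations and the reference coordinate map."""

    gene: str
    msa: Msa
    tree: GeneTree
    taxa: TaxonAnnotation
    refmap: ReferenceMap = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.refmap is None:
            self.refmap = build_reference_map(self.msa)

    @property
    def tree_rows(self) -> list[str]:
        """Alignment rows that are leaves of the tree (the rows that
        participate in weighting, ancestry and frequency statistics)."""
        return [sid for sid in self.msa.ids if sid in self.tree.leaf_index]
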