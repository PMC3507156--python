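"""Alignment-column conservation mapped to reference numbering.

Consumes a multiple sequence alignment (FASTA or Clustal), maps columns
onto a reference sequence's residue numbering — the wheat serine
carboxypeptidase 2 (CBP2) convention, under which the catalytic triad
reads Ser158/Asp361/His413 — and computes per-column occupancy
percentages with a three-level conservation category.

Producing the alignment is normally an external step (any standard MSA
tool); a small bundled center-star progressive aligner is provided so
the pipeline can run self-contained.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

from Bio import AlignIO, SeqIO

from .superpose import align_sequences_pairwise

__all__ = [
    "Alignment",
    "ColumnProfile",
    "read_alignment",
    "write_alignment_fasta",
    "map_reference_numbering",
    "column_occupancy",
    "classify_conservation",
    "progressive_align",
    "write_conservation_report",
]

AA20 = set("ACDEFGHIKLMNPQRSTVWY")
GAP = "-"
#: Default occupancy threshold (%) separating medium from low conservation.
MEDIUM_THRESHOLD = 60.0


@dataclass
class Alignment:
    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len(self.rows) < 2:
            raise ValueError("an alignment needs at least 2 rows")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            ragged = [i for i, r in zip(self.ids, self.rows)
                      if len(r) != len(self.rows[0])]
            raise ValueError(f"ragged alignment rows: {ragged}")
        for sid, row in zip(self.ids, self.rows):
            if not row.replace(GAP, ""):
                raise ValueError(f"row {sid!r} is all gaps")
            for pos, ch in enumerate(row, start=1):
                if ch not in AA20 and ch not in (GAP, "X"):
                    raise ValueError(
                        f"row {sid!r}: unknown character {ch!r} at position {pos}"
                    )

    @property
    def length(self) -> int:
        return len(self.rows[0])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def column(self, column: int) -> str:
        """1-based column as a string of characters, one per row."""
        if not 1 <= column <= self.length:
            raise IndexError(
                f"column {column} out of range 1..{self.length}"
            )
        return "".join(row[column - 1] for row in self.rows)

    def row(self, seq_id: str) -> str:
        try:
            return self.rows[self.ids.index(seq_id)]
        except ValueError:
            raise KeyError(f"no sequence {seq_id!r} in alignment") from None


@dataclass
class ColumnProfile:
    column: int
    occupancy_pct: float          # full precision; round for display
    modal_residue: str
    category: str                 # invariant | medium | low
    ref_number: int | None = None
    ref_residue: str | None = None

    @property
    def occupancy_rounded(self) -> int:
        return int(round(self.occupancy_pct))


def read_alignment(path: str | Path, format: str = "fasta") -> Alignment:
    """Read a FASTA or Clustal alignment, validating equal row lengths."""
    path = Path(path)
    if format not in ("fasta", "clustal"):
        raise ValueError(f"unknown alignment format {format!r}")
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "fasta":
        # read records directly so a ragged file can name the offender
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"{path}: no sequences")
        ids = [r.id for r in records]
        rows = [str(r.seq).upper().replace(".", GAP) for r in records]
    else:
        aln = AlignIO.read(str(path), "clustal")
        ids = [r.id for r in aln]
        rows = [str(r.seq).upper().replace(".", GAP) for r in aln]
    return Alignment(ids=ids, rows=rows)


def write_alignment_fasta(aln: Alignment, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        for sid, row in zip(aln.ids, aln.rows):
            fh.write(f">{sid}\n{row}\n")
    return path


def map_reference_numbering(
    aln: Alignment, reference_id: str, first_number: int = 1
) -> dict[int, int]:
    """Map alignment columns to the reference row's residue numbers.

    Columns where the reference carries a residue are numbered
    consecutively from *first_number*; reference-gap columns are absent
    from the returned map.
    """
    row = aln.row(reference_id)
    mapping: dict[int, int] = {}
    number = first_number
    for col, ch in enumerate(row, start=1):
        if ch != GAP:
            mapping[col] = number
            number += 1
    return mapping


def classify_conservation(
    occupancy_pct: float, medium_threshold: float = MEDIUM_THRESHOLD
) -> str:
    """invariant at 100%, medium at >= threshold (default 60%), else low."""
    if not 0.0 <= occupancy_pct <= 100.0:
        raise ValueError(f"occupancy {occupancy_pct} outside [0, 100]")
    if occupancy_pct >= 100.0:
        return "invariant"
    if occupancy_pct >= medium_threshold:
        return "medium"
    return "low"


def column_occupancy(
    aln: Alignment,
    column: int,
    residue: str | None = None,
    medium_threshold: float = MEDIUM_THRESHOLD,
) -> ColumnProfile:
    """Occupancy (%) of *residue* — or of the modal residue — at a column.

    Gaps count in the denominator, so occupancy is the percentage of
    aligned sequences carrying the residue at that position.
    """
    col = aln.column(column)
    counts = Counter(ch for ch in col if ch != GAP)
    if counts:
        # modal residue; ties broken alphabetically for determinism
        modal = min(counts, key=lambda ch: (-counts[ch], ch))
    else:
        modal = GAP
    query = residue.upper() if residue is not None else modal
    occ = 100.0 * counts.get(query, 0) / aln.n_rows
    return ColumnProfile(
        column=column,
        occupancy_pct=occ,
        modal_residue=modal,
        category=classify_conservation(occ, medium_threshold),
    )


def conservation_table(
    aln: Alignment,
    reference_id: str | None = None,
    first_number: int = 1,
    medium_threshold: float = MEDIUM_THRESHOLD,
) -> list[ColumnProfile]:
    """Per-column modal-residue occupancy for the whole alignment."""
    mapping = (
        map_reference_numbering(aln, reference_id, first_number)
        if reference_id is not None
        else {}
    )
    ref_row = aln.row(reference_id) if reference_id is not None else None
    profiles = []
    for col in range(1, aln.length + 1):
        prof = column_occupancy(aln, col, medium_threshold=medium_threshold)
        if col in mapping:
            prof.ref_number = mapping[col]
            prof.ref_residue = ref_row[col - 1]
        profiles.append(prof)
    return profiles


def progressive_align(sequences: dict[str, str]) -> Alignment:
    """Center-star progressive multiple alignment.

    The center is the sequence with the greatest summed pairwise
    alignment score to the others; every sequence is aligned to the
    center and the pairwise alignments are merged on center coordinates.
    Adequate as a self-contained fallback for occupancy profiling; a
    dedicated MSA tool is preferable for publication-grade alignments.
    """
    ids = list(sequences)
    if len(ids) < 2:
        raise ValueError("need at least 2 sequences to align")
    seqs = {sid: sequences[sid].upper() for sid in ids}

    # choose the center by summed pairwise alignment scores
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    totals = {sid: 0.0 for sid in ids}
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            score = aligner.score(seqs[a], seqs[b])
            totals[a] += score
            totals[b] += score
    center = max(ids, key=lambda sid: (totals[sid], sid))
    center_seq = seqs[center]
    n_center = len(center_seq)

    # align everything to the center; record, per center gap slot
    # (0..n_center), how many characters each sequence inserts there
    others = [sid for sid in ids if sid != center]
    inserts: dict[str, list[list[str]]] = {}
    matched: dict[str, list[str]] = {}
    max_insert = [0] * (n_center + 1)
    for sid in others:
        corr = align_sequences_pairwise(center_seq, seqs[sid])
        pair_of = dict(corr.pairs)
        ins: list[list[str]] = [[] for _ in range(n_center + 1)]
        row: list[str] = []
        next_j = 0
        for i in range(n_center):
            j = pair_of.get(i)
            if j is None:
                row.append(GAP)
            else:
                ins[i].extend(seqs[sid][next_j:j])
                row.append(seqs[sid][j])
                next_j = j + 1
        ins[n_center].extend(seqs[sid][next_j:])
        inserts[sid] = ins
        matched[sid] = row
        for slot in range(n_center + 1):
            max_insert[slot] = max(max_insert[slot], len(ins[slot]))

    def render(row_chars: list[str], ins: list[list[str]]) -> str:
        out: list[str] = []
        for slot in range(n_center):
            chunk = "".join(ins[slot])
            out.append(chunk + GAP * (max_insert[slot] - len(chunk)))
            out.append(row_chars[slot])
        chunk = "".join(ins[n_center])
        out.append(chunk + GAP * (max_insert[n_center] - len(chunk)))
        return "".join(out)

    rows = {center: render(list(center_seq), [[] for _ in range(n_center + 1)])}
    for sid in others:
        rows[sid] = render(matched[sid], inserts[sid])
    return Alignment(ids=ids, rows=[rows[sid] for sid in ids])


def write_conservation_report(
    profiles: list[ColumnProfile], path: str | Path
) -> Path:
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["column", "ref_number", "ref_residue", "modal_residue",
                    "occupancy_pct", "category"])
        for p in profiles:
            w.writerow([
                p.column,
                "" if p.ref_number is None else p.ref_number,
                "" if p.ref_residue is None else p.ref_residue,
                p.modal_residue,
                p.occupancy_rounded,
                p.category,
            ])
    return path
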