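"""Amino-acid physicochemical class composition.

Molar-percentage composition per physicochemical class — the classic
EMBOSS pepstats grouping — computed per sequence, with a cross-set
outlier rule flagging sequences whose class fraction exceeds the set
mean by more than one sample standard deviation (high side only).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

__all__ = [
    "CLASS_MEMBERS",
    "CLASSES",
    "CompositionProfile",
    "OutlierReport",
    "composition_profile",
    "flag_outliers",
    "read_fasta_sequences",
    "write_composition_report",
]

#: EMBOSS pepstats physicochemical classes over the 20 standard residues.
CLASS_MEMBERS: dict[str, frozenset[str]] = {
    "tiny": frozenset("ACGST"),
    "small": frozenset("ACDGNPSTV"),
    "aliphatic": frozenset("AILV"),
    "aromatic": frozenset("FHWY"),
    "nonpolar": frozenset("ACFGILMPVWY"),
    "polar": frozenset("DEHKNQRST"),
    "charged": frozenset("DEHKR"),
    "basic": frozenset("HKR"),
    "acidic": frozenset("DE"),
}

CLASSES = tuple(CLASS_MEMBERS)
AA20 = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class CompositionProfile:
    sequence_id: str
    length: int                       # standard residues counted
    class_pct: dict[str, float] = field(default_factory=dict)


@dataclass
class OutlierReport:
    """Per class: sequences whose value strictly exceeds mean + SD."""

    flags: dict[str, list[tuple[str, float, float, float]]]
    # (sequence_id, value %, set mean %, set SD %)

    def flagged_ids(self, cls: str) -> list[str]:
        return [sid for sid, *_ in self.flags.get(cls, [])]


def composition_profile(sequence: str, id: str = "") -> CompositionProfile:
    """Molar % of each physicochemical class (residue-count fractions).

    'X' is tolerated but excluded from both numerators and the
    denominator, so percentages always refer to standard residues.
    """
    seq = sequence.upper()
    if not seq:
        raise ValueError("empty sequence")
    bad = sorted({ch for ch in seq if ch not in AA20 and ch != "X"})
    if bad:
        raise ValueError(f"sequence {id!r}: unknown residue codes {bad}")
    standard = [ch for ch in seq if ch in AA20]
    if not standard:
        raise ValueError(f"sequence {id!r}: no standard residues (all X)")
    n = len(standard)
    pct = {
        cls: 100.0 * sum(1 for ch in standard if ch in members) / n
        for cls, members in CLASS_MEMBERS.items()
    }
    return CompositionProfile(sequence_id=id, length=n, class_pct=pct)


def flag_outliers(profiles: list[CompositionProfile]) -> OutlierReport:
    """Flag, per class, profiles strictly above the set mean + one sample SD."""
    if len(profiles) < 3:
        raise ValueError("outlier flagging needs at least 3 profiles")
    flags: dict[str, list[tuple[str, float, float, float]]] = {}
    for cls in CLASSES:
        values = np.array([p.class_pct[cls] for p in profiles])
        mean = float(values.mean())
        sd = float(values.std(ddof=1))
        hits = [
            (p.sequence_id, float(v), mean, sd)
            for p, v in zip(profiles, values)
            if v > mean + sd
        ]
        if hits:
            flags[cls] = hits
    return OutlierReport(flags=flags)


def read_fasta_sequences(path: str | Path) -> dict[str, str]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no sequences")
    return {r.id: str(r.seq).upper() for r in records}


def write_composition_report(
    profiles: list[CompositionProfile],
    report: OutlierReport,
    path: str | Path,
) -> Path:
    """TSV: one row per sequence, one column per class, plus high-outlier flags."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["sequence_id", "length", *CLASSES, "flagged_high"])
        for p in profiles:
            flagged = sorted(
                cls for cls in CLASSES if p.sequence_id in report.flagged_ids(cls)
            )
            w.writerow([
                p.sequence_id,
                p.length,
                *(int(round(p.class_pct[cls])) for cls in CLASSES),
                ",".join(flagged),
            ])
    return path
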