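"""Published per-structure reference values for the SC clan protease set.

The bundled table carries, for each analyzed structure (11 experimental
PDB entries plus 2 predicted models), its taxon, species, percentage of
Cα atoms in the superposed conserved core, core RMSD, and the three
catalytic-triad Cα distances (Asp–His, His–Ser, Ser–Asp) at the
1-decimal precision they were reported at.  These serve as inputs for
cross-taxa summaries and as regression anchors for the pipeline.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

from .triad import TriadGeometry

__all__ = ["ReferenceRow", "load_reference_rows", "reference_triads"]


@dataclass(frozen=True)
class ReferenceRow:
    id: str
    taxa: str
    species: str
    source: str          # experimental | predicted
    superposed_percent: float
    rmsd: float
    d_dh: float
    d_hs: float
    d_sd: float


def load_reference_rows() -> list[ReferenceRow]:
    text = resources.files("triadcore.data").joinpath("triad_reference.tsv").read_text()
    rows = []
    for rec in csv.DictReader(text.splitlines(), delimiter="\t"):
        rows.append(
            ReferenceRow(
                id=rec["id"],
                taxa=rec["taxa"],
                species=rec["species"],
                source=rec["source"],
                superposed_percent=float(rec["superposed_percent"]),
                rmsd=float(rec["rmsd"]),
                d_dh=float(rec["d_dh"]),
                d_hs=float(rec["d_hs"]),
                d_sd=float(rec["d_sd"]),
            )
        )
    return rows


def reference_triads(source: str | None = None) -> list[TriadGeometry]:
    """Reference triad distance triples as :class:`TriadGeometry` objects."""
    return [
        TriadGeometry(structure_id=r.id, d_dh=r.d_dh, d_hs=r.d_hs, d_sd=r.d_sd)
        for r in load_reference_rows()
        if source is None or r.source == source
    ]
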