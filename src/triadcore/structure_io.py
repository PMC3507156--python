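"""Coordinate and sequence input/output.

Reads protein coordinate files in PDB format into a light-weight
chain → residue → atom model, extracts Cα traces and one-letter
sequences, and loads catalytic-triad annotations from a key-value
config.  Author residue numbering (number + insertion code) is kept
verbatim throughout: it is the coordinate convention the downstream
reports use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import gemmi
import numpy as np
import yaml

__all__ = [
    "ResidueRef",
    "Residue",
    "Chain",
    "StructureModel",
    "TriadAnnotation",
    "CaTrace",
    "read_pdb",
    "write_pdb",
    "extract_ca_trace",
    "sequence_from_structure",
    "load_triad_annotations",
    "validate_triad",
]

#: Standard 3-letter → 1-letter amino-acid codes.
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

#: Nonstandard residues kept in the model (sequence letter 'X', Cα used).
NONSTANDARD_KEEP = {"MSE", "SEC", "PYL", "SEP", "TPO", "PTR", "CSO", "MLY"}

_WATER = {"HOH", "WAT", "DOD"}


@dataclass(frozen=True, order=True)
class ResidueRef:
    """Author numbering of a residue: chain, number, insertion code."""

    chain_id: str
    number: int
    icode: str = ""

    def __str__(self) -> str:  # e.g. "A:158" or "A:100A"
        return f"{self.chain_id}:{self.number}{self.icode}"


@dataclass
class Residue:
    ref: ResidueRef
    name: str
    atoms: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def is_standard(self) -> bool:
        return self.name in THREE_TO_ONE

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name, "X")

    def ca(self) -> np.ndarray | None:
        return self.atoms.get("CA")


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def find(self, number: int, icode: str = "") -> Residue | None:
        for res in self.residues:
            if res.ref.number == number and res.ref.icode == icode:
                return res
        return None


@dataclass
class StructureModel:
    id: str
    chains: list[Chain] = field(default_factory=list)
    source: str = "experimental"  # experimental | predicted | synthetic

    def chain(self, chain_id: str) -> Chain:
        for ch in self.chains:
            if ch.chain_id == chain_id:
                return ch
        raise KeyError(
            f"structure {self.id!r} has no chain {chain_id!r} "
            f"(available: {[c.chain_id for c in self.chains]})"
        )

    @property
    def default_chain(self) -> Chain:
        """First chain in file order (used when no chain is configured)."""
        return self.chains[0]


@dataclass
class TriadAnnotation:
    """Names the catalytic Ser/Asp/His of one structure."""

    structure_id: str
    ser: ResidueRef
    asp: ResidueRef
    his: ResidueRef
    source: str = "config"

    def refs(self) -> tuple[ResidueRef, ResidueRef, ResidueRef]:
        return (self.ser, self.asp, self.his)


@dataclass
class CaTrace:
    """Ordered Cα trace of one chain; residues lacking Cα are tallied."""

    entries: list[tuple[ResidueRef, np.ndarray]]
    n_skipped: int = 0

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def coords(self) -> np.ndarray:
        return np.array([xyz for _, xyz in self.entries], dtype=float)

    @property
    def refs(self) -> list[ResidueRef]:
        return [ref for ref, _ in self.entries]


# ---------------------------------------------------------------------------
# PDB reading / writing

def read_pdb(
    path: str | Path,
    model_index: int = 1,
    structure_id: str | None = None,
    source: str = "experimental",
) -> StructureModel:
    """Parse a PDB file into a :class:`StructureModel`.

    Alternate locations are resolved to the highest-occupancy atom
    (ties broken by earliest altloc identifier).  Waters are dropped;
    HETATM residues are kept only when they are standard amino acids
    recorded as heteroatoms (e.g. selenomethionine).

    Parameters
    ----------
    model_index:
        1-based MODEL number to load from multi-model files.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    st = gemmi.read_pdb(str(path))
    if len(st) == 0:
        raise ValueError(f"{path}: no ATOM records")
    if model_index < 1 or model_index > len(st):
        raise ValueError(
            f"{path}: model {model_index} not present ({len(st)} model(s))"
        )
    model = st[model_index - 1]

    out = StructureModel(
        id=structure_id or path.stem, chains=[], source=source
    )
    for gchain in model:
        chain = Chain(chain_id=gchain.name or "A")
        for gres in gchain:
            name = gres.name.strip().upper()
            if name in _WATER:
                continue
            het = gres.het_flag == "H"
            if het and name not in THREE_TO_ONE and name not in NONSTANDARD_KEEP:
                continue
            ref = ResidueRef(
                chain_id=chain.chain_id,
                number=gres.seqid.num,
                icode=(gres.seqid.icode or "").strip(),
            )
            residue = Residue(ref=ref, name=name)
            # altloc resolution: best (occupancy, -altloc) per atom name
            best: dict[str, tuple[float, str]] = {}
            for atom in gres:
                aname = atom.name.strip()
                occ = float(atom.occ)
                alt = atom.altloc or ""
                key = best.get(aname)
                # higher occupancy wins; tie -> earliest altloc letter
                rank = (occ, _alt_rank(alt))
                if key is None or rank > (key[0], _alt_rank(key[1])):
                    best[aname] = (occ, alt)
                    residue.atoms[aname] = np.array(
                        [atom.pos.x, atom.pos.y, atom.pos.z], dtype=float
                    )
            if not np.all(np.isfinite(np.array(list(residue.atoms.values())))):
                raise ValueError(f"{path}: non-finite coordinates in {ref}")
            if residue.atoms:
                chain.residues.append(residue)
        if chain.residues:
            chain.residues.sort(key=lambda r: (r.ref.number, r.ref.icode))
            out.chains.append(chain)
    if not out.chains:
        raise ValueError(f"{path}: no ATOM records")
    return out


def _alt_rank(alt: str) -> float:
    # earliest alphabet letter ranks highest; blank beats everything
    if alt == "":
        return 0.0
    return -ord(alt)


def write_pdb(structure: StructureModel, path: str | Path) -> Path:
    """Write the model back out as fixed-width ATOM records."""
    path = Path(path)
    lines: list[str] = []
    serial = 1
    for chain in structure.chains:
        for res in chain.residues:
            for aname, xyz in res.atoms.items():
                pad = aname if len(aname) >= 4 else f" {aname:<3s}"
                element = aname.lstrip("0123456789")[:1]
                lines.append(
                    f"ATOM  {serial:>5d} {pad}{'':1s}{res.name:>3s} "
                    f"{chain.chain_id:1s}{res.ref.number:>4d}{res.ref.icode or ' ':1s}"
                    f"   {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          {element:>2s}"
                )
                serial += 1
        lines.append(f"TER   {serial:>5d}")
        serial += 1
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# Derived views

def extract_ca_trace(structure: StructureModel, chain_id: str) -> CaTrace:
    """Ordered (ResidueRef, Cα coordinate) pairs for one chain.

    Residues without a Cα atom are skipped and counted, so
    ``len(trace) + trace.n_skipped`` equals the chain's residue count.
    """
    chain = structure.chain(chain_id)
    entries: list[tuple[ResidueRef, np.ndarray]] = []
    skipped = 0
    for res in chain.residues:
        ca = res.ca()
        if ca is None:
            skipped += 1
        else:
            entries.append((res.ref, ca))
    return CaTrace(entries=entries, n_skipped=skipped)


def sequence_from_structure(structure: StructureModel, chain_id: str) -> str:
    """One-letter sequence in chain order; nonstandard residues become 'X'."""
    chain = structure.chain(chain_id)
    return "".join(res.one_letter for res in chain.residues)


# ---------------------------------------------------------------------------
# Triad annotations

def _parse_resnum(raw) -> tuple[int, str]:
    """'120' -> (120, ''); '100A' -> (100, 'A')."""
    s = str(raw).strip()
    icode = ""
    if s and s[-1].isalpha():
        icode = s[-1].upper()
        s = s[:-1]
    return int(s), icode


def load_triad_annotations(config: str | Path) -> dict[str, TriadAnnotation]:
    """Load catalytic-triad annotations from a YAML config.

    The config maps structure ids to ``{chain, ser, asp, his}`` where the
    residue fields carry author residue numbers (optionally with an
    insertion-code suffix, e.g. ``100A``)::

        triads:
          pm0078228:
            chain: A
            ser: 120
            asp: 176
            his: 198
    """
    config = Path(config)
    if not config.exists():
        raise FileNotFoundError(config)
    try:
        doc = yaml.safe_load(config.read_text())
    except yaml.YAMLError as exc:
        raise ValueError(f"{config}: malformed triad config: {exc}") from exc
    if not isinstance(doc, Mapping) or "triads" not in doc:
        raise ValueError(f"{config}: expected a top-level 'triads' mapping")
    out: dict[str, TriadAnnotation] = {}
    for sid, entry in doc["triads"].items():
        missing = {"chain", "ser", "asp", "his"} - set(entry)
        if missing:
            raise ValueError(
                f"{config}: triad entry {sid!r} missing fields {sorted(missing)}"
            )
        chain = str(entry["chain"])
        refs = {}
        for role in ("ser", "asp", "his"):
            num, icode = _parse_resnum(entry[role])
            refs[role] = ResidueRef(chain_id=chain, number=num, icode=icode)
        if len({refs["ser"], refs["asp"], refs["his"]}) != 3:
            raise ValueError(f"{config}: triad entry {sid!r} repeats a residue")
        out[str(sid)] = TriadAnnotation(
            structure_id=str(sid), source="config", **refs
        )
    return out


def validate_triad(structure: StructureModel, annotation: TriadAnnotation) -> None:
    """Check an annotation against a loaded structure.

    Raises if a named residue is absent or lacks a Cα atom.  A residue
    whose type does not match its catalytic role only triggers a warning:
    predicted models may renumber or mutate positions.
    """
    expected = {"ser": "SER", "asp": "ASP", "his": "HIS"}
    for role, ref in zip(("ser", "asp", "his"), annotation.refs()):
        chain = structure.chain(ref.chain_id)
        res = chain.find(ref.number, ref.icode)
        if res is None:
            raise ValueError(
                f"structure {structure.id!r}: triad residue {ref} not found"
            )
        if res.ca() is None:
            raise ValueError(
                f"structure {structure.id!r}: triad residue {ref} has no CA atom"
            )
        if res.name != expected[role]:
            warnings.warn(
                f"structure {structure.id!r}: {ref} annotated as {role} "
                f"but is {res.name}",
                stacklevel=2,
            )


def get_residue(structure: StructureModel, ref: ResidueRef) -> Residue:
    res = structure.chain(ref.chain_id).find(ref.number, ref.icode)
    if res is None:
        raise KeyError(f"structure {structure.id!r}: residue {ref} not found")
    return res
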