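"""Backbone quality control: φ/ψ dihedrals, Ramachandran accounting,
and Cα-geometry secondary-structure assignment.

Dihedrals follow the IUPAC sign convention and are reported in
(−180, 180] degrees.  Region classification uses an embedded 10°×10°
four-level grid over the φ–ψ torus (most favoured / additionally
allowed / generously allowed / disallowed); glycine and proline are
excluded from the accounting, as is conventional for backbone
validation.  Secondary structure is assigned from Cα geometry alone
(P-SEA-style distance and pseudo-torsion windows), which works equally
on full backbones and Cα-only traces.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .structure_io import ResidueRef, StructureModel
from .triad import round_half_away

__all__ = [
    "DihedralRecord",
    "RamachandranReport",
    "SecondaryStructureSummary",
    "dihedral",
    "backbone_dihedrals",
    "classify_ramachandran",
    "ramachandran_report",
    "correct_dihedral_outliers",
    "assign_secondary_structure",
    "count_ss_elements",
    "write_ramachandran_report",
]

REGIONS = ("most_favoured", "additionally_allowed", "generously_allowed", "disallowed")
_GRADE_TO_REGION = {"F": "most_favoured", "A": "additionally_allowed",
                    "G": "generously_allowed", "D": "disallowed"}

#: Residues excluded from Ramachandran accounting.
RAMA_EXCLUDED = {"GLY", "PRO"}

#: Peptide-bond C–N distance (Å) beyond which the chain is treated as broken.
PEPTIDE_BOND_MAX = 2.5

# P-SEA-style windows for Cα-geometry secondary structure
HELIX_D13 = (4.8, 5.8)     # d(i, i+3) window, Å
HELIX_TORSION = (35.0, 75.0)
STRAND_D02 = (6.1, 7.3)    # d(i, i+2) window, Å
STRAND_TORSION = (120.0, 180.0)  # |pseudo-torsion| window


@dataclass
class DihedralRecord:
    ref: ResidueRef
    residue_name: str
    phi: float | None
    psi: float | None


@dataclass
class RamachandranReport:
    counts: dict[str, int]
    percentages: dict[str, float]
    n_assessed: int
    n_excluded: int


@dataclass
class SecondaryStructureSummary:
    states: str                # per-residue H/E/C after min-length filtering
    n_helices: int
    n_strands: int


# ---------------------------------------------------------------------------
# Dihedrals

def dihedral(p0, p1, p2, p3) -> float:
    """Torsion angle p0-p1-p2-p3 in degrees, IUPAC sign, (−180, 180]."""
    b0 = np.asarray(p1, float) - np.asarray(p0, float)
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = float(n1 @ n2)
    y = float(m1 @ n2)
    ang = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if ang <= -180.0 else ang


def backbone_dihedrals(
    structure: StructureModel, chain_id: str
) -> tuple[list[DihedralRecord], int]:
    """φ/ψ per residue of a chain, plus a tally of skipped residues.

    Residues missing any of N/CA/C are skipped.  φ(i) uses C(i−1); ψ(i)
    uses N(i+1); both are undefined at chain termini and across chain
    breaks (peptide C–N distance > 2.5 Å).
    """
    chain = structure.chain(chain_id)
    complete = [r for r in chain.residues
                if all(a in r.atoms for a in ("N", "CA", "C"))]
    skipped = len(chain.residues) - len(complete)
    if len(complete) < 2:
        raise ValueError(
            f"chain {chain_id!r} of {structure.id!r} has fewer than 2 "
            "residues with a complete N/CA/C backbone"
        )

    def bonded(prev, nxt) -> bool:
        return float(np.linalg.norm(nxt.atoms["N"] - prev.atoms["C"])) <= PEPTIDE_BOND_MAX

    records: list[DihedralRecord] = []
    for k, res in enumerate(complete):
        phi = psi = None
        if k > 0 and bonded(complete[k - 1], res):
            phi = dihedral(complete[k - 1].atoms["C"], res.atoms["N"],
                           res.atoms["CA"], res.atoms["C"])
        if k < len(complete) - 1 and bonded(res, complete[k + 1]):
            psi = dihedral(res.atoms["N"], res.atoms["CA"],
                           res.atoms["C"], complete[k + 1].atoms["N"])
        records.append(DihedralRecord(ref=res.ref, residue_name=res.name,
                                      phi=phi, psi=psi))
    return records, skipped


# ---------------------------------------------------------------------------
# Ramachandran regions

def _load_grid() -> list[str]:
    text = resources.files("triadcore.data").joinpath("rama_grid.txt").read_text()
    rows = [ln.strip() for ln in text.splitlines()
            if ln.strip() and not ln.startswith("#")]
    if len(rows) != 36 or any(len(r) != 36 for r in rows):
        raise RuntimeError("embedded Ramachandran grid is malformed")
    return rows


_GRID: list[str] | None = None


def _grid() -> list[str]:
    global _GRID
    if _GRID is None:
        _GRID = _load_grid()
    return _GRID


def _bin(angle: float) -> int:
    # (−180, 180] → bin 0..35; +180 wraps onto the −180 edge cell
    idx = int(np.floor((angle + 180.0) / 10.0))
    return idx % 36


def classify_ramachandran(phi: float, psi: float, residue_name: str = "ALA") -> str:
    """Four-level region of a (φ, ψ) pair from the embedded 10°×10° grid."""
    if phi is None or psi is None:
        raise ValueError("both phi and psi must be defined")
    grade = _grid()[_bin(phi)][_bin(psi)]
    return _GRADE_TO_REGION[grade]


def ramachandran_report(records: list[DihedralRecord]) -> RamachandranReport:
    """Count and percentage per region over the assessable residues.

    Gly, Pro and records with an undefined angle are excluded from the
    denominator.  Percentages are rounded half away from zero at one
    decimal.
    """
    if not records:
        raise ValueError("no dihedral records")
    counts = {region: 0 for region in REGIONS}
    excluded = 0
    for rec in records:
        if rec.residue_name in RAMA_EXCLUDED or rec.phi is None or rec.psi is None:
            excluded += 1
            continue
        counts[classify_ramachandran(rec.phi, rec.psi, rec.residue_name)] += 1
    n = sum(counts.values())
    percentages = {
        region: (round_half_away(100.0 * c / n, 1) if n else 0.0)
        for region, c in counts.items()
    }
    return RamachandranReport(counts=counts, percentages=percentages,
                              n_assessed=n, n_excluded=excluded)


def correct_dihedral_outliers(
    phi_psi: list[tuple[float, float]]
) -> list[tuple[float, float]]:
    """Snap generously-allowed/disallowed (φ, ψ) pairs into the favoured region.

    Mimics constraint-style backbone correction: each outlier pair moves
    to the center of the nearest most-favoured grid cell (toroidal
    distance); favoured/allowed pairs are untouched.
    """
    grid = _grid()
    fav = [(i, j) for i in range(36) for j in range(36) if grid[i][j] == "F"]
    centers = np.array([[-175.0 + 10 * i, -175.0 + 10 * j] for i, j in fav])

    def tor_dist2(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        d = np.abs(a - b)
        d = np.minimum(d, 360.0 - d)
        return (d ** 2).sum(axis=1)

    out: list[tuple[float, float]] = []
    for phi, psi in phi_psi:
        if grid[_bin(phi)][_bin(psi)] in ("F", "A"):
            out.append((phi, psi))
        else:
            k = int(np.argmin(tor_dist2(centers, np.array([phi, psi]))))
            out.append((float(centers[k][0]), float(centers[k][1])))
    return out


# ---------------------------------------------------------------------------
# Secondary structure from Cα geometry

def assign_secondary_structure(ca_trace: np.ndarray) -> str:
    """Per-residue H/E/C states from Cα distances and pseudo-torsions.

    Residue i is helical when d(i, i+3) falls in the helix window and
    the Cα pseudo-torsion (i−1 … i+2) in the helix torsion window;
    strand when d(i, i+2) and |pseudo-torsion| fall in the strand
    windows; otherwise coil.  Helix takes precedence where both match.
    """
    coords = np.asarray(ca_trace, dtype=float)
    n = len(coords)
    if n < 5:
        raise ValueError("Cα trace too short for secondary-structure assignment")
    torsions = np.full(n, np.nan)
    for i in range(1, n - 2):
        torsions[i] = dihedral(coords[i - 1], coords[i], coords[i + 1], coords[i + 2])
    states = []
    for i in range(n):
        state = "C"
        if i >= 1 and i + 3 < n:
            d13 = float(np.linalg.norm(coords[i + 3] - coords[i]))
            if HELIX_D13[0] <= d13 <= HELIX_D13[1] and \
                    HELIX_TORSION[0] <= torsions[i] <= HELIX_TORSION[1]:
                state = "H"
        if state == "C" and i >= 1 and i + 2 < n:
            d02 = float(np.linalg.norm(coords[i + 2] - coords[i]))
            if STRAND_D02[0] <= d02 <= STRAND_D02[1] and \
                    STRAND_TORSION[0] <= abs(torsions[i]) <= STRAND_TORSION[1]:
                state = "E"
        states.append(state)
    return "".join(states)


def count_ss_elements(
    states: str, min_helix: int = 4, min_strand: int = 3
) -> SecondaryStructureSummary:
    """Count maximal H/E runs meeting the minimum lengths; short runs → coil."""
    if not states:
        raise ValueError("empty state string")
    filtered = list(states)
    n_helices = n_strands = 0
    i = 0
    while i < len(states):
        j = i
        while j < len(states) and states[j] == states[i]:
            j += 1
        run, length = states[i], j - i
        if run == "H":
            if length >= min_helix:
                n_helices += 1
            else:
                filtered[i:j] = "C" * length
        elif run == "E":
            if length >= min_strand:
                n_strands += 1
            else:
                filtered[i:j] = "C" * length
        i = j
    return SecondaryStructureSummary(states="".join(filtered),
                                     n_helices=n_helices, n_strands=n_strands)


def write_ramachandran_report(
    reports: dict[str, RamachandranReport], path: str | Path
) -> Path:
    """TSV: one row per labelled report (counts and percentages per region)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        header = ["label", "n_assessed", "n_excluded"]
        for region in REGIONS:
            header += [f"{region}_n", f"{region}_pct"]
        w.writerow(header)
        for label, rep in reports.items():
            row = [label, rep.n_assessed, rep.n_excluded]
            for region in REGIONS:
                row += [rep.counts[region], rep.percentages[region]]
            w.writerow(row)
    return path
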