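"""Synthetic structure, alignment and sequence generators.

Every stage of the pipeline can be exercised without external
downloads: backbones are built from requested φ/ψ lists by forward
kinematics (NeRF chain extension with ideal peptide geometry), Cα
traces from ideal helix/strand parameters, catalytic triads are planted
at exact target distances, conserved cores are planted under controlled
noise with divergent decoy loops, alignment columns are built to
requested occupancies, and sequences to requested physicochemical class
percentages.  All randomness flows through a single integer seed per
call; fixtures can be written out as standard PDB/FASTA with a JSON
ground-truth sidecar so the real parsers are exercised.
"""

from __future__ import annotations

import copy
import json
from pathlib import Path

import numpy as np
from scipy.optimize import LinearConstraint, milp

from .composition import AA20, CLASS_MEMBERS
from .conservation import Alignment
from .structure_io import (
    Chain,
    Residue,
    ResidueRef,
    StructureModel,
    TriadAnnotation,
    write_pdb,
)

__all__ = [
    "IDEAL_GEOMETRY",
    "build_backbone_from_dihedrals",
    "make_ideal_ca_trace",
    "plant_triad",
    "perturb_with_core",
    "make_synthetic_alignment",
    "make_sequence_with_composition",
    "write_structure_fixture",
]

#: Ideal peptide geometry used by the forward-kinematics builder.
IDEAL_GEOMETRY = {
    "bond_n_ca": 1.458,
    "bond_ca_c": 1.525,
    "bond_c_n": 1.329,
    "angle_n_ca_c": 111.2,
    "angle_ca_c_n": 116.2,
    "angle_c_n_ca": 121.7,
    "omega": 180.0,
}

# ideal alpha-helix Cα parameters: radius, rise per residue, turn per residue
HELIX_RADIUS = 2.3
HELIX_RISE = 1.5
HELIX_TURN = 100.0
CA_CA = 3.8


def _place_atom(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """NeRF placement: position D with |CD|=bond, angle(BCD)=angle and
    torsion(ABCD)=torsion (degrees)."""
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    ang = np.radians(angle)
    tor = np.radians(torsion)
    # sign of the n-component chosen so dihedral(A, B, C, D) == torsion
    d2 = bond * np.array(
        [-np.cos(ang), np.sin(ang) * np.cos(tor), -np.sin(ang) * np.sin(tor)]
    )
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def build_backbone_from_dihedrals(
    phi_psi: list[tuple[float, float]],
    residue_names: list[str] | None = None,
    structure_id: str = "synthetic_backbone",
) -> StructureModel:
    """Build an N/CA/C backbone realizing the requested φ/ψ exactly.

    φ of the first residue and ψ of the last are not realizable (they
    need a neighbouring residue) and are ignored.  ω is fixed at 180°.
    """
    if not phi_psi:
        raise ValueError("empty dihedral list")
    n = len(phi_psi)
    if residue_names is None:
        residue_names = ["ALA"] * n
    if len(residue_names) != n:
        raise ValueError("residue_names length mismatch")
    g = IDEAL_GEOMETRY
    coords: list[dict[str, np.ndarray]] = []
    # first residue in a canonical frame
    n0 = np.zeros(3)
    ca0 = np.array([g["bond_n_ca"], 0.0, 0.0])
    ang = np.radians(g["angle_n_ca_c"])
    c0 = ca0 + g["bond_ca_c"] * np.array([-np.cos(ang), np.sin(ang), 0.0])
    coords.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n):
        prev = coords[i - 1]
        psi_prev = phi_psi[i - 1][1]
        n_i = _place_atom(prev["N"], prev["CA"], prev["C"],
                          g["bond_c_n"], g["angle_ca_c_n"], psi_prev)
        ca_i = _place_atom(prev["CA"], prev["C"], n_i,
                           g["bond_n_ca"], g["angle_c_n_ca"], g["omega"])
        c_i = _place_atom(prev["C"], n_i, ca_i,
                          g["bond_ca_c"], g["angle_n_ca_c"], phi_psi[i][0])
        coords.append({"N": n_i, "CA": ca_i, "C": c_i})

    chain = Chain(chain_id="A")
    for i, atoms in enumerate(coords, start=1):
        ref = ResidueRef(chain_id="A", number=i)
        chain.residues.append(
            Residue(ref=ref, name=residue_names[i - 1], atoms=dict(atoms))
        )
    return StructureModel(id=structure_id, chains=[chain], source="synthetic")


def _segment_points(kind: str, length: int) -> np.ndarray:
    """Local coordinates of one ideal secondary-structure segment."""
    t = np.arange(length, dtype=float)
    if kind == "helix":
        # clockwise turn viewed down +z gives the right-handed Cα
        # pseudo-torsion (~ +50 degrees) of a real alpha-helix
        theta = -np.radians(HELIX_TURN) * t
        return np.column_stack(
            [HELIX_RADIUS * np.cos(theta), HELIX_RADIUS * np.sin(theta),
             HELIX_RISE * t]
        )
    if kind == "strand":
        dx = 3.35  # gives d(i,i+2) = 6.7 with CA-CA 3.8
        h = 0.5 * np.sqrt(CA_CA ** 2 - dx ** 2)
        return np.column_stack([dx * t, h * (-1.0) ** t, np.zeros(length)])
    if kind == "loop":
        dx = 2.75  # tighter zigzag: d(i,i+2) = 5.5, outside both windows
        h = 0.5 * np.sqrt(CA_CA ** 2 - dx ** 2)
        return np.column_stack([dx * t, h * (-1.0) ** t, np.zeros(length)])
    raise ValueError(f"unknown segment kind {kind!r}")


def _rot_z(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def make_ideal_ca_trace(
    topology: list[tuple[str, int]],
    structure_id: str = "synthetic_trace",
) -> StructureModel:
    """Cα-only structure realizing a helix/strand/loop topology.

    Helical segments follow ideal α-helix geometry (radius 2.3 Å, rise
    1.5 Å, 100°/residue); strands are planar zigzags with
    d(i, i+2) = 6.7 Å; loops are tighter zigzags falling outside both
    assignment windows.  Segments are chained end-to-end with a turned
    axis per segment.
    """
    if not topology:
        raise ValueError("empty topology")
    if any(length < 1 for _, length in topology):
        raise ValueError("segment lengths must be >= 1")
    points: list[np.ndarray] = []
    end = np.zeros(3)
    for k, (kind, length) in enumerate(topology):
        local = _segment_points(kind, length)
        rot = _rot_z(55.0 * k)
        seg = local @ rot.T
        if points:
            # continue 3.8 Å beyond the previous endpoint, along the new axis
            direction = rot @ np.array([1.0, 0.0, 0.0])
            offset = end + CA_CA * direction - seg[0]
        else:
            offset = -seg[0]
        seg = seg + offset
        points.extend(seg)
        end = seg[-1]
    chain = Chain(chain_id="A")
    for i, xyz in enumerate(points, start=1):
        ref = ResidueRef(chain_id="A", number=i)
        chain.residues.append(
            Residue(ref=ref, name="ALA", atoms={"CA": np.array(xyz)})
        )
    return StructureModel(id=structure_id, chains=[chain], source="synthetic")


def plant_triad(
    structure: StructureModel,
    indices: tuple[int, int, int],
    distances: tuple[float, float, float],
) -> tuple[StructureModel, TriadAnnotation]:
    """Relocate three residues so their Cα distances equal the targets.

    ``indices`` are 0-based positions (Ser, Asp, His order) into the
    flattened residue list; ``distances`` are (Asp–His, His–Ser,
    Ser–Asp) in Å.  Each residue is rigidly translated; the triangle is
    centered on the three original Cα positions.  Residues are renamed
    SER/ASP/HIS and a matching annotation is returned.
    """
    d_dh, d_hs, d_sd = distances
    if len(set(indices)) != 3:
        raise ValueError("triad indices must be distinct")
    for d in distances:
        if d <= 0:
            raise ValueError("triad distances must be positive")
    s = d_dh + d_hs + d_sd
    if any(2 * d > s for d in distances):
        raise ValueError(f"distances {distances} violate the triangle inequality")

    result = copy.deepcopy(structure)
    residues = [r for ch in result.chains for r in ch.residues]
    if max(indices) >= len(residues) or min(indices) < 0:
        raise IndexError("triad index out of range")
    i_ser, i_asp, i_his = indices
    # triangle in a plane: Asp at origin, His on x, Ser by the law of cosines
    asp_t = np.zeros(3)
    his_t = np.array([d_dh, 0.0, 0.0])
    x = (d_sd ** 2 + d_dh ** 2 - d_hs ** 2) / (2.0 * d_dh)
    y2 = d_sd ** 2 - x ** 2
    ser_t = np.array([x, np.sqrt(max(y2, 0.0)), 0.0])
    targets = {i_ser: ser_t, i_asp: asp_t, i_his: his_t}
    # keep the triad where the residues originally sat
    orig = np.array([residues[i].ca() if residues[i].ca() is not None
                     else list(residues[i].atoms.values())[0] for i in indices])
    shift = orig.mean(axis=0) - np.array([ser_t, asp_t, his_t]).mean(axis=0)
    names = {i_ser: "SER", i_asp: "ASP", i_his: "HIS"}
    for idx, target in targets.items():
        res = residues[idx]
        anchor = res.ca() if res.ca() is not None else list(res.atoms.values())[0]
        delta = (target + shift) - anchor
        for aname in res.atoms:
            res.atoms[aname] = res.atoms[aname] + delta
        if "CA" not in res.atoms:
            res.atoms["CA"] = np.array(target + shift)
        res.name = names[idx]
    annotation = TriadAnnotation(
        structure_id=result.id,
        ser=residues[i_ser].ref,
        asp=residues[i_asp].ref,
        his=residues[i_his].ref,
        source="config",
    )
    return result, annotation


def perturb_with_core(
    structure: StructureModel,
    core_mask: np.ndarray,
    noise_sigma: float,
    loop_displacement: float,
    rigid: tuple[np.ndarray, np.ndarray] | None = None,
    seed: int = 0,
) -> tuple[StructureModel, dict]:
    """Rigid-transform a structure, jitter its core, displace its loops.

    Core residues (mask True) receive isotropic Gaussian noise of SD
    *noise_sigma* per atom; non-core residues are additionally pushed a
    distance ≥ *loop_displacement* along a random direction, emulating
    divergent loops outside a structurally conserved core.  Returns the
    perturbed copy and a ground-truth metadata dict.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    result = copy.deepcopy(structure)
    residues = [r for ch in result.chains for r in ch.residues]
    mask = np.asarray(core_mask, dtype=bool)
    if len(mask) != len(residues):
        raise ValueError(
            f"core mask length {len(mask)} != residue count {len(residues)}"
        )
    rng = np.random.default_rng(seed)
    if rigid is None:
        rotation, translation = np.eye(3), np.zeros(3)
    else:
        rotation = np.asarray(rigid[0], float)
        translation = np.asarray(rigid[1], float)
    for res, in_core in zip(residues, mask):
        if in_core:
            for aname in res.atoms:
                xyz = rotation @ res.atoms[aname] + translation
                if noise_sigma > 0:
                    xyz = xyz + rng.normal(0.0, noise_sigma, size=3)
                res.atoms[aname] = xyz
        else:
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            magnitude = loop_displacement * (1.0 + abs(rng.normal(0.0, 0.25)))
            shift = magnitude * direction
            for aname in res.atoms:
                res.atoms[aname] = rotation @ res.atoms[aname] + translation + shift
    metadata = {
        "seed": int(seed),
        "noise_sigma": float(noise_sigma),
        "loop_displacement": float(loop_displacement),
        "core_indices": [int(i) for i in np.flatnonzero(mask)],
        "rotation": rotation.tolist(),
        "translation": translation.tolist(),
    }
    return result, metadata


def make_synthetic_alignment(
    n_rows: int,
    length: int,
    column_spec: list[tuple[str, float]],
    seed: int = 0,
) -> Alignment:
    """Alignment whose columns carry a residue at a requested occupancy.

    Each column spec (residue, fraction) places ``round(fraction × n_rows)``
    copies of the residue in randomly chosen rows; remaining cells are
    drawn uniformly from the other 19 residues.  A residue of ``-``
    plants gaps.
    """
    if len(column_spec) != length:
        raise ValueError("column_spec length must equal alignment length")
    rng = np.random.default_rng(seed)
    letters = sorted(AA20)
    grid = np.empty((n_rows, length), dtype="<U1")
    for col, (residue, fraction) in enumerate(column_spec):
        if not 0.0 <= fraction <= 1.0:
            raise ValueError(f"column {col + 1}: fraction {fraction} outside [0, 1]")
        residue = residue.upper() if residue != "-" else residue
        k = int(round(fraction * n_rows))
        rows = rng.choice(n_rows, size=k, replace=False)
        others = [ch for ch in letters if ch != residue]
        fill = rng.choice(others, size=n_rows)
        fill[rows] = residue
        grid[:, col] = fill
    ids = [f"row{r + 1:02d}" for r in range(n_rows)]
    return Alignment(ids=ids, rows=["".join(grid[r]) for r in range(n_rows)])


def make_sequence_with_composition(
    class_targets: dict[str, float],
    length: int,
    seed: int = 0,
) -> str:
    """A shuffled sequence whose class composition matches the targets.

    Residue counts are found by an integer feasibility solve over the
    class-membership constraints (each target is matched to the nearest
    achievable residue count, i.e. within 100/(2·length) percent).
    Raises ``ValueError`` when no residue multiset can satisfy the
    targets (e.g. two disjoint classes both at 100%).
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    letters = sorted(AA20)
    unknown = set(class_targets) - set(CLASS_MEMBERS)
    if unknown:
        raise ValueError(f"unknown composition classes: {sorted(unknown)}")
    n_var = len(letters)
    constraints = [LinearConstraint(np.ones(n_var), lb=length, ub=length)]
    for cls, target in class_targets.items():
        if not 0.0 <= target <= 100.0:
            raise ValueError(f"target for {cls} outside [0, 100]")
        row = np.array([1.0 if ch in CLASS_MEMBERS[cls] else 0.0 for ch in letters])
        want = target * length / 100.0
        constraints.append(LinearConstraint(row, lb=want - 0.5, ub=want + 0.5))
    res = milp(
        c=np.zeros(n_var),
        constraints=constraints,
        integrality=np.ones(n_var),
        bounds=(0, length),
    )
    if res.status != 0 or res.x is None:
        raise ValueError(f"infeasible composition targets: {class_targets}")
    counts = np.round(res.x).astype(int)
    pool = [ch for ch, k in zip(letters, counts) for _ in range(k)]
    rng = np.random.default_rng(seed)
    rng.shuffle(pool)
    return "".join(pool)


def write_structure_fixture(
    structure: StructureModel,
    out_dir: str | Path,
    ground_truth: dict | None = None,
) -> dict[str, Path]:
    """Write a structure as PDB plus a JSON ground-truth sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pdb_path = out_dir / f"{structure.id}.pdb"
    write_pdb(structure, pdb_path)
    paths = {"pdb": pdb_path}
    if ground_truth is not None:
        sidecar = out_dir / f"{structure.id}.json"
        sidecar.write_text(json.dumps(ground_truth, indent=2, sort_keys=True))
        paths["ground_truth"] = sidecar
    return paths
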