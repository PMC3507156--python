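"""Rigid-body superposition and conserved-core detection.

Residue correspondence between two homologous structures is established
by global sequence alignment of the structure-derived sequences (affine
gaps, BLOSUM62).  The paired Cα coordinates are fitted by the Kabsch
closed-form least-squares rotation (reflections excluded), and the
structurally conserved core is obtained by iteratively refitting after
discarding pairs whose post-fit deviation exceeds a distance cutoff —
1.1 Å is the conventional threshold when comparing a predicted model
against a reference, 1.5 Å for X-ray vs X-ray comparisons.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .structure_io import CaTrace

__all__ = [
    "Correspondence",
    "SuperpositionResult",
    "CoreNotConvergedError",
    "align_sequences_pairwise",
    "kabsch_superpose",
    "detect_conserved_core",
    "write_superposition_report",
]

#: Default cutoff (Å) for predicted-model vs reference core detection.
CUTOFF_PREDICTED = 1.1
#: Default cutoff (Å) for X-ray vs X-ray core detection.
CUTOFF_XRAY = 1.5


@dataclass
class Correspondence:
    """Ordered, collinear pairing of positions in two Cα traces."""

    pairs: list[tuple[int, int]]

    def __post_init__(self) -> None:
        a = [i for i, _ in self.pairs]
        b = [j for _, j in self.pairs]
        if sorted(set(a)) != a or sorted(set(b)) != b:
            raise ValueError("correspondence indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class SuperpositionResult:
    rotation: np.ndarray          # 3x3, det +1
    translation: np.ndarray       # 3-vector, Å
    rmsd: float                   # Å over the fitted pairs
    n_pairs: int
    core_pairs: Correspondence
    superposed_percent: float = 100.0
    n_iterations: int = 1

    def transform(self, coords: np.ndarray) -> np.ndarray:
        """Apply the fitted rigid transform to (n, 3) coordinates."""
        return coords @ self.rotation.T + self.translation


class CoreNotConvergedError(RuntimeError):
    """Core pruning shrank the pair set below the minimum of 3."""

    def __init__(self, message: str, n_iterations: int, last_rmsd: float):
        super().__init__(message)
        self.n_iterations = n_iterations
        self.last_rmsd = last_rmsd


def _make_aligner(gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def align_sequences_pairwise(
    seq_a: str,
    seq_b: str,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> Correspondence:
    """Global pairwise alignment; returns the aligned non-gap position pairs."""
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    aligner = _make_aligner(gap_open, gap_extend)
    alignment = aligner.align(seq_a.upper(), seq_b.upper())[0]
    pairs: list[tuple[int, int]] = []
    for (a_start, a_end), (b_start, b_end) in zip(*alignment.aligned):
        pairs.extend(
            (a_start + k, b_start + k) for k in range(a_end - a_start)
        )
    return Correspondence(pairs=pairs)


def kabsch_superpose(
    moving: np.ndarray, fixed: np.ndarray
) -> SuperpositionResult:
    """Least-squares optimal proper rigid transform of *moving* onto *fixed*.

    Uses the Kabsch SVD construction; when the naive solution would be a
    reflection the smallest singular direction is flipped, so the returned
    rotation always has determinant +1.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape:
        raise ValueError(
            f"point sets differ in shape: {moving.shape} vs {fixed.shape}"
        )
    if moving.ndim != 2 or moving.shape[1] != 3 or moving.shape[0] < 3:
        raise ValueError("need at least 3 paired 3-D points")
    cm = moving.mean(axis=0)
    cf = fixed.mean(axis=0)
    x = moving - cm
    y = fixed - cf
    # collinear (or coincident) points leave the rotation underdetermined
    for pts in (x, y):
        if np.linalg.matrix_rank(pts, tol=1e-8 * max(1.0, np.abs(pts).max())) < 2:
            raise ValueError("degenerate (collinear) point configuration")
    h = x.T @ y
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rotation = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    translation = cf - rotation @ cm
    moved = x @ rotation.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - y) ** 2, axis=1))))
    n = moving.shape[0]
    return SuperpositionResult(
        rotation=rotation,
        translation=translation,
        rmsd=rmsd,
        n_pairs=n,
        core_pairs=Correspondence(pairs=[(i, i) for i in range(n)]),
    )


def detect_conserved_core(
    trace_a: CaTrace | np.ndarray,
    trace_b: CaTrace | np.ndarray,
    correspondence: Correspondence,
    cutoff: float = CUTOFF_PREDICTED,
    max_iter: int = 50,
) -> SuperpositionResult:
    """Iteratively prune a correspondence to the structurally conserved core.

    Fit on the current pair set, drop every pair whose post-fit Cα
    deviation exceeds an annealed threshold — max(*cutoff*, half the
    current worst deviation) — and refit; stop when every retained pair
    is within *cutoff* or *max_iter* is reached.  The annealed schedule
    trims the most divergent loops first, so a fit contaminated by many
    large outliers cannot prematurely discard genuine core residues; at
    convergence the retained set satisfies the plain cutoff rule.
    Pruning is monotone: a dropped pair never re-enters.

    ``trace_a`` is the moving structure: the reported
    ``superposed_percent`` is 100 × retained pairs / length of the
    moving trace.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if len(correspondence) < 3:
        raise ValueError("correspondence must contain at least 3 pairs")
    coords_a = trace_a.coords if isinstance(trace_a, CaTrace) else np.asarray(trace_a, float)
    coords_b = trace_b.coords if isinstance(trace_b, CaTrace) else np.asarray(trace_b, float)
    pairs = list(correspondence.pairs)
    n_moving = len(coords_a)

    result: SuperpositionResult | None = None
    for iteration in range(1, max_iter + 1):
        ia = [i for i, _ in pairs]
        ib = [j for _, j in pairs]
        try:
            result = kabsch_superpose(coords_a[ia], coords_b[ib])
        except ValueError as exc:
            raise CoreNotConvergedError(
                f"core fit degenerate after {iteration - 1} prunings: {exc}",
                n_iterations=iteration,
                last_rmsd=float("nan"),
            ) from exc
        deviations = np.linalg.norm(
            result.transform(coords_a[ia]) - coords_b[ib], axis=1
        )
        # annealed threshold: never discard more than the worst half-band
        # in one sweep, so early contaminated fits cannot drop core pairs
        threshold = max(cutoff, 0.5 * float(deviations.max()))
        keep = deviations <= threshold
        if keep.sum() < 3:
            raise CoreNotConvergedError(
                f"conserved core shrank below 3 pairs at iteration {iteration} "
                f"(cutoff {cutoff} Å, rmsd {result.rmsd:.3f} Å)",
                n_iterations=iteration,
                last_rmsd=result.rmsd,
            )
        if keep.all():
            result.n_iterations = iteration
            break
        pairs = [p for p, k in zip(pairs, keep) if k]
    else:
        result.n_iterations = max_iter

    result.core_pairs = Correspondence(pairs=pairs)
    result.n_pairs = len(pairs)
    result.superposed_percent = 100.0 * len(pairs) / n_moving
    return result


def write_superposition_report(
    rows: list[dict], path: str | Path
) -> Path:
    """TSV report: one row per structure (id, taxa, species, %, RMSD)."""
    path = Path(path)
    columns = ["id", "taxa", "species", "superposed_percent", "rmsd"]
    with path.open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=columns, delimiter="\t",
                                extrasaction="ignore")
        writer.writeheader()
        for row in rows:
            writer.writerow(row)
    return path
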