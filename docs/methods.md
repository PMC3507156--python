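# Methods

This note records the models, conventions and numerical choices behind
`triadcore`, and what the synthetic-data generator does and does not
emulate.

## Structure model and PDB handling

Coordinate files are parsed with gemmi into a minimal
chain → residue → atom model.  Author residue numbering (number plus
insertion code) is kept verbatim and never renumbered: published triad
annotations and conservation tables are expressed in author numbers, so
they are the coordinate system of every report.  Alternate locations
are resolved to the highest-occupancy atom, ties broken by the earliest
altloc letter — deterministic and the common single-conformer
convention.  Waters are dropped; HETATM residues are kept only when
they are amino acids recorded as heteroatoms (MSE and friends), which
contribute their Cα to traces but read as `X` in derived sequences so
the alignment alphabet stays clean.  Multi-chain files default to the
first chain in file order; the analyzed chain should be named in the
run config whenever it matters, since for multimeric entries there is
no universally right default.

## Correspondence and superposition

Residue correspondence between two structures comes from global
pairwise alignment of the structure-derived sequences (BLOSUM62,
gap open 10, gap extend 0.5 — ordinary values for homolog alignment,
fixed in config for reproducibility).  Sequence-based correspondence is
appropriate here because the compared structures are homologs; the
package deliberately does not attempt sequence-independent structural
alignment (DALI/TM-align style).

The rigid-body fit is the closed-form Kabsch solution: SVD of the
cross-covariance of the centered paired coordinates, with the smallest
singular direction flipped whenever the naive optimum would be a
reflection, so the returned matrix is always a proper rotation
(det = +1).  Degenerate inputs — fewer than 3 pairs, or collinear
points, which leave the rotation underdetermined — are rejected.

### Conserved-core detection

The structurally conserved core is found by iterative pruning: fit on
the current pair set, discard pairs whose post-fit deviation exceeds a
threshold, refit, and stop when all retained pairs sit within the
cutoff.  The per-iteration threshold is **annealed**:
`max(cutoff, 0.5 × current worst deviation)`.  A plain
"drop everything above the cutoff in one sweep" rule was evaluated and
rejected: when a third of the residues are loops displaced by several
Å, the first fit is contaminated by those outliers and the one-sweep
rule permanently discards genuine core residues (simulated recall at
σ = 0.2 Å noise, 80-residue core, 40 loop residues, cutoff 1.1 Å drops
to 0.83–0.95 depending on the noise realization).  The annealed
schedule trims the most divergent pairs first, decontaminating the fit
gradually; simulated recall is 1.0 across 200 noise realizations.
Pruning stays monotone (a dropped pair never re-enters) and terminates,
because whenever the worst deviation exceeds the cutoff the worst pair
is always above the threshold.

Default cutoffs: 1.1 Å when a predicted model is compared against a
reference, 1.5 Å for X-ray-vs-X-ray comparisons; both configurable.
The reported `superposed_percent` uses the moving structure's analyzed
chain length as the denominator.  Published coverage/RMSD values from
other software are **not** comparison targets: they depend on an
unpublished atom-selection procedure, so the package reports its own
core statistics and anchors only the trivially reproducible
self-superposition row (100 % at 0.000 Å).

## Triad geometry

The three catalytic-triad distances are Euclidean Cα–Cα distances —
explicitly not side-chain (Oγ/Nε2) distances, which belong to
hydrogen-bond geometry and are out of scope.  Cross-set summaries use
the arithmetic mean and the sample (n−1) standard deviation, with the
convention recorded in the report metadata.  Note that summarizing the
bundled reference table's 1-decimal per-structure values yields SDs of
≈ 0.15–0.2 Å per distance; the much smaller dispersions published
alongside the same means could only have come from unrounded inputs or
a different dispersion measure, so the package's regression anchors
bind to the means, not the SDs.  Report tables round half away from
zero at 1 decimal (with a 1e-6 snap so decimal half-boundaries that
fall a hair low in binary still round up); full precision is kept
internally.

## Conservation

Occupancy of a column is the percentage of aligned sequences carrying
the queried (or modal) residue, with gaps counted in the denominator —
under that convention 10 of 13 sequences give the 77 % figure for the
conserved glycine two positions after the catalytic serine.  Columns
are mapped to reference numbering by walking the reference row and
numbering its non-gap positions consecutively.  Categories: invariant
at exactly 100 %, medium at ≥ 60 % (configurable; no published
definition of "medium" exists, so the threshold is explicit in the
output metadata), low below.  A bundled center-star progressive aligner
(align everything to the highest-scoring center sequence and merge on
center coordinates) keeps self-contained runs possible; it is a
fallback, and a dedicated MSA tool is preferable for production
alignments.

## Composition

Classes follow the EMBOSS pepstats convention: tiny {A,C,G,S,T}, small
{A,C,D,G,N,P,S,T,V}, aliphatic {A,I,L,V}, aromatic {F,H,W,Y}, nonpolar
{A,C,F,G,I,L,M,P,V,W,Y}, polar {D,E,H,K,N,Q,R,S,T}, charged
{D,E,H,K,R}, basic {H,K,R}, acidic {D,E}.  Molar % is a residue-count
fraction; `X` is excluded from numerator and denominator.  The outlier
rule is one-sided and strict — flag a sequence when its class value
exceeds the set mean by more than one sample SD — matching the
"higher proportion" reading; nothing is flagged on the low side.

## Backbone QC

φ(i) is the C(i−1)–N(i)–Cα(i)–C(i) torsion, ψ(i) the
N(i)–Cα(i)–C(i)–N(i+1) torsion, IUPAC sign, reported in (−180°, 180°].
Angles are undefined at chain termini and across chain breaks (peptide
C–N distance > 2.5 Å).  Ramachandran classification uses an embedded
36×36 four-level grid over the φ–ψ torus (`data/rama_grid.txt`,
regenerable by `scripts/make_rama_grid.py`): rectangular core regions
for the right-handed α, β and left-handed α basins, allowed
surroundings including the α/β bridge and ε regions, and a ~20°
generously-allowed margin obtained by toroidal dilation.  The grid is
this package's own versioned approximation of the classic four-level
validation map; it is intentionally a data file so a byte-exact copy of
any particular program's grid can be swapped in.  Gly and Pro are
excluded from the accounting, as their accessible regions differ.
Exact parity with published validation tables of any specific historical
tool is not claimed — those depend on that tool's database-derived grid
and on model states that are not distributed.

`correct_dihedral_outliers` mimics constraint-style backbone
refinement: each (φ, ψ) pair in the generously-allowed or disallowed
levels snaps to the nearest most-favoured cell center (toroidal
distance); favoured/allowed pairs are untouched.  After correction a
chain reports 0 residues in the two outlier levels, the qualitative
signature of dihedral-constrained refinement.

Secondary structure is assigned from Cα geometry alone (in the spirit
of P-SEA), so it works identically on full backbones, Cα-only models
and synthetic traces: helix when d(i, i+3) ∈ [4.8, 5.8] Å and the Cα
pseudo-torsion ∈ [35°, 75°]; strand when d(i, i+2) ∈ [6.1, 7.3] Å and
|pseudo-torsion| ∈ [120°, 180°]; coil otherwise, helix winning ties.
Elements are maximal runs of ≥ 4 H (helix) or ≥ 3 E (strand); shorter
runs relabel to coil.  The assignment is invariant under rigid
transforms but not under trace reversal (the pseudo-torsion is
directional) — a documented asymmetry, not a bug.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *geometric and statistical signatures* the
pipeline measures: rigid cores inside divergent loops, exact triad
distances, exact φ/ψ backbones (NeRF forward kinematics with ideal
bond geometry N–Cα 1.458 Å, Cα–C 1.525 Å, C–N 1.329 Å, ω = 180°), ideal
helix (radius 2.3 Å, rise 1.5 Å, 100°/residue) and strand geometry,
alignment columns at requested occupancies, and sequences whose class
composition is found by an integer feasibility solve (scipy MILP) over
the class-membership constraints.  It does **not** emulate real
side-chain packing, real loop conformational ensembles, evolutionary
substitution patterns within alignments, or physically plausible
all-atom energetics.  Green tests therefore demonstrate that the
*measurement machinery* is correct under controlled truth, not that any
particular biological dataset will reproduce a particular number.
Stand-in inputs built to published figures (e.g. sequences constructed
at 32 % aliphatic, alignments at 10/13 occupancy) are labelled
synthetic wherever they appear.

Determinism: every generator call takes one integer seed feeding a
single `numpy` Generator; the same seed reproduces fixtures
bit-identically, and fixtures are emitted as standard PDB/FASTA so the
real parsers are exercised end to end.

## Problem sizes and defaults in the shipped checks

The test suite and the acceptance script use planted structures of
~120–320 residues, 20 noise realizations for core recovery, 50 random
instances against a 5° brute-force rotation grid for Kabsch optimality,
100 seeds for dihedral round trips, and 1000 random sequences for the
composition partition property — sizes at which the Monte-Carlo
tolerance bands (frozen from 2000-replicate pilot simulations, e.g.
residual RMSD 0.857 ± 0.025 for σ = 0.5 noise on 100 points) are tight.
An occupancy target of 70 % over 13 sequences is not representable
(9/13 = 69.2 %); the checks allow a one-sequence-count discrepancy
there and say so where they do.

## Known limitations

- Sequence-based correspondence degrades for very low sequence
  identity; a structural aligner would be the right tool there.
- The Ramachandran grid is an approximation adequate for four-level
  accounting and planted-count tests, not a drop-in replica of any
  specific validation program.
- The center-star fallback aligner has no iterative refinement; column
  occupancies from it can shift by a sequence or two relative to a
  production MSA tool, which is exactly the sensitivity the occupancy
  checks tolerate.
- The composition outlier rule assumes approximately symmetric spread;
  with n as small as the 13-sequence study set, one extreme value
  inflates the SD and can mask a second outlier.
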