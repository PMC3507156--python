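# triadcore

Structural comparison of SC clan serine proteases — and, more generally,
of homologous protein families sharing a rigid catalytic scaffold inside
divergent surroundings.

Proteases of the SC clan (prolyl oligopeptidases, serine
carboxypeptidases and relatives) share an α/β hydrolase fold whose
catalytic machinery is a Ser/Asp/His triad, in that sequence order.
Across bacteria, archaea, fungi, animals, plants and protozoa the fold's
loops diverge heavily while the triad's Cα geometry stays nearly fixed.
`triadcore` quantifies that picture:

- **Conserved-core superposition** — residue correspondence by global
  sequence alignment (BLOSUM62, affine gaps), least-squares rigid-body
  fitting by the Kabsch construction `R = V diag(1,1,det(VUᵀ)) Uᵀ`
  (reflections excluded), and iterative pruning of pairs whose post-fit
  Cα deviation exceeds a cutoff (1.1 Å for model-vs-reference, 1.5 Å for
  X-ray pairs), yielding the structurally conserved core, its RMSD and
  the percentage of superposed residues.
- **Catalytic-triad geometry** — the three Cα–Cα distances d(Asp–His),
  d(His–Ser), d(Ser–Asp) per structure, summarized as mean ± sample SD
  across experimental and predicted structure sets.
- **Alignment conservation** — per-column occupancy (gaps count in the
  denominator) mapped onto a reference sequence's residue numbering
  (the wheat carboxypeptidase CBP2 convention, under which the triad is
  Ser158/Asp361/His413), with invariant/medium/low categories.
- **Physicochemical composition** — molar % per EMBOSS-style class
  (tiny, small, aliphatic, aromatic, nonpolar, polar, charged, basic,
  acidic) and a one-sided outlier rule flagging sequences more than one
  sample SD above the set mean.
- **Backbone QC** — φ/ψ dihedrals (IUPAC convention), four-level
  Ramachandran accounting over an embedded 10°×10° region grid (Gly/Pro
  excluded), and Cα-geometry secondary-structure assignment with
  helix/strand element counts.
- **Synthetic structures** — a generator that builds backbones from
  dihedrals (NeRF forward kinematics), ideal Cα helices and strands,
  planted triads at exact distances, planted rigid cores under
  controlled noise, alignments with controlled occupancy, and sequences
  with controlled class composition; every analysis is testable offline.

## Worked example

Generate a synthetic dataset — a reference structure with a triad
planted at (4.6, 8.1, 10.5) Å, three rigid-transformed copies whose
loops are displaced ≥ 5 Å while the core only jitters at σ = 0.2 Å, an
alignment with controlled occupancies, and composition-controlled
sequences — then run the full pipeline on it:

```sh
triadcore simulate --seed 3 --out demo
triadcore run demo/run_config.yaml
cat demo/reports/triads.tsv
```

```text
id	taxa	species	source	d_dh	d_hs	d_sd
ref	Synthetica	reference	experimental	4.6	8.1	10.5
model1	Synthetica	variant 1	predicted	4.9	7.9	10.4
model2	Synthetica	variant 2	predicted	5.0	8.0	10.7
model3	Synthetica	variant 3	predicted	4.7	8.2	10.8
mean_experimental			experimental	4.6	8.1	10.5
sd_experimental			experimental	0.0	0.0	0.0
mean_predicted			predicted	4.9	8.1	10.6
sd_predicted			predicted	0.18	0.17	0.21
```

The perturbed copies keep the planted triad geometry to within the core
noise — the same signature of a conserved catalytic site that the real
structure set shows.  The superposition report tells the complementary
story: every copy retains exactly the planted core (48 of 68 residues,
70.59 %) at an RMSD of ~0.35 Å, while the reference-on-itself row reads
100 % at 0.000 Å:

```text
id	taxa	species	superposed_percent	rmsd
ref	Synthetica	reference	100.0	0.0
model1	Synthetica	variant 1	70.59	0.343
model2	Synthetica	variant 2	70.59	0.348
model3	Synthetica	variant 3	70.59	0.347
backbone	Synthetica	backbone demo	nan	nan
```

(The demo also includes a full-backbone chain for the Ramachandran
stage; it shares no core with the Cα fold, so its superposition row is
reported as non-converged — the pipeline keeps going and says why.)

Single-shot commands work on individual files: `triadcore triad
<pdb> --config <triads.yaml>`, `triadcore rama <pdb> --chain A`,
`triadcore compose <fasta>`.

The package also bundles the published per-structure reference table
for the 13-structure SC clan set (11 experimental, 2 predicted) in
`triadcore.reference`; summarizing it reproduces the cross-taxa triad
distance means 4.6/7.9/10.5 Å (experimental) and 4.6/8.2/10.9 Å
(predicted).

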