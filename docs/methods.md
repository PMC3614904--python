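# Methods

This note documents the models, numerical choices and limitations behind
`restrelax`. Energies are in the package's own arbitrary "units"; distances
in Å; angles in degrees.

## Structure model

Structures are single chains of the 20 canonical amino acids, heavy atoms
only. Cleaning removes waters, heteroatom records, non-canonical residues
and hydrogens, re-indexes contiguously (original numbering is kept as
metadata), completes missing template atoms from ideal geometry, and
measures torsions. Alternate locations resolve to the highest-occupancy
conformer (ties by altloc letter), the common crystallographic convention.
Multi-chain files are rejected rather than silently truncated.

Internally every residue carries ideal bond lengths and angles from a
built-in template table (one z-matrix per residue type); the degrees of
freedom are the torsions φ/ψ/χ (ω is held planar at 180°). Cartesian
coordinates are a pure function of the torsion vector given the fixed root
triad (residue 1 N/CA/C), so there are no rigid-body degrees of freedom —
the same convention as a rooted fold tree. Proline's two ring pseudo-χ
values are frozen (the ring closure is a bond in the exclusion graph, not
an energy term), so proline sidechains neither repack nor minimize.

## Energy function

Four channels, each with an explicit closed form:

* **rep** (clash): Σ_pairs (σ_ij/d)¹² − 1 for d < σ_ij, zero at and beyond
  contact, linearized below 0.6 σ_ij so gradients stay bounded.
  σ_ij = r_i + r_j with per-element radii C 1.75, N 1.45, O 1.40, S 1.80 Å.
  "Soft" mode multiplies σ_ij by 0.9 (used in the first design cycle).
* **atr** (packing): a Lennard-Jones well of depth ε = 0.2 with its minimum
  at σ_ij, clamped to −ε inside contact (so it never fights rep), smoothly
  switched off between 5.5 and 6.0 Å. ε was set while developing the design
  stage: at ε = 0.1 packing differences were too small to discriminate
  amino-acid identities at all.
* **rot** (rotamer strain): per χ, ((Δχ)/20°)² to the nearest rotamer well.
  Wells are the staggered triplet (−60, 60, 180) for sp³ torsions and
  (±90) for terminal sp² torsions (Asp/Asn χ2, Glu/Gln χ3, aromatic χ2), so
  a His/Asn/Gln 180° flip maps wells onto wells.
* **cst** (restraints): see below; zero when no restraints are passed.

Pairs separated by ≤ 3 bonds are excluded; pairs at exactly 4 bonds use
σ_ij scaled by 0.85. The attenuation is the usual near-bonded compromise
and is what makes ideal-geometry structures exactly clash-free: without it,
covalently forced 1-5 contacts (the O(i)–C(i+1) peptide pair at 2.89 Å, the
C–CD1 contact of any χ1 = 180 rotamer at 3.2 Å) would register as strain
that no conformational change can relieve.

Pairwise energies split half/half between the two residues for per-residue
reporting, which keeps the decomposition exactly conservative (per-residue
and per-term sums both reproduce the total).

Radii, well assignments and the default ("most common") rotamer table were
fixed once, jointly, under the requirement that ideal helix and ideal
strand conformations of all 20 residue types are contact- and strain-free —
the generator's clean fixtures are exactly zero in rep and rot by
construction, which every defect and every refinement gain is measured
against.

*Not modeled:* solvation, electrostatics, hydrogen bonds, backbone-dependent
rotamer probabilities. Consequences are discussed under Limitations.

## Restraints

Coordinate restraints anchor each selected atom to its cleaned input
position: harmonic f(d) = (d/sd)², or bounded — zero within `width`,
((d−width)/sd)² up to width + sd/2, then linear with slope 1/sd (value 0.25
and matching slope at the junction: the unique quadratic consistent with a
flat/transition/linear layout). The sidechain–sidechain scheme places one
harmonic distance restraint (sd = 2.0) on every unordered cross-residue
sidechain heavy-atom pair within a cutoff, plus backbone coordinate anchors
(sd = 0.5). Intra-residue pairs are not distance-restrained (they are fixed
by the templates). For His/Asn/Gln the terminal-group coordinate restraints
score the better of the two 180°-flip atom assignments, so a chemically
equivalent flip is never penalized.

## Refinement protocol

Five cycles; per cycle the repulsive weight steps through
(0.02, 0.25, 0.55, 1.0); each stage repacks then minimizes. Defaults:

* Repack: per-residue candidates are the input rotamer, its His/Asn/Gln
  flip, and the combinatorial rotamer wells (optionally ±10° sub-samples on
  χ1/χ2 — the "extra rotamers" variant, off by default). Simulated
  annealing with temperature ladder (10, 3, 1, 0.3) units, one pass per
  residue per temperature, Metropolis acceptance, then a zero-temperature
  greedy sweep; if the final assignment is worse than the input the input
  is restored, so repacking never raises the stage objective.
* Minimize: L-BFGS over all active torsions with analytic gradients
  (Cartesian forces projected on rotation axes via suffix-summed torques);
  stage objective includes the restraints at the stage's restraint weight.
  Defaults: gradient tolerance 1e-4, 500 iterations. The best-seen point is
  returned, so minimization is a descent by construction.
* Restraint ramping: off by default (restraints at full weight in every
  stage — appropriate when the restraints *are* the input coordinates);
  when on, the restraint weight steps through (1.0, 0.7, 0.3, 0.0) as the
  repulsive weight ramps up. Ramping is the right choice when a defect is
  held in place by the restraints themselves — the pocket case study below
  is the worked instance.

All stochasticity (annealing order, proposals, acceptance) flows from the
run seed; identical seeds give bit-identical trajectories.

## Metrics and aggregation

All-atom RMSD is over all heavy atoms after Kabsch (SVD, proper-rotation
corrected) superposition on the same atoms, no outlier rejection; a
Cα-only variant exists. An optional flip-aware mode scores His/Asn/Gln
terminal pairs under the better flip assignment, off by default (the plain
number reports flips as real deviation). Replicate sets aggregate as the
median within a structure then the unweighted mean across structures, for
both RMSD and energy/residue; the Pareto front flags points not dominated
in (RMSD, energy) with ties retained.

## Design

Fixed-backbone annealing over (identity × rotamer) at designable positions
and rotamer-only at repackable positions; designable = any heavy atom
within `cut_design` (default 6 Å) of the site, repackable within
`cut_repack` (default 12 Å); the site is a residue-index set or a point
(sites should be residue-based when the structure will be refined first —
a fixed point loses its meaning once the structure moves). Two cycles: soft
repulsion, then standard, each followed by continuous χ minimization. The
native identity and the input rotamer are always among the candidates.

Per-identity reference energies balance identity choices against sidechain
size. They were fitted once, perceptron-style, to maximize native recovery
on the clean fixture suite — the standard way design force fields calibrate
references — and frozen. Clean-context recovery saturates near 0.30: most
surface positions of ideal mini-helices are genuinely interchangeable under
a packing-only energy, which is the ceiling against which recovery changes
are read. Sequence recovery is reported over designable positions.

## Synthetic fixtures

The generator builds ideal-geometry peptides (helix φ/ψ = −57/−47, strand
−120/120), sidechains at the most-common rotamer, and plants three defect
kinds: `clash_rotamer` (χ set to the 60°-grid candidate maximizing the
clash term), `chi_offset` (stated χ1 offset), and `coord_noise` (Gaussian
sidechain displacement, σ in Å). The standard suite has 8 fixtures of
10–30 residues spanning clean helix/strand, single and double clashes,
rotamer offsets, noise, and His/Asn/Gln-containing sequences. The sizing
(10–30 rather than hundreds of residues) is the package's chosen benchmark
scale; the refinement cost per structure grows roughly quadratically with
atom count, and the mini-protein scale already exhibits every mechanism the
protocol is meant to demonstrate. A helix-loop-helix hairpin (24 residues,
loop torsions chosen so the helices pack) provides genuinely buried
positions; its pocket phenylalanine with a planted pocket-blocking neighbor
rotamer is the design case study.

What the fixtures do *not* emulate: real crystallographic noise models
(B-factors, missing density, alternate conformations), hydrogen-bonded
networks, buried polar interactions, and protein sizes where relax
convergence becomes the bottleneck. Passing tests demonstrate the
mechanisms — strain relief under restraints, the energy/RMSD frontier,
recovery degradation from strain — not force-field accuracy on real
proteins.

## Benchmark configuration

The benchmark entry points (`restrelax.benchmarks`) run the relax with
`max_min_iters = 80, min_tolerance = 1e-2` — at mini-protein scale the
stage objectives are converged well past the point where the monitored
quantities (energies per residue, RMSDs, recovery rates) change, and the
full frontier scan (5 settings × 8 fixtures × 10 replicates) completes in
minutes. The case-study benchmark uses constraint ramping (rationale
above); the frontier and recovery benchmarks hold restraints throughout.

## Known limitations

* The energy function is deliberately minimal; absolute energies and
  recovery values are not comparable to any production force field — only
  directions and orderings are meaningful.
* Idealization: structures whose strain is not representable in torsion
  space (e.g. planted Cartesian noise) carry a small irreducible RMSD floor
  (~0.2-0.3 Å at σ = 0.3) between the input and any refined structure.
* Single chains only; no ligands, no symmetry, no multi-model files.
* The packer's rotamer set is well-centered (plus input rotamer); it has no
  backbone-dependent rotamer statistics.
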