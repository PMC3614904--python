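"""Restrained vs unrestrained relax on a mini-protein with a planted clash.

Builds a 16-residue helix in which residue 8 (Phe) is set to its worst
rotamer, then refines it twice: once with all-atom harmonic coordinate
restraints (sd = 0.5 Å) anchored to the input, once without restraints.
The restrained run removes the strain while staying close to the input;
the unrestrained run reaches a lower energy but drifts far away.
"""

from restrelax import (FixtureSpec, RelaxConfig, build_coordinate_restraints,
                       build_peptide, fast_relax, plant_defects, score,
                       write_pdb)

spec = FixtureSpec("AVLSKEAFKSAAQWEL", "helix",
                   defects=[(8, "clash_rotamer", None)], seed=2)
planted = plant_defects(build_peptide(spec), spec)
print(f"input energy: {score(planted).total:10.2f} units "
      f"({score(planted).per_residue_mean:.2f}/residue)")

cfg = RelaxConfig(seed=7, max_min_iters=80, min_tolerance=1e-2)
restraints = build_coordinate_restraints(planted, "all_heavy", "harmonic",
                                         sd=0.5)
restrained = fast_relax(planted, restraints, cfg)
free = fast_relax(planted, None, cfg)

for label, res in (("restrained", restrained), ("unrestrained", free)):
    print(f"{label:>12}: energy {res.final_score.total:8.2f} units, "
          f"all-atom RMSD to input {res.rmsd_to_input:.3f} Å")
write_pdb(restrained.final, "relaxed_restrained.pdb")
print("wrote relaxed_restrained.pdb")
# The restrained RMSD stays in the ~0.1 Å regime (strain removed, structure
# preserved); the unrestrained one typically exceeds 1 Å.
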