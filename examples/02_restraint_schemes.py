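"""The three restraint schemes and their functional forms.

Prints the harmonic and bounded (flat-bottom) coordinate-restraint energies
over distance, and builds the sidechain-sidechain distance scheme on a small
helix. Smaller sd = stiffer restraint; the bounded form is free within
`width`, quadratic for half an sd, then linear with slope 1/sd.
"""

import numpy as np

from restrelax import (FixtureSpec, bounded_energy, build_peptide,
                       build_scsc_restraints, build_coordinate_restraints,
                       harmonic_energy, restraint_energy)

print("displacement  harmonic(sd=0.5)  bounded(sd=0.5,width=0.25)")
for d in np.arange(0.0, 1.51, 0.25):
    print(f"{d:10.2f} {harmonic_energy(d, 0.5):15.3f} "
          f"{bounded_energy(d, 0.5, 0.25):22.3f}")

helix = build_peptide(FixtureSpec("AVLSKEALRSAL", "helix"))
coord = build_coordinate_restraints(helix, "all_heavy", "harmonic", sd=0.5)
scsc = build_scsc_restraints(helix, cutoff=6.0)
print(f"\nall-atom coordinate scheme: {len(coord.coordinate_restraints)} "
      f"restraints (one per heavy atom)")
print(f"sidechain-sidechain scheme: {len(scsc.distance_restraints)} distance "
      f"pairs within 6 Å + {len(scsc.coordinate_restraints)} backbone anchors")
print(f"energy at the anchored input: {restraint_energy(coord, helix):.3f} "
      "(zero by construction)")
scsc.save("restraints.txt")
print("wrote restraints.txt (plain-text, round-trippable)")
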