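"""Deterministic synthetic mini-proteins with planted strain.

Crystal structures entering design pipelines typically score well except for
a handful of high-energy residues (sidechain clashes, off-rotamer torsions,
small coordinate errors). The generator emulates exactly those three defect
channels on ideal-geometry peptides, so the refinement protocol can be
exercised and validated without any external structure files:

* ``clash_rotamer`` — the residue's chi angles are set to the discrete
  candidate that maximizes the clash energy (a badly packed sidechain);
* ``chi_offset`` — a stated offset in degrees is added to chi1 (rotamer
  strain without necessarily clashing);
* ``coord_noise`` — zero-mean Gaussian displacement of the residue's
  sidechain heavy atoms (small coordinate error).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

from . import templates as T
from .energy import score
from .structure import (Structure, StructureError, build_chain,
                        measure_torsions, rebuild_sidechain)

SECONDARY_TORSIONS = {
    "helix": (-57.0, -47.0),
    "strand": (-120.0, 120.0),
    "extended": (180.0, 180.0),
}

# chi samples (60° grid) searched when planting a clash rotamer
CLASH_CHI_SAMPLES = (-120.0, -60.0, 0.0, 60.0, 120.0, 180.0)


@dataclass
class FixtureSpec:
    sequence: str
    secondary: str = "helix"
    defects: list[tuple] = field(default_factory=list)  # (index, kind, param)
    seed: int = 0

    def __post_init__(self):
        if self.secondary not in SECONDARY_TORSIONS:
            raise StructureError(f"unknown secondary {self.secondary!r}")
        bad = set(self.sequence) - set(T.CANONICAL_AAS)
        if bad:
            raise StructureError(f"non-canonical letters in sequence: {bad}")
        for idx, kind, _ in self.defects:
            if not 1 <= idx <= len(self.sequence):
                raise StructureError(f"defect index {idx} outside sequence")
            if kind not in ("clash_rotamer", "chi_offset", "coord_noise"):
                raise StructureError(f"unknown defect kind {kind!r}")


def build_peptide(spec: FixtureSpec) -> Structure:
    """Ideal-geometry chain at the FixtureSpec's secondary-structure torsions,
    every sidechain at its most-common rotamer. Deterministic."""
    phi, psi = SECONDARY_TORSIONS[spec.secondary]
    n = len(spec.sequence)
    return build_chain(spec.sequence, [phi] * n, [psi] * n,
                       [T.default_chis(aa) for aa in spec.sequence],
                       id=f"{spec.secondary}:{spec.sequence}")


def plant_defects(s: Structure, spec: FixtureSpec) -> Structure:
    """Apply the FixtureSpec's defects to a copy of s. The planted structure
    always scores strictly higher than the input (asserted)."""
    out = s.copy()
    rng = np.random.default_rng(spec.seed)
    e_before = score(out).total
    for idx, kind, param in spec.defects:
        res = out.residue(idx)
        if kind in ("clash_rotamer", "chi_offset") and not T.chi_count(res.aa):
            raise StructureError(
                f"defect {kind} needs chi angles; residue {idx} is {res.aa}")
        if kind == "clash_rotamer":
            best, best_rep = None, -1.0
            for combo in product(*(CLASH_CHI_SAMPLES,) * T.chi_count(res.aa)):
                rebuild_sidechain(res, list(combo))
                rep = score(out).by_term["rep"]
                if rep > best_rep:
                    best, best_rep = combo, rep
            rebuild_sidechain(res, list(best))
        elif kind == "chi_offset":
            chi = list(res.chi)
            chi[0] += float(param)
            rebuild_sidechain(res, chi)
        else:  # coord_noise
            for a in res.atoms:
                if not a.is_backbone:
                    a.coord = a.coord + rng.normal(0.0, float(param), 3)
    measure_torsions(out)
    if spec.defects:
        e_after = score(out).total
        assert e_after > e_before, "defects failed to raise the energy"
    return out


@dataclass
class Fixture:
    name: str
    structure: Structure
    clean: Structure            # defect-free parent (== structure when clean)
    defective: bool


def _make(name: str, seq: str, secondary: str, defects: list[tuple],
          seed: int) -> Fixture:
    spec = FixtureSpec(seq, secondary, defects, seed)
    clean = build_peptide(spec)
    if defects:
        return Fixture(name, plant_defects(clean, spec), clean, True)
    return Fixture(name, clean, clean, False)


HAIRPIN_LOOP = ((-60.0, -30.0), (60.0, 60.0), (-90.0, 0.0), (-60.0, -30.0))


def build_hairpin(sequence: str, n_helix1: int = 10, n_loop: int = 4,
                  loop_torsions=HAIRPIN_LOOP, id: str = "hairpin") -> Structure:
    """Helix-loop-helix mini-protein: two 10-residue helices connected by a
    4-residue loop whose torsions pack the helices against each other,
    creating genuinely buried sidechain positions."""
    n = len(sequence)
    n2 = n - n_helix1 - n_loop
    if n2 <= 0 or len(loop_torsions) != n_loop:
        raise StructureError("hairpin sequence/loop lengths inconsistent")
    phi = [-57.0] * n_helix1 + [p for p, _ in loop_torsions] + [-57.0] * n2
    psi = [-47.0] * n_helix1 + [s for _, s in loop_torsions] + [-47.0] * n2
    return build_chain(sequence, phi, psi,
                       [T.default_chis(aa) for aa in sequence], id=id)


@dataclass
class CaseStudyFixture:
    """A buried-native design case: the pocket phenylalanine (residue 8 of
    helix 1) is natively packed against helix 2, and a neighboring glutamine
    (residue 17) is planted rotated across the pocket mouth. On the rigid
    input no Phe rotamer fits, so fixed-backbone design replaces it; after
    restrained relax clears the pocket the native Phe is preferred again."""
    structure: Structure          # defective (pocket blocked)
    clean: Structure              # defect-free parent
    position: int                 # the case position (native Phe)
    native_aa: str
    blocker: int                  # the planted pocket-blocking residue


def case_study_fixture(seed: int = 0) -> CaseStudyFixture:
    seq = "AAAAAAAFAA" + "GGSG" + "AAQAAAAAAA"
    clean = build_hairpin(seq, id="hairpin_pocket")
    spec = FixtureSpec(seq, "helix", [(17, "chi_offset", 60.0)], seed)
    planted = plant_defects(clean, spec)
    return CaseStudyFixture(structure=planted, clean=clean, position=8,
                            native_aa="F", blocker=17)


def fixture_suite(seed: int = 0) -> list[Fixture]:
    """The standard benchmark suite: >= 8 mini-proteins (10-30 residues)
    spanning clean helix/strand, planted clashes, rotamer offsets,
    coordinate noise, and His/Asn/Gln flip-ambiguous residues."""
    return [
        _make("helix_clean", "AVLSKEALRSAL", "helix", [], seed),
        _make("helix_clash", "AVLSKEAFKSAAQWEL", "helix",
              [(8, "clash_rotamer", None)], seed + 1),
        _make("helix_chi3", "AVLSKEALKSILQMELAVKS", "helix",
              [(3, "chi_offset", 40.0), (9, "chi_offset", -45.0),
               (13, "chi_offset", 40.0)], seed + 2),
        _make("helix_hnq", "AVHSKANLAQALAV", "helix",
              [(3, "chi_offset", 35.0), (10, "chi_offset", -40.0)], seed + 3),
        _make("strand_clean", "ATAVAEATKVAS", "strand", [], seed + 4),
        _make("strand_noise", "ATAVAEATKVASAL", "strand",
              [(4, "coord_noise", 0.3), (9, "coord_noise", 0.3)], seed + 5),
        _make("helix30_two_clash", "AVLSKEAFKSAAQWELAVKSTLESAVRSAL", "helix",
              [(8, "clash_rotamer", None), (21, "clash_rotamer", None)],
              seed + 6),
        _make("helix_mixed_defects", "AVLSKEALKSALQVELAVKSALES", "helix",
              [(5, "clash_rotamer", None), (13, "chi_offset", 40.0),
               (19, "coord_noise", 0.25)], seed + 7),
    ]
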