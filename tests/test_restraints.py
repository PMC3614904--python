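import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from restrelax.fixtures import FixtureSpec, build_peptide
from restrelax.restraints import (CoordinateRestraint, DistanceRestraint,
                                  RestraintError, RestraintSet, bounded_energy,
                                  build_coordinate_restraints,
                                  build_scsc_restraints, harmonic_energy,
                                  restraint_energy)
from restrelax.structure import StructureError
from tests.conftest import rigid_motion


def test_harmonic_energy_values():
    assert harmonic_energy(0.0, 0.3) == 0.0
    assert harmonic_energy(0.7, 0.7) == 1.0
    assert harmonic_energy(1.0, 0.5) == 4.0
    with pytest.raises(RestraintError):
        harmonic_energy(1.0, 0.0)


@settings(max_examples=200, deadline=None)
@given(sd=st.floats(0.05, 5.0), width=st.floats(0.0, 1.0),
       d=st.floats(0.0, 10.0))
def test_bounded_energy_piecewise(sd, width, d):
    e = bounded_energy(d, sd, width)
    if d <= width:
        assert e == 0.0
    elif d <= width + 0.5 * sd:
        assert e == pytest.approx(((d - width) / sd) ** 2)
    else:
        assert e == pytest.approx(0.25 + (d - width - 0.5 * sd) / sd)
    assert e >= 0.0


@settings(max_examples=100, deadline=None)
@given(sd=st.floats(0.05, 5.0), width=st.floats(0.0, 1.0))
def test_bounded_energy_smooth_at_junctions(sd, width):
    """Continuity and first-derivative continuity at both segment junctions."""
    h = 1e-7 * max(sd, 1.0)
    for x in (width, width + 0.5 * sd):
        lo = bounded_energy(max(x - h, 0.0), sd, width)
        hi = bounded_energy(x + h, sd, width)
        assert hi - lo == pytest.approx(0.0, abs=1e-5)
    # asymptotic slope 1/sd
    far = width + 0.5 * sd + 3.0
    num = (bounded_energy(far + 1e-6, sd, width) -
           bounded_energy(far - 1e-6, sd, width)) / 2e-6
    assert num == pytest.approx(1.0 / sd, rel=1e-6)


@settings(max_examples=100, deadline=None)
@given(d=st.floats(0.0, 3.0), sd1=st.floats(0.05, 5.0), sd2=st.floats(0.05, 5.0))
def test_looser_restraints_are_cheaper(d, sd1, sd2):
    lo, hi = sorted([sd1, sd2])
    assert harmonic_energy(d, hi) <= harmonic_energy(d, lo) + 1e-12
    assert bounded_energy(d, hi, 0.2) <= bounded_energy(d, lo, 0.2) + 1e-12


def test_bounded_equals_harmonic_with_zero_width():
    for d in np.linspace(0, 0.5 * 0.8, 20):
        assert bounded_energy(d, 0.8, 0.0) == pytest.approx(harmonic_energy(d, 0.8))


def test_build_coordinate_restraints_counts(polyala10):
    rs_all = build_coordinate_restraints(polyala10, "all_heavy", "harmonic", 0.5)
    rs_bb = build_coordinate_restraints(polyala10, "backbone_heavy", "harmonic", 0.5)
    assert len(rs_all.coordinate_restraints) == 50
    assert len(rs_bb.coordinate_restraints) == 40
    assert restraint_energy(rs_all, polyala10) == 0.0


def test_restraint_energy_displacement(polyala10):
    rs = build_coordinate_restraints(polyala10, "all_heavy", "harmonic", 0.5)
    moved = polyala10.copy()
    moved.residue(3).atom("CB").coord += np.array([0.5, 0.0, 0.0])
    assert restraint_energy(rs, moved) == pytest.approx(1.0)
    rs.weight = 0.0
    assert restraint_energy(rs, moved) == 0.0


def test_scsc_restraints_poly_gly():
    s = build_peptide(FixtureSpec("G" * 8, "helix"))
    rs = build_scsc_restraints(s, 6.0)
    assert rs.distance_restraints == []
    assert len(rs.coordinate_restraints) == 32  # backbone only


def test_scsc_pair_enumeration(polyala10):
    """Every cross-residue sidechain pair within the cutoff, counted once."""
    from restrelax.structure import select_atoms
    rs = build_scsc_restraints(polyala10, 6.0)
    sc = select_atoms(polyala10, "sidechain_heavy")
    expected = set()
    for a in range(len(sc)):
        for b in range(a + 1, len(sc)):
            if sc[a][0] == sc[b][0]:
                continue
            d = np.linalg.norm(polyala10.residue(sc[a][0]).atom(sc[a][1]).coord -
                               polyala10.residue(sc[b][0]).atom(sc[b][1]).coord)
            if d <= 6.0:
                expected.add((sc[a], sc[b]))
    got = {(d.atom_a, d.atom_b) for d in rs.distance_restraints}
    assert got == expected
    for d in rs.distance_restraints:
        assert d.sd == 2.0
        ref = np.linalg.norm(polyala10.residue(d.atom_a[0]).atom(d.atom_a[1]).coord -
                             polyala10.residue(d.atom_b[0]).atom(d.atom_b[1]).coord)
        assert d.d0 == pytest.approx(ref)
    # monotone in cutoff
    assert len(build_scsc_restraints(polyala10, 8.0).distance_restraints) >= \
        len(rs.distance_restraints)


def test_restraint_rigid_motion_invariance(helix10):
    """Distance restraints are invariant under rigid motion; coordinate
    restraints are not."""
    rng = np.random.default_rng(5)
    R, t = rigid_motion(rng)
    moved = helix10.copy()
    for r in moved.residues:
        for a in r.atoms:
            a.coord = R @ a.coord + t
    scsc = build_scsc_restraints(helix10, 8.0)
    scsc.coordinate_restraints = []   # isolate the distance terms
    assert restraint_energy(scsc, moved) == pytest.approx(0.0, abs=1e-9)
    coord = build_coordinate_restraints(helix10, "all_heavy", "harmonic", 0.5)
    assert restraint_energy(coord, moved) > 1.0


def test_restraint_set_text_round_trip(helix10):
    rs = build_scsc_restraints(helix10, 6.0)
    rs.weight = 0.7
    back = RestraintSet.from_text(rs.to_text())
    assert back.weight == rs.weight
    assert len(back) == len(rs)
    # x0 is serialized at PDB-like fixed precision
    assert restraint_energy(back, helix10) == pytest.approx(
        restraint_energy(rs, helix10), abs=1e-9)


def test_restraint_validation(polyala10):
    with pytest.raises(RestraintError):
        CoordinateRestraint((1, "CA"), np.zeros(3), sd=-1.0)
    with pytest.raises(RestraintError):
        CoordinateRestraint((1, "CA"), np.zeros(3), form="harmonic", width=0.3)
    with pytest.raises(RestraintError):
        DistanceRestraint((1, "CB"), (1, "CA"), d0=3.0)
    with pytest.raises(RestraintError):
        build_scsc_restraints(polyala10, cutoff=-2.0)


def test_dangling_reference(helix10):
    rs = RestraintSet(coordinate_restraints=[
        CoordinateRestraint((99, "CA"), np.zeros(3))])
    with pytest.raises(StructureError):
        restraint_energy(rs, helix10)


def test_flip_aware_coordinate_restraints():
    """His/Asn/Gln terminal flips are scored as the better assignment."""
    s = build_peptide(FixtureSpec("AANAA", "helix"))
    rs = build_coordinate_restraints(s, "all_heavy", "harmonic", 0.5)
    assert any(resi == 3 for resi, _ in rs.flip_groups)
    flipped = s.copy()
    res = flipped.residue(3)
    od1, nd2 = res.atom("OD1").coord.copy(), res.atom("ND2").coord.copy()
    res.atom("OD1").coord, res.atom("ND2").coord = nd2, od1
    assert restraint_energy(rs, flipped) == pytest.approx(0.0, abs=1e-9)
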