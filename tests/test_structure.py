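import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from restrelax import templates as T
from restrelax.geometry import bond_angle, dihedral, place_atom, wrap_angle
from restrelax.structure import (EmptyStructureError, MultiChainError,
                                 PdbFormatError, StructureError, build_chain,
                                 clean_structure, coords_for, measure_torsions,
                                 read_pdb, select_atoms, write_pdb)
from restrelax.fixtures import FixtureSpec, build_peptide


@settings(max_examples=100, deadline=None)
@given(bond=st.floats(0.8, 2.2), angle=st.floats(30, 150),
       tors=st.floats(-179.9, 180))
def test_place_atom_reproduces_internal_coordinates(bond, angle, tors):
    """NeRF placement followed by measurement is the identity."""
    a, b, c = (0.0, 0.0, 0.0), (1.5, 0.0, 0.0), (2.3, 1.2, 0.1)
    d = place_atom(a, b, c, bond, angle, tors)
    assert np.linalg.norm(np.subtract(d, c)) == pytest.approx(bond, abs=1e-9)
    assert bond_angle(b, c, d) == pytest.approx(angle, abs=1e-7)
    assert wrap_angle(dihedral(a, b, c, d) - tors) == pytest.approx(0, abs=1e-7)


def test_build_chain_torsion_round_trip():
    seq = "AVLSKFHNQW"
    n = len(seq)
    s = build_chain(seq, [-57.0] * n, [-47.0] * n,
                    [T.default_chis(aa) for aa in seq])
    measure_torsions(s)
    for r in s.residues:
        assert r.psi == pytest.approx(-47.0, abs=1e-6)
        if r.index > 1:
            assert r.phi == pytest.approx(-57.0, abs=1e-6)
        for c, d in zip(r.chi, T.default_chis(r.aa)):
            assert wrap_angle(c - d) == pytest.approx(0, abs=1e-6)


def test_chain_is_l_chiral():
    """The C-N-CA-CB improper dihedral has the L-amino-acid sign."""
    s = build_chain("AA", [-57.0] * 2, [-47.0] * 2, [[], []])
    r = s.residues[0]
    imp = dihedral(r.atom("C").coord, r.atom("N").coord,
                   r.atom("CA").coord, r.atom("CB").coord)
    assert -135 < imp < -110


def test_pdb_round_trip(tmp_path, helix10):
    path = tmp_path / "x.pdb"
    write_pdb(helix10, str(path))
    back = clean_structure(read_pdb(str(path)))
    assert back.sequence == helix10.sequence
    refs = select_atoms(helix10, "all_heavy")
    delta = np.abs(coords_for(helix10, refs) - coords_for(back, refs))
    assert delta.max() <= 1e-3  # PDB fixed-precision


def test_read_pdb_two_residue_poly_ala(tmp_path):
    s = build_peptide(FixtureSpec("AA", "helix"))
    path = tmp_path / "aa.pdb"
    write_pdb(s, str(path))
    back = read_pdb(str(path))
    assert len(back) == 2
    assert all(len(r.heavy_atoms()) == 5 for r in back.residues)


def test_read_pdb_errors(tmp_path):
    with pytest.raises((StructureError, OSError)):
        read_pdb(str(tmp_path / "missing.pdb"))
    empty = tmp_path / "empty.pdb"
    empty.write_text("HETATM    1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00           O\nEND\n")
    with pytest.raises(EmptyStructureError):
        read_pdb(str(empty))


def test_read_pdb_altloc_keeps_highest_occupancy(tmp_path):
    text = (
        "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N\n"
        "ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C\n"
        "ATOM      3  C   ALA A   1       2.009   1.421   0.000  1.00  0.00           C\n"
        "ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O\n"
        "ATOM      5  CB AALA A   1       2.000   1.000   1.000  0.60  0.00           C\n"
        "ATOM      6  CB BALA A   1       3.000   2.000   2.000  0.40  0.00           C\n"
        "END\n")
    p = tmp_path / "alt.pdb"
    p.write_text(text)
    s = read_pdb(str(p))
    cb = s.residues[0].atom("CB")
    assert np.allclose(cb.coord, [2.0, 1.0, 1.0])  # occupancy 0.6 conformer


def test_read_pdb_multichain_rejected(tmp_path):
    text = (
        "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N\n"
        "ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C\n"
        "ATOM      3  C   ALA A   1       2.009   1.421   0.000  1.00  0.00           C\n"
        "TER\n"
        "ATOM      4  N   GLY B   1       9.000   0.000   0.000  1.00  0.00           N\n"
        "ATOM      5  CA  GLY B   1      10.458   0.000   0.000  1.00  0.00           C\n"
        "ATOM      6  C   GLY B   1      11.009   1.421   0.000  1.00  0.00           C\n"
        "END\n")
    p = tmp_path / "mc.pdb"
    p.write_text(text)
    with pytest.raises(MultiChainError):
        read_pdb(str(p))


def test_write_pdb_coordinate_overflow(tmp_path, helix10):
    bad = helix10.copy()
    bad.residues[0].atom("N").coord = np.array([123456.0, 0.0, 0.0])
    with pytest.raises(PdbFormatError):
        write_pdb(bad, str(tmp_path / "bad.pdb"))


def test_clean_structure_removes_waters_and_noncanonical(tmp_path, polyala10):
    path = tmp_path / "mixed.pdb"
    write_pdb(polyala10, str(path))
    lines = path.read_text().splitlines()
    extra = [
        "HETATM  900  O   HOH A  90      20.000  20.000  20.000  1.00  0.00           O",
        "HETATM  901  O   HOH A  91      21.000  21.000  21.000  1.00  0.00           O",
        "HETATM  902  O   HOH A  92      22.000  22.000  22.000  1.00  0.00           O",
    ]
    idx = next(i for i, ln in enumerate(lines) if ln.startswith("TER") or ln.startswith("END"))
    path.write_text("\n".join(lines[:idx] + extra + lines[idx:]) + "\n")
    s = clean_structure(read_pdb(str(path)))
    assert len(s) == 10
    assert s.sequence == "A" * 10


def test_clean_structure_drops_selenomethionine(tmp_path, polyala10):
    path = tmp_path / "mse.pdb"
    write_pdb(polyala10, str(path))
    lines = path.read_text().splitlines()
    mse = [
        "HETATM  950  N   MSE A  50      30.000  30.000  30.000  1.00  0.00           N",
        "HETATM  951  CA  MSE A  50      31.458  30.000  30.000  1.00  0.00           C",
        "HETATM  952  C   MSE A  50      32.009  31.421  30.000  1.00  0.00           C",
    ]
    idx = next(i for i, ln in enumerate(lines)
               if ln.startswith("TER") or ln.startswith("END"))
    path.write_text("\n".join(lines[:idx] + mse + lines[idx:]) + "\n")
    s = clean_structure(read_pdb(str(path)))
    assert s.sequence == "A" * 10


def test_clean_structure_idempotent(helix10):
    once = clean_structure(helix10)
    twice = clean_structure(once)
    assert twice.sequence == once.sequence
    refs = select_atoms(once, "all_heavy")
    assert np.allclose(coords_for(once, refs), coords_for(twice, refs))


def test_clean_structure_empty_error():
    from restrelax.structure import Residue, Structure
    s = Structure(residues=[Residue(index=1, aa="X", res_name="HOH")])
    with pytest.raises(EmptyStructureError):
        clean_structure(s)


@pytest.mark.parametrize("selector,expected", [
    ("backbone_heavy", 40), ("sidechain_heavy", 10), ("all_heavy", 50),
    ("ca", 10)])
def test_select_atoms_poly_ala(polyala10, selector, expected):
    assert len(select_atoms(polyala10, selector)) == expected


def test_select_atoms_glycine_has_no_sidechain():
    s = build_peptide(FixtureSpec("G", "helix"))
    assert select_atoms(s, "sidechain_heavy") == []
    assert len(select_atoms(s, "all_heavy")) == 4


def test_select_atoms_partition(suite):
    for f in suite:
        bb = set(select_atoms(f.structure, "backbone_heavy"))
        sc = set(select_atoms(f.structure, "sidechain_heavy"))
        allh = set(select_atoms(f.structure, "all_heavy"))
        assert bb | sc == allh
        assert not bb & sc


def test_select_atoms_unknown_selector(polyala10):
    with pytest.raises(StructureError):
        select_atoms(polyala10, "sidechains_and_waters")
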