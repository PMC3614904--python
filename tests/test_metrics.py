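import numpy as np
import pytest

from restrelax.fixtures import FixtureSpec, build_peptide
from restrelax.pareto import (ParetoPoint, aggregate, kabsch_superpose,
                              pareto_front, rmsd_all_atom, rmsd_ca)
from restrelax.structure import StructureError
from tests.conftest import rigid_motion


def quaternion_rmsd(A, B):
    """Independent superposition oracle: Horn's quaternion eigenvalue method."""
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    a = A - A.mean(axis=0)
    b = B - B.mean(axis=0)
    M = b.T @ a
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz]])
    lam = np.linalg.eigvalsh(K)[-1]
    n = A.shape[0]
    msd = max(((a ** 2).sum() + (b ** 2).sum() - 2.0 * lam) / n, 0.0)
    return float(np.sqrt(msd))


def test_kabsch_identity_and_rigid_motion():
    rng = np.random.default_rng(0)
    A = rng.normal(size=(25, 3))
    res = kabsch_superpose(A, A)
    assert res.rmsd == pytest.approx(0.0, abs=1e-12)
    assert np.allclose(res.rotation, np.eye(3), atol=1e-9)
    R, t = rigid_motion(rng)
    res2 = kabsch_superpose(A, A @ R.T + t)
    assert res2.rmsd == pytest.approx(0.0, abs=1e-9)
    assert np.linalg.det(res2.rotation) == pytest.approx(1.0, abs=1e-9)


def test_kabsch_matches_quaternion_oracle():
    """200 random instances agree with the quaternion method to 1e-9."""
    rng = np.random.default_rng(42)
    for _ in range(200):
        n = int(rng.integers(4, 60))
        A = rng.normal(scale=5.0, size=(n, 3))
        B = A + rng.normal(scale=rng.uniform(0.01, 2.0), size=(n, 3))
        R, t = rigid_motion(rng)
        B = B @ R.T + t
        assert kabsch_superpose(A, B).rmsd == pytest.approx(
            quaternion_rmsd(A, B), abs=1e-9)


def test_kabsch_errors():
    with pytest.raises(ValueError):
        kabsch_superpose(np.zeros((3, 3)), np.zeros((4, 3)))
    line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], float)
    with pytest.raises(ValueError):
        kabsch_superpose(line, line.copy())


def test_rmsd_self_and_rigid_motion(helix10):
    assert rmsd_all_atom(helix10, helix10) == pytest.approx(0.0, abs=1e-12)
    moved = helix10.copy()
    R, t = rigid_motion(np.random.default_rng(1))
    for r in moved.residues:
        for a in r.atoms:
            a.coord = R @ a.coord + t
    assert rmsd_all_atom(helix10, moved) == pytest.approx(0.0, abs=1e-9)
    assert rmsd_ca(helix10, moved) == pytest.approx(0.0, abs=1e-9)


def test_rmsd_single_perturbed_atom_closed_form():
    """Moving one atom by delta with the superposition pinned by many others
    gives rmsd ~ delta/sqrt(N)."""
    s = build_peptide(FixtureSpec("A" * 20, "helix"))
    n_atoms = 100
    moved = s.copy()
    delta = 0.8
    moved.residue(10).atom("CB").coord += np.array([0, 0, delta])
    expected = delta / np.sqrt(n_atoms)
    assert rmsd_all_atom(s, moved) == pytest.approx(expected, rel=0.05)


def test_rmsd_sequence_mismatch(helix10, polyala10):
    with pytest.raises(StructureError):
        rmsd_all_atom(helix10, polyala10)


def test_rmsd_flip_aware():
    s = build_peptide(FixtureSpec("AAQAA", "helix"))
    flipped = s.copy()
    res = flipped.residue(3)
    oe1, ne2 = res.atom("OE1").coord.copy(), res.atom("NE2").coord.copy()
    res.atom("OE1").coord, res.atom("NE2").coord = ne2, oe1
    plain = rmsd_all_atom(s, flipped)
    aware = rmsd_all_atom(s, flipped, flip_aware=True)
    assert plain > 0.1
    assert aware == pytest.approx(0.0, abs=1e-9)


def brute_force_front(points):
    out = []
    for p in points:
        dominated = any(
            (q.mean_rmsd <= p.mean_rmsd and
             q.mean_energy_per_residue <= p.mean_energy_per_residue and
             (q.mean_rmsd, q.mean_energy_per_residue) !=
             (p.mean_rmsd, p.mean_energy_per_residue))
            for q in points)
        if not dominated:
            out.append(p)
    return sorted(out, key=lambda p: (p.mean_rmsd, p.mean_energy_per_residue))


def test_pareto_front_trivial_cases():
    p = ParetoPoint("a", 1.0, -1.0)
    assert pareto_front([p]) == [p]
    a, b = ParetoPoint("a", 1, 1), ParetoPoint("b", 2, 2)
    front = pareto_front([a, b])
    assert front == [a]
    assert b.dominated and not a.dominated


def test_pareto_front_matches_bruteforce_oracle():
    """100 random 50-point sets agree exactly with O(n^2) dominance."""
    rng = np.random.default_rng(7)
    for trial in range(100):
        pts = [ParetoPoint(f"p{i}", float(rng.integers(0, 12)) / 4.0,
                           float(rng.integers(-12, 0)) / 4.0)
               for i in range(50)]
        got = pareto_front(pts)
        expect = brute_force_front(pts)
        assert [(p.mean_rmsd, p.mean_energy_per_residue) for p in got] == \
            [(p.mean_rmsd, p.mean_energy_per_residue) for p in expect]


class _FakeResult:
    def __init__(self, rmsd, e):
        self.rmsd_to_input = rmsd
        self.final_score = type("S", (), {"per_residue_mean": e})()


def test_aggregate_median_then_mean():
    single = aggregate("x", [[_FakeResult(0.5, -1.0)]])
    assert single.mean_rmsd == 0.5 and single.mean_energy_per_residue == -1.0
    robust = aggregate("y", [[_FakeResult(1, 0), _FakeResult(2, 0),
                              _FakeResult(100, 0)]])
    assert robust.mean_rmsd == 2.0
    multi = aggregate("z", [[_FakeResult(0.1, 0)], [_FakeResult(0.2, 0)],
                            [_FakeResult(0.3, 0)]])
    assert multi.mean_rmsd == pytest.approx(0.2)


def test_aggregate_permutation_invariance():
    rng = np.random.default_rng(3)
    reps = [[_FakeResult(rng.uniform(), rng.uniform()) for _ in range(5)]
            for _ in range(4)]
    p1 = aggregate("a", reps)
    shuffled = [list(reversed(r)) for r in reversed(reps)]
    p2 = aggregate("a", shuffled)
    assert p1.mean_rmsd == pytest.approx(p2.mean_rmsd)
    assert p1.mean_energy_per_residue == pytest.approx(p2.mean_energy_per_residue)


def test_aggregate_empty_error():
    with pytest.raises(ValueError):
        aggregate("x", [])


def test_sweep_single_setting_and_report(tmp_path, clash16, fast_cfg):
    from restrelax.pareto import sweep
    from restrelax.restraints import build_coordinate_restraints
    settings = [("harmonic sd=0.5",
                 lambda s: build_coordinate_restraints(s, "all_heavy",
                                                       "harmonic", 0.5))]
    rep = sweep([clash16], settings, fast_cfg, n_replicates=1, seed=3)
    assert len(rep.points) == 1
    assert rep.front == rep.points        # a single point is trivially optimal
    assert not rep.points[0].dominated
    tsv = tmp_path / "sweep.tsv"
    rep.to_tsv(str(tsv))
    assert "harmonic sd=0.5" in tsv.read_text()
    png = tmp_path / "sweep.png"
    rep.plot(str(png))
    assert png.exists()
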