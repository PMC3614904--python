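import numpy as np
import pytest

from restrelax import templates as T
from restrelax.energy import EnergyWeights, score
from restrelax.fixtures import FixtureSpec, build_peptide, plant_defects
from restrelax.pareto import rmsd_all_atom
from restrelax.relax import (RelaxConfig, fast_relax, minimize, relax_replicates,
                             repack)
from restrelax.restraints import build_coordinate_restraints
from restrelax.structure import coords_for, rebuild_sidechain, measure_torsions, select_atoms


def total_energy(s, restraints=None):
    return score(s, EnergyWeights(), restraints).total


def test_repack_never_worsens_good_rotamers(helix10):
    out = repack(helix10, EnergyWeights(), None, rng=0)
    assert total_energy(out) <= total_energy(helix10) + 1e-9


def test_repack_fixes_planted_clash(clash16):
    before = score(clash16)
    out = repack(clash16, EnergyWeights(), None, rng=1)
    after = score(out)
    # the severe planted clash is resolved (small residual contact strain may
    # be traded against packing)
    assert after.by_term["rep"] < before.by_term["rep"] / 1000
    assert after.by_term["rep"] < 5.0
    assert after.total < before.total


def test_repack_single_val_staggered():
    """A lone valine planted eclipsed repacks into a staggered well."""
    s = build_peptide(FixtureSpec("AVA", "helix"))
    rebuild_sidechain(s.residue(2), [0.0])
    measure_torsions(s)
    out = repack(s, EnergyWeights(), None, rng=0)
    assert out.residue(2).chi[0] == pytest.approx(180.0, abs=1e-6) or \
        abs(abs(out.residue(2).chi[0]) - 60.0) < 1e-6


def test_repack_gly_only_structure_unchanged():
    s = build_peptide(FixtureSpec("G" * 6, "helix"))
    out = repack(s, EnergyWeights(), None, rng=3)
    refs = select_atoms(s, "all_heavy")
    assert np.array_equal(coords_for(s, refs), coords_for(out, refs))


def test_repack_respects_restraints(clash16):
    """Astronomically tight coordinate restraints freeze the rotamers."""
    rs = build_coordinate_restraints(clash16, "all_heavy", "harmonic", 1e-6)
    out = repack(clash16, EnergyWeights(), rs, rng=1)
    refs = select_atoms(clash16, "all_heavy")
    assert np.allclose(coords_for(clash16, refs), coords_for(out, refs))


def test_minimize_is_descent(clash16, fast_cfg):
    out = minimize(clash16, EnergyWeights(), None, fast_cfg)
    assert total_energy(out) <= total_energy(clash16) + 1e-9


def test_minimize_returns_displaced_atom_to_anchor(helix10, fast_cfg):
    """Pure quadratic objective: a chi displacement relaxes back to zero."""
    anchors = build_coordinate_restraints(helix10, "all_heavy", "harmonic", 0.5)
    moved = helix10.copy()
    chi = list(moved.residue(2).chi)
    chi[0] += 30.0
    rebuild_sidechain(moved.residue(2), chi)
    measure_torsions(moved)
    w = EnergyWeights(w_rep=0, w_atr=0, w_rot=0)
    cfg = RelaxConfig(max_min_iters=300, min_tolerance=1e-6)
    out = minimize(moved, w, anchors, cfg)
    assert rmsd_all_atom(helix10, out) < 5e-3


def test_minimize_at_exact_minimum_stays(helix10):
    """With only restraints active and the structure at its anchors, the
    gradient is exactly zero and minimization returns the input."""
    anchors = build_coordinate_restraints(helix10, "all_heavy", "harmonic", 0.5)
    w = EnergyWeights(w_rep=0, w_atr=0, w_rot=0)
    out = minimize(helix10, w, anchors, RelaxConfig())
    assert rmsd_all_atom(helix10, out) < 1e-6
    assert score(out, w, anchors).total == pytest.approx(0.0, abs=1e-9)


def test_minimize_near_minimum_stays_close(helix10):
    cfg = RelaxConfig(max_min_iters=2000, min_tolerance=1e-5)
    once = minimize(helix10, EnergyWeights(), None, cfg)
    again = minimize(once, EnergyWeights(), None, cfg)
    assert total_energy(again) <= total_energy(once) + 1e-9
    assert rmsd_all_atom(once, again) < 0.05


def test_minimize_chi_only_keeps_backbone(clash16, fast_cfg):
    out = minimize(clash16, EnergyWeights(), None, fast_cfg, dofs="chi")
    refs = select_atoms(clash16, "backbone_heavy")
    # backbone is rebuilt through the torsion map: identical up to round-off
    assert np.allclose(coords_for(clash16, refs), coords_for(out, refs),
                       atol=1e-9)


def test_fast_relax_deterministic(clash16, fast_cfg):
    rs = build_coordinate_restraints(clash16, "all_heavy", "harmonic", 0.5)
    r1 = fast_relax(clash16, rs, fast_cfg)
    r2 = fast_relax(clash16, rs, fast_cfg)
    assert r1.trajectory == r2.trajectory
    refs = select_atoms(clash16, "all_heavy")
    assert np.array_equal(coords_for(r1.final, refs), coords_for(r2.final, refs))


def test_fast_relax_trajectory_schedule(clash16, fast_cfg):
    rs = build_coordinate_restraints(clash16, "all_heavy", "harmonic", 0.5)
    res = fast_relax(clash16, rs, fast_cfg)
    cfg = fast_cfg
    assert len(res.trajectory) == cfg.n_cycles * len(cfg.rep_schedule)
    for rec in res.trajectory:
        assert rec.rep_weight == cfg.rep_schedule[rec.stage]
        assert rec.cst_weight == 1.0      # ramp_constraints defaults to off
    assert res.trajectory[-1].rep_weight == 1.0
    # stored final score is reproducible from the final structure
    assert score(res.final).total == pytest.approx(res.final_score.total,
                                                   abs=1e-6)


def test_fast_relax_ramped_constraints_schedule(clash16):
    cfg = RelaxConfig(max_min_iters=30, min_tolerance=1e-2,
                      ramp_constraints=True)
    rs = build_coordinate_restraints(clash16, "all_heavy", "harmonic", 0.5)
    res = fast_relax(clash16, rs, cfg)
    for rec in res.trajectory:
        assert rec.cst_weight == cfg.restraint_schedule[rec.stage]


def test_fast_relax_restrained_beats_unrestrained_rmsd(clash16, fast_cfg):
    """Fig.-1 mechanism: restraints trade a little energy for much less
    structural drift."""
    rs = build_coordinate_restraints(clash16, "all_heavy", "harmonic", 0.5)
    restrained = fast_relax(clash16, rs, fast_cfg)
    free = fast_relax(clash16, None, fast_cfg)
    e_in = total_energy(clash16)
    assert restrained.final_score.total < e_in
    assert free.final_score.total < e_in
    assert restrained.rmsd_to_input < free.rmsd_to_input
    assert free.final_score.total <= restrained.final_score.total


def test_fast_relax_tightest_restraint_pins_structure(clash16, fast_cfg):
    rs = build_coordinate_restraints(clash16, "all_heavy", "harmonic", 1e-6)
    res = fast_relax(clash16, rs, fast_cfg)
    assert res.rmsd_to_input <= 0.01


def test_backbone_only_restraints_allow_sidechain_drift(fast_cfg):
    spec = FixtureSpec("AVLSKEALKSILQMELAVKS", "helix",
                       [(3, "chi_offset", 40.0), (9, "chi_offset", -45.0),
                        (13, "chi_offset", 40.0)], seed=4)
    s = plant_defects(build_peptide(spec), spec)
    bb = build_coordinate_restraints(s, "backbone_heavy", "harmonic", 0.5)
    aa = build_coordinate_restraints(s, "all_heavy", "harmonic", 0.5)
    r_bb = fast_relax(s, bb, fast_cfg)
    r_aa = fast_relax(s, aa, fast_cfg)
    assert r_bb.rmsd_to_input > r_aa.rmsd_to_input


def test_relax_replicates_summary(clash16, fast_cfg):
    rs = build_coordinate_restraints(clash16, "all_heavy", "harmonic", 0.5)
    one = relax_replicates(clash16, rs, fast_cfg, n=1, seeds=[5])
    assert one.median_rmsd == one.results[0].rmsd_to_input
    assert one.rmsd_range == 0.0
    with pytest.raises(ValueError):
        relax_replicates(clash16, rs, fast_cfg, n=2, seeds=[3, 3])
    # fully pinned replicates are identical: zero ranges
    tight = build_coordinate_restraints(clash16, "all_heavy", "harmonic", 1e-6)
    rep = relax_replicates(clash16, tight, fast_cfg, n=3, seeds=[1, 2, 3])
    assert rep.rmsd_range == pytest.approx(0.0, abs=1e-9)
    assert rep.energy_range == pytest.approx(0.0, abs=1e-9)


def test_relax_config_validation():
    with pytest.raises(ValueError):
        RelaxConfig(rep_schedule=(0.5, 0.2, 1.0))
    with pytest.raises(ValueError):
        RelaxConfig(rep_schedule=(0.1, 0.5))
    with pytest.raises(ValueError):
        RelaxConfig(ramp_constraints=True, restraint_schedule=(0.1, 0.5, 0.7, 1.0))
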