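import numpy as np
import pytest

from restrelax import templates as T
from restrelax.energy import (ATR_EPS, EnergyWeights,
                              atr_energy_scalar, high_energy_residues,
                              nonbonded_terms, per_residue_deltas,
                              rep_energy_scalar, score)
from restrelax.fixtures import FixtureSpec, build_peptide, plant_defects
from restrelax.structure import StructureError, rebuild_sidechain, measure_torsions


def brute_force_rep(s):
    """Independent O(n^2) clash-energy oracle over all heavy-atom pairs,
    with its own bond-graph bookkeeping."""
    atoms = []
    for r in s.residues:
        for name in T.template_atom_names(r.aa):
            atoms.append((r.index, name, r.atom(name).coord,
                          T.VDW_RADII[T.element_of(name)]))
    # bond adjacency
    index = {(ri, n): k for k, (ri, n, _, _) in enumerate(atoms)}
    import networkx as nx
    g = nx.Graph()
    g.add_nodes_from(range(len(atoms)))
    for r in s.residues:
        for a, b in T.residue_bonds(r.aa):
            g.add_edge(index[(r.index, a)], index[(r.index, b)])
        if (r.index + 1, "N") in index:
            g.add_edge(index[(r.index, "C")], index[(r.index + 1, "N")])
    dist = dict(nx.all_pairs_shortest_path_length(g, cutoff=4))
    total = 0.0
    for i in range(len(atoms)):
        for j in range(i + 1, len(atoms)):
            bd = dist.get(i, {}).get(j, 99)
            if bd <= 3:
                continue
            sigma = (atoms[i][3] + atoms[j][3]) * (0.85 if bd == 4 else 1.0)
            d = float(np.linalg.norm(atoms[i][2] - atoms[j][2]))
            if d < sigma:
                if d >= 0.6 * sigma:
                    total += (sigma / d) ** 12 - 1.0
                else:
                    f0 = 0.6 ** -12 - 1.0
                    total += f0 + 12.0 * 0.6 ** -13 / sigma * (0.6 * sigma - d)
    return total


def test_lj_boundary_at_contact():
    """At exactly the contact distance: no clash, attraction at its minimum."""
    sigma = np.array([3.5])
    d = np.array([3.5])
    assert rep_energy_scalar(d, sigma)[0] == 0.0
    assert atr_energy_scalar(d, sigma)[0] == pytest.approx(-ATR_EPS)
    grid = np.linspace(3.0, 5.4, 200)
    assert atr_energy_scalar(grid, np.full_like(grid, 3.5)).min() == \
        pytest.approx(-ATR_EPS, abs=1e-9)


def test_single_ala_ideal_rotamer_zero_strain():
    s = build_peptide(FixtureSpec("A", "helix"))
    b = score(s)
    assert b.by_term["rot"] == 0.0
    assert b.by_term["rep"] == 0.0


def test_rep_matches_brute_force_oracle():
    """Library clash energy equals an independent O(n^2) pairwise loop."""
    spec = FixtureSpec("AVLSKEAF", "helix", [(8, "clash_rotamer", None)], 3)
    s = plant_defects(build_peptide(spec), spec)
    b = score(s, EnergyWeights(w_atr=0, w_rot=0))
    assert b.by_term["rep"] == pytest.approx(brute_force_rep(s), rel=1e-9)


def test_score_is_pure_and_conservative(clash16):
    b1 = score(clash16)
    b2 = score(clash16)
    assert b1.total == b2.total
    assert np.array_equal(b1.by_residue, b2.by_residue)
    assert sum(b1.by_term.values()) == pytest.approx(b1.total, abs=1e-6)
    assert b1.by_residue.sum() == pytest.approx(b1.total, abs=1e-6)


def test_soft_mode_never_exceeds_standard(suite):
    for f in suite:
        e_soft = score(f.structure, EnergyWeights(rep_mode="soft")).by_term["rep"]
        e_std = score(f.structure, EnergyWeights()).by_term["rep"]
        assert e_soft <= e_std + 1e-12
        assert e_soft >= 0.0 and e_std >= 0.0


def test_nan_coordinates_rejected(helix10):
    bad = helix10.copy()
    bad.residues[0].atom("CA").coord[0] = np.inf
    with pytest.raises(StructureError):
        score(bad)


def test_per_residue_deltas_identity_and_ranking(clash16):
    before = score(clash16)
    assert all(d == 0.0 for _, d in per_residue_deltas(before, before))
    # relieve the planted clash only
    relieved = clash16.copy()
    rebuild_sidechain(relieved.residue(8), T.default_chis("F"))
    measure_torsions(relieved)
    after = score(relieved)
    ranked = per_residue_deltas(before, after, term="rep")
    assert ranked[0][0] == 8
    assert ranked[0][1] < 0


def test_per_residue_deltas_truncation_and_errors(helix10, clash16):
    b = score(helix10)
    assert len(per_residue_deltas(b, b, top_n=10)) == 10
    assert len(per_residue_deltas(b, b, top_n=25)) == len(helix10)
    with pytest.raises(ValueError):
        per_residue_deltas(b, score(clash16))
    with pytest.raises(ValueError):
        per_residue_deltas(b, b, term="solvation")


def test_high_energy_residues(clash16, helix10):
    b = score(clash16)
    flagged = high_energy_residues(b, 5.0)
    assert 8 in flagged
    assert flagged == {i for i, e in zip(b.residue_index, b.by_residue) if e > 5.0}
    assert high_energy_residues(score(helix10), 5.0) == set()
    assert high_energy_residues(b, -1e9) == set(b.residue_index)


def test_score_table_round_trip(tmp_path, clash16):
    b = score(clash16)
    path = tmp_path / "scores.tsv"
    b.to_tsv(str(path))
    import pandas as pd
    df = pd.read_csv(path, sep="\t")
    assert list(df.columns) == ["residue", "aa", "rep", "atr", "rot", "cst", "total"]
    assert df["total"].sum() == pytest.approx(b.total, abs=1e-4)
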