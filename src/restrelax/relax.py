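"""Cyclic repack-and-minimize refinement with repulsive-weight ramping.

The protocol runs ``n_cycles`` cycles; within each cycle the repulsive weight
steps through ``rep_schedule`` (low to high, ending at 1.0), and at every
stage the sidechains are repacked by simulated annealing and then all
phi/psi/chi torsions are minimized with L-BFGS over the total energy
(physical terms + restraints). Restraints are either held at full weight
throughout (the default, matching restraints derived from the input
coordinates) or ramped off as the repulsive weight ramps up.

Degrees of freedom are torsions over ideal-geometry templates; the first
residue's N/CA/C triad anchors the chain, so there are no rigid-body moves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from itertools import product
from typing import NamedTuple, Sequence

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from . import templates as T
from .energy import (EnergyWeights, ScoreBreakdown, Topology,
                     nonbonded_energy_forces, rot_energy_chi, score, SIGMA_CHI)
from .geometry import wrap_angle
from .restraints import CompiledRestraints, NullRestraints, RestraintSet
from .structure import Structure, StructureError, measure_torsions
from .pareto import rmsd_all_atom

ANNEAL_TEMPS = (10.0, 3.0, 1.0, 0.3)


@dataclass(frozen=True)
class RelaxConfig:
    n_cycles: int = 5
    rep_schedule: tuple[float, ...] = (0.02, 0.25, 0.55, 1.0)
    ramp_constraints: bool = False
    restraint_schedule: tuple[float, ...] = (1.0, 0.7, 0.3, 0.0)
    min_tolerance: float = 1e-4
    max_min_iters: int = 500
    seed: int = 0
    extra_rotamers: bool = False

    def __post_init__(self):
        rs = self.rep_schedule
        if any(b <= a for a, b in zip(rs, rs[1:])) or rs[-1] != 1.0:
            raise ValueError("rep_schedule must be strictly increasing and end at 1.0")
        if self.ramp_constraints:
            cs = self.restraint_schedule
            if len(cs) != len(rs):
                raise ValueError("restraint_schedule must match rep_schedule length")
            if any(b > a for a, b in zip(cs, cs[1:])):
                raise ValueError("restraint_schedule must be non-increasing")

    def stage_cst_weight(self, stage: int) -> float:
        return self.restraint_schedule[stage] if self.ramp_constraints else 1.0


class StageRecord(NamedTuple):
    cycle: int
    stage: int
    rep_weight: float
    cst_weight: float
    total_energy: float


@dataclass
class RelaxResult:
    final: Structure
    trajectory: list[StageRecord]
    final_score: ScoreBreakdown
    rmsd_to_input: float
    seed: int

    def trajectory_table(self):
        import pandas as pd
        return pd.DataFrame(self.trajectory,
                            columns=["cycle", "stage", "rep_weight",
                                     "cst_weight", "total_energy"])


# ================================================================ torsion system

class TorsionSystem:
    """Idealized torsion-space view of a cleaned structure.

    Coordinates are a pure function of the torsion vector given the fixed root
    triad (residue 1 N/CA/C). Atom order matches :class:`~restrelax.energy.Topology`.
    """

    def __init__(self, s: Structure):
        if any(len(r.chi) != T.chi_count(r.aa) for r in s.residues):
            raise StructureError("structure is not cleaned (chi lists incomplete)")
        self.sequence = s.sequence
        self.n_res = len(s.residues)
        self.topo = Topology.for_structure(s)

        # torsion vector layout: per residue [phi, psi, chi...]
        self.tor_index: dict[tuple[int, str, int], int] = {}
        vals: list[float] = []
        for i, r in enumerate(s.residues):
            self.tor_index[(i, "phi", 0)] = len(vals)
            vals.append(r.phi)
            self.tor_index[(i, "psi", 0)] = len(vals)
            vals.append(r.psi)
            for k, c in enumerate(r.chi):
                self.tor_index[(i, "chi", k)] = len(vals)
                vals.append(c)
        self.torsions = np.array(vals)

        self.root = (tuple(s.residues[0].atom("N").coord),
                     tuple(s.residues[0].atom("CA").coord),
                     tuple(s.residues[0].atom("C").coord))
        self._build_instructions()
        self._build_dofs()

    # ------------------------------------------------------------- construction
    def _build_instructions(self):
        """Flat placement program: one row per non-root atom."""
        idx = self.topo.index_of
        prog = []
        for i, aa in enumerate(self.sequence):
            ri = i + 1
            if i > 0:
                prog.append((idx[(ri, "N")], idx[(ri - 1, "N")],
                             idx[(ri - 1, "CA")], idx[(ri - 1, "C")],
                             T.B_C_N, T.A_CA_C_N,
                             self.tor_index[(i - 1, "psi", 0)], 0.0))
                prog.append((idx[(ri, "CA")], idx[(ri - 1, "CA")],
                             idx[(ri - 1, "C")], idx[(ri, "N")],
                             T.B_N_CA, T.A_C_N_CA, -1, T.OMEGA))
                prog.append((idx[(ri, "C")], idx[(ri - 1, "C")],
                             idx[(ri, "N")], idx[(ri, "CA")],
                             T.B_CA_C, T.A_N_CA_C,
                             self.tor_index[(i, "phi", 0)], 0.0))
            prog.append((idx[(ri, "O")], idx[(ri, "N")], idx[(ri, "CA")],
                         idx[(ri, "C")], T.B_C_O, T.A_CA_C_O,
                         self.tor_index[(i, "psi", 0)], 180.0))
            for row in T.SIDECHAINS[aa]:
                name, (a3, a2, a1), bond, angle, tors = row
                if isinstance(tors, tuple):
                    tref = self.tor_index[(i, "chi", tors[1] - 1)]
                    off = tors[2]
                else:
                    tref, off = -1, tors
                prog.append((idx[(ri, name)], idx[(ri, a3)], idx[(ri, a2)],
                             idx[(ri, a1)], bond, angle, tref, off))
        self.program = prog
        self.prog_i = np.array([[p[0], p[1], p[2], p[3], p[6]] for p in prog],
                               dtype=np.int64).reshape(-1, 5)
        self.prog_f = np.array([[p[4], p[5], p[7]] for p in prog],
                               dtype=float).reshape(-1, 3)
        self.root_arr = np.array(self.root, dtype=float)

    def _build_dofs(self):
        """Active DOFs with rotation axes and downstream atom sets."""
        idx = self.topo.index_of
        self.dofs: list[dict] = []
        for i, aa in enumerate(self.sequence):
            ri = i + 1
            res_atoms = [idx[(ri, n)] for n in T.template_atom_names(aa)]
            start = res_atoms[0]
            next_start = res_atoms[-1] + 1
            later = list(range(next_start, self.topo.n))
            if i > 0:
                # atoms from C_i to the chain end form a contiguous block
                moved = list(range(start + 2, next_start)) + later
                self.dofs.append(dict(
                    t=self.tor_index[(i, "phi", 0)], res=i, kind="phi", chi_k=None,
                    axis=(idx[(ri, "N")], idx[(ri, "CA")]),
                    moved=np.array(moved, dtype=int),
                    suffix_start=start + 2))
            moved = [idx[(ri, "O")]] + later
            self.dofs.append(dict(
                t=self.tor_index[(i, "psi", 0)], res=i, kind="psi", chi_k=None,
                axis=(idx[(ri, "CA")], idx[(ri, "C")]),
                moved=np.array(moved, dtype=int),
                o_idx=start + 3, next_start=next_start))
            if aa in ("G", "A", "P"):
                continue  # no chi DOFs (proline's pseudo-chis stay frozen)
            for k, quad in enumerate(T.CHI_ATOMS[aa]):
                moved_names: set[str] = set()
                for row in T.SIDECHAINS[aa]:
                    name, (_, _, a1), _, _, tors = row
                    if (isinstance(tors, tuple) and tors[1] - 1 == k) or \
                            a1 in moved_names:
                        moved_names.add(name)
                self.dofs.append(dict(
                    t=self.tor_index[(i, "chi", k)], res=i, kind="chi", chi_k=k,
                    axis=(idx[(ri, quad[1])], idx[(ri, quad[2])]),
                    moved=np.array(sorted(idx[(ri, n)] for n in moved_names),
                                   dtype=int)))

    # ---------------------------------------------------------------- rebuild
    def rebuild(self, torsions: np.ndarray | None = None) -> np.ndarray:
        """Cartesian heavy-atom coordinates from the torsion vector."""
        from ._kernels import place_program
        tv = self.torsions if torsions is None else torsions
        return place_program(self.prog_i, self.prog_f, np.ascontiguousarray(tv),
                             self.root_arr, self.topo.n)

    def residue_chis(self, tv: np.ndarray, i: int) -> list[float]:
        aa = self.sequence[i]
        return [tv[self.tor_index[(i, "chi", k)]] for k in range(T.chi_count(aa))]

    def rot_energy(self, tv: np.ndarray) -> float:
        e = 0.0
        for i, aa in enumerate(self.sequence):
            if T.chi_count(aa):
                e += rot_energy_chi(aa, self.residue_chis(tv, i))
        return e

    def write_to(self, s: Structure, coords: np.ndarray) -> Structure:
        """New structure with these coordinates (torsions re-measured)."""
        out = s.copy()
        k = 0
        for r in out.residues:
            for name in T.template_atom_names(r.aa):
                r.atom(name).coord = coords[k].copy()
                k += 1
        measure_torsions(out)
        return out


# ==================================================================== repacking

def _rotamer_candidates(aa: str, current: list[float], extra: bool) -> list[tuple]:
    """Candidate chi assignments: input rotamer, its H/N/Q flip, and the
    combinatorial rotamer wells (optionally with ±10° sub-samples on chi1/chi2)."""
    cands = [tuple(current)]
    if aa in T.FLIP_CHI:
        k = T.FLIP_CHI[aa] - 1
        flipped = list(current)
        flipped[k] = wrap_angle(flipped[k] + 180.0)
        cands.append(tuple(flipped))
    well_lists = []
    for k, wells in enumerate(T.chi_wells(aa)):
        if extra and k < 2:
            well_lists.append(tuple(w + d for w in wells for d in (-10.0, 0.0, 10.0)))
        else:
            well_lists.append(wells)
    cands.extend(product(*well_lists))
    seen, out = set(), []
    for c in cands:
        key = tuple(round(x, 4) for x in c)
        if key not in seen:
            seen.add(key)
            out.append(c)
    return out


class _Packer:
    """Single-sequence rotamer packer operating on a TorsionSystem state."""

    def __init__(self, sys: TorsionSystem, w: EnergyWeights,
                 cst: CompiledRestraints | NullRestraints, cst_weight: float,
                 extra_rotamers: bool = False):
        self.sys = sys
        self.topo = sys.topo
        self.w = w
        self.cst = cst
        self.cst_w = cst_weight
        self.extra = extra_rotamers

    def _movable(self, i: int) -> np.ndarray:
        aa = self.sys.sequence[i]
        idx = self.topo.index_of
        names = [n for n in T.template_atom_names(aa)
                 if n not in ("N", "CA", "C", "O", "CB")]
        return np.array([idx[(i + 1, n)] for n in names], dtype=int)

    def _prepare_residue(self, i: int) -> dict:
        mov = self._movable(i)
        incl_env = self.topo.incl_mat[mov].copy()
        incl_env[:, mov] = False
        return dict(
            mov=mov,
            incl_env=incl_env,
            sigma_env=np.ascontiguousarray(self.topo.sigma_mat[mov]),
            incl_mm=np.ascontiguousarray(self.topo.incl_mat[np.ix_(mov, mov)]),
            sigma_mm=np.ascontiguousarray(self.topo.sigma_mat[np.ix_(mov, mov)]),
            cst_eval=self.cst.residue_evaluator(mov))

    def _candidate_energy(self, coords: np.ndarray, pre: dict,
                          cand_coords: np.ndarray, aa: str, chis: tuple) -> float:
        """Interaction + rotamer + restraint energy of one residue's moving
        atoms in the current environment."""
        from ._kernels import group_env_energy, group_intra_energy
        from .energy import _soft_factor
        e = self.w.w_rot * rot_energy_chi(aa, list(chis))
        if len(pre["mov"]):
            soft = _soft_factor(self.w.rep_mode)
            e += group_env_energy(cand_coords, coords, pre["incl_env"],
                                  pre["sigma_env"], soft, self.w.w_rep,
                                  self.w.w_atr)
            if len(pre["mov"]) > 1:
                e += group_intra_energy(cand_coords, pre["incl_mm"],
                                        pre["sigma_mm"], soft, self.w.w_rep,
                                        self.w.w_atr)
            if pre["cst_eval"].active:
                e += self.cst_w * pre["cst_eval"](coords, cand_coords)
        return e

    def total_objective(self, coords: np.ndarray, tv: np.ndarray) -> float:
        e_nb, _ = nonbonded_energy_forces(coords, self.topo, self.w)
        return e_nb + self.w.w_rot * self.sys.rot_energy(tv) + \
            self.cst_w * self.cst.energy(coords)

    def run(self, coords: np.ndarray, tv: np.ndarray, rng: np.random.Generator
            ) -> tuple[np.ndarray, np.ndarray]:
        sys = self.sys
        coords = coords.copy()
        tv = tv.copy()
        start_obj = self.total_objective(coords, tv)
        start_coords, start_tv = coords.copy(), tv.copy()

        residues = [i for i, aa in enumerate(sys.sequence)
                    if T.chi_count(aa) and aa != "P"]
        if not residues:
            return coords, tv
        from .structure import place_sidechain
        cands: dict[int, list[tuple]] = {}
        cand_coords: dict[int, list[np.ndarray]] = {}
        pres: dict[int, dict] = {}
        cur: dict[int, int] = {}
        for i in residues:
            aa = sys.sequence[i]
            chis0 = sys.residue_chis(tv, i)
            cl = _rotamer_candidates(aa, chis0, self.extra)
            pre = self._prepare_residue(i)
            ri = i + 1
            bb = {n: tuple(coords[self.topo.index_of[(ri, n)]])
                  for n in ("N", "CA", "C")}
            names = [n for n in T.template_atom_names(aa)
                     if n not in ("N", "CA", "C", "O", "CB")]
            cc = []
            for chis in cl:
                placed = place_sidechain(aa, bb, list(chis))
                cc.append(np.array([placed[n] for n in names]))
            cands[i], cand_coords[i], pres[i], cur[i] = cl, cc, pre, 0

        def cand_e(i: int, ci: int) -> float:
            return self._candidate_energy(coords, pres[i], cand_coords[i][ci],
                                          sys.sequence[i], cands[i][ci])

        def apply(i: int, ci: int):
            coords[pres[i]["mov"]] = cand_coords[i][ci]
            for k, c in enumerate(cands[i][ci]):
                tv[sys.tor_index[(i, "chi", k)]] = c
            cur[i] = ci

        for temp in ANNEAL_TEMPS:
            for i in rng.permutation(residues):
                nc = len(cands[i])
                if nc < 2:
                    continue
                ci = int(rng.integers(nc))
                if ci == cur[i]:
                    continue
                de = cand_e(i, ci) - cand_e(i, cur[i])
                if de <= 0 or rng.random() < math.exp(-de / temp):
                    apply(i, ci)
        # zero-temperature greedy sweep
        for i in residues:
            energies = [cand_e(i, ci) for ci in range(len(cands[i]))]
            best = int(np.argmin(energies))
            if best != cur[i]:
                apply(i, best)
        # packer contract: never return an assignment worse than the input
        if self.total_objective(coords, tv) > start_obj + 1e-12:
            return start_coords, start_tv
        return coords, tv


def repack(s: Structure, w: EnergyWeights, restraints: RestraintSet | None,
           rng: np.random.Generator | int = 0,
           extra_rotamers: bool = False) -> Structure:
    """Simulated-annealing rotamer repack (sequence and backbone fixed)."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    sys = TorsionSystem(s)
    coords = sys.rebuild()
    cst = _compile(restraints, sys)
    packer = _Packer(sys, w, cst, 1.0, extra_rotamers)
    coords, tv = packer.run(coords, sys.torsions, rng)
    return sys.write_to(s, coords)


# ================================================================= minimization

def _compile(restraints: RestraintSet | None, sys: TorsionSystem):
    if restraints is None:
        return NullRestraints(sys.topo.n)
    return CompiledRestraints(restraints, sys.topo.index_of, sys.topo.n)


def _rot_energy_grad(sys: TorsionSystem, tv: np.ndarray
                     ) -> tuple[float, np.ndarray]:
    e = 0.0
    g = np.zeros(len(tv))
    for i, aa in enumerate(sys.sequence):
        wells = T.chi_wells(aa)
        for k in range(T.chi_count(aa)):
            t = sys.tor_index[(i, "chi", k)]
            c = tv[t]
            devs = [wrap_angle(c - w) for w in wells[k]]
            dev = min(devs, key=abs)
            e += (dev / SIGMA_CHI) ** 2
            g[t] = 2.0 * dev / SIGMA_CHI ** 2
    return e, g


def _minimize_system(sys: TorsionSystem, tv0: np.ndarray, w: EnergyWeights,
                     cst, cst_weight: float, cfg: RelaxConfig,
                     dof_filter=None) -> tuple[np.ndarray, np.ndarray, float]:
    """L-BFGS over the active torsions; returns (coords, torsions, energy).
    Guaranteed not to end above the starting energy."""
    dofs = [d for d in sys.dofs if dof_filter is None or dof_filter(d)]
    if not dofs:
        coords = sys.rebuild(tv0)
        packer = _Packer(sys, w, cst, cst_weight)
        return coords, tv0.copy(), packer.total_objective(coords, tv0)
    act = np.array([d["t"] for d in dofs], dtype=int)
    deg2rad = math.pi / 180.0
    best = {"e": np.inf, "x": None}

    # vectorized DOF metadata
    ax_a = np.array([d["axis"][0] for d in dofs], dtype=int)
    ax_b = np.array([d["axis"][1] for d in dofs], dtype=int)
    kinds = np.array([{"phi": 0, "psi": 1, "chi": 2}[d["kind"]] for d in dofs])
    sel_phi = kinds == 0
    sel_psi = kinds == 1
    sel_chi = kinds == 2
    phi_suffix = np.array([d["suffix_start"] for d in dofs if d["kind"] == "phi"],
                          dtype=int)
    psi_o = np.array([d["o_idx"] for d in dofs if d["kind"] == "psi"], dtype=int)
    psi_ns = np.array([d["next_start"] for d in dofs if d["kind"] == "psi"],
                      dtype=int)
    chi_moved = [d["moved"] for d in dofs if d["kind"] == "chi"]
    chi_flat = np.concatenate(chi_moved) if chi_moved else np.empty(0, dtype=int)
    chi_off = np.cumsum([0] + [len(m) for m in chi_moved[:-1]]).astype(int) \
        if chi_moved else np.empty(0, dtype=int)

    def objective(x):
        tv = tv0.copy()
        tv[act] = x
        coords = sys.rebuild(tv)
        e_nb, F = nonbonded_energy_forces(coords, sys.topo, w)
        e_cst, F_cst = cst.energy_forces(coords)
        e_cst *= cst_weight
        F = F + cst_weight * F_cst
        e_rot, g_rot = _rot_energy_grad(sys, tv)
        e = e_nb + e_cst + w.w_rot * e_rot
        if not np.isfinite(e):
            raise FloatingPointError("non-finite energy during minimization")
        # torsion gradient via torque sums: dE/dtheta = u . sum_m (x_m - p) x F_m
        # backbone DOFs move contiguous tail blocks, so suffix sums give O(1)
        # lookups per DOF; chi downstream sets use segment sums
        cross = np.cross(coords, F)
        S_xF = np.zeros((len(coords) + 1, 3))
        S_xF[:-1] = np.cumsum(cross[::-1], axis=0)[::-1]
        S_F = np.zeros((len(coords) + 1, 3))
        S_F[:-1] = np.cumsum(F[::-1], axis=0)[::-1]
        tq = np.empty((len(dofs), 3))
        fs = np.empty((len(dofs), 3))
        tq[sel_phi] = S_xF[phi_suffix]
        fs[sel_phi] = S_F[phi_suffix]
        tq[sel_psi] = cross[psi_o] + S_xF[psi_ns]
        fs[sel_psi] = F[psi_o] + S_F[psi_ns]
        if len(chi_flat):
            tq[sel_chi] = np.add.reduceat(cross[chi_flat], chi_off, axis=0)
            fs[sel_chi] = np.add.reduceat(F[chi_flat], chi_off, axis=0)
        u = coords[ax_b] - coords[ax_a]
        u /= np.linalg.norm(u, axis=1)[:, None]
        arm = tq - np.cross(coords[ax_b], fs)
        g = deg2rad * np.einsum("ij,ij->i", u, arm) + w.w_rot * g_rot[act]
        if e < best["e"]:
            best["e"] = e
            best["x"] = x.copy()
        return e, g

    x0 = tv0[act].copy()
    _scipy_minimize(objective, x0, jac=True, method="L-BFGS-B",
                    options={"maxiter": cfg.max_min_iters,
                             "gtol": cfg.min_tolerance, "ftol": 1e-12})
    tv = tv0.copy()
    tv[act] = best["x"] if best["x"] is not None else x0
    for j in act:
        tv[j] = wrap_angle(tv[j])
    coords = sys.rebuild(tv)
    return coords, tv, best["e"]


def minimize(s: Structure, w: EnergyWeights, restraints: RestraintSet | None,
             cfg: RelaxConfig | None = None, dofs: str = "all") -> Structure:
    """Gradient-based torsion minimization of the total energy.

    dofs: "all" (phi/psi/chi) or "chi" (sidechains only, fixed backbone)."""
    cfg = cfg or RelaxConfig()
    sys = TorsionSystem(s)
    cst = _compile(restraints, sys)
    dof_filter = None if dofs == "all" else (lambda d: d["kind"] == "chi")
    coords, tv, _ = _minimize_system(sys, sys.torsions, w, cst, 1.0, cfg,
                                     dof_filter)
    return sys.write_to(s, coords)


# ==================================================================== fast relax

def fast_relax(s: Structure, restraints: RestraintSet | None,
               cfg: RelaxConfig | None = None) -> RelaxResult:
    """The five-cycle repack/minimize protocol with repulsive-weight ramping."""
    cfg = cfg or RelaxConfig()
    rng = np.random.default_rng(cfg.seed)
    sys = TorsionSystem(s)
    cst = _compile(restraints, sys)
    tv = sys.torsions.copy()
    coords = sys.rebuild(tv)
    trajectory: list[StageRecord] = []
    for cycle in range(cfg.n_cycles):
        for stage, w_rep in enumerate(cfg.rep_schedule):
            w = EnergyWeights(w_rep=w_rep)
            cw = cfg.stage_cst_weight(stage)
            packer = _Packer(sys, w, cst, cw, cfg.extra_rotamers)
            coords, tv = packer.run(coords, tv, rng)
            coords, tv, e = _minimize_system(sys, tv, w, cst, cw, cfg)
            trajectory.append(StageRecord(cycle, stage, w_rep, cw, e))
    final = sys.write_to(s, coords)
    final_score = score(final, EnergyWeights(), None)
    return RelaxResult(final=final, trajectory=trajectory,
                       final_score=final_score,
                       rmsd_to_input=rmsd_all_atom(s, final), seed=cfg.seed)


@dataclass
class ReplicateSummary:
    results: list[RelaxResult]
    median_energy_per_residue: float
    median_rmsd: float
    energy_range: float
    rmsd_range: float


def relax_replicates(s: Structure, restraints: RestraintSet | None,
                     cfg: RelaxConfig | None = None, n: int = 10,
                     seeds: Sequence[int] | None = None) -> ReplicateSummary:
    """n independent relax replicates; medians and ranges of per-residue
    energy and RMSD-to-input across replicates."""
    cfg = cfg or RelaxConfig()
    if n < 1:
        raise ValueError("n must be >= 1")
    if seeds is None:
        seeds = [cfg.seed + 1000 * k for k in range(n)]
    if len(set(seeds)) != len(seeds) or len(seeds) != n:
        raise ValueError("seeds must be n distinct values")
    results = [fast_relax(s, restraints, replace(cfg, seed=int(sd)))
               for sd in seeds]
    eng = np.array([r.final_score.per_residue_mean for r in results])
    rms = np.array([r.rmsd_to_input for r in results])
    return ReplicateSummary(
        results=results,
        median_energy_per_residue=float(np.median(eng)),
        median_rmsd=float(np.median(rms)),
        energy_range=float(eng.max() - eng.min()),
        rmsd_range=float(rms.max() - rms.min()))
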