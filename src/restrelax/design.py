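"""Fixed-backbone sequence design in distance-defined shells and
sequence-recovery evaluation.

Residues within ``cut_design`` of the functional site may change amino-acid
identity and rotamer; residues within ``cut_repack`` may change rotamer only;
everything else is fixed. Design runs two annealing cycles — the first with a
soft (shrunken-radius) repulsive term, the second with the standard one —
optionally followed by continuous sidechain (chi) minimization after each
cycle. The native identity and the input rotamer are always among the
candidates.

Sequence recovery is the fraction of designable positions at which the
native amino acid is re-selected; it is the quantity that degrades when a
design calculation is fed a strained input structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from . import templates as T
from .energy import EnergyWeights, SCALE_15, score
from .geometry import wrap_angle
from .relax import RelaxConfig, fast_relax, minimize
from .restraints import build_coordinate_restraints, build_scsc_restraints
from .structure import (Atom, Structure, measure_torsions,
                        place_sidechain)

# Per-residue-type reference energies (units), fitted once to maximize native
# sequence recovery on strain-free ideal-geometry fixtures — the usual way
# design force fields balance identity choices against raw sidechain size.
# Larger value = stronger penalty for choosing that type.
REF_ENERGIES = {
    "A": 0.000, "C": 2.550, "D": 2.600, "E": 2.450, "F": 3.300,
    "G": 2.550, "H": 2.900, "I": 2.500, "K": 2.750, "L": 2.050,
    "M": 2.900, "N": 2.600, "P": 2.550, "Q": 2.750, "R": 4.150,
    "S": 0.550, "T": 1.250, "V": 1.600, "W": 5.000, "Y": 4.000,
}

ANNEAL_TEMPS = (10.0, 3.0, 1.0, 0.3)


@dataclass
class ShellDefinition:
    site: object                      # residue index list OR (3,) point in Å
    cut_design: float = 6.0
    cut_repack: float = 12.0
    cut2: float = 8.0                 # recorded for forward compatibility
    cut3: float = 10.0

    def __post_init__(self):
        if not 0 < self.cut_design <= self.cut_repack:
            raise ValueError("need 0 < cut_design <= cut_repack")


@dataclass
class DesignConfig:
    n_cycles: int = 2                 # soft cycle, then standard
    allowed_aas: str = T.CANONICAL_AAS
    chi_min: bool = True
    n_runs: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        bad = set(self.allowed_aas) - set(T.CANONICAL_AAS)
        if bad:
            raise ValueError(f"non-canonical letters in allowed_aas: {bad}")


@dataclass
class RecoveryReport:
    per_position: list[tuple[int, str, str]]   # (index, native, designed)
    recovery: float | None

    @classmethod
    def from_positions(cls, rows):
        if not rows:
            return cls(per_position=[], recovery=None)
        hits = sum(1 for _, nat, des in rows if nat == des)
        return cls(per_position=rows, recovery=hits / len(rows))


def _site_coords(s: Structure, site) -> np.ndarray:
    if isinstance(site, (list, tuple, set)) and site and \
            all(isinstance(x, (int, np.integer)) for x in site):
        pts = [a.coord for idx in sorted(site) for a in s.residue(idx).heavy_atoms()]
        return np.array(pts)
    arr = np.asarray(site, float)
    if arr.shape == (3,):
        return arr.reshape(1, 3)
    raise ValueError("site must be residue indices or a 3-vector")


def detect_design_shell(s: Structure, shell: ShellDefinition
                        ) -> tuple[set[int], set[int]]:
    """(designable, repackable) residue index sets; disjoint by construction."""
    site = _site_coords(s, shell.site)
    if site.size == 0:
        raise ValueError("empty site")
    designable, repackable = set(), set()
    for r in s.residues:
        X = np.array([a.coord for a in r.heavy_atoms()])
        dmin = np.sqrt(((X[:, None, :] - site[None, :, :]) ** 2).sum(-1)).min()
        if dmin <= shell.cut_design:
            designable.add(r.index)
        elif dmin <= shell.cut_repack:
            repackable.add(r.index)
    return designable, repackable


# ------------------------------------------------------------- residue metadata

class _AAInfo:
    """Per-residue-type tables used by the design annealer."""

    _cache: dict[str, "_AAInfo"] = {}

    def __init__(self, aa: str):
        self.aa = aa
        self.sc_names = [n for n in T.template_atom_names(aa)
                         if n not in T.BACKBONE_NAMES]
        names = list(T.BACKBONE_NAMES) + self.sc_names
        order = {n: k for k, n in enumerate(names)}
        adj = {n: set() for n in names}
        for a, b in T.residue_bonds(aa):
            adj[a].add(b)
            adj[b].add(a)

        def bfs(src):
            dist = {src: 0}
            frontier = [src]
            while frontier:
                nxt = []
                for u in frontier:
                    for v in adj[u]:
                        if v not in dist:
                            dist[v] = dist[u] + 1
                            nxt.append(v)
                frontier = nxt
            return dist

        dN, dC = bfs("N"), bfs("C")
        self.d_to_N = np.array([dN[n] for n in names], dtype=np.int64)
        self.d_to_C = np.array([dC[n] for n in names], dtype=np.int64)
        self.sc_d_to_N = self.d_to_N[4:]
        self.sc_d_to_C = self.d_to_C[4:]
        self.radii = np.array([T.VDW_RADII[T.element_of(n)] for n in names])
        self.sc_radii = self.radii[4:]

        m = len(self.sc_names)
        pair_d = {}
        for src in names:
            dd = bfs(src)
            for tgt in names:
                pair_d[(src, tgt)] = dd[tgt]
        self.bb_incl = np.zeros((m, 4), dtype=bool)
        self.bb_sigma = np.zeros((m, 4))
        for a, an in enumerate(self.sc_names):
            for b, bn in enumerate(T.BACKBONE_NAMES):
                bd = pair_d[(an, bn)]
                self.bb_incl[a, b] = bd > 3
                self.bb_sigma[a, b] = (self.radii[4 + a] + self.radii[b]) * \
                    (SCALE_15 if bd == 4 else 1.0)
        self.intra_incl = np.zeros((m, m), dtype=bool)
        self.intra_sigma = np.zeros((m, m))
        for a in range(m):
            for b in range(m):
                bd = pair_d[(self.sc_names[a], self.sc_names[b])]
                self.intra_incl[a, b] = a < b and bd > 3
                self.intra_sigma[a, b] = (self.radii[4 + a] + self.radii[4 + b]) * \
                    (SCALE_15 if bd == 4 else 1.0)
        self.n_sc = m
        self.ref_energy = REF_ENERGIES[aa]
        self.rotamers = [tuple(c) for c in product(*T.chi_wells(aa))] \
            if T.chi_count(aa) else [()]

    @classmethod
    def get(cls, aa: str) -> "_AAInfo":
        if aa not in cls._cache:
            cls._cache[aa] = cls(aa)
        return cls._cache[aa]


# -------------------------------------------------------------- design annealer

class _DesignState:
    def __init__(self, s: Structure):
        self.n = len(s)
        self.seq = list(s.sequence)
        self.backbone = []            # (4,3) arrays
        self.sc_coords = []           # (m,3) arrays
        self.chis = []
        for r in s.residues:
            self.backbone.append(np.array([r.atom(n).coord
                                           for n in T.BACKBONE_NAMES]))
            info = _AAInfo.get(r.aa)
            self.sc_coords.append(np.array([r.atom(n).coord
                                            for n in info.sc_names]).reshape(-1, 3))
            self.chis.append(list(r.chi))
        self._flat = None

    def flat_env(self):
        if self._flat is None:
            coords, radii, res_of, dN, dC = [], [], [], [], []
            for i in range(self.n):
                info = _AAInfo.get(self.seq[i])
                coords.append(self.backbone[i])
                coords.append(self.sc_coords[i])
                radii.append(info.radii)
                res_of.append(np.full(4 + info.n_sc, i, dtype=np.int64))
                dN.append(info.d_to_N)
                dC.append(info.d_to_C)
            self._flat = (np.ascontiguousarray(np.concatenate(coords)),
                          np.concatenate(radii),
                          np.concatenate(res_of),
                          np.concatenate(dN), np.concatenate(dC))
        return self._flat

    def set_residue(self, i: int, aa: str, chis, sc_coords: np.ndarray):
        self.seq[i] = aa
        self.chis[i] = list(chis)
        self.sc_coords[i] = sc_coords
        self._flat = None

    def to_structure(self, template: Structure) -> Structure:
        out = template.copy()
        for i, r in enumerate(out.residues):
            aa = self.seq[i]
            info = _AAInfo.get(aa)
            r.aa = aa
            r.res_name = T.AA1_TO_3[aa]
            bb = {a.name: a for a in r.atoms if a.name in T.BACKBONE_NAMES}
            r.atoms = [bb[n] for n in T.BACKBONE_NAMES]
            for k, name in enumerate(info.sc_names):
                r.atoms.append(Atom(name, T.element_of(name),
                                    self.sc_coords[i][k].copy(),
                                    is_backbone=False))
        measure_torsions(out)
        return out


def _candidate_energy(state: _DesignState, i: int, aa: str, chis,
                      sc: np.ndarray, w: EnergyWeights) -> float:
    from ._kernels import (_pair_e_dedr, design_env_energy,
                           group_intra_energy)
    from .energy import _soft_factor, rot_energy_chi
    info = _AAInfo.get(aa)
    soft = _soft_factor(w.rep_mode)
    e = w.w_rot * rot_energy_chi(aa, list(chis)) + info.ref_energy
    if info.n_sc:
        X, radii, res_of, dN, dC = state.flat_env()
        e += design_env_energy(sc, info.sc_radii, info.sc_d_to_N,
                               info.sc_d_to_C, X, radii, res_of, dN, dC,
                               i, SCALE_15, soft, w.w_rep, w.w_atr)
        # own backbone
        bb = state.backbone[i]
        for a in range(info.n_sc):
            for b in range(4):
                if not info.bb_incl[a, b]:
                    continue
                d = float(np.linalg.norm(sc[a] - bb[b]))
                sig = info.bb_sigma[a, b]
                ea, _ = _pair_e_dedr(d, sig, sig * soft, w.w_rep, w.w_atr)
                e += ea
        if info.n_sc > 1:
            e += group_intra_energy(sc, info.intra_incl, info.intra_sigma,
                                    soft, w.w_rep, w.w_atr)
    return e


def _position_candidates(state: _DesignState, i: int, allowed: str,
                         native_aa: str, native_chis) -> list[tuple]:
    """(aa, chis) candidates; the native identity is always present."""
    out = []
    aas = sorted(set(allowed) | {native_aa})
    for aa in aas:
        info = _AAInfo.get(aa)
        rots = list(info.rotamers)
        if aa == state.seq[i] and tuple(state.chis[i]) not in rots:
            rots.append(tuple(state.chis[i]))
        if aa == native_aa and tuple(native_chis) not in rots:
            rots.append(tuple(native_chis))
        if aa in T.FLIP_CHI:
            k = T.FLIP_CHI[aa] - 1
            extra = []
            for rc in rots:
                fl = list(rc)
                fl[k] = wrap_angle(fl[k] + 180.0)
                if tuple(fl) not in rots:
                    extra.append(tuple(fl))
            rots.extend(extra)
        out.extend((aa, rc) for rc in rots)
    return out


def design(s: Structure, shells, dcfg: DesignConfig,
           rng: np.random.Generator | int = 0
           ) -> tuple[Structure, RecoveryReport]:
    """One design run. shells is a ShellDefinition or an explicit
    (designable, repackable) pair of residue-index sets."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if isinstance(shells, ShellDefinition):
        designable, repackable = detect_design_shell(s, shells)
    else:
        designable, repackable = (set(shells[0]), set(shells[1]))
        if designable & repackable:
            raise ValueError("designable and repackable sets overlap")

    native = {r.index: (r.aa, tuple(r.chi)) for r in s.residues}
    state = _DesignState(s)

    if not designable:
        return s.copy(), RecoveryReport.from_positions([])

    def anneal_cycle(w: EnergyWeights):
        positions = sorted(designable | repackable)
        # candidate (aa, chis, sidechain coords) per position; the backbone is
        # fixed throughout, so coordinates are placed once per cycle
        cand: dict[int, list[tuple]] = {}
        for idx in positions:
            i = idx - 1
            if idx in designable:
                raw = _position_candidates(state, i, dcfg.allowed_aas,
                                           *native[idx])
            else:
                raw = _position_candidates(state, i, state.seq[i],
                                           state.seq[i],
                                           tuple(state.chis[i]))
            bb = {n: tuple(state.backbone[i][k])
                  for k, n in enumerate(("N", "CA", "C"))}
            built = []
            for aa, chis in raw:
                info = _AAInfo.get(aa)
                placed = place_sidechain(aa, bb, list(chis))
                built.append((aa, chis,
                              np.array([placed[n] for n in info.sc_names]
                                       ).reshape(-1, 3)))
            cand[idx] = built
        for temp in ANNEAL_TEMPS + (None,):
            order = (rng.permutation(positions) if temp is not None
                     else positions)
            for idx in order:
                i = idx - 1
                cur_aa, cur_chis = state.seq[i], tuple(state.chis[i])
                e_cur = _candidate_energy(state, i, cur_aa, cur_chis,
                                          state.sc_coords[i], w)
                if temp is not None:
                    aa, chis, sc = cand[idx][int(rng.integers(len(cand[idx])))]
                    if aa == cur_aa and tuple(chis) == cur_chis:
                        continue
                    de = _candidate_energy(state, i, aa, chis, sc, w) - e_cur
                    if de <= 0 or rng.random() < math.exp(-de / temp):
                        state.set_residue(i, aa, chis, sc)
                    continue
                best = (e_cur, None)
                for aa, chis, sc in cand[idx]:
                    if aa == cur_aa and tuple(chis) == cur_chis:
                        continue
                    e_new = _candidate_energy(state, i, aa, chis, sc, w)
                    if e_new < best[0]:
                        best = (e_new, (aa, chis, sc))
                if best[1] is not None:
                    state.set_residue(i, *best[1])

    for cycle in range(dcfg.n_cycles):
        mode = "soft" if cycle < dcfg.n_cycles - 1 else "standard"
        anneal_cycle(EnergyWeights(rep_mode=mode))
        if dcfg.chi_min:
            stru = state.to_structure(s)
            stru = minimize(stru, EnergyWeights(rep_mode=mode), None,
                            RelaxConfig(max_min_iters=100), dofs="chi")
            refreshed = _DesignState(stru)
            state.backbone = refreshed.backbone
            state.sc_coords = refreshed.sc_coords
            state.chis = refreshed.chis
            state._flat = None

    final = state.to_structure(s)
    rows = [(idx, native[idx][0], final.residue(idx).aa)
            for idx in sorted(designable)]
    return final, RecoveryReport.from_positions(rows)


# ------------------------------------------------------- recovery experiments

PRETREATMENTS = ("none", "unrestrained", "bb", "bb+scsc", "bb+sccoord",
                 "ex_rotamers")


def _pretreat(s: Structure, label: str, relax_cfg: RelaxConfig,
              sd: float = 0.5, scsc_cutoff: float = 6.0):
    if label == "none":
        return s.copy()
    if label == "unrestrained":
        return fast_relax(s, None, relax_cfg).final
    if label == "bb":
        rs = build_coordinate_restraints(s, "backbone_heavy", "harmonic", sd)
    elif label == "bb+scsc":
        rs = build_scsc_restraints(s, scsc_cutoff)
    elif label == "bb+sccoord":
        rs = build_coordinate_restraints(s, "all_heavy", "harmonic", sd)
    elif label == "ex_rotamers":
        rs = build_coordinate_restraints(s, "all_heavy", "harmonic", sd)
        relax_cfg = RelaxConfig(**{**relax_cfg.__dict__, "extra_rotamers": True})
    else:
        raise ValueError(f"unknown pretreatment {label!r}")
    return fast_relax(s, rs, relax_cfg).final


def recovery_experiment(s: Structure, pretreatments, dcfg: DesignConfig,
                        shell: ShellDefinition,
                        relax_cfg: RelaxConfig | None = None) -> pd.DataFrame:
    """For each pretreatment protocol: relax (or not), then run n_runs designs
    and report mean sequence recovery, the pretreated structure's all-atom
    RMSD to the input, and its per-residue energy."""
    from .pareto import rmsd_all_atom
    if not pretreatments:
        raise ValueError("need at least one pretreatment")
    relax_cfg = relax_cfg or RelaxConfig()
    rows = []
    for label in pretreatments:
        pre = _pretreat(s, label, relax_cfg)
        recs = []
        for k in range(dcfg.n_runs):
            _, rep = design(pre, shell, dcfg,
                            rng=np.random.default_rng(dcfg.seed + 7919 * k))
            if rep.recovery is not None:
                recs.append(rep.recovery)
        rows.append({
            "pretreatment": label,
            "mean_recovery": float(np.mean(recs)) if recs else np.nan,
            "rmsd_to_input": rmsd_all_atom(s, pre),
            "energy_per_residue": score(pre).per_residue_mean,
        })
    return pd.DataFrame(rows)
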