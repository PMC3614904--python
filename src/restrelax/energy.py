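"""Simplified all-atom energy with per-term and per-residue decomposition.

Three physical channels plus restraints:

* ``rep`` — clamped inverse-12 clash term: (sigma_ij/d)^12 - 1 for d < sigma_ij,
  0 at and beyond contact, linearized below 0.6*sigma_ij so gradients stay
  bounded. sigma_ij is the sum of per-element radii; "soft" mode shrinks all
  radii by 0.9.
* ``atr`` — a small Lennard-Jones well (depth eps at d = sigma_ij), clamped to
  -eps inside contact so the attractive channel never fights the clash term,
  smoothly switched off between 5.5 and 6 Å.
* ``rot`` — rotamer strain: for each chi, the squared deviation (in units of
  sigma_chi = 20 deg) from the nearest rotamer well.
* ``cst`` — restraint energy (see :mod:`restrelax.restraints`), zero when no
  restraint set is given.

Pairs separated by three or fewer bonds are excluded from rep/atr, and pairs
exactly four bonds apart (1-5 pairs, whose separation is largely fixed by the
covalent geometry) use contact radii scaled by 0.85, the usual near-bonded
attenuation. Pairwise energies are split half/half between the two residues
for per-residue reporting, which keeps the decomposition exactly conservative.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import templates as T
from .structure import Structure, StructureError
from .geometry import dihedral, wrap_angle

ATR_EPS = 0.2          # depth of the attractive well (energy units)
ATR_CUTOFF = 6.0       # Å, hard truncation
ATR_SWITCH = 5.5       # Å, start of the smooth switch
SOFT_FACTOR = 0.9      # radius shrink factor in soft repulsive mode
SCALE_15 = 0.85        # sigma attenuation for pairs exactly 4 bonds apart
REP_LIN_FRACTION = 0.6  # linearize rep below this fraction of sigma
SIGMA_CHI = 20.0       # deg, width of a rotamer well

TERM_NAMES = ("rep", "atr", "rot", "cst")


@dataclass(frozen=True)
class EnergyWeights:
    w_rep: float = 1.0
    w_atr: float = 1.0
    w_rot: float = 1.0
    w_cst: float = 1.0
    rep_mode: str = "standard"

    def __post_init__(self):
        for w in (self.w_rep, self.w_atr, self.w_rot, self.w_cst):
            if w < 0:
                raise ValueError("energy weights must be >= 0")
        if self.rep_mode not in ("standard", "soft"):
            raise ValueError("rep_mode must be 'standard' or 'soft'")

    def with_rep(self, w_rep: float) -> "EnergyWeights":
        return replace(self, w_rep=w_rep)


@dataclass
class ScoreBreakdown:
    total: float
    by_term: dict[str, float]
    by_residue: np.ndarray
    by_residue_term: dict[str, np.ndarray]
    residue_index: list[int]
    aas: list[str]

    @property
    def per_residue_mean(self) -> float:
        return self.total / len(self.by_residue)

    def table(self) -> pd.DataFrame:
        df = pd.DataFrame({"residue": self.residue_index, "aa": self.aas})
        for t in TERM_NAMES:
            df[t] = self.by_residue_term[t]
        df["total"] = self.by_residue
        return df

    def to_tsv(self, path: str) -> None:
        self.table().to_csv(path, sep="\t", index=False, float_format="%.6f")


class Topology:
    """Flattened heavy-atom view of a cleaned structure with the 1-4 exclusion
    graph precomputed. Depends only on the sequence, so instances are cached."""

    _cache: dict[str, "Topology"] = {}

    def __init__(self, sequence: str):
        self.sequence = sequence
        refs: list[tuple[int, str]] = []
        res_of: list[int] = []
        radii: list[float] = []
        index_of: dict[tuple[int, str], int] = {}
        for ri, aa in enumerate(sequence):
            for name in T.template_atom_names(aa):
                index_of[(ri + 1, name)] = len(refs)
                refs.append((ri + 1, name))
                res_of.append(ri)
                radii.append(T.VDW_RADII[T.element_of(name)])
        self.refs = refs
        self.index_of = index_of
        self.n = len(refs)
        self.res_of = np.array(res_of)
        self.radii = np.array(radii)
        self.n_res = len(sequence)

        adj = [[] for _ in range(self.n)]
        for ri, aa in enumerate(sequence):
            for a, b in T.residue_bonds(aa):
                ia, ib = index_of[(ri + 1, a)], index_of[(ri + 1, b)]
                adj[ia].append(ib)
                adj[ib].append(ia)
            if ri + 1 < len(sequence):
                ia, ib = index_of[(ri + 1, "C")], index_of[(ri + 2, "N")]
                adj[ia].append(ib)
                adj[ib].append(ia)

        excl = np.zeros((self.n, self.n), dtype=bool)
        near15 = np.zeros((self.n, self.n), dtype=bool)
        np.fill_diagonal(excl, True)
        for i in range(self.n):
            # BFS to bond depth 4: depth <= 3 excluded, depth == 4 attenuated
            seen = {i: 0}
            frontier = [i]
            for depth in range(1, 5):
                nxt = []
                for u in frontier:
                    for v in adj[u]:
                        if v not in seen:
                            seen[v] = depth
                            nxt.append(v)
                frontier = nxt
            for v, depth in seen.items():
                if depth <= 3:
                    excl[i, v] = True
                    excl[v, i] = True
                else:
                    near15[i, v] = True
                    near15[v, i] = True
        near15 &= ~excl
        self.excl = excl
        iu, ju = np.triu_indices(self.n, k=1)
        keep = ~excl[iu, ju]
        self.pi = iu[keep]
        self.pj = ju[keep]
        scale = np.where(near15[self.pi, self.pj], SCALE_15, 1.0)
        self.sigma = (self.radii[self.pi] + self.radii[self.pj]) * scale
        # full matrices for the packer's subset scoring
        self.sigma_mat = (self.radii[:, None] + self.radii[None, :]) * \
            np.where(near15, SCALE_15, 1.0)
        self.incl_mat = ~excl

    @classmethod
    def for_structure(cls, s: Structure) -> "Topology":
        seq = s.sequence
        if seq not in cls._cache:
            if len(cls._cache) > 64:
                cls._cache.clear()
            cls._cache[seq] = cls(seq)
        return cls._cache[seq]

    def coords(self, s: Structure) -> np.ndarray:
        out = np.empty((self.n, 3))
        k = 0
        for r in s.residues:
            for name in T.template_atom_names(r.aa):
                out[k] = r.atom(name).coord
                k += 1
        return out


# ------------------------------------------------------------ pairwise kernels

def rep_energy_scalar(d: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Clash energy per pair; vectorized over matching-shape arrays."""
    d = np.asarray(d, float)
    sigma = np.asarray(sigma, float)
    e = np.zeros(np.broadcast(d, sigma).shape)
    d, sigma = np.broadcast_arrays(d, sigma)
    inside = d < sigma
    if np.any(inside):
        dlin = REP_LIN_FRACTION * sigma
        quad = inside & (d >= dlin)
        e[quad] = (sigma[quad] / d[quad]) ** 12 - 1.0
        lin = inside & (d < dlin)
        if np.any(lin):
            f0 = REP_LIN_FRACTION ** -12 - 1.0
            slope = 12.0 * REP_LIN_FRACTION ** -13 / sigma[lin]  # -f'(dlin)
            e[lin] = f0 + slope * (dlin[lin] - d[lin])
    return e


def rep_dedr(d: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """d(rep)/dd per pair."""
    d, sigma = np.broadcast_arrays(np.asarray(d, float), np.asarray(sigma, float))
    g = np.zeros(d.shape)
    dlin = REP_LIN_FRACTION * sigma
    quad = (d < sigma) & (d >= dlin)
    g[quad] = -12.0 * (sigma[quad] / d[quad]) ** 12 / d[quad]
    lin = d < dlin
    g[lin] = -12.0 * REP_LIN_FRACTION ** -13 / sigma[lin]
    return g


def _switch(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Smoothstep 1 -> 0 over [ATR_SWITCH, ATR_CUTOFF]; returns (S, dS/dd)."""
    t = np.clip((d - ATR_SWITCH) / (ATR_CUTOFF - ATR_SWITCH), 0.0, 1.0)
    s = 1.0 - t * t * (3.0 - 2.0 * t)
    ds = -6.0 * t * (1.0 - t) / (ATR_CUTOFF - ATR_SWITCH)
    return s, ds


def atr_energy_scalar(d: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    d, sigma = np.broadcast_arrays(np.asarray(d, float), np.asarray(sigma, float))
    e = np.full(d.shape, -ATR_EPS)
    out = d >= sigma
    x6 = (sigma[out] / d[out]) ** 6
    e[out] = ATR_EPS * (x6 * x6 - 2.0 * x6)
    s, _ = _switch(d)
    e = e * s
    e[d >= ATR_CUTOFF] = 0.0
    return e


def atr_dedr(d: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    d, sigma = np.broadcast_arrays(np.asarray(d, float), np.asarray(sigma, float))
    e = np.full(d.shape, -ATR_EPS)
    de = np.zeros(d.shape)
    out = d >= sigma
    x6 = (sigma[out] / d[out]) ** 6
    e[out] = ATR_EPS * (x6 * x6 - 2.0 * x6)
    de[out] = ATR_EPS * (-12.0 * x6 * x6 + 12.0 * x6) / d[out]
    s, ds = _switch(d)
    g = de * s + e * ds
    g[d >= ATR_CUTOFF] = 0.0
    return g


def effective_sigma(sigma: np.ndarray, rep_mode: str) -> np.ndarray:
    return sigma * SOFT_FACTOR if rep_mode == "soft" else sigma


def _soft_factor(rep_mode: str) -> float:
    return SOFT_FACTOR if rep_mode == "soft" else 1.0


def nonbonded_terms(coords: np.ndarray, topo: Topology, rep_mode: str = "standard"
                    ) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Unweighted (E_rep, E_atr, rep_by_res, atr_by_res)."""
    from ._kernels import pair_energy_by_residue
    e_rep, e_atr, rep_res, atr_res = pair_energy_by_residue(
        coords, topo.pi, topo.pj, topo.sigma, topo.res_of, topo.n_res,
        _soft_factor(rep_mode))
    return e_rep, e_atr, rep_res, atr_res


def nonbonded_energy_forces(coords: np.ndarray, topo: Topology, w: EnergyWeights
                            ) -> tuple[float, np.ndarray]:
    """Weighted rep+atr energy and Cartesian gradient dE/dx."""
    from ._kernels import pair_energy_forces
    return pair_energy_forces(coords, topo.pi, topo.pj, topo.sigma,
                              _soft_factor(w.rep_mode), w.w_rep, w.w_atr)


# ------------------------------------------------------------------ rotamer term

def rot_energy_chi(aa: str, chi: list[float]) -> float:
    """Rotamer strain of one residue given its chi angles."""
    e = 0.0
    wells = T.chi_wells(aa)
    for c, ws in zip(chi, wells):
        dev = min(abs(wrap_angle(c - w)) for w in ws)
        e += (dev / SIGMA_CHI) ** 2
    return e


def rot_energy_residue(res) -> float:
    chi = [dihedral(*(res.atom(n).coord for n in quad))
           for quad in T.CHI_ATOMS[res.aa]]
    return rot_energy_chi(res.aa, chi)


# ------------------------------------------------------------------------ scoring

def score(s: Structure, w: EnergyWeights = EnergyWeights(),
          restraints=None) -> ScoreBreakdown:
    """Deterministic full score of a cleaned structure.

    total = w_rep*E_rep + w_atr*E_atr + w_rot*E_rot + w_cst*E_cst; by_term and
    by_residue store the weighted contributions so that each sums to total.
    """
    topo = Topology.for_structure(s)
    coords = topo.coords(s)
    if not np.all(np.isfinite(coords)):
        raise StructureError("structure has non-finite coordinates")

    e_rep, e_atr, rep_res, atr_res = nonbonded_terms(coords, topo, w.rep_mode)
    rot_res = np.array([rot_energy_residue(r) for r in s.residues])
    cst_res = np.zeros(topo.n_res)
    e_cst = 0.0
    if restraints is not None:
        from .restraints import restraint_energy_breakdown
        e_cst, cst_res = restraint_energy_breakdown(restraints, s)

    by_residue_term = {
        "rep": w.w_rep * rep_res,
        "atr": w.w_atr * atr_res,
        "rot": w.w_rot * rot_res,
        "cst": w.w_cst * cst_res,
    }
    by_term = {t: float(v.sum()) for t, v in by_residue_term.items()}
    by_residue = sum(by_residue_term.values())
    total = (w.w_rep * e_rep + w.w_atr * e_atr +
             w.w_rot * float(rot_res.sum()) + w.w_cst * e_cst)
    return ScoreBreakdown(total=total, by_term=by_term, by_residue=by_residue,
                          by_residue_term=by_residue_term,
                          residue_index=[r.index for r in s.residues],
                          aas=[r.aa for r in s.residues])


def per_residue_deltas(before: ScoreBreakdown, after: ScoreBreakdown,
                       term: str = "total", top_n: int | None = None
                       ) -> list[tuple[int, float]]:
    """Residues ranked by energy improvement (most negative delta first)."""
    if len(before.by_residue) != len(after.by_residue):
        raise ValueError("mismatched residue counts")
    if term == "total":
        delta = after.by_residue - before.by_residue
    elif term in TERM_NAMES:
        delta = after.by_residue_term[term] - before.by_residue_term[term]
    else:
        raise ValueError(f"unknown term {term!r}")
    order = sorted(range(len(delta)), key=lambda i: (delta[i], before.residue_index[i]))
    ranked = [(before.residue_index[i], float(delta[i])) for i in order]
    return ranked[:top_n] if top_n is not None else ranked


def high_energy_residues(b: ScoreBreakdown, threshold: float) -> set[int]:
    """Residue indices whose per-residue total exceeds the threshold."""
    return {idx for idx, e in zip(b.residue_index, b.by_residue) if e > threshold}
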