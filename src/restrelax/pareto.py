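"""Superposition RMSD, replicate/structure aggregation and Pareto-front
analysis of the energy-RMSD trade-off."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import templates as T
from .structure import Structure, StructureError, coords_for, select_atoms


@dataclass
class SuperpositionResult:
    rotation: np.ndarray     # 3x3, proper (det +1)
    translation: np.ndarray  # 3-vector
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch_superpose(coords_a: np.ndarray, coords_b: np.ndarray
                     ) -> SuperpositionResult:
    """Least-squares rigid superposition of B onto A (single pass, every atom
    weighted equally, no outlier rejection).

    Returns the proper rotation R and translation t minimizing
    || A - (B R^T + t) ||, and the minimized RMSD."""
    A = np.asarray(coords_a, float)
    B = np.asarray(coords_b, float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("coordinate sets must be matched (n, 3) arrays")
    n = A.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points to superpose")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    A0, B0 = A - ca, B - cb
    if np.linalg.matrix_rank(np.vstack([A0, B0])) < 2:
        raise ValueError("degenerate (collinear) geometry")
    H = B0.T @ A0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ca - R @ cb
    diff = A0 - B0 @ R.T
    rmsd = float(np.sqrt((diff ** 2).sum() / n))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd)


def _matched_refs(a: Structure, b: Structure, selector: str):
    if a.sequence != b.sequence:
        raise StructureError("structures differ in sequence; cannot compute RMSD")
    return select_atoms(a, selector)


def rmsd_all_atom(a: Structure, b: Structure, flip_aware: bool = False) -> float:
    """All-heavy-atom RMSD after heavy-atom superposition.

    flip_aware=True scores His/Asn/Gln terminal groups with the better of the
    two chemically equivalent 180°-flip atom assignments (off by default: the
    plain number reports flips as real deviation)."""
    refs = _matched_refs(a, b, "all_heavy")
    A = coords_for(a, refs)
    B = coords_for(b, refs)
    sup = kabsch_superpose(A, B)
    if not flip_aware:
        return sup.rmsd
    Bs = sup.apply(B)
    idx = {r: i for i, r in enumerate(refs)}
    sq = ((A - Bs) ** 2).sum(axis=1)
    for res in a.residues:
        pairs = T.FLIP_ATOM_PAIRS.get(res.aa)
        if not pairs:
            continue
        norm = flip = 0.0
        rows = []
        for na, nb in pairs:
            ia, ib = idx[(res.index, na)], idx[(res.index, nb)]
            norm += sq[ia] + sq[ib]
            flip += ((A[ia] - Bs[ib]) ** 2).sum() + ((A[ib] - Bs[ia]) ** 2).sum()
            rows.append((ia, ib))
        if flip < norm:
            for ia, ib in rows:
                swapped_a = ((A[ia] - Bs[ib]) ** 2).sum()
                swapped_b = ((A[ib] - Bs[ia]) ** 2).sum()
                sq[ia], sq[ib] = swapped_a, swapped_b
    return float(np.sqrt(sq.mean()))


def rmsd_ca(a: Structure, b: Structure) -> float:
    """C-alpha RMSD after C-alpha superposition."""
    refs = _matched_refs(a, b, "ca")
    return kabsch_superpose(coords_for(a, refs), coords_for(b, refs)).rmsd


# ---------------------------------------------------------------- Pareto front

@dataclass
class ParetoPoint:
    label: str
    mean_rmsd: float
    mean_energy_per_residue: float
    dominated: bool = False
    rmsd_range: float = 0.0
    energy_range: float = 0.0


def aggregate(label: str, per_structure_replicates: Sequence[Sequence]
              ) -> ParetoPoint:
    """Median over replicates within each structure, then unweighted mean over
    structures, for both RMSD and per-residue energy.

    per_structure_replicates: one sequence of RelaxResult-like objects
    (attributes rmsd_to_input, final_score.per_residue_mean) per structure."""
    if not per_structure_replicates or any(len(reps) == 0
                                           for reps in per_structure_replicates):
        raise ValueError("need at least one replicate for at least one structure")
    med_r, med_e, rng_r, rng_e = [], [], [], []
    for reps in per_structure_replicates:
        r = np.array([x.rmsd_to_input for x in reps])
        e = np.array([x.final_score.per_residue_mean for x in reps])
        med_r.append(np.median(r))
        med_e.append(np.median(e))
        rng_r.append(r.max() - r.min())
        rng_e.append(e.max() - e.min())
    return ParetoPoint(label=label,
                       mean_rmsd=float(np.mean(med_r)),
                       mean_energy_per_residue=float(np.mean(med_e)),
                       rmsd_range=float(np.mean(rng_r)),
                       energy_range=float(np.mean(rng_e)))


def pareto_front(points: Sequence[ParetoPoint]) -> list[ParetoPoint]:
    """Flag dominance (minimizing both axes) and return the non-dominated
    subset sorted by RMSD. Exact ties on both axes are all retained."""
    if not points:
        raise ValueError("empty point set")
    for p in points:
        p.dominated = any(
            q.mean_rmsd <= p.mean_rmsd and
            q.mean_energy_per_residue <= p.mean_energy_per_residue and
            (q.mean_rmsd < p.mean_rmsd or
             q.mean_energy_per_residue < p.mean_energy_per_residue)
            for q in points)
    return sorted((p for p in points if not p.dominated),
                  key=lambda p: (p.mean_rmsd, p.mean_energy_per_residue))


# ---------------------------------------------------------------------- sweeps

@dataclass
class SweepReport:
    points: list[ParetoPoint]
    front: list[ParetoPoint]
    table: "object" = None  # pandas DataFrame

    def to_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6f")

    def plot(self, path: str) -> None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(5, 4))
        on = [p for p in self.points if not p.dominated]
        off = [p for p in self.points if p.dominated]
        if off:
            ax.scatter([p.mean_rmsd for p in off],
                       [p.mean_energy_per_residue for p in off],
                       c="0.6", label="dominated")
        ax.scatter([p.mean_rmsd for p in on],
                   [p.mean_energy_per_residue for p in on],
                   c="tab:red", label="Pareto front")
        for p in self.points:
            ax.annotate(p.label, (p.mean_rmsd, p.mean_energy_per_residue),
                        fontsize=7, xytext=(3, 3), textcoords="offset points")
        ax.set_xlabel("mean all-atom RMSD to input (Å)")
        ax.set_ylabel("mean energy per residue (units)")
        ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def sweep(structures: Sequence[Structure], settings: Sequence[tuple],
          cfg=None, n_replicates: int = 10, seed: int = 0) -> SweepReport:
    """Run relax_replicates for every (structure, setting) pair, aggregate to
    one ParetoPoint per setting, and compute the front.

    settings: (label, restraint_builder) pairs, where restraint_builder maps a
    structure to a RestraintSet or None (unrestrained)."""
    from .relax import RelaxConfig, relax_replicates
    import pandas as pd
    if not structures or not settings:
        raise ValueError("need at least one structure and one setting")
    cfg = cfg or RelaxConfig()
    points = []
    for label, builder in settings:
        per_structure = []
        for si, s in enumerate(structures):
            restraints = builder(s) if builder is not None else None
            seeds = [seed + 7919 * si + 104729 * k for k in range(n_replicates)]
            summary = relax_replicates(s, restraints, cfg, n=n_replicates,
                                       seeds=seeds)
            per_structure.append(summary.results)
        points.append(aggregate(label, per_structure))
    front = pareto_front(points)
    table = pd.DataFrame([{
        "label": p.label, "mean_rmsd": p.mean_rmsd,
        "mean_energy_per_residue": p.mean_energy_per_residue,
        "rmsd_range": p.rmsd_range, "energy_range": p.energy_range,
        "on_front": not p.dominated} for p in points])
    return SweepReport(points=points, front=front, table=table)
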