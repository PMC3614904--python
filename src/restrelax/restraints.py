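"""Coordinate and distance restraints: harmonic, bounded (flat-bottom) and
sidechain-sidechain schemes, with evaluation, gradients and text serialization.

Forms
-----
harmonic:  f(d) = (d/sd)^2
bounded:   0 for d <= width;
           ((d - width)/sd)^2 for width < d <= width + 0.5*sd;
           0.25 + (d - width - 0.5*sd)/sd beyond.
           Continuous with continuous first derivative (slope 1/sd at the
           quadratic/linear junction).

Coordinate restraints are anchored to the (cleaned) input coordinates. For
His/Asn/Gln the terminal sidechain group is chemically ambiguous under a 180°
flip, so coordinate restraints on those atoms score the better of the two
symmetric atom assignments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import templates as T
from .structure import AtomRef, Structure, StructureError, select_atoms


class RestraintError(ValueError):
    pass


def _check_sd(sd: float) -> None:
    if sd <= 0:
        raise RestraintError(f"sd must be > 0, got {sd}")


def harmonic_energy(d: float, sd: float) -> float:
    """(d/sd)^2 — smooth, convex, zero at the reference."""
    _check_sd(sd)
    return (d / sd) ** 2


def harmonic_dedd(d: float, sd: float) -> float:
    return 2.0 * d / (sd * sd)


def bounded_energy(d: float, sd: float, width: float) -> float:
    """Flat within width, harmonic to width + 0.5*sd, then linear (slope 1/sd)."""
    _check_sd(sd)
    if width < 0:
        raise RestraintError(f"width must be >= 0, got {width}")
    if d <= width:
        return 0.0
    if d <= width + 0.5 * sd:
        return ((d - width) / sd) ** 2
    return 0.25 + (d - width - 0.5 * sd) / sd


def bounded_dedd(d: float, sd: float, width: float) -> float:
    if d <= width:
        return 0.0
    if d <= width + 0.5 * sd:
        return 2.0 * (d - width) / (sd * sd)
    return 1.0 / sd


@dataclass
class CoordinateRestraint:
    atom_ref: AtomRef
    x0: np.ndarray
    form: str = "harmonic"            # harmonic | bounded
    sd: float = 0.5
    width: float = 0.0

    def __post_init__(self):
        self.x0 = np.asarray(self.x0, float)
        _check_sd(self.sd)
        if self.form not in ("harmonic", "bounded"):
            raise RestraintError(f"unknown form {self.form!r}")
        if self.form == "harmonic" and self.width != 0.0:
            raise RestraintError("harmonic restraints have width 0")
        if self.width < 0:
            raise RestraintError("width must be >= 0")

    def energy(self, x: np.ndarray) -> float:
        d = float(np.linalg.norm(np.asarray(x, float) - self.x0))
        if self.form == "harmonic":
            return harmonic_energy(d, self.sd)
        return bounded_energy(d, self.sd, self.width)


@dataclass
class DistanceRestraint:
    atom_a: AtomRef
    atom_b: AtomRef
    d0: float
    sd: float = 2.0

    def __post_init__(self):
        if self.atom_a[0] == self.atom_b[0]:
            raise RestraintError("distance restraints must span distinct residues")
        if self.d0 <= 0:
            raise RestraintError("d0 must be > 0")
        _check_sd(self.sd)

    def energy(self, xa: np.ndarray, xb: np.ndarray) -> float:
        d = float(np.linalg.norm(np.asarray(xa, float) - np.asarray(xb, float)))
        return harmonic_energy(abs(d - self.d0), self.sd)


@dataclass
class RestraintSet:
    coordinate_restraints: list[CoordinateRestraint] = field(default_factory=list)
    distance_restraints: list[DistanceRestraint] = field(default_factory=list)
    weight: float = 1.0
    # per-residue groups of flip-ambiguous coordinate-restraint atom pairs:
    # (residue index, [(atom_a, atom_b), ...])
    flip_groups: list[tuple[int, list[tuple[str, str]]]] = field(default_factory=list)

    def __post_init__(self):
        if self.weight < 0:
            raise RestraintError("weight must be >= 0")

    def __len__(self) -> int:
        return len(self.coordinate_restraints) + len(self.distance_restraints)

    # ---------------------------------------------------------- serialization
    def to_text(self) -> str:
        lines = [f"weight {self.weight!r}"]
        for c in self.coordinate_restraints:
            lines.append("coord {} {} {} {!r} {!r} {:.6f} {:.6f} {:.6f}".format(
                c.atom_ref[0], c.atom_ref[1], c.form, c.sd, c.width, *c.x0))
        for d in self.distance_restraints:
            lines.append("dist {} {} {} {} {!r} {!r}".format(
                d.atom_a[0], d.atom_a[1], d.atom_b[0], d.atom_b[1], d.d0, d.sd))
        for resi, pairs in self.flip_groups:
            spec = ",".join(f"{a}:{b}" for a, b in pairs)
            lines.append(f"flip {resi} {spec}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "RestraintSet":
        rs = cls()
        for ln, line in enumerate(text.splitlines(), start=1):
            parts = line.split()
            if not parts:
                continue
            try:
                kind = parts[0]
                if kind == "weight":
                    rs.weight = float(parts[1])
                elif kind == "coord":
                    rs.coordinate_restraints.append(CoordinateRestraint(
                        (int(parts[1]), parts[2]),
                        np.array([float(parts[6]), float(parts[7]), float(parts[8])]),
                        form=parts[3], sd=float(parts[4]), width=float(parts[5])))
                elif kind == "dist":
                    rs.distance_restraints.append(DistanceRestraint(
                        (int(parts[1]), parts[2]), (int(parts[3]), parts[4]),
                        d0=float(parts[5]), sd=float(parts[6])))
                elif kind == "flip":
                    pairs = [tuple(p.split(":")) for p in parts[2].split(",")]
                    rs.flip_groups.append((int(parts[1]), pairs))
                else:
                    raise RestraintError(f"unknown record {kind!r}")
            except (IndexError, ValueError) as e:
                raise RestraintError(f"bad restraint line {ln}: {line!r}: {e}") from e
        return rs

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_text())

    @classmethod
    def load(cls, path: str) -> "RestraintSet":
        with open(path) as fh:
            return cls.from_text(fh.read())


# -------------------------------------------------------------------- builders

def build_coordinate_restraints(s: Structure, selection: str = "all_heavy",
                                form: str = "harmonic", sd: float = 0.5,
                                width: float = 0.0) -> RestraintSet:
    """One coordinate restraint per selected atom, anchored at its current
    position. selection is 'backbone_heavy' (backbone-only scheme) or
    'all_heavy' (all-atom scheme)."""
    if selection not in ("backbone_heavy", "all_heavy"):
        raise StructureError(f"selection must be backbone_heavy or all_heavy, "
                             f"got {selection!r}")
    refs = select_atoms(s, selection)
    if not refs:
        raise StructureError("empty restraint selection")
    rs = RestraintSet()
    for ref in refs:
        x0 = s.residue(ref[0]).atom(ref[1]).coord.copy()
        rs.coordinate_restraints.append(
            CoordinateRestraint(ref, x0, form=form, sd=sd,
                                width=width if form == "bounded" else 0.0))
    if selection == "all_heavy":
        for r in s.residues:
            pairs = T.FLIP_ATOM_PAIRS.get(r.aa)
            if pairs:
                rs.flip_groups.append((r.index, [tuple(p) for p in pairs]))
    return rs


def build_scsc_restraints(s: Structure, cutoff: float,
                          sd_dist: float = 2.0, sd_bb: float = 0.5) -> RestraintSet:
    """Sidechain-sidechain scheme: harmonic distance restraints (sd = 2.0) for
    every unordered pair of sidechain heavy atoms in distinct residues within
    the cutoff, plus harmonic coordinate restraints (sd = 0.5) on all backbone
    heavy atoms."""
    if cutoff <= 0:
        raise RestraintError(f"cutoff must be > 0, got {cutoff}")
    rs = build_coordinate_restraints(s, "backbone_heavy", "harmonic", sd=sd_bb)
    sc = select_atoms(s, "sidechain_heavy")
    coords = np.array([s.residue(i).atom(n).coord for i, n in sc]) \
        if sc else np.zeros((0, 3))
    for a in range(len(sc)):
        for b in range(a + 1, len(sc)):
            if sc[a][0] == sc[b][0]:
                continue
            d0 = float(np.linalg.norm(coords[a] - coords[b]))
            if d0 <= cutoff:
                rs.distance_restraints.append(
                    DistanceRestraint(sc[a], sc[b], d0=d0, sd=sd_dist))
    return rs


# ------------------------------------------------------------------ evaluation

def restraint_energy(r: RestraintSet, s: Structure) -> float:
    return restraint_energy_breakdown(r, s)[0]


def restraint_energy_breakdown(r: RestraintSet, s: Structure
                               ) -> tuple[float, np.ndarray]:
    """(weighted total, per-residue array). Distance terms split 50/50."""
    per_res = np.zeros(len(s))
    pos_of = {res.index: i for i, res in enumerate(s.residues)}
    flip_atoms = {(resi, a) for resi, pairs in r.flip_groups for p in pairs for a in p}

    by_ref = {}
    for c in r.coordinate_restraints:
        by_ref[c.atom_ref] = c
        if c.atom_ref in flip_atoms:
            continue
        x = s.residue(c.atom_ref[0]).atom(c.atom_ref[1]).coord
        per_res[pos_of[c.atom_ref[0]]] += c.energy(x)

    for resi, pairs in r.flip_groups:
        e_norm = e_flip = 0.0
        seen = False
        for a, b in pairs:
            ca, cb = by_ref.get((resi, a)), by_ref.get((resi, b))
            if ca is None or cb is None:
                continue
            seen = True
            xa = s.residue(resi).atom(a).coord
            xb = s.residue(resi).atom(b).coord
            e_norm += ca.energy(xa) + cb.energy(xb)
            e_flip += ca.energy(xb) + cb.energy(xa)
        if seen:
            per_res[pos_of[resi]] += min(e_norm, e_flip)

    for d in r.distance_restraints:
        xa = s.residue(d.atom_a[0]).atom(d.atom_a[1]).coord
        xb = s.residue(d.atom_b[0]).atom(d.atom_b[1]).coord
        e = d.energy(xa, xb)
        per_res[pos_of[d.atom_a[0]]] += 0.5 * e
        per_res[pos_of[d.atom_b[0]]] += 0.5 * e

    per_res *= r.weight
    return float(per_res.sum()), per_res


class CompiledRestraints:
    """Array-compiled evaluator for a RestraintSet against a fixed atom
    indexing (used by the minimizer and the packer's delta scoring)."""

    def __init__(self, r: RestraintSet, index_of: dict[AtomRef, int], n_atoms: int):
        self.weight = r.weight
        self.n_atoms = n_atoms

        flip_atoms = {(resi, a) for resi, pairs in r.flip_groups
                      for p in pairs for a in p}
        plain = [c for c in r.coordinate_restraints if c.atom_ref not in flip_atoms]
        self.c_idx = np.array([index_of[c.atom_ref] for c in plain], dtype=int)
        self.c_x0 = np.array([c.x0 for c in plain]).reshape(-1, 3)
        self.c_harm = np.array([c.form == "harmonic" for c in plain])
        self.c_sd = np.array([c.sd for c in plain])
        self.c_width = np.array([c.width for c in plain])

        by_ref = {c.atom_ref: c for c in r.coordinate_restraints}
        self.flips = []  # (idx_a array, idx_b array, x0_a, x0_b, sd, width, harm)
        for resi, pairs in r.flip_groups:
            rows = [(by_ref[(resi, a)], by_ref[(resi, b)], index_of[(resi, a)],
                     index_of[(resi, b)])
                    for a, b in pairs
                    if (resi, a) in by_ref and (resi, b) in by_ref]
            if rows:
                self.flips.append((
                    np.array([ia for _, _, ia, _ in rows]),
                    np.array([ib for _, _, _, ib in rows]),
                    np.array([ca.x0 for ca, _, _, _ in rows]),
                    np.array([cb.x0 for _, cb, _, _ in rows]),
                    np.array([ca.sd for ca, _, _, _ in rows]),
                    np.array([ca.width for ca, _, _, _ in rows]),
                    np.array([ca.form == "harmonic" for ca, _, _, _ in rows])))

        self.d_i = np.array([index_of[d.atom_a] for d in r.distance_restraints],
                            dtype=int)
        self.d_j = np.array([index_of[d.atom_b] for d in r.distance_restraints],
                            dtype=int)
        self.d_d0 = np.array([d.d0 for d in r.distance_restraints])
        self.d_sd = np.array([d.sd for d in r.distance_restraints])
        self.atom_touch = np.zeros(n_atoms, dtype=bool)
        if len(self.c_idx):
            self.atom_touch[self.c_idx] = True
        for fi in self.flips:
            self.atom_touch[fi[0]] = True
            self.atom_touch[fi[1]] = True
        if len(self.d_i):
            self.atom_touch[self.d_i] = True
            self.atom_touch[self.d_j] = True

    @staticmethod
    def _coord_e_g(d: np.ndarray, harm, sd, width):
        e = np.empty_like(d)
        g = np.empty_like(d)
        h = harm
        e[h] = (d[h] / sd[h]) ** 2
        g[h] = 2.0 * d[h] / sd[h] ** 2
        b = ~h
        if np.any(b):
            db, sdb, wb = d[b], sd[b], width[b]
            eb = np.where(db <= wb, 0.0,
                          np.where(db <= wb + 0.5 * sdb,
                                   ((db - wb) / sdb) ** 2,
                                   0.25 + (db - wb - 0.5 * sdb) / sdb))
            gb = np.where(db <= wb, 0.0,
                          np.where(db <= wb + 0.5 * sdb,
                                   2.0 * (db - wb) / sdb ** 2, 1.0 / sdb))
            e[b] = eb
            g[b] = gb
        return e, g

    def energy_forces(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        """Weighted restraint energy and Cartesian gradient."""
        F = np.zeros_like(coords)
        total = 0.0
        if len(self.c_idx):
            dv = coords[self.c_idx] - self.c_x0
            if self.c_harm.all():
                # harmonic fast path: (|dv|/sd)^2 has gradient 2 dv / sd^2
                inv_sd2 = 1.0 / (self.c_sd * self.c_sd)
                total += float(np.einsum("ij,ij->i", dv, dv) @ inv_sd2)
                F[self.c_idx] += 2.0 * dv * inv_sd2[:, None]
            else:
                d = np.linalg.norm(dv, axis=1)
                e, g = self._coord_e_g(d, self.c_harm, self.c_sd, self.c_width)
                total += e.sum()
                with np.errstate(invalid="ignore", divide="ignore"):
                    scale = np.where(d > 0, g / d, 0.0)
                F[self.c_idx] += dv * scale[:, None]
        for ia, ib, x0a, x0b, sd, width, harm in self.flips:
            dn_a = np.linalg.norm(coords[ia] - x0a, axis=1)
            dn_b = np.linalg.norm(coords[ib] - x0b, axis=1)
            df_a = np.linalg.norm(coords[ia] - x0b, axis=1)
            df_b = np.linalg.norm(coords[ib] - x0a, axis=1)
            en_a, gn_a = self._coord_e_g(dn_a, harm, sd, width)
            en_b, gn_b = self._coord_e_g(dn_b, harm, sd, width)
            ef_a, gf_a = self._coord_e_g(df_a, harm, sd, width)
            ef_b, gf_b = self._coord_e_g(df_b, harm, sd, width)
            if en_a.sum() + en_b.sum() <= ef_a.sum() + ef_b.sum():
                total += en_a.sum() + en_b.sum()
                pairs = ((ia, x0a, dn_a, gn_a), (ib, x0b, dn_b, gn_b))
            else:
                total += ef_a.sum() + ef_b.sum()
                pairs = ((ia, x0b, df_a, gf_a), (ib, x0a, df_b, gf_b))
            for idx, x0, d, g in pairs:
                dv = coords[idx] - x0
                with np.errstate(invalid="ignore", divide="ignore"):
                    scale = np.where(d > 0, g / d, 0.0)
                F[idx] += dv * scale[:, None]
        if len(self.d_i):
            dv = coords[self.d_i] - coords[self.d_j]
            d = np.linalg.norm(dv, axis=1)
            dev = d - self.d_d0
            total += float(((dev / self.d_sd) ** 2).sum())
            g = 2.0 * dev / self.d_sd ** 2
            with np.errstate(invalid="ignore", divide="ignore"):
                scale = np.where(d > 0, g / d, 0.0)
            fv = dv * scale[:, None]
            np.add.at(F, self.d_i, fv)
            np.add.at(F, self.d_j, -fv)
        return self.weight * total, self.weight * F

    def energy(self, coords: np.ndarray) -> float:
        return self.energy_forces(coords)[0]

    def residue_evaluator(self, mov: np.ndarray):
        """Fast evaluator for the packer: energy of all terms touching the
        atom set `mov` (one residue's moving sidechain atoms), as a callable
        f(X_full, G) where G holds candidate coordinates for `mov` rows."""
        local = {int(a): k for k, a in enumerate(mov)}
        movset = set(local)

        c_rows = [(local[int(i)], k) for k, i in enumerate(self.c_idx)
                  if int(i) in movset]
        c_loc = np.array([a for a, _ in c_rows], dtype=int)
        c_glob = np.array([k for _, k in c_rows], dtype=int)

        flips = []
        for ia, ib, x0a, x0b, sd, width, harm in self.flips:
            if any(int(i) in movset for i in ia) or \
                    any(int(i) in movset for i in ib):
                la = np.array([local[int(i)] for i in ia], dtype=int)
                lb = np.array([local[int(i)] for i in ib], dtype=int)
                flips.append((la, lb, x0a, x0b, sd, width, harm))

        d_rows = []
        for k in range(len(self.d_i)):
            ai, bi = int(self.d_i[k]), int(self.d_j[k])
            if ai in movset:
                d_rows.append((local[ai], bi, k))
            elif bi in movset:
                d_rows.append((local[bi], ai, k))
        d_loc = np.array([a for a, _, _ in d_rows], dtype=int)
        d_other = np.array([b for _, b, _ in d_rows], dtype=int)
        d_k = np.array([k for _, _, k in d_rows], dtype=int)

        weight = self.weight
        ceg = self._coord_e_g

        def evaluate(X: np.ndarray, G: np.ndarray) -> float:
            total = 0.0
            if len(c_loc):
                dv = G[c_loc] - self.c_x0[c_glob]
                d = np.sqrt(np.einsum("ij,ij->i", dv, dv))
                total += ceg(d, self.c_harm[c_glob], self.c_sd[c_glob],
                             self.c_width[c_glob])[0].sum()
            for la, lb, x0a, x0b, sd, width, harm in flips:
                dn = np.linalg.norm(G[la] - x0a, axis=1)
                dnb = np.linalg.norm(G[lb] - x0b, axis=1)
                df = np.linalg.norm(G[la] - x0b, axis=1)
                dfb = np.linalg.norm(G[lb] - x0a, axis=1)
                en = ceg(dn, harm, sd, width)[0].sum() + \
                    ceg(dnb, harm, sd, width)[0].sum()
                ef = ceg(df, harm, sd, width)[0].sum() + \
                    ceg(dfb, harm, sd, width)[0].sum()
                total += min(en, ef)
            if len(d_loc):
                dv = G[d_loc] - X[d_other]
                d = np.sqrt(np.einsum("ij,ij->i", dv, dv))
                dev = (d - self.d_d0[d_k]) / self.d_sd[d_k]
                total += float((dev * dev).sum())
            return weight * total

        evaluate.active = bool(len(c_loc) or flips or len(d_loc))  # type: ignore
        return evaluate

    def energy_subset(self, coords: np.ndarray, members: np.ndarray) -> float:
        """Weighted energy of all terms touching any atom in `members`
        (a boolean mask over atoms). Terms are counted once."""
        total = 0.0
        if len(self.c_idx):
            sel = members[self.c_idx]
            if np.any(sel):
                dv = coords[self.c_idx[sel]] - self.c_x0[sel]
                d = np.linalg.norm(dv, axis=1)
                e, _ = self._coord_e_g(d, self.c_harm[sel], self.c_sd[sel],
                                       self.c_width[sel])
                total += e.sum()
        for ia, ib, x0a, x0b, sd, width, harm in self.flips:
            if not (np.any(members[ia]) or np.any(members[ib])):
                continue
            dn = np.linalg.norm(coords[ia] - x0a, axis=1)
            dnb = np.linalg.norm(coords[ib] - x0b, axis=1)
            df = np.linalg.norm(coords[ia] - x0b, axis=1)
            dfb = np.linalg.norm(coords[ib] - x0a, axis=1)
            en = self._coord_e_g(dn, harm, sd, width)[0].sum() + \
                self._coord_e_g(dnb, harm, sd, width)[0].sum()
            ef = self._coord_e_g(df, harm, sd, width)[0].sum() + \
                self._coord_e_g(dfb, harm, sd, width)[0].sum()
            total += min(en, ef)
        if len(self.d_i):
            sel = members[self.d_i] | members[self.d_j]
            if np.any(sel):
                dv = coords[self.d_i[sel]] - coords[self.d_j[sel]]
                d = np.linalg.norm(dv, axis=1)
                dev = d - self.d_d0[sel]
                total += float(((dev / self.d_sd[sel]) ** 2).sum())
        return self.weight * total


class NullRestraints:
    """Evaluator used when no restraints are active."""

    weight = 0.0

    def __init__(self, n_atoms: int):
        self.n_atoms = n_atoms
        self.atom_touch = np.zeros(n_atoms, dtype=bool)

    def energy_forces(self, coords):
        return 0.0, np.zeros_like(coords)

    def energy(self, coords):
        return 0.0

    def energy_subset(self, coords, members):
        return 0.0

    def residue_evaluator(self, mov):
        def evaluate(X, G):
            return 0.0
        evaluate.active = False
        return evaluate
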