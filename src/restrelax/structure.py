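"""Protein structure model: atoms/residues/structures, PDB I/O, cleaning, selection.

The in-memory model is deliberately small: single chain, heavy atoms only
after cleaning, ideal-geometry internal coordinates (phi/psi/chi are the
degrees of freedom; bond lengths and angles come from the residue templates).
"""

from __future__ import annotations

import copy as _copy
import logging
import math
from dataclasses import dataclass, field

import gemmi
import numpy as np

from . import templates as T
from .geometry import dihedral, place_atom

log = logging.getLogger(__name__)


class StructureError(ValueError):
    """Base class for structure-model errors."""


class PdbParseError(StructureError):
    pass


class PdbFormatError(StructureError):
    pass


class EmptyStructureError(StructureError):
    pass


class MultiChainError(StructureError):
    pass


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray
    is_backbone: bool
    is_hydrogen: bool = False

    def __post_init__(self):
        self.coord = np.asarray(self.coord, dtype=float)
        if not np.all(np.isfinite(self.coord)):
            raise StructureError(f"non-finite coordinate for atom {self.name}")


@dataclass
class Residue:
    index: int                       # 1-based position after cleaning
    aa: str                          # one-letter code, or "X" pre-cleaning
    atoms: list[Atom] = field(default_factory=list)
    phi: float = 0.0
    psi: float = 0.0
    chi: list[float] = field(default_factory=list)
    res_name: str = ""               # 3-letter PDB residue name
    orig_label: str = ""             # original chain/seq id, kept as metadata
    het: bool = False                # came from HETATM records

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise StructureError(f"residue {self.index} ({self.res_name}) has no atom {name}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]


@dataclass
class Structure:
    residues: list[Residue] = field(default_factory=list)
    id: str = ""

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def copy(self) -> "Structure":
        return _copy.deepcopy(self)

    def residue(self, index: int) -> Residue:
        for r in self.residues:
            if r.index == index:
                return r
        raise StructureError(f"no residue with index {index}")


AtomRef = tuple[int, str]  # (residue index, atom name)

SELECTORS = ("backbone_heavy", "sidechain_heavy", "all_heavy", "ca")


def select_atoms(s: Structure, selector: str) -> list[AtomRef]:
    """Deterministically ordered atom references for a cleaned structure."""
    if selector not in SELECTORS:
        raise StructureError(f"unknown selector {selector!r}; one of {SELECTORS}")
    refs: list[AtomRef] = []
    for r in s.residues:
        names = T.template_atom_names(r.aa)
        if selector == "ca":
            refs.append((r.index, "CA"))
        elif selector == "backbone_heavy":
            refs.extend((r.index, n) for n in T.BACKBONE_NAMES)
        elif selector == "sidechain_heavy":
            refs.extend((r.index, n) for n in names if n not in T.BACKBONE_NAMES)
        else:
            refs.extend((r.index, n) for n in names)
    return refs


def coords_for(s: Structure, refs: list[AtomRef]) -> np.ndarray:
    """(n, 3) coordinate array for a list of atom references."""
    return np.array([s.residue(i).atom(n).coord for i, n in refs], dtype=float)


# ---------------------------------------------------------------- chain building

def build_chain(sequence: str, phi: list[float], psi: list[float],
                chis: list[list[float]],
                root: tuple | None = None, id: str = "") -> Structure:
    """Build an ideal-geometry chain from torsions.

    root, if given, is an (N1, CA1, C1) coordinate triad anchoring the chain;
    otherwise the chain starts in a canonical frame at the origin (phi of the
    first residue is then undefined and ignored).
    """
    n = len(sequence)
    if not all(aa in T.AA1_TO_3 for aa in sequence):
        raise StructureError(f"non-canonical letter in sequence {sequence!r}")
    if not (len(phi) == len(psi) == len(chis) == n):
        raise StructureError("torsion lists must match sequence length")

    residues: list[Residue] = []
    prev: dict[str, tuple] | None = None
    for i, aa in enumerate(sequence):
        atoms: dict[str, tuple] = {}
        if i == 0:
            if root is not None:
                atoms["N"] = tuple(map(float, root[0]))
                atoms["CA"] = tuple(map(float, root[1]))
                atoms["C"] = tuple(map(float, root[2]))
            else:
                atoms["N"] = (0.0, 0.0, 0.0)
                atoms["CA"] = (T.B_N_CA, 0.0, 0.0)
                th = math.radians(T.A_N_CA_C)
                atoms["C"] = (T.B_N_CA - T.B_CA_C * math.cos(th),
                              T.B_CA_C * math.sin(th), 0.0)
        else:
            atoms["N"] = place_atom(prev["N"], prev["CA"], prev["C"],
                                    T.B_C_N, T.A_CA_C_N, psi[i - 1])
            atoms["CA"] = place_atom(prev["CA"], prev["C"], atoms["N"],
                                     T.B_N_CA, T.A_C_N_CA, T.OMEGA)
            atoms["C"] = place_atom(prev["C"], atoms["N"], atoms["CA"],
                                    T.B_CA_C, T.A_N_CA_C, phi[i])
        atoms["O"] = place_atom(atoms["N"], atoms["CA"], atoms["C"],
                                T.B_C_O, T.A_CA_C_O, psi[i] + 180.0)
        chi = list(chis[i])
        if len(chi) != T.chi_count(aa):
            raise StructureError(
                f"residue {i + 1} ({aa}): expected {T.chi_count(aa)} chi values")
        for row in T.SIDECHAINS[aa]:
            name, (a3, a2, a1), bond, angle, tors = row
            tdeg = (chi[tors[1] - 1] + tors[2]) if isinstance(tors, tuple) else tors
            atoms[name] = place_atom(atoms[a3], atoms[a2], atoms[a1],
                                     bond, angle, tdeg)
        res = Residue(index=i + 1, aa=aa, res_name=T.AA1_TO_3[aa],
                      phi=phi[i], psi=psi[i], chi=chi)
        for name in T.template_atom_names(aa):
            res.atoms.append(Atom(name, T.element_of(name), np.array(atoms[name]),
                                  is_backbone=name in T.BACKBONE_NAMES))
        residues.append(res)
        prev = atoms
    return Structure(residues=residues, id=id)


def rebuild_sidechain(res: Residue, chi: list[float]) -> None:
    """Re-place sidechain heavy atoms from new chi values, using the residue's
    actual backbone positions as the reference frame."""
    atoms = {a.name: tuple(a.coord) for a in res.atoms if a.name in T.BACKBONE_NAMES}
    for row in T.SIDECHAINS[res.aa]:
        name, (a3, a2, a1), bond, angle, tors = row
        tdeg = (chi[tors[1] - 1] + tors[2]) if isinstance(tors, tuple) else tors
        atoms[name] = place_atom(atoms[a3], atoms[a2], atoms[a1], bond, angle, tdeg)
        if res.has_atom(name):
            res.atom(name).coord = np.array(atoms[name])
        else:
            res.atoms.append(Atom(name, T.element_of(name), np.array(atoms[name]),
                                  is_backbone=False))
    res.chi = list(chi)


def place_sidechain(aa: str, backbone: dict[str, tuple], chis: list[float]
                    ) -> dict[str, tuple]:
    """Sidechain heavy-atom coordinates for residue type `aa` given backbone
    N/CA/C positions and chi angles. Returns {atom name: xyz} (CB included)."""
    atoms = dict(backbone)
    for row in T.SIDECHAINS[aa]:
        name, (a3, a2, a1), bond, angle, tors = row
        tdeg = (chis[tors[1] - 1] + tors[2]) if isinstance(tors, tuple) else tors
        atoms[name] = place_atom(atoms[a3], atoms[a2], atoms[a1], bond, angle, tdeg)
    return {k: v for k, v in atoms.items() if k not in backbone}


def measure_torsions(s: Structure) -> None:
    """Set phi/psi/chi on every residue from its current coordinates."""
    for i, r in enumerate(s.residues):
        N, CA, C = r.atom("N").coord, r.atom("CA").coord, r.atom("C").coord
        if i > 0:
            r.phi = dihedral(s.residues[i - 1].atom("C").coord, N, CA, C)
        else:
            r.phi = -57.0
        # psi recovered from the carbonyl oxygen (O is anti to the next N)
        r.psi = dihedral(N, CA, C, r.atom("O").coord) - 180.0
        if r.psi <= -180.0:
            r.psi += 360.0
        r.chi = []
        for quad in T.CHI_ATOMS[r.aa]:
            if all(r.has_atom(n) for n in quad):
                r.chi.append(dihedral(*(r.atom(n).coord for n in quad)))
            else:
                r.chi.append(T.default_chis(r.aa)[len(r.chi)])


# ------------------------------------------------------------------------ PDB I/O

def read_pdb(path: str) -> Structure:
    """Read a single-chain PDB file. Alternate locations are resolved to the
    highest-occupancy conformer (ties broken by altloc letter). The returned
    structure may still contain waters/heteroatoms/hydrogens; pass it through
    clean_structure before refinement."""
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as e:
        raise PdbParseError(f"cannot parse PDB file {path}: {e}") from e
    if len(st) == 0:
        raise EmptyStructureError(f"no models in {path}")
    model = st[0]

    aa_chains = [ch.name for ch in model
                 if any(r.name in T.AA3_TO_1 for r in ch)]
    if len(set(aa_chains)) > 1:
        raise MultiChainError(
            f"{path} has amino acids in chains {sorted(set(aa_chains))}; "
            "only single-chain structures are supported")

    residues: list[Residue] = []
    idx = 0
    for chain in model:
        for gres in chain:
            idx += 1
            aa = T.AA3_TO_1.get(gres.name, "X")
            res = Residue(index=idx, aa=aa, res_name=gres.name,
                          orig_label=f"{chain.name}:{gres.seqid.num}{gres.seqid.icode}".strip(),
                          het=gres.het_flag == "H")
            best: dict[str, gemmi.Atom] = {}
            for ga in gres:
                cur = best.get(ga.name)
                if cur is None or (ga.occ, _altloc_rank(ga.altloc)) > \
                        (cur.occ, _altloc_rank(cur.altloc)):
                    best[ga.name] = ga
            for name, ga in best.items():
                el = ga.element.name if ga.element.name else name[0]
                res.atoms.append(Atom(
                    name=name, element=el,
                    coord=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                    is_backbone=name in T.BACKBONE_NAMES and aa != "X",
                    is_hydrogen=el in ("H", "D")))
            residues.append(res)
    if not any(r.aa != "X" for r in residues):
        raise EmptyStructureError(f"no canonical amino-acid ATOM records in {path}")
    return Structure(residues=residues, id=str(path))


def _altloc_rank(altloc: str) -> float:
    # higher is better: blank beats none; earlier letters beat later ones
    if not altloc or altloc == "\x00":
        return 0.0
    return -ord(altloc)


def write_pdb(s: Structure, path: str) -> None:
    """Write fixed-column ATOM records (heavy atoms and any hydrogens present)."""
    if len(s) == 0:
        raise EmptyStructureError("cannot write an empty structure")
    st = gemmi.Structure()
    st.name = s.id or "restrelax"
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for r in s.residues:
        gres = gemmi.Residue()
        gres.name = r.res_name or T.AA1_TO_3.get(r.aa, "UNK")
        gres.seqid = gemmi.SeqId(r.index, " ")
        for a in r.atoms:
            if np.any(np.abs(a.coord) > 9999.999):
                raise PdbFormatError(
                    f"coordinate overflow for atom {a.name} in residue {r.index}: "
                    f"{a.coord} does not fit PDB fixed columns")
            ga = gemmi.Atom()
            ga.name = a.name
            ga.element = gemmi.Element(a.element)
            ga.pos = gemmi.Position(*a.coord)
            ga.occ = 1.0
            ga.b_iso = 0.0
            gres.add_atom(ga)
        chain.add_residue(gres)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    doc = st.make_pdb_string()
    with open(path, "w") as fh:
        fh.write(doc)


# ------------------------------------------------------------------------ cleaning

def clean_structure(s: Structure) -> Structure:
    """Remove waters, heteroatom residues, non-canonical residues and hydrogens;
    re-index contiguously (original numbering kept in orig_label); complete
    missing template atoms from ideal geometry; measure torsions.

    Idempotent on already-clean structures."""
    kept: list[Residue] = []
    for r in s.residues:
        if r.res_name in T.WATER_NAMES:
            continue
        if r.aa == "X" or r.res_name not in T.AA3_TO_1:
            log.warning("dropping non-canonical residue %s %s", r.res_name,
                        r.orig_label or r.index)
            continue
        if r.het:
            continue
        rc = _copy.deepcopy(r)
        rc.atoms = [a for a in rc.atoms if not a.is_hydrogen and
                    a.name in T.template_atom_names(rc.aa)]
        if not all(rc.has_atom(n) for n in ("N", "CA", "C")):
            log.warning("dropping residue %s with incomplete backbone",
                        r.orig_label or r.index)
            continue
        kept.append(rc)
    if not kept:
        raise EmptyStructureError("cleaning removed every residue")

    out = Structure(residues=kept, id=s.id)
    for new_idx, r in enumerate(kept, start=1):
        if not r.orig_label:
            r.orig_label = str(r.index)
        r.index = new_idx
        for a in r.atoms:
            a.is_backbone = a.name in T.BACKBONE_NAMES
        _complete_residue(out, r)
    measure_torsions(out)
    return out


def _complete_residue(s: Structure, r: Residue) -> None:
    """Fill in missing heavy atoms (O and sidechain) from ideal geometry."""
    if not r.has_atom("O"):
        # place O anti to the next residue's N when available
        pos = s.residues.index(r)
        psi = 180.0
        if pos + 1 < len(s.residues):
            nn = s.residues[pos + 1]
            psi = dihedral(r.atom("N").coord, r.atom("CA").coord,
                           r.atom("C").coord, nn.atom("N").coord)
        o = place_atom(tuple(r.atom("N").coord), tuple(r.atom("CA").coord),
                       tuple(r.atom("C").coord), T.B_C_O, T.A_CA_C_O, psi + 180.0)
        r.atoms.append(Atom("O", "O", np.array(o), is_backbone=True))
    needed = T.template_atom_names(r.aa)
    if all(r.has_atom(n) for n in needed):
        _order_atoms(r)
        return
    # measure what chi we can from present atoms, default the rest, rebuild
    chi = []
    for k, quad in enumerate(T.CHI_ATOMS[r.aa]):
        if all(r.has_atom(n) for n in quad):
            chi.append(dihedral(*(r.atom(n).coord for n in quad)))
        else:
            chi.append(T.default_chis(r.aa)[k])
    rebuild_sidechain(r, chi)
    _order_atoms(r)


def _order_atoms(r: Residue) -> None:
    order = {n: i for i, n in enumerate(T.template_atom_names(r.aa))}
    r.atoms.sort(key=lambda a: order[a.name])
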