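"""Ideal-geometry residue templates, chi definitions, rotamer wells and radii.

Each sidechain heavy atom is defined by a z-matrix row relative to previously
placed atoms of the same residue: (name, (a3, a2, a1), bond, angle, torsion).
The torsion entry is either a fixed value in degrees or ("chi", k, offset),
meaning chi_k + offset. Backbone atoms N/CA/C/O are placed by the chain
builder from phi/psi/omega.
"""

from __future__ import annotations

# --- backbone ideal internal coordinates (Å, degrees) ---
B_N_CA = 1.458
B_CA_C = 1.525
B_C_N = 1.329
B_C_O = 1.231
A_N_CA_C = 111.2
A_CA_C_N = 116.2
A_C_N_CA = 121.7
A_CA_C_O = 120.8
OMEGA = 180.0

# improper dihedral C-N-CA-CB giving an L-alpha carbon
IMPROPER_CB = -122.6
B_CA_CB = 1.530
A_N_CA_CB = 110.5

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}
CANONICAL_AAS = "ACDEFGHIKLMNPQRSTVWY"

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}

_CB = ("CB", ("C", "N", "CA"), B_CA_CB, A_N_CA_CB, IMPROPER_CB)


def _chi(k: int, offset: float = 0.0):
    return ("chi", k, offset)


# sidechain z-matrices (heavy atoms only), keyed by one-letter code
SIDECHAINS: dict[str, list[tuple]] = {
    "G": [],
    "A": [_CB],
    "S": [_CB, ("OG", ("N", "CA", "CB"), 1.417, 110.8, _chi(1))],
    "C": [_CB, ("SG", ("N", "CA", "CB"), 1.808, 113.8, _chi(1))],
    "T": [_CB,
          ("OG1", ("N", "CA", "CB"), 1.433, 109.5, _chi(1)),
          ("CG2", ("N", "CA", "CB"), 1.521, 110.5, _chi(1, -120.0))],
    "V": [_CB,
          ("CG1", ("N", "CA", "CB"), 1.527, 110.5, _chi(1)),
          ("CG2", ("N", "CA", "CB"), 1.527, 110.5, _chi(1, 122.0))],
    "L": [_CB,
          ("CG", ("N", "CA", "CB"), 1.530, 116.3, _chi(1)),
          ("CD1", ("CA", "CB", "CG"), 1.521, 110.7, _chi(2)),
          ("CD2", ("CA", "CB", "CG"), 1.521, 110.7, _chi(2, 122.0))],
    "I": [_CB,
          ("CG1", ("N", "CA", "CB"), 1.530, 110.4, _chi(1)),
          ("CG2", ("N", "CA", "CB"), 1.521, 110.5, _chi(1, -122.0)),
          ("CD1", ("CA", "CB", "CG1"), 1.513, 113.8, _chi(2))],
    "M": [_CB,
          ("CG", ("N", "CA", "CB"), 1.520, 114.1, _chi(1)),
          ("SD", ("CA", "CB", "CG"), 1.803, 112.7, _chi(2)),
          ("CE", ("CB", "CG", "SD"), 1.791, 100.9, _chi(3))],
    "P": [_CB,
          ("CG", ("N", "CA", "CB"), 1.495, 104.5, _chi(1)),
          ("CD", ("CA", "CB", "CG"), 1.507, 105.5, _chi(2))],
    "F": [_CB,
          ("CG", ("N", "CA", "CB"), 1.502, 113.8, _chi(1)),
          ("CD1", ("CA", "CB", "CG"), 1.384, 120.8, _chi(2)),
          ("CD2", ("CA", "CB", "CG"), 1.384, 120.8, _chi(2, 180.0)),
          ("CE1", ("CB", "CG", "CD1"), 1.382, 120.8, 180.0),
          ("CE2", ("CB", "CG", "CD2"), 1.382, 120.8, 180.0),
          ("CZ", ("CG", "CD1", "CE1"), 1.382, 120.0, 0.0)],
    "Y": [_CB,
          ("CG", ("N", "CA", "CB"), 1.502, 113.8, _chi(1)),
          ("CD1", ("CA", "CB", "CG"), 1.384, 120.8, _chi(2)),
          ("CD2", ("CA", "CB", "CG"), 1.384, 120.8, _chi(2, 180.0)),
          ("CE1", ("CB", "CG", "CD1"), 1.382, 120.8, 180.0),
          ("CE2", ("CB", "CG", "CD2"), 1.382, 120.8, 180.0),
          ("CZ", ("CG", "CD1", "CE1"), 1.382, 120.0, 0.0),
          ("OH", ("CD1", "CE1", "CZ"), 1.376, 119.9, 180.0)],
    "W": [_CB,
          ("CG", ("N", "CA", "CB"), 1.498, 114.0, _chi(1)),
          ("CD1", ("CA", "CB", "CG"), 1.365, 126.9, _chi(2)),
          ("CD2", ("CA", "CB", "CG"), 1.433, 126.7, _chi(2, 180.0)),
          ("NE1", ("CB", "CG", "CD1"), 1.374, 110.1, 180.0),
          ("CE2", ("CB", "CG", "CD2"), 1.409, 107.2, 180.0),
          ("CE3", ("CB", "CG", "CD2"), 1.398, 133.9, 0.0),
          ("CZ2", ("CG", "CD2", "CE2"), 1.394, 122.4, 180.0),
          ("CZ3", ("CG", "CD2", "CE3"), 1.382, 118.6, 180.0),
          ("CH2", ("CD2", "CE2", "CZ2"), 1.368, 117.5, 0.0)],
    "H": [_CB,
          ("CG", ("N", "CA", "CB"), 1.504, 113.8, _chi(1)),
          ("ND1", ("CA", "CB", "CG"), 1.378, 122.7, _chi(2)),
          ("CD2", ("CA", "CB", "CG"), 1.354, 131.0, _chi(2, 180.0)),
          ("CE1", ("CB", "CG", "ND1"), 1.321, 109.0, 180.0),
          ("NE2", ("CB", "CG", "CD2"), 1.374, 107.0, 180.0)],
    "D": [_CB,
          ("CG", ("N", "CA", "CB"), 1.516, 112.6, _chi(1)),
          ("OD1", ("CA", "CB", "CG"), 1.249, 118.4, _chi(2)),
          ("OD2", ("CA", "CB", "CG"), 1.249, 118.4, _chi(2, 180.0))],
    "N": [_CB,
          ("CG", ("N", "CA", "CB"), 1.516, 112.6, _chi(1)),
          ("OD1", ("CA", "CB", "CG"), 1.231, 120.8, _chi(2)),
          ("ND2", ("CA", "CB", "CG"), 1.328, 116.4, _chi(2, 180.0))],
    "E": [_CB,
          ("CG", ("N", "CA", "CB"), 1.520, 114.1, _chi(1)),
          ("CD", ("CA", "CB", "CG"), 1.516, 112.6, _chi(2)),
          ("OE1", ("CB", "CG", "CD"), 1.249, 118.4, _chi(3)),
          ("OE2", ("CB", "CG", "CD"), 1.249, 118.4, _chi(3, 180.0))],
    "Q": [_CB,
          ("CG", ("N", "CA", "CB"), 1.520, 114.1, _chi(1)),
          ("CD", ("CA", "CB", "CG"), 1.516, 112.6, _chi(2)),
          ("OE1", ("CB", "CG", "CD"), 1.231, 120.8, _chi(3)),
          ("NE2", ("CB", "CG", "CD"), 1.328, 116.4, _chi(3, 180.0))],
    "K": [_CB,
          ("CG", ("N", "CA", "CB"), 1.520, 114.1, _chi(1)),
          ("CD", ("CA", "CB", "CG"), 1.520, 111.3, _chi(2)),
          ("CE", ("CB", "CG", "CD"), 1.508, 111.3, _chi(3)),
          ("NZ", ("CG", "CD", "CE"), 1.489, 111.5, _chi(4))],
    "R": [_CB,
          ("CG", ("N", "CA", "CB"), 1.520, 114.1, _chi(1)),
          ("CD", ("CA", "CB", "CG"), 1.520, 111.3, _chi(2)),
          ("NE", ("CB", "CG", "CD"), 1.461, 112.0, _chi(3)),
          ("CZ", ("CG", "CD", "NE"), 1.329, 124.2, _chi(4)),
          ("NH1", ("CD", "NE", "CZ"), 1.326, 120.0, 0.0),
          ("NH2", ("CD", "NE", "CZ"), 1.326, 120.0, 180.0)],
}

BACKBONE_NAMES = ("N", "CA", "C", "O")


def template_atom_names(aa: str) -> list[str]:
    """Ordered heavy-atom names for a residue type (backbone then sidechain)."""
    return list(BACKBONE_NAMES) + [row[0] for row in SIDECHAINS[aa]]


# chi-defining atom quadruples
CHI_ATOMS: dict[str, list[tuple[str, str, str, str]]] = {
    "G": [], "A": [],
    "S": [("N", "CA", "CB", "OG")],
    "C": [("N", "CA", "CB", "SG")],
    "T": [("N", "CA", "CB", "OG1")],
    "V": [("N", "CA", "CB", "CG1")],
    "L": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "I": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "M": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
          ("CB", "CG", "SD", "CE")],
    "P": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")],
    "F": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "Y": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "W": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "H": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "D": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "N": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "E": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
          ("CB", "CG", "CD", "OE1")],
    "Q": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
          ("CB", "CG", "CD", "OE1")],
    "K": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
          ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "R": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
          ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
}


def chi_count(aa: str) -> int:
    return len(CHI_ATOMS[aa])


# terminal sp2 torsions have two-fold symmetric wells; everything else is staggered
_TERMINAL_SP2 = {("F", 2), ("Y", 2), ("W", 2), ("H", 2),
                 ("D", 2), ("N", 2), ("E", 3), ("Q", 3)}
_STAGGERED = (-60.0, 60.0, 180.0)
_SYMMETRIC = (90.0, -90.0)


def chi_wells(aa: str) -> list[tuple[float, ...]]:
    """Rotamer well centers per chi; the first entry of chi 1 / the defaults
    below give the most-common rotamer."""
    if aa == "P":
        return [(25.0,), (-35.0,)]
    wells = []
    for k in range(1, chi_count(aa) + 1):
        wells.append(_SYMMETRIC if (aa, k) in _TERMINAL_SP2 else _STAGGERED)
    return wells


# most-common rotamer per residue type; every entry is a well center and is
# contact-free in both ideal helix and ideal strand contexts
_DEFAULT_CHIS = {
    "A": [], "G": [],
    "C": [180.0], "S": [-60.0], "T": [-60.0], "V": [180.0],
    "D": [180.0, 90.0], "N": [180.0, 90.0],
    "E": [-60.0, 180.0, 90.0], "Q": [-60.0, 180.0, 90.0],
    "F": [180.0, 90.0], "Y": [180.0, 90.0], "W": [180.0, -90.0],
    "H": [180.0, 90.0],
    "I": [-60.0, 180.0], "L": [-60.0, 180.0], "M": [-60.0, -60.0, 180.0],
    "K": [-60.0, -60.0, 180.0, 180.0], "R": [-60.0, -60.0, 180.0, 180.0],
    "P": [25.0, -35.0],
}


def default_chis(aa: str) -> list[float]:
    """Most-common rotamer chi values for a residue type."""
    return list(_DEFAULT_CHIS[aa])


# His/Asn/Gln terminal-group 180° flip: ambiguous in crystal structures
FLIP_CHI = {"H": 2, "N": 2, "Q": 3}
FLIP_ATOM_PAIRS = {
    "H": [("ND1", "CD2"), ("CE1", "NE2")],
    "N": [("OD1", "ND2")],
    "Q": [("OE1", "NE2")],
}

# ring/cycle closures not expressed by z-matrix parentage (for the bond graph)
EXTRA_BONDS = {
    "F": [("CE2", "CZ")],
    "Y": [("CE2", "CZ")],
    "W": [("NE1", "CE2"), ("CZ3", "CH2")],
    "H": [("CE1", "NE2")],
    "P": [("CD", "N")],
}

# per-element hard-sphere radii (Å); contact distance sigma_ij = r_i + r_j.
# Chosen so ideal helix/strand backbones (including the i,i+4 carbonyl-amide
# contact at ~3.0 Å) are contact-free.
VDW_RADII = {"C": 1.75, "N": 1.45, "O": 1.40, "S": 1.80}


def element_of(atom_name: str) -> str:
    return atom_name.strip()[0]


def residue_bonds(aa: str) -> list[tuple[str, str]]:
    """Intra-residue heavy-atom bonds (backbone + sidechain + ring closures)."""
    bonds = [("N", "CA"), ("CA", "C"), ("C", "O")]
    for row in SIDECHAINS[aa]:
        name, (_, _, a1) = row[0], row[1]
        bonds.append((a1, name))
    bonds.extend(EXTRA_BONDS.get(aa, []))
    return bonds
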