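"""Bundled chemistry tables: radii, reference areas, hydrogen-bond roles."""

from __future__ import annotations

# van der Waals radii (Angstrom), Bondi set with common defaults
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52,
    "S": 1.80, "P": 1.80, "SE": 1.90,
}
DEFAULT_RADIUS = 1.70

# Gly-X-Gly maximum accessible surface areas (A^2), theoretical values
# (Tien et al. 2013), used to normalize per-residue SASA.
GXG_MAX_SASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

AMINO_ACIDS = tuple(sorted(GXG_MAX_SASA))
DNA_BASES = ("DA", "DC", "DG", "DT")
BASE_LETTER = {"DA": "A", "DC": "C", "DG": "G", "DT": "T"}
LETTER_BASE = {v: k for k, v in BASE_LETTER.items()}
COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}

# aromatic ring atoms defining the base plane
PURINE_RING = ("N9", "C8", "N7", "C5", "C4", "N3", "C2", "N1", "C6")
PYRIMIDINE_RING = ("N1", "C2", "N3", "C4", "C5", "C6")
BASE_RING_ATOMS = {
    "DA": PURINE_RING, "DG": PURINE_RING,
    "DC": PYRIMIDINE_RING, "DT": PYRIMIDINE_RING,
}

BACKBONE_ATOMS = ("N", "CA", "C", "O", "OXT")

# Hydrogen-bond donor heavy atoms (carry a polar H) and acceptors,
# keyed by (residue name, atom name); "*" matches any residue of that class.
HBOND_DONORS = {
    ("*", "N"),                      # backbone amide
    ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
    ("ASN", "ND2"), ("GLN", "NE2"),
    ("HIS", "ND1"), ("HIS", "NE2"),
    ("LYS", "NZ"), ("TRP", "NE1"),
    ("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"), ("CYS", "SG"),
    ("DA", "N6"), ("DC", "N4"), ("DG", "N1"), ("DG", "N2"), ("DT", "N3"),
    ("DA", "O2'"), ("DC", "O2'"), ("DG", "O2'"), ("DT", "O2'"),
}
HBOND_ACCEPTORS = {
    ("*", "O"), ("*", "OXT"),        # backbone carbonyl
    ("ASN", "OD1"), ("ASP", "OD1"), ("ASP", "OD2"),
    ("GLN", "OE1"), ("GLU", "OE1"), ("GLU", "OE2"),
    ("HIS", "ND1"), ("HIS", "NE2"), ("MET", "SD"),
    ("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"),
    ("DA", "N1"), ("DA", "N3"), ("DA", "N7"),
    ("DC", "N3"), ("DC", "O2"),
    ("DG", "N3"), ("DG", "N7"), ("DG", "O6"),
    ("DT", "O2"), ("DT", "O4"),
    ("DA", "OP1"), ("DA", "OP2"), ("DC", "OP1"), ("DC", "OP2"),
    ("DG", "OP1"), ("DG", "OP2"), ("DT", "OP1"), ("DT", "OP2"),
    ("DA", "O4'"), ("DC", "O4'"), ("DG", "O4'"), ("DT", "O4'"),
    ("DA", "O3'"), ("DC", "O3'"), ("DG", "O3'"), ("DT", "O3'"),
    ("DA", "O5'"), ("DC", "O5'"), ("DG", "O5'"), ("DT", "O5'"),
}


def is_hbond_donor(resname: str, atom_name: str) -> bool:
    return (resname, atom_name) in HBOND_DONORS or ("*", atom_name) in HBOND_DONORS


def is_hbond_acceptor(resname: str, atom_name: str) -> bool:
    return (resname, atom_name) in HBOND_ACCEPTORS or ("*", atom_name) in HBOND_ACCEPTORS
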