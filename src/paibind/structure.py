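"""Molecular models: PDB IO (via gemmi) and idealized toy builders.

The in-memory container is a flat atom table with per-chain roles
(protein / dna).  Toy construction provides an idealized fiber-model B-DNA
duplex (3.38 A rise, 36 deg twist per base pair, planar idealized base
rings) and a poly-alanine alpha-helix, which together form a minimal,
fully synthetic protein-DNA complex for exercising the docking engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

from .chemistry import (
    AMINO_ACIDS,
    BASE_RING_ATOMS,
    COMPLEMENT,
    LETTER_BASE,
)

__all__ = [
    "MolecularModel",
    "read_structure",
    "write_structure",
    "build_bdna",
    "build_polyala_helix",
    "RISE_PER_BP",
    "TWIST_PER_BP_DEG",
]

RISE_PER_BP = 3.38        # Angstrom, fiber-model B-DNA
TWIST_PER_BP_DEG = 36.0


@dataclass(frozen=True)
class MolecularModel:
    """Flat atom table plus per-chain roles.

    ``chain_roles`` maps chain id to "protein" or "dna"; residues whose
    name is neither a standard amino acid nor a deoxynucleotide are listed
    in ``flagged_residues`` and are excluded from scoring.
    """

    serial: np.ndarray
    name: np.ndarray
    element: np.ndarray
    resnum: np.ndarray
    resname: np.ndarray
    chain: np.ndarray
    coords: np.ndarray
    chain_roles: dict = field(default_factory=dict)
    flagged_residues: tuple = ()

    def __post_init__(self):
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return int(self.coords.shape[0])

    def chain_mask(self, role: str) -> np.ndarray:
        chains = {c for c, r in self.chain_roles.items() if r == role}
        return np.isin(self.chain, sorted(chains))

    def protein_atoms(self) -> np.ndarray:
        return np.where(self.chain_mask("protein"))[0]

    def dna_atoms(self) -> np.ndarray:
        return np.where(self.chain_mask("dna"))[0]

    def residues(self, role: str | None = None):
        """Yield (chain, resnum, resname, atom index array) in file order."""
        mask = np.ones(self.n_atoms, bool) if role is None else self.chain_mask(role)
        idx = np.where(mask)[0]
        seen: dict[tuple, list] = {}
        for i in idx:
            seen.setdefault((self.chain[i], int(self.resnum[i])), []).append(i)
        for (ch, rn), atoms in seen.items():
            yield ch, rn, str(self.resname[atoms[0]]), np.asarray(atoms)

    def sequence(self, chain_id: str) -> str:
        """One-letter DNA sequence of a chain, in residue-number order."""
        rows = [(int(self.resnum[i]), str(self.resname[i]))
                for i in range(self.n_atoms) if self.chain[i] == chain_id]
        out, last = [], None
        for rn, name in sorted(set(rows)):
            if rn != last:
                out.append(name[-1])
                last = rn
        return "".join(out)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray,
                    role: str = "protein") -> "MolecularModel":
        """Return a copy with the rigid transform applied to one role."""
        coords = self.coords.copy()
        m = self.chain_mask(role)
        coords[m] = coords[m] @ np.asarray(rotation).T + np.asarray(translation)
        return replace(self, coords=coords)


_GEMMI_DNA = {"DA", "DC", "DG", "DT", "A", "C", "G", "T"}


def _role_of(resname: str) -> str:
    if resname in _GEMMI_DNA:
        return "dna"
    if resname in AMINO_ACIDS:
        return "protein"
    return "other"


def read_structure(pdb_text: str) -> MolecularModel:
    """Parse PDB-format text into a :class:`MolecularModel` (first model).

    Chain roles are assigned from residue names; residues that are neither
    standard amino acids nor A/C/G/T deoxynucleotides are flagged.
    """
    st = gemmi.read_pdb_string(pdb_text)
    if len(st) == 0:
        raise ValueError("no models in PDB input")
    model = st[0]
    rows = {k: [] for k in
            ("serial", "name", "element", "resnum", "resname", "chain")}
    xyz = []
    roles: dict[str, set] = {}
    flagged = []
    for chain in model:
        for res in chain:
            rname = res.name.strip()
            if rname in {"A", "C", "G", "T"}:
                rname = LETTER_BASE[rname]
            role = _role_of(rname)
            if role == "other":
                flagged.append((chain.name, res.seqid.num, rname))
            roles.setdefault(chain.name, set()).add(role)
            for atom in res:
                rows["serial"].append(atom.serial)
                rows["name"].append(atom.name)
                rows["element"].append(atom.element.name.upper())
                rows["resnum"].append(res.seqid.num)
                rows["resname"].append(rname)
                rows["chain"].append(chain.name)
                xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
    if not xyz:
        raise ValueError("no atoms parsed from PDB input")
    chain_roles = {}
    for ch, rs in roles.items():
        rs = rs - {"other"}
        chain_roles[ch] = rs.pop() if len(rs) == 1 else "mixed"
    return MolecularModel(
        serial=np.array(rows["serial"]),
        name=np.array(rows["name"]),
        element=np.array(rows["element"]),
        resnum=np.array(rows["resnum"]),
        resname=np.array(rows["resname"]),
        chain=np.array(rows["chain"]),
        coords=np.array(xyz, dtype=float),
        chain_roles=chain_roles,
        flagged_residues=tuple(flagged),
    )


def write_structure(model: MolecularModel, poses=None) -> str:
    """Serialize to PDB text; with ``poses``, one MODEL per pose is written
    with the pose transform baked into the protein coordinates."""
    models = [model] if poses is None else [
        model.transformed(p.rotation, p.translation) for p in poses
    ]
    st = gemmi.Structure()
    st.name = "paibind"
    for k, m in enumerate(models, start=1):
        gm = gemmi.Model(k)
        for ch_name in dict.fromkeys(m.chain):  # preserve order
            chain = gemmi.Chain(str(ch_name))
            idx = [i for i in range(m.n_atoms) if m.chain[i] == ch_name]
            current = None
            res = None
            for i in idx:
                key = int(m.resnum[i])
                if key != current:
                    res = gemmi.Residue()
                    res.name = str(m.resname[i])
                    res.seqid = gemmi.SeqId(key, " ")
                    chain.add_residue(res)
                    current = key
                atom = gemmi.Atom()
                atom.name = str(m.name[i])
                atom.serial = int(m.serial[i])
                atom.element = gemmi.Element(str(m.element[i]))
                atom.pos = gemmi.Position(*m.coords[i])
                chain[-1].add_atom(atom)
            gm.add_chain(chain)
        st.add_model(gm)
    st.setup_entities()
    return st.make_pdb_string()


# --- idealized geometry ----------------------------------------------------

def _ring_template(resname: str) -> dict[str, np.ndarray]:
    """Planar idealized base ring in its local frame (plane z = 0).

    Pyrimidines are a regular hexagon (1.39 A bonds); purines add the fused
    five-membered ring on the C4-C5 edge.  The glycosidic nitrogen points
    toward -x so C1' can be attached outward.  Geometry is idealized, not
    sequence-specific -- sufficient for centroid/plane computations.
    """
    r6 = 1.39
    hex_names = ["N1", "C2", "N3", "C4", "C5", "C6"]
    ring = {}
    for k, nm in enumerate(hex_names):
        a = np.deg2rad(180.0 + 60.0 * k)  # N1 at -x
        ring[nm] = np.array([r6 * np.cos(a), r6 * np.sin(a), 0.0])
    if resname in ("DA", "DG"):
        # fused 5-ring across C4-C5, on the far side from N1
        c4, c5 = ring["C4"], ring["C5"]
        mid = (c4 + c5) / 2.0
        out = mid / np.linalg.norm(mid)
        ring["N9"] = c4 + 1.37 * _rot_in_plane(out, -54.0)
        ring["N7"] = c5 + 1.37 * _rot_in_plane(out, 54.0)
        ring["C8"] = mid + 2.2 * out
    return ring


def _rot_in_plane(v, deg):
    a = np.deg2rad(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1], 0.0])


def _glycosidic(resname: str) -> str:
    return "N9" if resname in ("DA", "DG") else "N1"


def _canonical_glycosidic_frame(template: dict, glyc: str) -> dict:
    """Center a base template on its glycosidic atom and rotate in-plane so
    the ring centroid lies along +x (backbone outside, ring inside)."""
    centered = {nm: p - template[glyc] for nm, p in template.items()}
    centroid = np.mean(list(centered.values()), axis=0)
    ang = -np.arctan2(centroid[1], centroid[0])
    c, s = np.cos(ang), np.sin(ang)
    return {nm: np.array([c * p[0] - s * p[1], s * p[0] + c * p[1], p[2]])
            for nm, p in centered.items()}


def build_bdna(sequence: str, chain_ids: tuple[str, str] = ("B", "C"),
               origin: np.ndarray | None = None) -> MolecularModel:
    """Idealized fiber-model B-DNA duplex for the given forward sequence.

    Base pair k sits at height k*3.38 A along z, rotated k*36 deg about the
    helix axis; each base is a planar idealized ring with C1' attached at
    the glycosidic atom, and base-pair centers lie exactly on the axis.
    The complementary strand runs antiparallel, so its 5'->3' sequence is
    the reverse complement of ``sequence``.
    """
    seq = sequence.upper()
    if any(b not in COMPLEMENT for b in seq):
        raise ValueError("DNA sequence must contain only A, C, G, T")
    if origin is None:
        origin = np.zeros(3)
    n = len(seq)
    rows = {k: [] for k in ("serial", "name", "element", "resnum", "resname", "chain")}
    xyz = []
    serial = 1

    def add_atom(name, element, resnum, resname, chain, pos):
        nonlocal serial
        rows["serial"].append(serial)
        rows["name"].append(name)
        rows["element"].append(element)
        rows["resnum"].append(resnum)
        rows["resname"].append(resname)
        rows["chain"].append(chain)
        xyz.append(pos)
        serial += 1

    comp_rows = []  # built per bp, emitted afterwards in 5'->3' order
    for k, letter in enumerate(seq):
        res_a = LETTER_BASE[letter]
        res_b = LETTER_BASE[COMPLEMENT[letter]]
        z = k * RISE_PER_BP
        twist = np.deg2rad(k * TWIST_PER_BP_DEG)
        c, s = np.cos(twist), np.sin(twist)
        rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])

        def place(template, offset, flip):
            out = {}
            for nm, p in template.items():
                q = p.copy()
                if flip:  # 180 deg about x: antiparallel partner
                    q = np.array([q[0], -q[1], -q[2]])
                q = q + offset
                out[nm] = rot @ q + np.array([0.0, 0.0, z]) + origin
            return out

        # glycosidic atoms face each other across the axis, rings extending
        # inward toward the axis
        ta = _ring_template(res_a)
        tb = _ring_template(res_b)
        ga, gb = _glycosidic(res_a), _glycosidic(res_b)
        ta = _canonical_glycosidic_frame(ta, ga)
        tb = _canonical_glycosidic_frame(tb, gb)
        # in-plane 180 deg turn so the strand-A ring points toward -x
        ta = {nm: np.array([-p[0], -p[1], p[2]]) for nm, p in ta.items()}
        pa = place(ta, np.array([4.4, 0.0, 0.0]), flip=False)
        pb = place(tb, np.array([-4.4, 0.0, 0.0]), flip=True)
        # recenter both rings so that the pair midpoint is on the axis
        mid = (np.mean(list(pa.values()), axis=0) + np.mean(list(pb.values()), axis=0)) / 2
        corr = np.array([0.0, 0.0, z]) + origin - mid
        pa = {nm: p + corr for nm, p in pa.items()}
        pb = {nm: p + corr for nm, p in pb.items()}
        c1a = pa[ga] + (pa[ga] - np.mean(list(pa.values()), axis=0)) * 1.0
        c1b = pb[gb] + (pb[gb] - np.mean(list(pb.values()), axis=0)) * 1.0

        for nm in BASE_RING_ATOMS[res_a]:
            add_atom(nm, nm[0], k + 1, res_a, chain_ids[0], pa[nm])
        add_atom("C1'", "C", k + 1, res_a, chain_ids[0], c1a)
        comp_rows.append((n - k, res_b, [(nm, pb[nm]) for nm in BASE_RING_ATOMS[res_b]]
                          + [("C1'", c1b)]))

    for resnum, resname, atoms in sorted(comp_rows):
        for nm, pos in atoms:
            add_atom(nm, nm[0], resnum, resname, chain_ids[1], pos)

    return MolecularModel(
        serial=np.array(rows["serial"]), name=np.array(rows["name"]),
        element=np.array(rows["element"]), resnum=np.array(rows["resnum"]),
        resname=np.array(rows["resname"]), chain=np.array(rows["chain"]),
        coords=np.array(xyz, dtype=float),
        chain_roles={chain_ids[0]: "dna", chain_ids[1]: "dna"},
    )


def build_polyala_helix(n_residues: int, chain_id: str = "A",
                        origin: np.ndarray | None = None) -> MolecularModel:
    """Idealized poly-alanine alpha-helix (1.5 A rise, 100 deg/residue).

    Backbone N/CA/C/O plus CB; CB points radially outward so sidechain
    direction vectors are well defined for orientation scoring.
    """
    if n_residues < 2:
        raise ValueError("need at least 2 residues")
    if origin is None:
        origin = np.zeros(3)
    radius, rise, turn = 2.3, 1.5, np.deg2rad(100.0)
    rows = {k: [] for k in ("serial", "name", "element", "resnum", "resname", "chain")}
    xyz = []
    serial = 1

    def add(name, element, resnum, pos):
        nonlocal serial
        rows["serial"].append(serial)
        rows["name"].append(name)
        rows["element"].append(element)
        rows["resnum"].append(resnum)
        rows["resname"].append("ALA")
        rows["chain"].append(chain_id)
        xyz.append(np.asarray(pos, dtype=float) + origin)
        serial += 1

    def ca(i):
        a = i * turn
        return np.array([radius * np.cos(a), radius * np.sin(a), i * rise])

    for i in range(n_residues):
        p = ca(i)
        prev_dir = p - ca(i - 1)
        next_dir = ca(i + 1) - p
        prev_dir /= np.linalg.norm(prev_dir)
        next_dir /= np.linalg.norm(next_dir)
        radial = np.array([p[0], p[1], 0.0])
        radial /= np.linalg.norm(radial)
        add("N", "N", i + 1, p - 1.46 * prev_dir)
        add("CA", "C", i + 1, p)
        add("C", "C", i + 1, p + 1.52 * next_dir)
        add("O", "O", i + 1, p + 1.52 * next_dir + 1.23 * radial)
        add("CB", "C", i + 1, p + 1.53 * radial)

    return MolecularModel(
        serial=np.array(rows["serial"]), name=np.array(rows["name"]),
        element=np.array(rows["element"]), resnum=np.array(rows["resnum"]),
        resname=np.array(rows["resname"]), chain=np.array(rows["chain"]),
        coords=np.array(xyz, dtype=float), chain_roles={chain_id: "protein"},
    )
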