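"""Rigid-body protein-DNA docking with a knowledge-based orientation potential.

The interaction energy of a complex is a sum over residue-base pairs,

    E = sum_ij  E0_ij(r, phi),

where r is the distance between the residue sidechain centroid (Calpha for
glycine) and the base ring centroid, and phi in [0, 90] deg is the angle
between the sidechain direction vector (Calpha -> sidechain centroid) and
the least-squares base plane.  The binned table E0 is derived from training
complexes by inverse-Boltzmann statistics against an angle-uniform,
distance-marginal reference state.

Docking runs independent Metropolis Monte Carlo searches over rigid 6-DOF
protein moves with geometric cooling, keeping the best pose per run (the
DNA stays fixed).  A soft-core steric penalty (quadratic in the overlap
below 2.5 A heavy-atom distance) supplements the statistical potential
during the search only and is reported separately.  Poses are clustered by
complete-linkage hierarchical clustering of pairwise protein-Calpha RMSD at
a 3 A cutoff and clusters are ranked by the energy of their lowest-energy
member (representative); mean-of-top-k ranking is available as an
alternative.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, squareform
from scipy.spatial.transform import Rotation

from .chemistry import (
    AMINO_ACIDS,
    BACKBONE_ATOMS,
    BASE_RING_ATOMS,
    DNA_BASES,
    is_hbond_acceptor,
    is_hbond_donor,
)
from .structure import MolecularModel

__all__ = [
    "OrientationPotential",
    "DockPose",
    "ClusterSolution",
    "residue_base_geometry",
    "interaction_energy",
    "inverse_boltzmann",
    "derive_potential",
    "mc_dock",
    "superpose",
    "cluster_poses",
    "interface_contacts",
    "steric_penalty",
]


# --- potential -------------------------------------------------------------

@dataclass(frozen=True)
class OrientationPotential:
    """Binned residue-type x base-type x distance x angle energy table.

    Distances beyond the last edge contribute exactly zero.  Energies are in
    arbitrary (kT-like) units.
    """

    r_edges: np.ndarray            # contiguous distance bin edges, Angstrom
    phi_edges: np.ndarray          # angle bin edges covering [0, 90] deg
    aa_types: tuple[str, ...]
    base_types: tuple[str, ...]
    table: np.ndarray              # (n_aa, n_base, n_r, n_phi)

    def __post_init__(self):
        object.__setattr__(self, "r_edges", np.asarray(self.r_edges, float))
        object.__setattr__(self, "phi_edges", np.asarray(self.phi_edges, float))
        object.__setattr__(self, "table", np.asarray(self.table, float))
        expect = (len(self.aa_types), len(self.base_types),
                  self.r_edges.size - 1, self.phi_edges.size - 1)
        if self.table.shape != expect:
            raise ValueError(f"table shape {self.table.shape} != {expect}")
        if not np.all(np.isfinite(self.table)):
            raise ValueError("non-finite energies in potential table")

    @property
    def cutoff(self) -> float:
        return float(self.r_edges[-1])

    def lookup(self, aa: str, base: str, r: float, phi: float) -> float:
        if r >= self.cutoff or r < self.r_edges[0]:
            return 0.0
        i = self.aa_types.index(aa)
        j = self.base_types.index(base)
        ri = min(np.searchsorted(self.r_edges, r, side="right") - 1,
                 self.r_edges.size - 2)
        pi = min(np.searchsorted(self.phi_edges, phi, side="right") - 1,
                 self.phi_edges.size - 2)
        return float(self.table[i, j, ri, pi])

    def to_json(self) -> str:
        return json.dumps({
            "r_edges": self.r_edges.tolist(),
            "phi_edges": self.phi_edges.tolist(),
            "aa_types": list(self.aa_types),
            "base_types": list(self.base_types),
            "table": self.table.tolist(),
        })

    @classmethod
    def from_json(cls, text: str) -> "OrientationPotential":
        d = json.loads(text)
        return cls(r_edges=np.array(d["r_edges"]), phi_edges=np.array(d["phi_edges"]),
                   aa_types=tuple(d["aa_types"]), base_types=tuple(d["base_types"]),
                   table=np.array(d["table"]))

    @classmethod
    def zeros(cls, r_max=15.0, r_step=1.0, phi_step=15.0,
              aa_types=AMINO_ACIDS, base_types=DNA_BASES):
        r_edges = np.arange(0.0, r_max + r_step / 2, r_step)
        phi_edges = np.arange(0.0, 90.0 + phi_step / 2, phi_step)
        table = np.zeros((len(aa_types), len(base_types),
                          r_edges.size - 1, phi_edges.size - 1))
        return cls(r_edges, phi_edges, tuple(aa_types), tuple(base_types), table)


@dataclass(frozen=True)
class DockPose:
    """Rigid transform applied to the protein, with its score."""

    rotation: np.ndarray           # proper 3x3
    translation: np.ndarray        # Angstrom
    energy: float
    steric: float = 0.0
    run_id: int = 0
    seed: int = 0

    def __post_init__(self):
        R = np.asarray(self.rotation, float)
        t = np.asarray(self.translation, float)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-6) or np.linalg.det(R) < 0:
            raise ValueError("rotation must be orthonormal with det +1")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


@dataclass(frozen=True)
class ClusterSolution:
    labels: np.ndarray             # pose index -> cluster label (1-based)
    ranking: tuple[int, ...]       # cluster labels, best first
    representatives: dict          # label -> pose index of lowest-energy member
    linkage_matrix: np.ndarray


# --- geometry --------------------------------------------------------------

def _fit_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares plane through points: (centroid, unit normal)."""
    c = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - c)
    return c, vt[-1]


class _Scorer:
    """Precomputed geometry for fast repeated energy evaluation.

    Protein-side reference points (Calpha, sidechain centroid) are stored in
    the protein frame; DNA base centroids and plane normals are fixed.
    """

    def __init__(self, model: MolecularModel, potential: OrientationPotential):
        self.potential = potential
        self.ca = []
        self.sc = []
        self.aa_idx = []
        skipped = []
        for ch, rn, rname, atoms in model.residues("protein"):
            if rname not in potential.aa_types:
                skipped.append((ch, rn, rname))
                continue
            names = model.name[atoms]
            ca = atoms[names == "CA"]
            if ca.size == 0:
                skipped.append((ch, rn, rname))
                continue
            ca_xyz = model.coords[ca[0]]
            side = [i for i in atoms
                    if model.name[i] not in BACKBONE_ATOMS and model.element[i] != "H"]
            sc_xyz = model.coords[side].mean(axis=0) if side else ca_xyz
            self.ca.append(ca_xyz)
            self.sc.append(sc_xyz)
            self.aa_idx.append(potential.aa_types.index(rname))
        if skipped:
            warnings.warn(f"{len(skipped)} protein residues skipped in scoring")
        self.ca = np.array(self.ca)
        self.sc = np.array(self.sc)
        self.aa_idx = np.array(self.aa_idx, dtype=int)

        self.base_centroid = []
        self.base_normal = []
        self.base_idx = []
        for ch, rn, rname, atoms in model.residues("dna"):
            if rname not in potential.base_types:
                continue
            ring = [i for i in atoms if model.name[i] in BASE_RING_ATOMS[rname]]
            if len(ring) < 3:
                continue
            c, n = _fit_plane(model.coords[ring])
            self.base_centroid.append(c)
            self.base_normal.append(n)
            self.base_idx.append(potential.base_types.index(rname))
        if not self.base_idx:
            raise ValueError("no scoreable DNA bases in model")
        self.base_centroid = np.array(self.base_centroid)
        self.base_normal = np.array(self.base_normal)
        self.base_idx = np.array(self.base_idx, dtype=int)

        # heavy-atom coordinates for the steric term
        self.prot_xyz = model.coords[model.protein_atoms()]
        self.dna_xyz = model.coords[model.dna_atoms()]

        p = potential
        self._nr = p.r_edges.size - 1
        self._nphi = p.phi_edges.size - 1

    def pair_geometry(self, rotation, translation):
        """(i_res, j_base, r, phi) arrays for all in-cutoff pairs."""
        ca = self.ca @ rotation.T + translation
        sc = self.sc @ rotation.T + translation
        d = cdist(sc, self.base_centroid)
        ii, jj = np.where(d < self.potential.cutoff)
        vec = sc[ii] - ca[ii]
        norm = np.linalg.norm(vec, axis=1)
        dot = np.abs(np.einsum("ij,ij->i", vec, self.base_normal[jj]))
        with np.errstate(invalid="ignore", divide="ignore"):
            sinphi = np.where(norm > 1e-9, dot / np.maximum(norm, 1e-12), 0.0)
        phi = np.degrees(np.arcsin(np.clip(sinphi, 0.0, 1.0)))
        return ii, jj, d[ii, jj], phi

    def energy(self, rotation, translation) -> float:
        ii, jj, r, phi = self.pair_geometry(rotation, translation)
        if ii.size == 0:
            return 0.0
        p = self.potential
        ri = np.clip(np.searchsorted(p.r_edges, r, side="right") - 1, 0, self._nr - 1)
        pi = np.clip(np.searchsorted(p.phi_edges, phi, side="right") - 1,
                     0, self._nphi - 1)
        return float(p.table[self.aa_idx[ii], self.base_idx[jj], ri, pi].sum())

    def steric(self, rotation, translation, clash_dist=2.5) -> float:
        xyz = self.prot_xyz @ rotation.T + translation
        d = cdist(xyz, self.dna_xyz)
        overlap = np.maximum(clash_dist - d, 0.0)
        return float((overlap**2).sum())


def residue_base_geometry(model: MolecularModel,
                          potential: OrientationPotential | None = None,
                          pose: DockPose | None = None):
    """List of (aa type, base type, r, phi) records for in-cutoff pairs.

    phi = 0 when the sidechain vector lies in the base plane, 90 when along
    its normal; glycine (no sidechain beyond Calpha) gets phi = 0.
    """
    if potential is None:
        potential = OrientationPotential.zeros()
    s = _Scorer(model, potential)
    R = pose.rotation if pose is not None else np.eye(3)
    t = pose.translation if pose is not None else np.zeros(3)
    ii, jj, r, phi = s.pair_geometry(R, t)
    return [(potential.aa_types[s.aa_idx[i]], potential.base_types[s.base_idx[j]],
             float(rr), float(pp))
            for i, j, rr, pp in zip(ii, jj, r, phi)]


def interaction_energy(model: MolecularModel, potential: OrientationPotential,
                       pose: DockPose | None = None) -> float:
    """Knowledge-based interaction energy of the (posed) complex."""
    s = _Scorer(model, potential)
    R = pose.rotation if pose is not None else np.eye(3)
    t = pose.translation if pose is not None else np.zeros(3)
    return s.energy(R, t)


def inverse_boltzmann(n_obs, n_ref, pseudocount: float = 0.0) -> np.ndarray:
    """E = -ln((N_obs + p) / (N_ref + p)); bins with empty reference get 0."""
    n_obs = np.asarray(n_obs, float)
    n_ref = np.asarray(n_ref, float)
    num = n_obs + pseudocount
    den = n_ref + pseudocount
    out = np.zeros(np.broadcast(num, den).shape)
    ok = (num > 0) & (den > 0)
    out[ok] = -np.log(num[ok] / den[ok])
    return out


def derive_potential(training: list[MolecularModel],
                     r_max: float = 15.0, r_step: float = 1.0,
                     phi_step: float = 15.0,
                     pseudocount: float = 0.5) -> OrientationPotential:
    """Inverse-Boltzmann potential from observed residue-base geometries.

    The reference state is angle-uniform at each (residue type, base type,
    distance) triple: N_ref(i,j,r,phi) = N_obs(i,j,r,.) / n_phi_bins, so the
    energies encode angular preference at a given separation while the
    distance dependence of contact frequency cancels.  The result is
    invariant to duplicating the training set.
    """
    if not training:
        raise ValueError("need at least one training complex")
    pot = OrientationPotential.zeros(r_max=r_max, r_step=r_step, phi_step=phi_step)
    counts = np.zeros_like(pot.table)
    nphi = pot.phi_edges.size - 1
    for model in training:
        s = _Scorer(model, pot)
        ii, jj, r, phi = s.pair_geometry(np.eye(3), np.zeros(3))
        ri = np.clip(np.searchsorted(pot.r_edges, r, "right") - 1, 0,
                     pot.r_edges.size - 2)
        pi = np.clip(np.searchsorted(pot.phi_edges, phi, "right") - 1, 0, nphi - 1)
        np.add.at(counts, (s.aa_idx[ii], s.base_idx[jj], ri, pi), 1.0)
    if counts.sum() == 0:
        raise ValueError("no in-cutoff residue-base pairs in the training set")
    ref = counts.sum(axis=3, keepdims=True) / nphi
    table = inverse_boltzmann(counts, np.broadcast_to(ref, counts.shape), pseudocount)
    return OrientationPotential(pot.r_edges, pot.phi_edges, pot.aa_types,
                                pot.base_types, table)


# --- Monte Carlo search ----------------------------------------------------

def _random_start(rng, scorer, translate_only, start_radius):
    if translate_only:
        R = np.eye(3)
    else:
        R = Rotation.random(random_state=rng).as_matrix()
    center = scorer.base_centroid.mean(axis=0)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    target = center + start_radius * direction
    prot_center = scorer.prot_xyz.mean(axis=0)
    t = target - R @ prot_center
    return R, t


def mc_dock(model: MolecularModel, potential: OrientationPotential,
            runs: int = 200, seed: int = 0, steps: int = 5000,
            trans_step: float = 1.0, rot_step_deg: float = 5.0,
            t_start: float = 5.0, t_end: float = 0.1,
            steric_weight: float = 1.0, clash_dist: float = 2.5,
            translate_only: bool = False,
            start_radius: float | None = None) -> list[DockPose]:
    """Independent Metropolis Monte Carlo docking runs; best pose per run.

    Each run starts from a random pose on a sphere around the DNA and
    performs ``steps`` rigid moves (random translation up to ``trans_step``
    and rotation up to ``rot_step_deg`` about the protein centroid) under a
    geometric cooling schedule from ``t_start`` to ``t_end``.  The search
    score is E + steric_weight * soft-core overlap penalty; the returned
    pose is the best-scoring state visited (elitism), with the statistical
    energy and the steric term reported separately.  Run k uses seed
    seed + k, so a fixed seed reproduces the pose list exactly.
    """
    if runs < 1:
        raise ValueError("runs must be >= 1")
    scorer = _Scorer(model, potential)
    if start_radius is None:
        dna_extent = np.linalg.norm(
            scorer.dna_xyz - scorer.dna_xyz.mean(axis=0), axis=1).max()
        prot_extent = np.linalg.norm(
            scorer.prot_xyz - scorer.prot_xyz.mean(axis=0), axis=1).max()
        start_radius = dna_extent + prot_extent + 2.0

    cool = (t_end / t_start) ** (1.0 / max(steps - 1, 1))
    poses = []
    for run in range(runs):
        rng = np.random.default_rng(seed + run)
        for _ in range(20):  # re-initialize on unresolvable steric overlap
            R, t = _random_start(rng, scorer, translate_only, start_radius)
            if scorer.steric(R, t, clash_dist) < 100.0:
                break
        prot_center_0 = scorer.prot_xyz.mean(axis=0)

        def score(Rm, tm):
            e = scorer.energy(Rm, tm)
            st = scorer.steric(Rm, tm, clash_dist)
            return e + steric_weight * st, e, st

        cur, cur_e, cur_st = score(R, t)
        best = (cur, cur_e, cur_st, R, t)
        temp = t_start
        for _ in range(steps):
            dt = rng.uniform(-trans_step, trans_step, size=3)
            if translate_only:
                Rn = R
            else:
                axis = rng.normal(size=3)
                axis /= np.linalg.norm(axis)
                ang = np.deg2rad(rng.uniform(-rot_step_deg, rot_step_deg))
                dR = Rotation.from_rotvec(ang * axis).as_matrix()
                # rotate about the current protein centroid
                c = R @ prot_center_0 + t
                Rn = dR @ R
                tn_rot = c - Rn @ prot_center_0
            if translate_only:
                tn = t + dt
            else:
                tn = tn_rot + dt
            new, new_e, new_st = score(Rn, tn)
            if new <= cur or rng.random() < np.exp(-(new - cur) / temp):
                R, t, cur, cur_e, cur_st = Rn, tn, new, new_e, new_st
                if cur < best[0]:
                    best = (cur, cur_e, cur_st, R, t)
            temp *= cool
        poses.append(DockPose(rotation=best[3], translation=best[4],
                              energy=best[1], steric=best[2],
                              run_id=run, seed=seed + run))
    return poses


def steric_penalty(model: MolecularModel, pose: DockPose | None = None,
                   clash_dist: float = 2.5,
                   potential: OrientationPotential | None = None) -> float:
    """Soft-core overlap penalty used during the search (reported separately)."""
    s = _Scorer(model, potential or OrientationPotential.zeros())
    R = pose.rotation if pose is not None else np.eye(3)
    t = pose.translation if pose is not None else np.zeros(3)
    return s.steric(R, t, clash_dist)


# --- superposition and clustering ------------------------------------------

def superpose(reference: np.ndarray, mobile: np.ndarray):
    """Least-squares rigid superposition (Kabsch) of mobile onto reference.

    Returns (rotation, translation, rmsd) with a proper rotation enforced
    (reflections are never returned); apply as x @ R.T + t.
    """
    ref = np.asarray(reference, float)
    mob = np.asarray(mobile, float)
    if ref.shape != mob.shape or ref.ndim != 2 or ref.shape[0] < 3:
        raise ValueError("need matching point sets with >= 3 points")
    cr, cm = ref.mean(axis=0), mob.mean(axis=0)
    A = ref - cr
    B = mob - cm
    if np.linalg.matrix_rank(B) < 2:
        raise ValueError("degenerate (collinear) point set")
    H = B.T @ A
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cr - R @ cm
    moved = mob @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))
    return R, t, rmsd


def cluster_poses(model: MolecularModel, poses: list[DockPose],
                  cutoff: float = 3.0, rank_by: str = "representative",
                  top_k: int = 10) -> ClusterSolution:
    """Complete-linkage clustering of poses by protein-Calpha RMSD.

    Pose distance is the RMSD of protein Calpha atoms in the common DNA
    frame (the DNA is fixed during docking, so superposing the DNA frames
    is the identity).  The dendrogram is cut at ``cutoff`` (which bounds
    every cluster's diameter) and clusters are ranked by the energy of the
    lowest-energy member, or with ``rank_by="topk_mean"`` by the mean energy
    of their ``top_k`` best members.
    """
    if len(poses) < 2:
        raise ValueError("need >= 2 poses to cluster")
    prot = model.protein_atoms()
    ca_local = model.coords[prot[model.name[prot] == "CA"]]
    coords = np.stack([p.apply(ca_local) for p in poses])
    n = len(poses)
    dmat = np.zeros((n, n))
    for i in range(n):
        diff = coords[i + 1:] - coords[i]
        dmat[i, i + 1:] = np.sqrt(np.mean(np.sum(diff**2, axis=2), axis=1))
    dmat = dmat + dmat.T
    Z = linkage(squareform(dmat, checks=False), method="complete")
    labels = fcluster(Z, t=cutoff, criterion="distance")

    energies = np.array([p.energy for p in poses])
    reps, scores = {}, {}
    for lab in np.unique(labels):
        members = np.where(labels == lab)[0]
        order = members[np.argsort(energies[members])]
        reps[int(lab)] = int(order[0])
        if rank_by == "topk_mean":
            scores[int(lab)] = float(energies[order[:top_k]].mean())
        else:
            scores[int(lab)] = float(energies[order[0]])
    ranking = tuple(sorted(scores, key=scores.get))
    return ClusterSolution(labels=labels, ranking=ranking,
                           representatives=reps, linkage_matrix=Z)


# --- interface annotation --------------------------------------------------

def interface_contacts(model: MolecularModel, pose: DockPose | None = None,
                       cutoff: float = 5.0, hbond_dist: float = 3.5,
                       hbond_angle: float = 120.0):
    """Interface atoms (any partner atom within ``cutoff``) and hydrogen bonds.

    Hydrogen bonds are donor-acceptor heavy-atom pairs within
    ``hbond_dist`` whose angle (donor antecedent - donor - acceptor) is at
    least ``hbond_angle`` degrees; donors/acceptors come from the bundled
    chemistry table.  Returns (protein atom index set, DNA atom index set,
    list of (donor index, acceptor index, distance, angle)).
    """
    m = model if pose is None else model.transformed(pose.rotation, pose.translation)
    prot = m.protein_atoms()
    dna = m.dna_atoms()
    if prot.size == 0 or dna.size == 0:
        return set(), set(), []
    d = cdist(m.coords[prot], m.coords[dna])
    pi, di = np.where(d <= cutoff)
    prot_iface = {int(prot[i]) for i in pi}
    dna_iface = {int(dna[j]) for j in di}

    def antecedent(i):
        same = np.where((m.chain == m.chain[i]) & (m.resnum == m.resnum[i]))[0]
        same = same[same != i]
        if same.size == 0:
            return None
        dd = np.linalg.norm(m.coords[same] - m.coords[i], axis=1)
        j = same[np.argmin(dd)]
        return int(j) if dd.min() < 1.8 else None

    def angle_ok(don, acc):
        a = antecedent(don)
        if a is None:
            return True, 180.0
        v1 = m.coords[a] - m.coords[don]
        v2 = m.coords[acc] - m.coords[don]
        cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        ang = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
        return ang >= hbond_angle, ang

    hbonds = []
    for i, j in zip(pi, di):
        if d[i, j] > hbond_dist:
            continue
        ip, jd = int(prot[i]), int(dna[j])
        pairs = []
        if is_hbond_donor(str(m.resname[ip]), str(m.name[ip])) and \
           is_hbond_acceptor(str(m.resname[jd]), str(m.name[jd])):
            pairs.append((ip, jd))
        if is_hbond_donor(str(m.resname[jd]), str(m.name[jd])) and \
           is_hbond_acceptor(str(m.resname[ip]), str(m.name[ip])):
            pairs.append((jd, ip))
        for don, acc in pairs:
            ok, ang = angle_ok(don, acc)
            if ok:
                hbonds.append((don, acc, float(d[i, j]), ang))
    return prot_iface, dna_iface, hbonds
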