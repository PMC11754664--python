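"""Numeric solvent-accessible surface area (Shrake-Rupley).

Each atom is expanded by the probe radius (default 1.4 A, water) and sampled
with a deterministic Fibonacci sphere of >= 960 points; points inside any
neighbouring expanded sphere are occluded.  Per-residue relative
accessibility divides the residue SASA by its Gly-X-Gly maximum reference
area, the convention used to call residues surface-exposed (> 50%) when
selecting docking restraints.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial import cKDTree

from .chemistry import DEFAULT_RADIUS, GXG_MAX_SASA, VDW_RADII
from .structure import MolecularModel

__all__ = ["fibonacci_sphere", "atom_sasa", "sasa", "relative_sasa"]


def fibonacci_sphere(n: int = 960) -> np.ndarray:
    """Deterministic quasi-uniform unit sphere sampling (n points)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0**0.5) * k
    return np.column_stack([
        np.cos(theta) * np.sin(phi),
        np.sin(theta) * np.sin(phi),
        np.cos(phi),
    ])


def _radii(elements) -> np.ndarray:
    out = np.empty(len(elements))
    for i, e in enumerate(elements):
        e = str(e).upper()
        if e not in VDW_RADII:
            warnings.warn(f"unknown element {e!r}: default vdW radius used")
        out[i] = VDW_RADII.get(e, DEFAULT_RADIUS)
    return out


def atom_sasa(coords: np.ndarray, elements, probe: float = 1.4,
              n_points: int = 960) -> np.ndarray:
    """Per-atom solvent-accessible area (A^2)."""
    xyz = np.asarray(coords, float)
    radii = _radii(elements) + probe
    sphere = fibonacci_sphere(n_points)
    tree = cKDTree(xyz)
    rmax = radii.max()
    areas = np.zeros(len(xyz))
    for i in range(len(xyz)):
        pts = xyz[i] + radii[i] * sphere
        neighbours = [j for j in tree.query_ball_point(xyz[i], radii[i] + rmax)
                      if j != i]
        exposed = np.ones(n_points, bool)
        for j in neighbours:
            exposed &= np.linalg.norm(pts - xyz[j], axis=1) >= radii[j]
            if not exposed.any():
                break
        areas[i] = 4.0 * np.pi * radii[i]**2 * exposed.sum() / n_points
    return areas


def sasa(model: MolecularModel, probe: float = 1.4, n_points: int = 960) -> np.ndarray:
    """Per-atom SASA of a molecular model (all chains together)."""
    return atom_sasa(model.coords, model.element, probe, n_points)


def relative_sasa(model: MolecularModel, probe: float = 1.4,
                  n_points: int = 960) -> dict[int, float]:
    """Per-residue relative accessibility of the protein chains (0-1 scale).

    Residue SASA is summed over the residue's atoms and divided by the
    Gly-X-Gly reference area for the residue type; values can slightly
    exceed 1 for highly exposed termini.
    """
    areas = sasa(model, probe, n_points)
    out: dict[int, float] = {}
    for ch, rn, rname, atoms in model.residues("protein"):
        ref = GXG_MAX_SASA.get(rname)
        if ref is None:
            continue
        out[int(rn)] = float(areas[atoms].sum() / ref)
    return out
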