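"""Structural metrics: solvent-accessible surface area (SASA), buried
interface area, rigid transforms, and least-squares superposition RMSD.

SASA uses the Shrake–Rupley method with a deterministic Fibonacci sphere
lattice (no randomness: results are exactly reproducible for a fixed point
count). Superposition is the Kabsch least-squares rigid fit with reflections
excluded. Hydrogens are normally absent from the models handled here; radii
come from a standard van der Waals set (Bondi).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "StructureModel",
    "RigidTransform",
    "VDW_RADII",
    "sasa",
    "buried_surface_area",
    "apply_transform",
    "superpose_rmsd",
]

#: Van der Waals radii (Å), Bondi set; fallback 1.70 Å for unlisted elements.
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "SE": 1.90, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
}
DEFAULT_RADIUS = 1.70


def vdw_radius(element: str) -> float:
    return VDW_RADII.get(element.strip().upper(), DEFAULT_RADIUS)


@dataclass
class StructureModel:
    """Flat atom-array model: parallel arrays over atoms.

    chain/resnum/resname/atomname/element per atom; coords (N, 3) in Å;
    radii (N,) in Å (van der Waals).
    """

    chain: np.ndarray
    resnum: np.ndarray
    resname: np.ndarray
    atomname: np.ndarray
    element: np.ndarray
    coords: np.ndarray
    radii: np.ndarray
    title: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        for name in ("chain", "resnum", "resname", "atomname", "element"):
            setattr(self, name, np.asarray(getattr(self, name)))
        n = self.coords.shape[0]
        if self.coords.shape != (n, 3):
            raise ValueError("coords must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if self.radii.shape != (n,) or np.any(self.radii <= 0):
            raise ValueError("radii must be positive, one per atom")
        for name in ("chain", "resnum", "resname", "atomname", "element"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"{name} must have one entry per atom")

    def __len__(self) -> int:
        return self.coords.shape[0]

    @classmethod
    def from_atoms(cls, atoms, title: str = "") -> "StructureModel":
        """Build from an iterable of (chain, resnum, resname, atomname, element, x, y, z)."""
        rows = list(atoms)
        if not rows:
            raise ValueError("no atoms")
        chain, resnum, resname, atomname, element = zip(
            *[(a[0], a[1], a[2], a[3], a[4]) for a in rows])
        coords = np.array([[a[5], a[6], a[7]] for a in rows], dtype=float)
        radii = np.array([vdw_radius(e) for e in element])
        return cls(np.array(chain), np.array(resnum, dtype=int), np.array(resname),
                   np.array(atomname), np.array(element), coords, radii, title=title)

    def concat(self, other: "StructureModel") -> "StructureModel":
        return StructureModel(
            np.concatenate([self.chain, other.chain]),
            np.concatenate([self.resnum, other.resnum]),
            np.concatenate([self.resname, other.resname]),
            np.concatenate([self.atomname, other.atomname]),
            np.concatenate([self.element, other.element]),
            np.vstack([self.coords, other.coords]),
            np.concatenate([self.radii, other.radii]),
            title=f"{self.title}+{other.title}",
        )

    def select(self, mask: np.ndarray) -> "StructureModel":
        return StructureModel(
            self.chain[mask], self.resnum[mask], self.resname[mask],
            self.atomname[mask], self.element[mask],
            self.coords[mask], self.radii[mask], title=self.title)

    def ca_coords(self, chain: str | None = None) -> dict[int, np.ndarray]:
        """Map residue number -> Cα coordinate (optionally restricted to one chain)."""
        mask = self.atomname == "CA"
        if chain is not None:
            mask &= self.chain == chain
        return {int(r): c for r, c in zip(self.resnum[mask], self.coords[mask])}


@dataclass
class RigidTransform:
    """Proper rigid motion x -> R x + t (rotation R orthonormal, det +1)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation length 3")
        err = np.abs(self.rotation @ self.rotation.T - np.eye(3)).max()
        if err > 1e-8:
            raise ValueError(f"rotation is not orthonormal (max deviation {err:.2e})")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation has det -1 (reflection not allowed)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere lattice (golden-spiral)."""
    i = np.arange(n, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0))  # golden angle
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    theta = phi * i
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def sasa(model: StructureModel, probe: float = 1.4, n_points: int = 960):
    """Shrake–Rupley SASA on a deterministic Fibonacci lattice.

    Returns (per_atom, total) in Å². For each atom, test points are placed
    on its solvent-expanded sphere (radius + probe); the accessible fraction
    is the share of points outside every neighbor's expanded sphere.
    """
    if len(model) == 0:
        raise ValueError("empty model")
    pts = fibonacci_sphere(n_points)
    expanded = model.radii + probe
    tree = cKDTree(model.coords)
    rmax = expanded.max()
    per_atom = np.zeros(len(model))
    for i in range(len(model)):
        ri = expanded[i]
        test = model.coords[i] + ri * pts
        free = np.ones(n_points, dtype=bool)
        buried_duplicate = False
        for j in tree.query_ball_point(model.coords[i], ri + rmax):
            if j == i:
                continue
            dc = np.linalg.norm(model.coords[j] - model.coords[i])
            if dc < 1e-9 and expanded[j] >= ri:
                # exactly coincident sphere: count the surface once, on the
                # earlier atom (the later duplicate is fully buried)
                if j < i or expanded[j] > ri:
                    buried_duplicate = True
                    break
                continue
            d2 = np.sum((test - model.coords[j]) ** 2, axis=1)
            free &= d2 > expanded[j] ** 2 * (1.0 + 1e-12)
        if buried_duplicate:
            continue
        per_atom[i] = free.mean() * 4.0 * math.pi * ri * ri
    return per_atom, float(per_atom.sum())


def buried_surface_area(a: StructureModel, b: StructureModel,
                        probe: float = 1.4, n_points: int = 960) -> dict:
    """SASA buried on complex formation.

    delta_total = SASA(a) + SASA(b) - SASA(a ∪ b); delta_half is the
    per-interface half, the other common reporting convention. Both are
    returned along with the SASA parameters used.
    """
    _, sa = sasa(a, probe, n_points)
    _, sb = sasa(b, probe, n_points)
    _, sab = sasa(a.concat(b), probe, n_points)
    delta = sa + sb - sab
    return {
        "delta_total": delta,
        "delta_half": delta / 2.0,
        "sasa_a": sa,
        "sasa_b": sb,
        "sasa_complex": sab,
        "probe": probe,
        "n_points": n_points,
    }


def apply_transform(model: StructureModel, t: RigidTransform) -> StructureModel:
    """Return a copy of the model with coordinates mapped x -> R x + t."""
    out = StructureModel(model.chain.copy(), model.resnum.copy(), model.resname.copy(),
                         model.atomname.copy(), model.element.copy(),
                         t.apply(model.coords), model.radii.copy(),
                         title=model.title, meta=dict(model.meta))
    return out


def _match_atoms(a: StructureModel, b: StructureModel, offset: int,
                 atom_selection) -> tuple[np.ndarray, np.ndarray]:
    """Pair atoms by (residue number, atom name); b residues are shifted by
    ``offset`` (a_resnum = b_resnum + offset) before matching."""
    def keyed(m: StructureModel, shift: int):
        out = {}
        for i in range(len(m)):
            name = str(m.atomname[i])
            if atom_selection is not None and name not in atom_selection:
                continue
            out.setdefault((int(m.resnum[i]) + shift, name), i)
        return out

    ka = keyed(a, 0)
    kb = keyed(b, offset)
    common = sorted(set(ka) & set(kb))
    ia = np.array([ka[k] for k in common], dtype=int)
    ib = np.array([kb[k] for k in common], dtype=int)
    return ia, ib


def superpose_rmsd(a: StructureModel, b: StructureModel,
                   atom_selection=None, offset: int = 0) -> dict:
    """Kabsch least-squares superposition of b onto a.

    Atoms are matched by (residue number, atom name) after shifting b's
    numbering by ``offset``; ``atom_selection`` restricts to a set of atom
    names (e.g. {"CA"}). Returns {"rmsd", "transform", "n_atoms"}; the
    transform maps b coordinates onto a. Reflections are excluded.
    """
    ia, ib = _match_atoms(a, b, offset, atom_selection)
    if ia.size < 3:
        raise ValueError(f"need >= 3 matched atoms, found {ia.size}")
    xa = a.coords[ia]
    xb = b.coords[ib]
    ca_, cb_ = xa.mean(axis=0), xb.mean(axis=0)
    pa, pb = xa - ca_, xb - cb_
    # collinearity check: rank of the centered coordinates
    if np.linalg.matrix_rank(pa, tol=1e-8) < 2 or np.linalg.matrix_rank(pb, tol=1e-8) < 2:
        raise ValueError("matched atoms are collinear; superposition is degenerate")
    h = pb.T @ pa
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = ca_ - rot @ cb_
    diff = pa - pb @ rot.T
    rmsd = float(np.sqrt(np.mean(np.sum(diff ** 2, axis=1))))
    return {"rmsd": rmsd,
            "transform": RigidTransform(rot, trans),
            "n_atoms": int(ia.size)}
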