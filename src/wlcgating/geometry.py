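"""Superposition, fourfold-axis alignment and linker distance geometry.

The analysis frame puts the tetramer's pore (C4) axis on z, selectivity
filter up.  In that frame each linker's end-to-end vector (ring anchor
Ser115 → pore anchor Ile99) splits into a vertical component ``L_z``
(along the pore axis) and a radial component ``L_xy`` (the outward pull
on the bundle-crossing gate), with L² = L_z² + L_xy².
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "AlignmentError",
    "AnchorSet",
    "LinkerGeometry",
    "RigidTransform",
    "SpreadMetrics",
    "SymmetryError",
    "align_pore_axis_to_z",
    "kabsch",
    "linker_lengths",
    "spread_metrics",
    "superpose_on_pore",
    "transform_structure",
]

DEFAULT_SELECTION = (20, 83)


class AlignmentError(ValueError):
    """Too few common atoms, or otherwise impossible superposition."""


class SymmetryError(ValueError):
    """The structure does not look fourfold symmetric."""


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x ↦ R·x + t (Å)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if R.shape != (3, 3) or t.shape != (3,):
            raise AlignmentError("rotation must be 3x3 and translation length 3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise AlignmentError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise AlignmentError("rotation determinant is not +1")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equal to applying ``other`` first, then ``self``."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)


@dataclass
class AnchorSet:
    """Per-subunit linker endpoint Cα coordinates for one structure (Å)."""

    structure_id: str
    chain_ids: list[str]
    pore: np.ndarray  # (n, 3) pore anchors (Ile99-equivalent)
    ring: np.ndarray  # (n, 3) ring anchors (Ser115-equivalent)
    aligned: bool = False

    def __post_init__(self) -> None:
        self.pore = np.atleast_2d(np.asarray(self.pore, dtype=float))
        self.ring = np.atleast_2d(np.asarray(self.ring, dtype=float))
        if self.pore.shape != self.ring.shape or self.pore.shape[1] != 3:
            raise ValueError("pore and ring must be matching (n, 3) arrays")
        if len(self.chain_ids) != len(self.pore):
            raise ValueError("one chain id per anchor pair required")

    def __len__(self) -> int:
        return len(self.chain_ids)

    def subset(self, chain_ids: list[str]) -> "AnchorSet":
        idx = [self.chain_ids.index(c) for c in chain_ids]
        return AnchorSet(self.structure_id, [self.chain_ids[i] for i in idx],
                         self.pore[idx], self.ring[idx], self.aligned)


@dataclass(frozen=True)
class LinkerGeometry:
    """End-to-end length of one linker and its axis-frame components (Å)."""

    chain_id: str
    L: float
    L_z: float | None = None
    L_xy: float | None = None
    structure_id: str = ""


@dataclass(frozen=True)
class SpreadMetrics:
    """Ring spread of four equivalent Cα: adjacent distance and radius (Å)."""

    interresidue_distance: float
    radius: float | None


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of paired point sets.

    Returns the proper rotation+translation mapping ``mobile`` onto
    ``reference`` and the post-fit RMSD.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[0] < 3:
        raise AlignmentError("need >= 3 paired points of equal shape")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = cq - R @ cp
    rt = RigidTransform(R, t)
    rmsd = float(np.sqrt(np.mean(np.sum((rt.apply(P) - Q) ** 2, axis=1))))
    return rt, rmsd


def transform_structure(structure, rt: RigidTransform):
    """Copy of a StructureModel with ``rt`` applied to every Cα."""
    new_chains = [replace(c, ca_coords={r: rt.apply(xyz)
                                        for r, xyz in c.ca_coords.items()})
                  for c in structure.chains]
    return replace(structure, chains=new_chains)


def _selection_coords(structure, selection, common: set[int] | None = None):
    """Stacked per-chain Cα of the analysis chains over a residue interval."""
    lo, hi = selection
    chains = structure.analysis_chains()
    resolved = [set(r for r in c.ca_coords if lo <= r <= hi) for c in chains]
    shared = set.intersection(*resolved)
    if common is not None:
        shared &= common
    residues = sorted(shared)
    coords = [np.array([c.ca_coords[r] for r in residues]) for c in chains]
    return residues, coords


def superpose_on_pore(mobile, reference, selection: tuple[int, int] = DEFAULT_SELECTION):
    """Superpose ``mobile`` onto ``reference`` over pore-domain Cα.

    The fit uses the Cα of all analysis chains over ``selection``
    (default: transmembrane helix 1 through the glycine hinge, residues
    20–83), restricted to residues resolved in both structures.

    Returns ``(transformed_copy, rmsd, transform)``.
    """
    res_m, coords_m = _selection_coords(mobile, selection)
    res_r, coords_r = _selection_coords(reference, selection)
    common = sorted(set(res_m) & set(res_r))
    if len(common) * min(len(coords_m), 1) < 1:
        raise AlignmentError("no common residues in selection")
    idx_m = [res_m.index(r) for r in common]
    idx_r = [res_r.index(r) for r in common]
    P = np.vstack([c[idx_m] for c in coords_m])
    Q = np.vstack([c[idx_r] for c in coords_r])
    if len(P) < 3:
        raise AlignmentError(f"only {len(P)} common atoms in selection {selection}")
    rt, rmsd = kabsch(P, Q)
    moved = transform_structure(mobile, rt)
    moved.aligned = reference.aligned
    return moved, rmsd, rt


def _axis_from_permutation(coords: list[np.ndarray], centroid: np.ndarray,
                           max_rmsd: float) -> np.ndarray:
    """C4 axis as the rotation axis of the chain-permutation superposition."""
    P = np.vstack(coords[1:] + coords[:1]) - centroid
    Q = np.vstack(coords) - centroid
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    rmsd = float(np.sqrt(np.mean(np.sum((P @ R.T - Q) ** 2, axis=1))))
    if rmsd > max_rmsd:
        raise SymmetryError(
            f"chain-permutation fit RMSD {rmsd:.2f} Å exceeds {max_rmsd} Å: "
            "structure does not look fourfold symmetric")
    angle = np.arccos(np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0))
    if not np.degrees(angle) > 45.0:
        raise SymmetryError("permutation rotation is not a quarter turn")
    w, v = np.linalg.eig(R)
    axis = np.real(v[:, np.argmin(np.abs(w - 1.0))])
    return axis / np.linalg.norm(axis)


def _axis_from_principal(coords: list[np.ndarray], centroid: np.ndarray) -> np.ndarray:
    """C4 axis as the gyration-tensor eigenvector with the odd eigenvalue.

    For an axially symmetric point set two eigenvalues coincide (in-plane)
    and the third, most separated from the others, belongs to the axis.
    """
    X = np.vstack(coords) - centroid
    w, v = np.linalg.eigh(X.T @ X / len(X))
    sep = [abs(w[i] - w[(i + 1) % 3]) + abs(w[i] - w[(i + 2) % 3]) for i in range(3)]
    return v[:, int(np.argmax(sep))]


def _rotation_to_z(axis: np.ndarray) -> np.ndarray:
    """Minimal proper rotation taking ``axis`` to +z."""
    a = axis / np.linalg.norm(axis)
    z = np.array([0.0, 0.0, 1.0])
    vcross = np.cross(a, z)
    c = float(a @ z)
    if np.linalg.norm(vcross) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    K = np.array([[0, -vcross[2], vcross[1]],
                  [vcross[2], 0, -vcross[0]],
                  [-vcross[1], vcross[0], 0]])
    return np.eye(3) + K + K @ K / (1.0 + c)


def align_pore_axis_to_z(structure, selection: tuple[int, int] = DEFAULT_SELECTION,
                         method: str = "permutation", max_fit_rmsd: float = 3.0):
    """Rotate/translate a tetramer so its pore C4 axis coincides with z.

    The axis is found either from the cyclic chain-permutation best-fit
    rotation (default) or from the principal-axis method; the structure
    centroid over ``selection`` fixes a point on the axis and is moved to
    the origin in x, y.  The z-sign is chosen so that the selectivity
    filter end (the ``selection`` centroid) lies above the linker anchors.
    """
    chains = structure.analysis_chains()
    if len(chains) != 4:
        raise SymmetryError(f"expected 4 analysis chains, got {len(chains)}")
    _, coords = _selection_coords(structure, selection)
    if min(len(c) for c in coords) < 3:
        raise AlignmentError("selection resolves fewer than 3 residues per chain")
    centroid = np.vstack(coords).mean(axis=0)
    if method == "permutation":
        axis = _axis_from_permutation(coords, centroid, max_fit_rmsd)
    elif method == "principal":
        axis = _axis_from_principal(coords, centroid)
    else:
        raise ValueError(f"unknown axis method {method!r}")
    R = _rotation_to_z(axis)
    rt = RigidTransform(R, -R @ centroid)
    moved = transform_structure(structure, rt)

    # z-sign: selection (selectivity-filter side) above the anchor residues.
    anchor_z, sel_z = [], []
    lo, hi = selection
    for c in moved.analysis_chains():
        for r, xyz in c.ca_coords.items():
            (sel_z if lo <= r <= hi else anchor_z).append(xyz[2])
    if anchor_z and np.mean(sel_z) < np.mean(anchor_z):
        flip = RigidTransform(np.diag([1.0, -1.0, -1.0]), np.zeros(3))
        moved = transform_structure(moved, flip)
    moved.aligned = True
    return moved


def linker_lengths(anchors: AnchorSet) -> list[LinkerGeometry]:
    """Per-subunit linker end-to-end lengths and (if aligned) components.

    L is the Euclidean ring→pore anchor distance; in the aligned frame
    L_z = |Δz| and L_xy = √(Δx² + Δy²), so L² = L_z² + L_xy².
    """
    delta = anchors.ring - anchors.pore
    L = np.linalg.norm(delta, axis=1)
    out = []
    for i, cid in enumerate(anchors.chain_ids):
        if anchors.aligned:
            lz = abs(delta[i, 2])
            lxy = float(np.hypot(delta[i, 0], delta[i, 1]))
            out.append(LinkerGeometry(cid, float(L[i]), lz, lxy,
                                      anchors.structure_id))
        else:
            out.append(LinkerGeometry(cid, float(L[i]),
                                      structure_id=anchors.structure_id))
    return out


def spread_metrics(points: np.ndarray, aligned: bool = True) -> SpreadMetrics:
    """Spread of four symmetry-equivalent Cα around the pore axis.

    ``interresidue_distance`` is the mean over the four adjacent-neighbor
    pairs (cyclic order by azimuth about z); ``radius`` the mean distance
    from the z-axis (requires the aligned frame).  For exact C4 geometry
    interresidue_distance = radius·√2.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape != (4, 3):
        raise ValueError("spread metrics are defined for exactly 4 points")
    order = np.argsort(np.arctan2(pts[:, 1], pts[:, 0]))
    ordered = pts[order]
    adjacent = np.linalg.norm(ordered - np.roll(ordered, -1, axis=0), axis=1)
    radius = float(np.mean(np.hypot(pts[:, 0], pts[:, 1]))) if aligned else None
    return SpreadMetrics(float(np.mean(adjacent)), radius)
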