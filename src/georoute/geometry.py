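"""Exact geometric measurements on coordinate sets.

Distances, angles, dihedrals, backbone torsions, optimal-superposition RMSD
and the six Boresch degrees of freedom (r, thetaA, thetaB, phiA, phiB, phiC)
of a "ligand" relative to a "receptor".

Conventions
-----------
* Coordinates are in angstrom, all angular interfaces in degrees.  Internally
  everything is computed in radians.
* Dihedral sign follows the IUPAC convention: looking along the p2->p3 axis,
  a clockwise rotation of the far bond relative to the near bond is positive.
  Values are wrapped to (-180, 180].
* Degenerate geometries (coincident points, collinear dihedral frames) raise
  :class:`DegenerateGeometryError` instead of returning NaN, because a silent
  NaN would poison downstream free-energy assembly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "DegenerateGeometryError",
    "Coordinates",
    "AtomRef",
    "AnchorSet",
    "BoreschDOF",
    "measure_angle",
    "measure_dihedral",
    "measure_boresch",
    "backbone_torsions",
    "optimal_rmsd",
    "kabsch_rotation",
    "wrap_deg",
]

_EPS = 1e-12


class DegenerateGeometryError(ValueError):
    """Raised when an angle or dihedral is geometrically undefined."""


def wrap_deg(x):
    """Wrap an angle in degrees to the interval (-180, 180]."""
    w = np.asarray(x, dtype=float)
    w = -((-w + 180.0) % 360.0 - 180.0)
    return float(w) if np.isscalar(x) or w.ndim == 0 else w


@dataclass(frozen=True)
class AtomRef:
    """Reference to one atom: (chain id, residue index, atom name)."""

    chain: str
    residue: int
    name: str

    def as_tuple(self):
        return (self.chain, self.residue, self.name)


class Coordinates:
    """An ordered set of atoms with chain/residue/name identity.

    Parameters
    ----------
    chains, residues, names : per-atom identity arrays
    xyz : (n, 3) float array of positions in angstrom

    The (chain, residue, name) triple must be unique per atom and all
    positions finite.
    """

    def __init__(self, chains: Sequence[str], residues: Sequence[int],
                 names: Sequence[str], xyz: np.ndarray):
        self.chains = list(map(str, chains))
        self.residues = [int(r) for r in residues]
        self.names = list(map(str, names))
        self.xyz = np.array(xyz, dtype=float).reshape(len(self.chains), 3)
        if self.xyz.shape[0] == 0:
            raise ValueError("Coordinates must contain at least one atom")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("non-finite atom positions")
        self._index: dict[tuple, int] = {}
        for i, key in enumerate(zip(self.chains, self.residues, self.names)):
            if key in self._index:
                raise ValueError(f"duplicate atom key {key}")
            self._index[key] = i

    def __len__(self) -> int:
        return self.xyz.shape[0]

    def index_of(self, ref: AtomRef | tuple) -> int:
        key = ref.as_tuple() if isinstance(ref, AtomRef) else tuple(ref)
        key = (str(key[0]), int(key[1]), str(key[2]))
        try:
            return self._index[key]
        except KeyError:
            raise KeyError(f"atom {key} not found") from None

    def position(self, ref: AtomRef | tuple) -> np.ndarray:
        return self.xyz[self.index_of(ref)]

    def chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chains:
            seen.setdefault(c)
        return list(seen)

    def select(self, chain: str | None = None, names: Iterable[str] | None = None,
               residues: Iterable[int] | None = None) -> np.ndarray:
        """Return atom indices matching the given identity filters."""
        nameset = set(names) if names is not None else None
        resset = set(int(r) for r in residues) if residues is not None else None
        idx = [i for i in range(len(self))
               if (chain is None or self.chains[i] == chain)
               and (nameset is None or self.names[i] in nameset)
               and (resset is None or self.residues[i] in resset)]
        return np.asarray(idx, dtype=int)

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "Coordinates":
        """Return a rigidly moved copy: x -> R x + t."""
        xyz = self.xyz
        if rotation is not None:
            xyz = xyz @ np.asarray(rotation, dtype=float).T
        if translation is not None:
            xyz = xyz + np.asarray(translation, dtype=float)
        return Coordinates(self.chains, self.residues, self.names, xyz)

    def subset(self, indices: Sequence[int]) -> "Coordinates":
        idx = np.asarray(indices, dtype=int)
        return Coordinates([self.chains[i] for i in idx],
                           [self.residues[i] for i in idx],
                           [self.names[i] for i in idx],
                           self.xyz[idx])


@dataclass(frozen=True)
class AnchorSet:
    """The six Boresch anchor atoms: c, b, a on the receptor; A, B, C on the ligand."""

    c: AtomRef
    b: AtomRef
    a: AtomRef
    A: AtomRef
    B: AtomRef
    C: AtomRef

    def __post_init__(self):
        refs = [self.c, self.b, self.a, self.A, self.B, self.C]
        if len({r.as_tuple() for r in refs}) != 6:
            raise ValueError("anchor atoms must be six distinct atoms")
        if {self.c.chain, self.b.chain, self.a.chain} & {self.A.chain, self.B.chain, self.C.chain}:
            raise ValueError("receptor anchors and ligand anchors must be on different chains")

    def receptor_refs(self):
        return (self.c, self.b, self.a)

    def ligand_refs(self):
        return (self.A, self.B, self.C)

    def to_dict(self) -> dict:
        """Serialize as chain/residue/atom triples."""
        return {name: list(getattr(self, name).as_tuple())
                for name in ("c", "b", "a", "A", "B", "C")}

    @classmethod
    def from_dict(cls, data: dict) -> "AnchorSet":
        return cls(**{name: AtomRef(str(v[0]), int(v[1]), str(v[2]))
                      for name, v in data.items()})


@dataclass(frozen=True)
class BoreschDOF:
    """The six external degrees of freedom of a ligand relative to a receptor.

    r : distance a-A (angstrom); thetaA: angle b-a-A; thetaB: angle a-A-B;
    phiA: dihedral c-b-a-A; phiB: dihedral b-a-A-B; phiC: dihedral a-A-B-C
    (all angles in degrees, dihedrals wrapped to (-180, 180]).
    """

    r: float
    thetaA: float
    thetaB: float
    phiA: float
    phiB: float
    phiC: float

    def __post_init__(self):
        if not self.r > 0:
            raise ValueError("Boresch distance r must be > 0")
        for name in ("thetaA", "thetaB"):
            v = getattr(self, name)
            if not (0.0 <= v <= 180.0):
                raise ValueError(f"{name}={v} outside [0, 180]")
        for name in ("phiA", "phiB", "phiC"):
            v = getattr(self, name)
            if not (-180.0 < v <= 180.0):
                raise ValueError(f"{name}={v} outside (-180, 180]")

    def as_dict(self) -> dict[str, float]:
        return {"r": self.r, "thetaA": self.thetaA, "thetaB": self.thetaB,
                "phiA": self.phiA, "phiB": self.phiB, "phiC": self.phiC}


def _as_vec(p) -> np.ndarray:
    v = np.asarray(p, dtype=float).reshape(3)
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite position")
    return v


def measure_distance(p1, p2) -> float:
    d = float(np.linalg.norm(_as_vec(p1) - _as_vec(p2)))
    return d


def measure_angle(p1, p2, p3) -> float:
    """Angle p1-p2-p3 in degrees, in [0, 180]."""
    v1 = _as_vec(p1) - _as_vec(p2)
    v2 = _as_vec(p3) - _as_vec(p2)
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < _EPS or n2 < _EPS:
        raise DegenerateGeometryError("coincident points in angle measurement")
    # atan2 form is numerically robust near 0 and 180 degrees
    cross = np.linalg.norm(np.cross(v1, v2))
    dot = float(np.dot(v1, v2))
    return float(np.degrees(np.arctan2(cross, dot)))


def measure_dihedral(p1, p2, p3, p4) -> float:
    """Dihedral p1-p2-p3-p4 in degrees in (-180, 180], IUPAC sign convention."""
    b1 = _as_vec(p2) - _as_vec(p1)
    b2 = _as_vec(p3) - _as_vec(p2)
    b3 = _as_vec(p4) - _as_vec(p3)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if np.linalg.norm(n1) < _EPS or np.linalg.norm(n2) < _EPS or nb2 < _EPS:
        raise DegenerateGeometryError("collinear points in dihedral measurement")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2) / nb2)
    ang = float(np.degrees(np.arctan2(y, x)))
    return wrap_deg(ang)


def measure_boresch(coords: Coordinates, anchors: AnchorSet) -> BoreschDOF:
    """Evaluate all six Boresch degrees of freedom for the given anchor set."""
    pc, pb, pa = (coords.position(r) for r in anchors.receptor_refs())
    pA, pB, pC = (coords.position(r) for r in anchors.ligand_refs())
    return BoreschDOF(
        r=measure_distance(pa, pA),
        thetaA=measure_angle(pb, pa, pA),
        thetaB=measure_angle(pa, pA, pB),
        phiA=measure_dihedral(pc, pb, pa, pA),
        phiB=measure_dihedral(pb, pa, pA, pB),
        phiC=measure_dihedral(pa, pA, pB, pC),
    )


@dataclass(frozen=True)
class ResidueTorsions:
    residue: int
    phi: float | None
    psi: float | None


def backbone_torsions(coords: Coordinates, chain: str) -> list[ResidueTorsions]:
    """Backbone phi/psi torsions for consecutive residues of one chain.

    phi(i) = C(i-1)-N(i)-CA(i)-C(i); psi(i) = N(i)-CA(i)-C(i)-N(i+1).
    phi is None for the first residue and psi None for the last; residues
    with missing backbone atoms yield None for the affected torsions rather
    than failing.
    """
    res_ids = sorted({coords.residues[i] for i in range(len(coords))
                      if coords.chains[i] == chain})
    if not res_ids:
        raise KeyError(f"chain {chain!r} not found")

    def atom(res, name):
        try:
            return coords.position((chain, res, name))
        except KeyError:
            return None

    out: list[ResidueTorsions] = []
    for k, res in enumerate(res_ids):
        n, ca, c = atom(res, "N"), atom(res, "CA"), atom(res, "C")
        phi = psi = None
        if k > 0:
            c_prev = atom(res_ids[k - 1], "C")
            if all(p is not None for p in (c_prev, n, ca, c)):
                phi = measure_dihedral(c_prev, n, ca, c)
        if k < len(res_ids) - 1:
            n_next = atom(res_ids[k + 1], "N")
            if all(p is not None for p in (n, ca, c, n_next)):
                psi = measure_dihedral(n, ca, c, n_next)
        out.append(ResidueTorsions(residue=res, phi=phi, psi=psi))
    return out


def kabsch_rotation(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal proper rotation superposing centred `mobile` onto centred `reference`.

    Returns (R, t_mobile, t_reference): the rotation and the two centroids.
    Reflections are explicitly excluded (determinant forced to +1).
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3 or P.shape[0] < 3:
        raise ValueError("selections must be matched (n, 3) arrays with n >= 3")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return R, cp, cq


def optimal_rmsd(mobile: Coordinates | np.ndarray, reference: Coordinates | np.ndarray,
                 selection: Sequence[int] | None = None,
                 reference_selection: Sequence[int] | None = None) -> float:
    """RMSD in angstrom after optimal rigid (rotation + translation) superposition.

    `selection`/`reference_selection` are matched-order atom index arrays; by
    default all atoms are used (counts must agree).
    """
    P = mobile.xyz if isinstance(mobile, Coordinates) else np.asarray(mobile, float)
    Q = reference.xyz if isinstance(reference, Coordinates) else np.asarray(reference, float)
    if selection is not None:
        P = P[np.asarray(selection, dtype=int)]
    if reference_selection is not None:
        Q = Q[np.asarray(reference_selection, dtype=int)]
    elif selection is not None and Q.shape[0] != P.shape[0]:
        Q = Q[np.asarray(selection, dtype=int)]
    if P.shape != Q.shape:
        raise ValueError("mismatched selections for RMSD")
    R, cp, cq = kabsch_rotation(P, Q)
    diff = (P - cp) @ R.T - (Q - cq)
    return float(np.sqrt((diff ** 2).sum() / P.shape[0]))
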