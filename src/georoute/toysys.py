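"""Desk-scale model systems for validating the geometrical route.

Two families of systems are provided:

* :class:`ParticleSystem` — point particles with masses in an analytic
  potential, propagated by BAOAB Langevin dynamics (see :mod:`.metad`).
  Used for the one-dimensional well-tempered metadynamics validation.

* :class:`RigidBodySystem` — rigid bead "helices" (positions parameterised
  by a centre and an orientation matrix, no constraint solver) interacting
  through smooth pair potentials: a short-range Gaussian repulsion between
  all inter-body bead pairs plus Gaussian attraction wells between matched
  bead pairs.  Sampled by seeded Metropolis Monte Carlo rigid moves.  Each
  body's first bead sits at its local origin, so the centre-centre distance
  doubles as the separation collective variable.

The hot paths (pair energies, angles, dihedrals) are scalar-Python
implementations; the test suite cross-checks them against the vectorised
:mod:`georoute.geometry` routines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "ParticleSystem",
    "DoubleWellPotential",
    "HarmonicPotential",
    "RigidBody",
    "PairTerm",
    "RigidBodySystem",
    "make_toy_dimer",
    "make_toy_trimer",
    "scalar_angle_deg",
    "scalar_dihedral_deg",
    "rotation_about_axis",
    "mat_mul",
    "mat_vec",
]

# ---------------------------------------------------------------------------
# particle systems (Langevin dynamics)


class DoubleWellPotential:
    """V(x) = barrier * ((x/a)^2 - 1)^2 acting on the x coordinate.

    Minima at +/-a, barrier height `barrier` (kcal/mol) at x = 0.
    """

    def __init__(self, barrier: float = 4.0, a: float = 1.2):
        self.barrier = barrier
        self.a = a

    def energy(self, x: np.ndarray) -> float:
        s = x[0, 0] / self.a
        return self.barrier * (s * s - 1.0) ** 2

    def forces(self, x: np.ndarray) -> np.ndarray:
        f = np.zeros_like(x)
        s = x[0, 0] / self.a
        f[0, 0] = -4.0 * self.barrier * s * (s * s - 1.0) / self.a
        return f

    def analytic(self, s) -> np.ndarray:
        s = np.asarray(s, dtype=float) / self.a
        return self.barrier * (s * s - 1.0) ** 2


class HarmonicPotential:
    """V(x) = 0.5 * k * (x - x0)^2 on the x coordinate."""

    def __init__(self, k: float = 2.0, x0: float = 0.0):
        self.k = k
        self.x0 = x0

    def energy(self, x: np.ndarray) -> float:
        d = x[0, 0] - self.x0
        return 0.5 * self.k * d * d

    def forces(self, x: np.ndarray) -> np.ndarray:
        f = np.zeros_like(x)
        f[0, 0] = -self.k * (x[0, 0] - self.x0)
        return f

    def analytic(self, s) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        return 0.5 * self.k * (s - self.x0) ** 2


@dataclass
class ParticleSystem:
    """Point particles in an analytic potential.

    masses in amu, positions in angstrom, velocities in angstrom/fs.
    """

    masses: np.ndarray
    positions: np.ndarray
    potential: object
    velocities: np.ndarray | None = None
    temperature: float = 298.15

    def __post_init__(self):
        self.masses = np.asarray(self.masses, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        if np.any(self.masses <= 0):
            raise ValueError("masses must be > 0")
        if self.velocities is None:
            self.velocities = np.zeros_like(self.positions)
        e = self.potential.energy(self.positions)
        if not math.isfinite(e):
            raise ValueError("non-finite energy at initial configuration")


# ---------------------------------------------------------------------------
# scalar geometry (hot path)


def scalar_angle_deg(p1, p2, p3) -> float:
    v1 = (p1[0] - p2[0], p1[1] - p2[1], p1[2] - p2[2])
    v2 = (p3[0] - p2[0], p3[1] - p2[1], p3[2] - p2[2])
    cx = v1[1] * v2[2] - v1[2] * v2[1]
    cy = v1[2] * v2[0] - v1[0] * v2[2]
    cz = v1[0] * v2[1] - v1[1] * v2[0]
    cross = math.sqrt(cx * cx + cy * cy + cz * cz)
    dot = v1[0] * v2[0] + v1[1] * v2[1] + v1[2] * v2[2]
    return math.degrees(math.atan2(cross, dot))


def scalar_dihedral_deg(p1, p2, p3, p4) -> float:
    b1 = (p2[0] - p1[0], p2[1] - p1[1], p2[2] - p1[2])
    b2 = (p3[0] - p2[0], p3[1] - p2[1], p3[2] - p2[2])
    b3 = (p4[0] - p3[0], p4[1] - p3[1], p4[2] - p3[2])
    n1 = (b1[1] * b2[2] - b1[2] * b2[1],
          b1[2] * b2[0] - b1[0] * b2[2],
          b1[0] * b2[1] - b1[1] * b2[0])
    n2 = (b2[1] * b3[2] - b2[2] * b3[1],
          b2[2] * b3[0] - b2[0] * b3[2],
          b2[0] * b3[1] - b2[1] * b3[0])
    nb2 = math.sqrt(b2[0] * b2[0] + b2[1] * b2[1] + b2[2] * b2[2])
    m = (n1[1] * n2[2] - n1[2] * n2[1],
         n1[2] * n2[0] - n1[0] * n2[2],
         n1[0] * n2[1] - n1[1] * n2[0])
    y = (m[0] * b2[0] + m[1] * b2[1] + m[2] * b2[2]) / nb2
    x = n1[0] * n2[0] + n1[1] * n2[1] + n1[2] * n2[2]
    return math.degrees(math.atan2(y, x))


def mat_vec(R, v):
    return (R[0][0] * v[0] + R[0][1] * v[1] + R[0][2] * v[2],
            R[1][0] * v[0] + R[1][1] * v[1] + R[1][2] * v[2],
            R[2][0] * v[0] + R[2][1] * v[1] + R[2][2] * v[2])


def mat_mul(A, B):
    return tuple(tuple(A[i][0] * B[0][j] + A[i][1] * B[1][j] + A[i][2] * B[2][j]
                       for j in range(3)) for i in range(3))


def rotation_about_axis(axis, angle_rad):
    """Rodrigues rotation matrix about a (not necessarily unit) axis."""
    ax, ay, az = axis
    n = math.sqrt(ax * ax + ay * ay + az * az)
    ax, ay, az = ax / n, ay / n, az / n
    c, s = math.cos(angle_rad), math.sin(angle_rad)
    t = 1.0 - c
    return ((c + ax * ax * t, ax * ay * t - az * s, ax * az * t + ay * s),
            (ay * ax * t + az * s, c + ay * ay * t, ay * az * t - ax * s),
            (az * ax * t - ay * s, az * ay * t + ax * s, c + az * az * t))


_IDENTITY = ((1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0))


# ---------------------------------------------------------------------------
# rigid-body systems


@dataclass
class RigidBody:
    """A rigid bead body: world position = center + R @ local_bead."""

    name: str
    local: tuple  # tuple of (x, y, z) bead positions in the body frame
    center: tuple = (0.0, 0.0, 0.0)
    R: tuple = _IDENTITY

    def bead_positions(self) -> list[tuple]:
        c, R = self.center, self.R
        return [(c[0] + R[0][0] * l[0] + R[0][1] * l[1] + R[0][2] * l[2],
                 c[1] + R[1][0] * l[0] + R[1][1] * l[1] + R[1][2] * l[2],
                 c[2] + R[2][0] * l[0] + R[2][1] * l[1] + R[2][2] * l[2])
                for l in self.local]

    def moved(self, center=None, R=None) -> "RigidBody":
        return RigidBody(self.name, self.local,
                         self.center if center is None else center,
                         self.R if R is None else R)


@dataclass(frozen=True)
class PairTerm:
    """Interaction between bead `i` of one body and bead `j` of another.

    u(r) = A * exp(-(r/w_rep)^2) - eps * exp(-(r - r0)^2 / (2 w_att^2))
    """

    body_i: int
    bead_i: int
    body_j: int
    bead_j: int
    A: float = 0.0
    w_rep: float = 1.0
    eps: float = 0.0
    r0: float = 0.0
    w_att: float = 1.0

    def energy(self, r: float) -> float:
        e = 0.0
        if self.A != 0.0:
            x = r / self.w_rep
            e += self.A * math.exp(-x * x)
        if self.eps != 0.0:
            d = (r - self.r0) / self.w_att
            e -= self.eps * math.exp(-0.5 * d * d)
        return e


class RigidBodySystem:
    """Rigid bodies with inter-body pair potentials at a fixed temperature."""

    def __init__(self, bodies: Sequence[RigidBody], pair_terms: Sequence[PairTerm],
                 temperature: float = 298.15):
        self.bodies = list(bodies)
        self.pair_terms = list(pair_terms)
        self.temperature = temperature
        e = self.pair_energy()
        if not math.isfinite(e):
            raise ValueError("non-finite energy at initial configuration")

    def bead_positions(self) -> list[list[tuple]]:
        return [b.bead_positions() for b in self.bodies]

    def bead(self, ref: tuple[int, int]) -> tuple:
        body, i = ref
        return self.bodies[body].bead_positions()[i]

    def pair_energy(self, positions: list[list[tuple]] | None = None) -> float:
        pos = positions if positions is not None else self.bead_positions()
        e = 0.0
        for t in self.pair_terms:
            p = pos[t.body_i][t.bead_i]
            q = pos[t.body_j][t.bead_j]
            dx, dy, dz = p[0] - q[0], p[1] - q[1], p[2] - q[2]
            e += t.energy(math.sqrt(dx * dx + dy * dy + dz * dz))
        return e

    def subsystem(self, body_indices: Sequence[int]) -> "RigidBodySystem":
        """System restricted to the given bodies (pair terms re-indexed)."""
        keep = list(body_indices)
        remap = {old: new for new, old in enumerate(keep)}
        terms = [PairTerm(remap[t.body_i], t.bead_i, remap[t.body_j], t.bead_j,
                          t.A, t.w_rep, t.eps, t.r0, t.w_att)
                 for t in self.pair_terms
                 if t.body_i in remap and t.body_j in remap]
        return RigidBodySystem([self.bodies[i] for i in keep], terms,
                               self.temperature)

    def coordinates(self):
        """Bead positions as a :class:`georoute.geometry.Coordinates`."""
        from .geometry import Coordinates
        chains, residues, names, xyz = [], [], [], []
        for b in self.bodies:
            for i, p in enumerate(b.bead_positions()):
                chains.append(b.name)
                residues.append(i + 1)
                names.append("CA")
                xyz.append(p)
        return Coordinates(chains, residues, names, np.asarray(xyz))


# ---------------------------------------------------------------------------
# toy "helix" fixtures
#
# Each toy helix is a rigid 3-bead body: bead 0 at the local origin (the
# separation anchor), bead 1 displaced along the body axis, bead 2 a side
# bead breaking the axial symmetry (the "interface face" of a real helix).
# Matched-bead attraction wells between bodies produce a well-defined
# docking pose: the centre-centre well sets the separation, the axis-bead
# well the parallel alignment and registry, and the side well the roll and
# approach azimuth.

TOY_LOCAL = ((0.0, 0.0, 0.0), (0.0, 0.0, 1.8), (1.1, 1.1, 0.9))
TOY_EPS = 3.0          # kcal/mol per matched-bead attraction well
TOY_W_ATT = 0.8        # attraction width (A)
TOY_A_REP = 20.0       # repulsion amplitude (kcal/mol)
TOY_W_REP = 1.0        # repulsion width (A)
TOY_CONTACT = 4.0      # centre-centre and axis-bead equilibrium distance (A)


def _toy_pair_terms(body_i: int, body_j: int, well_r0: dict) -> list[PairTerm]:
    """All-pairs repulsion plus matched-bead attraction wells.

    `well_r0` maps (bead, bead) to the well centre distance.
    """
    n = len(TOY_LOCAL)
    terms = []
    for bi in range(n):
        for bj in range(n):
            eps, r0 = 0.0, 0.0
            if (bi, bj) in well_r0:
                eps = TOY_EPS
                r0 = well_r0[(bi, bj)]
            terms.append(PairTerm(body_i, bi, body_j, bj, A=TOY_A_REP,
                                  w_rep=TOY_W_REP, eps=eps, r0=r0,
                                  w_att=TOY_W_ATT))
    return terms


def _pose_well_r0(body_a: RigidBody, body_b: RigidBody) -> dict:
    """Matched-bead well centres measured in the constructed pose."""
    pa, pb = body_a.bead_positions(), body_b.bead_positions()
    return {(k, k): math.dist(pa[k], pb[k]) for k in range(len(TOY_LOCAL))}


def make_toy_dimer(contact: float = TOY_CONTACT,
                   temperature: float = 298.15) -> RigidBodySystem:
    """Two identical rigid toy helices in their bound pose.

    The receptor sits at the origin in the identity orientation; the ligand
    at (contact, 0, 0), rotated by 180 degrees about z so the side beads
    face each other.  The complex is exactly C2-symmetric about the axis
    through the bond midpoint.
    """
    r_lig = rotation_about_axis((0.0, 0.0, 1.0), math.pi)
    receptor = RigidBody("R", TOY_LOCAL)
    ligand = RigidBody("L", TOY_LOCAL, center=(contact, 0.0, 0.0), R=r_lig)
    return RigidBodySystem([receptor, ligand],
                           _toy_pair_terms(0, 1, _pose_well_r0(receptor, ligand)),
                           temperature)


def make_toy_trimer(contact: float = TOY_CONTACT,
                    temperature: float = 298.15) -> RigidBodySystem:
    """Three identical toy helices in a parallel C3 arrangement.

    Centres at the vertices of an equilateral triangle with side `contact`;
    each body rotated so its side bead points towards the bundle core.  The
    same pair potential acts between every body pair (identical chains).
    """
    rho = contact / math.sqrt(3.0)
    bodies = []
    for k, name in enumerate(("A", "B", "C")):
        phi = 2.0 * math.pi * k / 3.0
        center = (rho * math.cos(phi), rho * math.sin(phi), 0.0)
        # point the side beads' in-plane component towards the core
        R = rotation_about_axis((0.0, 0.0, 1.0), phi + math.pi)
        bodies.append(RigidBody(name, TOY_LOCAL, center=center, R=R))
    terms = []
    for i in range(3):
        for j in range(i + 1, 3):
            # wells centred on the constructed C3 pose; by symmetry the
            # (i, j) distances are the same for every body pair
            terms.extend(_toy_pair_terms(i, j, _pose_well_r0(bodies[i], bodies[j])))
    return RigidBodySystem(bodies, terms, temperature)
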