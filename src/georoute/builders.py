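"""Fixture builders and structure I/O.

Ideal alpha-helices with prescribed backbone torsions (internal-coordinate
chain construction), a minimal Crick-style parametric coiled-coil backbone
generator (superhelical radius, pitch, interface angle), interhelical
contact maps, PDB reading/writing (biotite-backed) and synthetic PMF
profiles for testing the assembly machinery.

The Crick builder is a fixture generator, not a design tool: bundle axis
along z, chain k phased by 2*pi*k/n, per-residue placement on a minor helix
about the local superhelical axis.  Residue numbering is 1-based and
coordinates are in angstrom throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import Coordinates
from .pmf import PMFProfile

__all__ = [
    "build_ideal_helix",
    "CrickParams",
    "build_crick_coil",
    "crick_axis_points",
    "ContactMap",
    "contact_map",
    "read_pdb",
    "write_pdb",
    "synth_pmf",
    "load_config",
    "save_config",
]

# backbone internal coordinates (angstrom / degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.2, 116.2, 121.7
_A_CA_C_O = 120.8
_OMEGA = 180.0


def _place_atom(p1, p2, p3, bond: float, angle_deg: float,
                torsion_deg: float) -> np.ndarray:
    """Natural-extension-reference-frame placement of the next atom.

    Returns the point at distance `bond` from p3, with angle p2-p3-new and
    torsion p1-p2-p3-new following the same sign convention as
    :func:`georoute.geometry.measure_dihedral`.
    """
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    bc = p3 - p2
    bc /= np.linalg.norm(bc)
    n = np.cross(p2 - p1, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([-bond * math.cos(ang),
                  bond * math.sin(ang) * math.cos(tor),
                  bond * math.sin(ang) * math.sin(tor)])
    return p3 + d[0] * bc + d[1] * m + d[2] * n


def build_ideal_helix(n_res: int, phi0: float = -57.0, psi0: float = -47.0,
                      chain: str = "A") -> Coordinates:
    """Backbone (N, CA, C, O) helix with uniform phi/psi torsions.

    ``backbone_torsions`` round-trips (phi0, psi0) for every interior
    residue; with standard bond geometry the CA-CA virtual bond is ~3.8 A.
    """
    if n_res < 3:
        raise ValueError("need at least 3 residues")
    chains, residues, names, xyz = [], [], [], []
    # seed triad for residue 1
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([_B_N_CA, 0.0, 0.0])
    c = _place_atom(np.array([0.0, 1.0, 0.0]), n, ca, _B_CA_C, _A_N_CA_C, 60.0)
    for res in range(1, n_res + 1):
        for name, pos in (("N", n), ("CA", ca), ("C", c)):
            chains.append(chain)
            residues.append(res)
            names.append(name)
            xyz.append(pos)
        n_next = _place_atom(n, ca, c, _B_C_N, _A_CA_C_N, psi0)
        o = _place_atom(n, ca, c, _B_C_O, _A_CA_C_O, psi0 + 180.0)
        chains.append(chain)
        residues.append(res)
        names.append("O")
        xyz.append(o)
        if res == n_res:
            break
        ca_next = _place_atom(ca, c, n_next, _B_N_CA, _A_C_N_CA, _OMEGA)
        c_next = _place_atom(c, n_next, ca_next, _B_CA_C, _A_N_CA_C, phi0)
        n, ca, c = n_next, ca_next, c_next
    return Coordinates(chains, residues, names, np.asarray(xyz))


@dataclass(frozen=True)
class CrickParams:
    """Minimal Crick parametrisation of a coiled-coil backbone trace.

    radius: superhelical radius (A); pitch: superhelical pitch (A, signed
    for handedness; None = straight, infinite-pitch bundle); interface_angle:
    rotation of each helix about its own axis (degrees); orientation pattern
    "parallel"/"antiparallel" per chain.
    """

    radius: float
    pitch: float | None
    interface_angle: float = 0.0
    n_chains: int = 2
    orientations: tuple = ()
    n_res: int = 28
    rise_per_res: float = 1.51
    res_per_turn: float = 3.5
    minor_radius: float = 2.26

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if self.pitch is not None and self.pitch == 0:
            raise ValueError("pitch must be nonzero or None (straight)")
        if self.n_chains < 2:
            raise ValueError("need at least 2 chains")
        if self.orientations and len(self.orientations) != self.n_chains:
            raise ValueError("one orientation per chain")

    def orientation(self, k: int) -> str:
        return self.orientations[k] if self.orientations else "parallel"


_CHAIN_IDS = "ABCDEFGHIJKLMNOP"


def crick_axis_points(params: CrickParams, chain_index: int) -> np.ndarray:
    """Exact local-axis sample points of one chain (on the radius cylinder)."""
    phase = 2.0 * math.pi * chain_index / params.n_chains
    z = np.arange(params.n_res) * params.rise_per_res
    if params.orientation(chain_index) == "antiparallel":
        z = z[::-1].copy()
    theta = phase + (np.zeros_like(z) if params.pitch is None
                     else 2.0 * math.pi * z / params.pitch)
    return np.stack([params.radius * np.cos(theta),
                     params.radius * np.sin(theta), z], axis=1)


def build_crick_coil(params: CrickParams) -> Coordinates:
    """CA trace of n chains winding about the bundle (z) axis."""
    chains, residues, names, xyz = [], [], [], []
    omega1 = 2.0 * math.pi / params.res_per_turn
    for k in range(params.n_chains):
        axis = crick_axis_points(params, k)
        phase = 2.0 * math.pi * k / params.n_chains
        anti = params.orientation(k) == "antiparallel"
        for i in range(params.n_res):
            z = axis[i, 2]
            theta = phase + (0.0 if params.pitch is None
                             else 2.0 * math.pi * z / params.pitch)
            # local frame on the superhelix: inward normal, tangent, binormal
            normal = np.array([-math.cos(theta), -math.sin(theta), 0.0])
            if params.pitch is None:
                tangent = np.array([0.0, 0.0, 1.0])
            else:
                dtheta_dz = 2.0 * math.pi / params.pitch
                tangent = np.array([-params.radius * math.sin(theta) * dtheta_dz,
                                    params.radius * math.cos(theta) * dtheta_dz,
                                    1.0])
                tangent /= np.linalg.norm(tangent)
            if anti:
                tangent = -tangent
            binormal = np.cross(tangent, normal)
            t = i * omega1 + math.radians(params.interface_angle)
            pos = axis[i] + params.minor_radius * (
                math.cos(t) * normal + math.sin(t) * binormal)
            chains.append(_CHAIN_IDS[k])
            residues.append(i + 1)
            names.append("CA")
            xyz.append(pos)
    return Coordinates(chains, residues, names, np.asarray(xyz))


@dataclass(frozen=True)
class ContactMap:
    """Interhelical residue contacts under a distance cutoff."""

    cutoff: float
    contacts: tuple  # of (chain_i, res_i, chain_j, res_j, min_distance)

    def pairs(self) -> set:
        return {(c[0], c[1], c[2], c[3]) for c in self.contacts}


def contact_map(coords: Coordinates, chain_i: str, chain_j: str,
                cutoff: float) -> ContactMap:
    """All residue pairs of two chains with minimum atom distance <= cutoff."""
    if chain_i == chain_j:
        raise ValueError("contact map is interhelical: chains must differ")
    idx_i = coords.select(chain=chain_i)
    idx_j = coords.select(chain=chain_j)
    if idx_i.size == 0 or idx_j.size == 0:
        raise KeyError("chain not found")
    from scipy.spatial.distance import cdist
    d = cdist(coords.xyz[idx_i], coords.xyz[idx_j])
    res_i = np.asarray([coords.residues[i] for i in idx_i])
    res_j = np.asarray([coords.residues[j] for j in idx_j])
    best: dict[tuple, float] = {}
    ii, jj = np.nonzero(d <= cutoff)
    for a, b in zip(ii, jj):
        key = (int(res_i[a]), int(res_j[b]))
        val = float(d[a, b])
        if key not in best or val < best[key]:
            best[key] = val
    contacts = tuple(sorted((chain_i, ri, chain_j, rj, dist)
                            for (ri, rj), dist in best.items()))
    return ContactMap(cutoff=cutoff, contacts=contacts)


# ---------------------------------------------------------------------------
# PDB I/O (biotite-backed)


def read_pdb(path) -> Coordinates:
    """Read a PDB file into Coordinates.

    Altloc policy: highest occupancy, first altloc on ties (biotite's
    "occupancy" policy).  Malformed ATOM records raise with the line number.
    """
    import biotite.structure.io.pdb as pdbio

    path = Path(path)
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if line.startswith(("ATOM", "HETATM")):
            try:
                float(line[30:38]); float(line[38:46]); float(line[46:54])
            except (ValueError, IndexError):
                raise ValueError(
                    f"{path}:{lineno}: malformed coordinate fields") from None
    pdb_file = pdbio.PDBFile.read(str(path))
    atoms = pdb_file.get_structure(model=1, altloc="occupancy")
    return Coordinates(list(atoms.chain_id), [int(r) for r in atoms.res_id],
                       list(atoms.atom_name), np.asarray(atoms.coord))


def write_pdb(coords: Coordinates, path, res_name: str = "ALA") -> None:
    """Write Coordinates as a PDB file with standard fixed-width columns."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdbio

    n = len(coords)
    atoms = struc.AtomArray(n)
    atoms.coord = coords.xyz.astype(np.float32)
    atoms.chain_id = np.asarray(coords.chains, dtype="U4")
    atoms.res_id = np.asarray(coords.residues, dtype=int)
    atoms.atom_name = np.asarray(coords.names, dtype="U6")
    atoms.res_name = np.full(n, res_name, dtype="U5")
    atoms.element = np.asarray([nm[0] for nm in coords.names], dtype="U2")
    atoms.hetero = np.zeros(n, dtype=bool)
    pdb_file = pdbio.PDBFile()
    pdb_file.set_structure(atoms)
    pdb_file.write(str(path))


# ---------------------------------------------------------------------------
# synthetic PMFs


def synth_pmf(kind: str, grid, params: dict | None = None,
              noise: float = 0.0, seed: int = 0,
              cv: str = "r", units: str = "A") -> PMFProfile:
    """Analytic test profiles: flat | harmonic | double-well | step.

    harmonic: 0.5*k*(s-s0)^2 (params k, s0); double-well:
    barrier*((s-s0)/a)^2-1)^2 (params barrier, s0, a); step: 0 below edge,
    height above (params edge, height).  Optional seeded Gaussian noise.
    """
    grid = np.asarray(grid, dtype=float)
    p = params or {}
    if kind == "flat":
        w = np.zeros_like(grid)
    elif kind == "harmonic":
        w = 0.5 * p.get("k", 1.0) * (grid - p.get("s0", grid.mean())) ** 2
    elif kind == "double-well":
        s = (grid - p.get("s0", grid.mean())) / p.get("a", 1.0)
        w = p.get("barrier", 4.0) * (s * s - 1.0) ** 2
    elif kind == "step":
        w = np.where(grid < p.get("edge", grid.mean()),
                     0.0, p.get("height", 1.0))
    else:
        raise ValueError(f"unknown profile kind {kind!r}")
    err = None
    if noise > 0.0:
        rng = np.random.default_rng(seed)
        w = w + rng.normal(0.0, noise, size=grid.shape)
        err = np.full(grid.shape, noise)
    return PMFProfile(cv=cv, units=units, grid=grid, w=w, error=err)


# ---------------------------------------------------------------------------
# config


def load_config(path) -> dict:
    import yaml
    with open(path, "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh) or {}


def save_config(cfg: dict, path) -> None:
    import yaml
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
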