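"""Brute-force free-energy and symmetry oracles for toy systems.

These reference calculations are deliberately independent of the sampling
protocol: the binding free energy of a two-body toy system is obtained by
direct deterministic quadrature of the bound configurational integral

    K_eq = Int_{r <= site_radius} d^3c  < exp(-beta U(c, Omega)) >_Omega ,
    dG_bind = -kT ln(K_eq * C0),

with the orientational average taken over the Haar measure of SO(3)
(volume 8 pi^2) and the position integral in spherical coordinates about
the receptor centre, so the site boundary is resolved exactly.  The true
binding free energy contains no restraints, so the oracle ignores any
restraint specification.

The symmetry-factor oracle counts, by exhaustive enumeration, the label
permutations of identical chains that a proper rotation can realise on the
bound complex: sigma = 1/g with g that count (g = 2 for a C2 homodimer,
g = n for a parallel C_n bundle).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .corrections import ThermoContext
from .geometry import kabsch_rotation
from .toysys import RigidBodySystem

__all__ = [
    "TooManyDOFsError",
    "ExactToyResult",
    "exact_toy_dg",
    "radial_pair_dg",
    "count_rotational_permutations",
    "symmetry_sigma_oracle",
]


class TooManyDOFsError(ValueError):
    """The system is too large for a direct configurational integral."""


@dataclass(frozen=True)
class ExactToyResult:
    dg: float            # kcal/mol at the 1 M standard state
    k_eq: float          # A^3
    convergence: float   # |dG(full) - dG(coarser)| estimate, kcal/mol


def _euler_zyz_matrices(n_alpha: int, n_beta: int, n_gamma: int):
    """Rotation matrices and Haar weights on a product grid (sums to 8 pi^2).

    alpha, gamma: periodic uniform grids (trapezoidal = spectral accuracy);
    cos(beta): Gauss-Legendre nodes.
    """
    alphas = np.arange(n_alpha) * (2.0 * math.pi / n_alpha)
    gammas = np.arange(n_gamma) * (2.0 * math.pi / n_gamma)
    cb, wb = np.polynomial.legendre.leggauss(n_beta)
    betas = np.arccos(cb)
    w_alpha = 2.0 * math.pi / n_alpha
    w_gamma = 2.0 * math.pi / n_gamma
    mats, weights = [], []
    for a in alphas:
        ca, sa = math.cos(a), math.sin(a)
        Ra = np.array([[ca, -sa, 0.0], [sa, ca, 0.0], [0.0, 0.0, 1.0]])
        for b, wbeta in zip(betas, wb):
            cbb, sbb = math.cos(b), math.sin(b)
            Rb = np.array([[cbb, 0.0, sbb], [0.0, 1.0, 0.0], [-sbb, 0.0, cbb]])
            Rab = Ra @ Rb
            for g in gammas:
                cg, sg = math.cos(g), math.sin(g)
                Rg = np.array([[cg, -sg, 0.0], [sg, cg, 0.0], [0.0, 0.0, 1.0]])
                mats.append(Rab @ Rg)
                weights.append(w_alpha * wbeta * w_gamma)
    return np.stack(mats), np.asarray(weights)


def _position_grid(site_radius: float, n_r: int, n_ct: int, n_phi: int):
    """Spherical-coordinate nodes and volume weights over |c| <= radius."""
    xr, wr = np.polynomial.legendre.leggauss(n_r)
    r = 0.5 * site_radius * (xr + 1.0)
    wr = 0.5 * site_radius * wr * r ** 2
    ct, wct = np.polynomial.legendre.leggauss(n_ct)
    st = np.sqrt(1.0 - ct ** 2)
    phi = np.arange(n_phi) * (2.0 * math.pi / n_phi)
    wphi = 2.0 * math.pi / n_phi
    pts, wts = [], []
    for ri, wri in zip(r, wr):
        for cti, sti, wcti in zip(ct, st, wct):
            x = ri * sti * np.cos(phi)
            y = ri * sti * np.sin(phi)
            z = np.full(n_phi, ri * cti)
            pts.append(np.stack([x, y, z], axis=1))
            wts.append(np.full(n_phi, wri * wcti * wphi))
    return np.concatenate(pts), np.concatenate(wts)


def _k_eq(system: RigidBodySystem, site_radius: float, beta: float,
          n_r: int, n_ct: int, n_phi: int,
          n_alpha: int, n_beta: int, n_gamma: int) -> float:
    rec, lig = system.bodies[0], system.bodies[1]
    rec_beads = np.asarray(rec.bead_positions())        # receptor held fixed
    rec_center = np.asarray(rec.center)
    lig_local = np.asarray(lig.local)

    terms = [t for t in system.pair_terms]
    # pair parameter arrays: receptor bead position and ligand local bead
    rec_idx, lig_idx, A, wrep, eps, r0, watt = [], [], [], [], [], [], []
    for t in terms:
        if t.body_i == 0 and t.body_j == 1:
            ri, li = t.bead_i, t.bead_j
        elif t.body_i == 1 and t.body_j == 0:
            ri, li = t.bead_j, t.bead_i
        else:  # pragma: no cover - guarded by exact_toy_dg
            raise TooManyDOFsError("pair term between unsupported bodies")
        rec_idx.append(ri)
        lig_idx.append(li)
        A.append(t.A); wrep.append(t.w_rep)
        eps.append(t.eps); r0.append(t.r0); watt.append(t.w_att)
    pos, wpos = _position_grid(site_radius, n_r, n_ct, n_phi)
    if not terms:  # non-interacting pair: ideal-gas site volume
        return float(wpos.sum())
    A = np.asarray(A); wrep = np.asarray(wrep)
    eps = np.asarray(eps); r0 = np.asarray(r0); watt = np.asarray(watt)
    rec_pts = rec_beads[np.asarray(rec_idx, dtype=int)]  # (P, 3)
    lig_pts = lig_local[np.asarray(lig_idx, dtype=int)]  # (P, 3)

    centers = pos + rec_center                          # ligand centre c
    mats, wori = _euler_zyz_matrices(n_alpha, n_beta, n_gamma)

    acc = np.zeros(centers.shape[0])
    for R, w in zip(mats, wori):
        # displaced well centres for this orientation: c + R l_i - p_j
        delta = lig_pts @ R.T - rec_pts                 # (P, 3)
        d = centers[None, :, :] + delta[:, None, :]     # (P, N, 3)
        rdist = np.sqrt(np.einsum("pnk,pnk->pn", d, d))
        u = (A[:, None] * np.exp(-(rdist / wrep[:, None]) ** 2)
             - eps[:, None] * np.exp(-0.5 * ((rdist - r0[:, None]) / watt[:, None]) ** 2))
        acc += w * np.exp(-beta * u.sum(axis=0))
    return float(np.dot(wpos, acc) / (8.0 * math.pi ** 2))


def exact_toy_dg(system: RigidBodySystem, ctx: ThermoContext,
                 site_radius: float,
                 resolution: tuple = (36, 16, 24, 16, 12, 16)) -> ExactToyResult:
    """Standard binding free energy of a two-body toy by direct quadrature.

    `resolution` = (n_r, n_costheta, n_phi, n_alpha, n_cosbeta, n_gamma).
    The convergence estimate compares against a grid coarsened by ~2/3 in
    every dimension.  Systems with more than two rigid bodies (more than six
    external degrees of freedom) are refused.
    """
    if len(system.bodies) != 2:
        raise TooManyDOFsError(
            f"direct quadrature supports exactly 2 rigid bodies, "
            f"got {len(system.bodies)}")
    beta = ctx.beta
    k_full = _k_eq(system, site_radius, beta, *resolution)
    coarse = tuple(max(6, int(round(2 * n / 3))) for n in resolution)
    k_coarse = _k_eq(system, site_radius, beta, *coarse)
    dg = -ctx.kT * math.log(k_full * ctx.c_standard)
    dg_coarse = -ctx.kT * math.log(k_coarse * ctx.c_standard)
    return ExactToyResult(dg=dg, k_eq=k_full,
                          convergence=abs(dg - dg_coarse))


def radial_pair_dg(pair_energy, site_radius: float, ctx: ThermoContext) -> float:
    """1-D oracle for a pair of single-bead bodies (orientation-independent).

        K = Int_0^R 4 pi r^2 exp(-beta u(r)) dr,   dG = -kT ln(K C0)

    Serves as an independent cross-check of the 6-D quadrature machinery on
    radially symmetric systems.
    """
    from scipy import integrate

    def f(r):
        return 4.0 * math.pi * r * r * math.exp(-ctx.beta * pair_energy(r))

    k, _ = integrate.quad(f, 0.0, site_radius, limit=200)
    return -ctx.kT * math.log(k * ctx.c_standard)


# ---------------------------------------------------------------------------
# symmetry counting


def count_rotational_permutations(chain_coords, tol: float = 1e-6) -> int:
    """Number of chain-label permutations realizable by a proper rotation.

    `chain_coords` is a list of (m, 3) arrays, one per identical chain, in
    the bound complex geometry (all chains must have the same bead count).
    A permutation pi is realizable if some proper rotation (+ translation)
    superposes chain k onto chain pi(k) for every k simultaneously.
    """
    chains = [np.asarray(c, dtype=float) for c in chain_coords]
    m = chains[0].shape[0]
    if any(c.shape != (m, 3) for c in chains):
        raise ValueError("all chains must have the same bead count")
    ref = np.concatenate(chains)
    g = 0
    for perm in itertools.permutations(range(len(chains))):
        target = np.concatenate([chains[k] for k in perm])
        R, cp, cq = kabsch_rotation(ref, target)
        rmsd = math.sqrt(float((((ref - cp) @ R.T - (target - cq)) ** 2).sum()) / ref.shape[0])
        if rmsd < tol:
            g += 1
    return g


def symmetry_sigma_oracle(system_or_coords, tol: float = 1e-6) -> float:
    """Brute-force symmetry factor sigma = 1/g for a bound homomultimer.

    The labelled stepwise protocol measures one permutation sector of the
    bound configurational integral; indistinguishability counting over all
    n! label assignments, of which g are rotationally connected to the
    reference sector, gives the physical binding constant as 1/g times the
    labelled one.
    """
    if isinstance(system_or_coords, RigidBodySystem):
        coords = [np.asarray(b.bead_positions()) for b in system_or_coords.bodies]
    else:
        coords = list(system_or_coords)
    return 1.0 / count_rotational_permutations(coords, tol=tol)
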