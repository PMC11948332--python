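"""Langevin dynamics and well-tempered metadynamics on toy systems.

The integrator is the BAOAB splitting of Langevin dynamics; rigid-body
systems are sampled with seeded Metropolis Monte Carlo rigid moves under
the same bias.  Gaussian hills are deposited along one collective variable
with the well-tempered height rule

    h_k = h0 * exp( -V(s_k) / ((gamma - 1) k_B T) ),

and the free-energy estimate follows the standard well-tempered identity
F(s) = -gamma/(gamma-1) * V(s) up to an additive constant.

Units: kcal/mol, angstrom, fs, amu, K.  Angular CVs are handled in degrees
and may be periodic (hills wrap around the grid).
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .corrections import KB_KCAL_MOL_K
from .pmf import PMFProfile
from .toysys import (ParticleSystem, RigidBody, RigidBodySystem, mat_mul,
                     rotation_about_axis, scalar_angle_deg,
                     scalar_dihedral_deg)

__all__ = [
    "ENERGY_TO_AKMA",
    "CV",
    "CoordinateCV",
    "DistanceCV",
    "AngleCV",
    "DihedralCV",
    "RmsdCV",
    "MetaDConfig",
    "BiasState",
    "deposit_hill",
    "langevin_step",
    "sample_mc",
    "run_wtmetad",
    "write_hills",
    "read_hills",
    "IntegrationBlowUpError",
    "restraint_terms_potential",
]

#: kcal/mol expressed in amu * A^2 / fs^2
ENERGY_TO_AKMA = 4.184e-4


class IntegrationBlowUpError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# collective variables


class CV:
    name = "cv"
    units = ""
    periodic = False

    def value(self, system) -> float:  # pragma: no cover - interface
        raise NotImplementedError


@dataclass
class CoordinateCV(CV):
    """One Cartesian coordinate of one particle (particle systems)."""

    particle: int = 0
    axis: int = 0
    name: str = "x"
    units: str = "A"
    periodic: bool = False

    def value(self, system: ParticleSystem) -> float:
        return float(system.positions[self.particle, self.axis])

    def gradient_entry(self):
        return self.particle, self.axis


@dataclass
class DistanceCV(CV):
    """Distance between two beads (body index, bead index) of a rigid system."""

    i: tuple[int, int] = (0, 0)
    j: tuple[int, int] = (1, 0)
    name: str = "r"
    units: str = "A"
    periodic: bool = False

    def value_from_positions(self, pos) -> float:
        p = pos[self.i[0]][self.i[1]]
        q = pos[self.j[0]][self.j[1]]
        return math.dist(p, q)

    def value(self, system: RigidBodySystem) -> float:
        return self.value_from_positions(system.bead_positions())


@dataclass
class AngleCV(CV):
    """Angle (degrees) over three beads of a rigid system."""

    refs: tuple = ((0, 0), (0, 1), (1, 0))
    name: str = "theta"
    units: str = "deg"
    periodic: bool = False

    def value_from_positions(self, pos) -> float:
        a, b, c = (pos[r[0]][r[1]] for r in self.refs)
        return scalar_angle_deg(a, b, c)

    def value(self, system: RigidBodySystem) -> float:
        return self.value_from_positions(system.bead_positions())


@dataclass
class DihedralCV(CV):
    """Dihedral (degrees, periodic) over four beads of a rigid system."""

    refs: tuple = ((0, 0), (0, 1), (1, 0), (1, 1))
    name: str = "phi"
    units: str = "deg"
    periodic: bool = True

    def value_from_positions(self, pos) -> float:
        a, b, c, d = (pos[r[0]][r[1]] for r in self.refs)
        return scalar_dihedral_deg(a, b, c, d)

    def value(self, system: RigidBodySystem) -> float:
        return self.value_from_positions(system.bead_positions())


@dataclass
class WrappedDihedralCV(CV):
    """Dihedral unwrapped about a reference value.

    Returns center + minimum-image(angle - center), i.e. a continuous
    coordinate in (center-180, center+180] suitable for windowed,
    non-periodic grids around a restraint centre.
    """

    refs: tuple = ((0, 0), (0, 1), (1, 0), (1, 1))
    center: float = 0.0
    name: str = "phi"
    units: str = "deg"
    periodic: bool = False

    def value_from_positions(self, pos) -> float:
        a, b, c, d = (pos[r[0]][r[1]] for r in self.refs)
        ang = scalar_dihedral_deg(a, b, c, d)
        return self.center + ((ang - self.center + 180.0) % 360.0 - 180.0)

    def value(self, system: RigidBodySystem) -> float:
        return self.value_from_positions(system.bead_positions())


@dataclass
class RmsdCV(CV):
    """Optimal-superposition RMSD of all beads to a reference snapshot."""

    reference: np.ndarray = None
    name: str = "rmsd"
    units: str = "A"
    periodic: bool = False

    def value_from_positions(self, pos) -> float:
        from .geometry import optimal_rmsd
        flat = np.asarray([p for body in pos for p in body], dtype=float)
        return optimal_rmsd(flat, self.reference)

    def value(self, system: RigidBodySystem) -> float:
        return self.value_from_positions(system.bead_positions())


# ---------------------------------------------------------------------------
# bias


@dataclass
class MetaDConfig:
    """Well-tempered metadynamics parameters for one CV.

    h0: initial hill height (kcal/mol); width: hill sigma in CV units;
    stride: steps between depositions; gamma: bias factor (> 1);
    grid bounds and resolution; wall: 'reject' skips depositions outside
    the grid (counted, never silent), 'reflect' reflects the Langevin CV
    at the bounds via half-harmonic walls of `wall_k`.
    """

    cv: CV
    h0: float = 0.3
    width: float = 0.25
    stride: int = 50
    gamma: float = 8.0
    grid_min: float = 0.0
    grid_max: float = 1.0
    n_grid: int = 301
    temperature: float = 298.15
    seed: int = 2024
    wall: str = "reject"
    wall_k: float = 100.0
    # Monte Carlo move sizes (rigid-body systems)
    mc_translation: float = 0.35
    mc_rotation: float = 0.25

    def __post_init__(self):
        if self.gamma <= 1.0:
            raise ValueError("bias factor gamma must be > 1")
        if self.h0 < 0:
            raise ValueError("hill height must be >= 0")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.wall not in ("reject", "reflect"):
            raise ValueError("wall must be 'reject' or 'reflect'")


@dataclass
class Hill:
    step: int
    center: float
    width: float
    height: float


class BiasState:
    """Deposited hills plus the accumulated bias V(s) on a grid."""

    def __init__(self, cfg: MetaDConfig):
        self.cfg = cfg
        self.grid = np.linspace(cfg.grid_min, cfg.grid_max, cfg.n_grid)
        self.V = np.zeros(cfg.n_grid)
        self.hills: list[Hill] = []
        self.n_rejected = 0
        self._dx = (cfg.grid_max - cfg.grid_min) / (cfg.n_grid - 1)
        self._span = cfg.grid_max - cfg.grid_min

    @property
    def kT(self) -> float:
        return KB_KCAL_MOL_K * self.cfg.temperature

    def bias_at(self, s: float) -> float:
        cfg = self.cfg
        if s <= cfg.grid_min:
            return float(self.V[0])
        if s >= cfg.grid_max:
            return float(self.V[-1])
        x = (s - cfg.grid_min) / self._dx
        i = int(x)
        f = x - i
        return float(self.V[i] * (1.0 - f) + self.V[i + 1] * f)

    def _kernel(self, center: float) -> np.ndarray:
        d = self.grid - center
        if self.cfg.cv.periodic:
            d = (d + 0.5 * self._span) % self._span - 0.5 * self._span
        return np.exp(-0.5 * (d / self.cfg.width) ** 2)

    def free_energy(self, error: np.ndarray | None = None,
                    r_star: float | None = None) -> PMFProfile:
        """F(s) = -gamma/(gamma-1) V(s), shifted so that min F = 0."""
        g = self.cfg.gamma
        f = -(g / (g - 1.0)) * self.V
        f = f - f.min()
        return PMFProfile(cv=self.cfg.cv.name, units=self.cfg.cv.units,
                          grid=self.grid.copy(), w=f, error=error,
                          r_star=r_star)


def deposit_hill(bias: BiasState, s: float, step: int = 0) -> BiasState:
    """Add a well-tempered Gaussian hill at CV value `s` (in place).

    The effective height decays with the accumulated bias:
    h = h0 * exp(-V(s) / ((gamma - 1) kT)).  Depositions outside the grid
    bounds are rejected and counted, never silently dropped.
    """
    cfg = bias.cfg
    if s < cfg.grid_min or s > cfg.grid_max:
        bias.n_rejected += 1
        return bias
    if cfg.h0 == 0.0:
        return bias
    h = cfg.h0 * math.exp(-bias.bias_at(s) / ((cfg.gamma - 1.0) * bias.kT))
    bias.V += h * bias._kernel(s)
    bias.hills.append(Hill(step=step, center=s, width=cfg.width, height=h))
    return bias


def write_hills(hills: Sequence[Hill], path) -> None:
    lines = ["# step center width height"]
    lines += [f"{h.step} {h.center:.10g} {h.width:.10g} {h.height:.10g}"
              for h in hills]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_hills(path) -> list[Hill]:
    out = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        step, center, width, height = line.split()
        out.append(Hill(int(step), float(center), float(width), float(height)))
    return out


# ---------------------------------------------------------------------------
# BAOAB Langevin integrator (particle systems)


def langevin_step(system: ParticleSystem, dt: float, friction: float,
                  temperature: float, rng: np.random.Generator,
                  extra_force: Callable | None = None) -> ParticleSystem:
    """One BAOAB Langevin update (in place; returns the system).

    dt in fs, friction in 1/ps, temperature in K.  Deterministic for a
    given generator state.  `extra_force` maps positions to an additional
    force array (bias/walls).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    m = system.masses[:, None]
    kT = KB_KCAL_MOL_K * temperature * ENERGY_TO_AKMA  # amu A^2 / fs^2

    def total_force(x):
        f = system.potential.forces(x)
        if extra_force is not None:
            f = f + extra_force(x)
        return f * ENERGY_TO_AKMA  # amu A / fs^2

    f = total_force(system.positions)
    if not np.all(np.isfinite(f)) or np.max(np.abs(f)) > 1e6:
        raise IntegrationBlowUpError("force overflow")
    v = system.velocities + 0.5 * dt * f / m
    x = system.positions + 0.5 * dt * v
    c1 = math.exp(-friction * 1e-3 * dt)
    c2 = math.sqrt(max(0.0, 1.0 - c1 * c1))
    v = c1 * v + c2 * np.sqrt(kT / m) * rng.standard_normal(v.shape)
    x = x + 0.5 * dt * v
    f = total_force(x)
    if not np.all(np.isfinite(f)) or np.max(np.abs(f)) > 1e6:
        raise IntegrationBlowUpError("force overflow")
    v = v + 0.5 * dt * f / m
    system.positions, system.velocities = x, v
    return system


# ---------------------------------------------------------------------------
# restraint adapters for sampling


def restraint_terms_potential(terms: Sequence) -> Callable:
    """Build an energy function over bead positions from restraint terms.

    Each term is a tuple whose first element names the form:

    * ("angle", ref1, ref2, ref3, eq_deg, k)           harmonic, k in
      kcal/mol/rad^2, minimum-image not needed (angles in [0, 180])
    * ("dihedral", ref1..ref4, eq_deg, k)              harmonic with
      minimum-image periodic difference
    * ("distance", ref1, ref2, eq_A, k)                harmonic, kcal/mol/A^2
    * ("flat_max", ref1, ref2, bound_A, k)             half-harmonic above
      the bound (site wall)
    * ("flat_bottom", ref1, ref2, eq_A, half_width, k) flat-bottom distance

    refs are (body index, bead index) pairs.
    """
    terms = [tuple(t) for t in terms]

    def energy(pos) -> float:
        e = 0.0
        for t in terms:
            kind = t[0]
            if kind == "angle":
                _, r1, r2, r3, eq, k = t
                a = scalar_angle_deg(pos[r1[0]][r1[1]], pos[r2[0]][r2[1]],
                                     pos[r3[0]][r3[1]])
                d = math.radians(a - eq)
                e += 0.5 * k * d * d
            elif kind == "dihedral":
                _, r1, r2, r3, r4, eq, k = t
                a = scalar_dihedral_deg(pos[r1[0]][r1[1]], pos[r2[0]][r2[1]],
                                        pos[r3[0]][r3[1]], pos[r4[0]][r4[1]])
                d = (a - eq + 180.0) % 360.0 - 180.0
                d = math.radians(d)
                e += 0.5 * k * d * d
            elif kind == "distance":
                _, r1, r2, eq, k = t
                d = math.dist(pos[r1[0]][r1[1]], pos[r2[0]][r2[1]]) - eq
                e += 0.5 * k * d * d
            elif kind == "flat_max":
                _, r1, r2, bound, k = t
                d = math.dist(pos[r1[0]][r1[1]], pos[r2[0]][r2[1]]) - bound
                if d > 0.0:
                    e += 0.5 * k * d * d
            elif kind == "flat_bottom":
                _, r1, r2, eq, w, k = t
                d = abs(math.dist(pos[r1[0]][r1[1]], pos[r2[0]][r2[1]]) - eq) - w
                if d > 0.0:
                    e += 0.5 * k * d * d
            else:
                raise ValueError(f"unknown restraint term {kind!r}")
        return e

    return energy


def sample_mc(system: RigidBodySystem, extra_potential: Callable | None,
              n_moves: int, seed: int,
              movable_bodies: Sequence[int] | None = None,
              mc_translation: float = 0.35, mc_rotation: float = 0.25,
              callback: Callable | None = None, callback_stride: int = 5,
              temperature: float | None = None) -> dict:
    """Plain (unbiased) Metropolis sampling of a rigid-body system.

    `callback(positions)` is invoked every `callback_stride` moves on the
    current configuration; used for ensemble averages such as staircase
    free-energy-perturbation estimates.
    """
    rng = random.Random(seed)
    movable = list(movable_bodies) if movable_bodies is not None \
        else list(range(1, len(system.bodies)))
    kT = KB_KCAL_MOL_K * (temperature if temperature is not None
                          else system.temperature)
    extra = extra_potential or (lambda pos: 0.0)
    pos = system.bead_positions()
    e_pot = system.pair_energy(pos) + extra(pos)
    accepted = 0
    for step in range(1, n_moves + 1):
        body_idx = movable[rng.randrange(len(movable))]
        body = system.bodies[body_idx]
        if rng.random() < 0.5:
            c = body.center
            trial = body.moved(center=(c[0] + rng.gauss(0.0, mc_translation),
                                       c[1] + rng.gauss(0.0, mc_translation),
                                       c[2] + rng.gauss(0.0, mc_translation)))
        else:
            axis = (rng.gauss(0.0, 1.0), rng.gauss(0.0, 1.0), rng.gauss(0.0, 1.0))
            dR = rotation_about_axis(axis, rng.gauss(0.0, mc_rotation))
            trial = body.moved(R=mat_mul(dR, body.R))
        old_body = system.bodies[body_idx]
        system.bodies[body_idx] = trial
        new_pos = system.bead_positions()
        new_e = system.pair_energy(new_pos) + extra(new_pos)
        if new_e - e_pot <= 0.0 or rng.random() < math.exp(-(new_e - e_pot) / kT):
            pos, e_pot = new_pos, new_e
            accepted += 1
        else:
            system.bodies[body_idx] = old_body
        if callback is not None and step % callback_stride == 0:
            callback(pos)
    return {"n_moves": n_moves, "acceptance": accepted / n_moves}


# ---------------------------------------------------------------------------
# run drivers


def _reweighted_profile(block_hists: list[np.ndarray], vbar: np.ndarray,
                        kT: float):
    """Umbrella-reweighted free energy with block errors.

    The sampling window runs under the frozen bias V, so the CV
    distribution obeys P(s) ~ exp(-beta (F(s) + V(s))) exactly:
    F(s) = -kT ln H(s) - V(s).  Unlike the -gamma/(gamma-1) V estimator
    this is free of hill-kernel smoothing and of the tempering transient;
    consecutive block histograms provide a per-point error.  Bins never
    visited in the window get the worst-case free energy of their block
    (they carry no weight in downstream Boltzmann integrals).
    """
    fs = []
    for h in block_hists:
        with np.errstate(divide="ignore"):
            f = np.where(h > 0, -kT * np.log(np.maximum(h, 1e-300)), np.nan) - vbar
        f = np.where(np.isnan(f), np.nanmax(f), f)
        fs.append(f)
    total = np.stack(fs)
    total = total - total.mean(axis=1, keepdims=True)
    mean = total.mean(axis=0)
    if len(fs) < 3:
        err = np.zeros_like(mean)
    else:
        err = total.std(axis=0, ddof=1) / math.sqrt(total.shape[0])
    return mean - mean.min(), err


def run_wtmetad(system, cfg: MetaDConfig, n_steps: int,
                extra_potential: Callable | None = None,
                movable_bodies: Sequence[int] | None = None,
                dt: float = 2.0, friction: float = 1.0,
                n_checkpoints: int = 10, freeze_fraction: float = 0.4):
    """Run well-tempered metadynamics and reconstruct the free energy.

    Particle systems are propagated with BAOAB Langevin dynamics (`dt` fs,
    `friction` 1/ps); rigid-body systems with Metropolis Monte Carlo rigid
    moves of the `movable_bodies` (default: all but body 0).

    The run has two phases: hills are deposited during the first
    ``1 - freeze_fraction`` of the steps; the bias is then frozen and the
    final stretch samples under the static (near-optimal) bias, from which
    the free energy is recovered exactly by umbrella reweighting,
    F(s) = -kT ln H(s) - V(s).  Consecutive block histograms give the
    per-point error.  With ``h0 = 0`` the run reduces to plain sampling and
    the profile to Boltzmann inversion of the histogram.  Returns
    (summary dict, BiasState, PMFProfile).
    """
    if not 0.0 < freeze_fraction < 1.0:
        raise ValueError("freeze_fraction must be in (0, 1)")
    bias = BiasState(cfg)
    freeze_at = int(n_steps * (1.0 - freeze_fraction))
    if isinstance(system, ParticleSystem):
        summary = _run_langevin(system, cfg, bias, n_steps, extra_potential,
                                dt, friction, freeze_at)
    elif isinstance(system, RigidBodySystem):
        summary = _run_mc(system, cfg, bias, n_steps, extra_potential,
                          movable_bodies, freeze_at)
    else:
        raise TypeError(f"unsupported system type {type(system).__name__}")
    block_hists = summary.pop("_block_hists")
    w, err = _reweighted_profile(block_hists, bias.V, bias.kT)
    profile = PMFProfile(cv=cfg.cv.name, units=cfg.cv.units,
                         grid=bias.grid.copy(), w=w, error=err)
    summary["block_hists"] = block_hists
    return summary, bias, profile


def _run_langevin(system, cfg, bias, n_steps, extra_potential, dt, friction,
                  freeze_at):
    # inlined BAOAB fast path (identical scheme to langevin_step, with the
    # bias/wall force on the CV coordinate and block-generated OU noise)
    rng = np.random.default_rng(cfg.seed)
    cv: CoordinateCV = cfg.cv
    pi, ax = cv.gradient_entry()
    grad = np.zeros(cfg.n_grid)
    lo, hi = cfg.grid_min, cfg.grid_max
    wall_k = cfg.wall_k
    reflect = cfg.wall == "reflect"
    m = system.masses[:, None]
    kT = KB_KCAL_MOL_K * cfg.temperature * ENERGY_TO_AKMA
    c1 = math.exp(-friction * 1e-3 * dt)
    c2 = math.sqrt(max(0.0, 1.0 - c1 * c1))
    sigma_v = c2 * np.sqrt(kT / m)
    x, v = system.positions, system.velocities
    pot = system.potential

    def force(x):
        f = pot.forces(x)
        s = x[pi, ax]
        f[pi, ax] -= np.interp(s, bias.grid, grad)
        if reflect:
            if s < lo:
                f[pi, ax] += wall_k * (lo - s)
            elif s > hi:
                f[pi, ax] -= wall_k * (s - hi)
        return f

    f = force(x) * ENERGY_TO_AKMA
    n_blocks = 4
    hists = [np.zeros(cfg.n_grid) for _ in range(n_blocks)]
    block_len = max(1, (n_steps - freeze_at) // n_blocks)
    inv_dx = (cfg.n_grid - 1) / (hi - lo)
    noise_block = 8192
    noise = rng.standard_normal((noise_block,) + x.shape)
    ni = 0
    for step in range(1, n_steps + 1):
        if ni == noise_block:
            noise = rng.standard_normal((noise_block,) + x.shape)
            ni = 0
        v = v + (0.5 * dt) * f / m
        x = x + (0.5 * dt) * v
        v = c1 * v + sigma_v * noise[ni]
        ni += 1
        x = x + (0.5 * dt) * v
        f = force(x) * ENERGY_TO_AKMA
        v = v + (0.5 * dt) * f / m
        if step % cfg.stride == 0 and step <= freeze_at:
            if not np.all(np.isfinite(f)):
                raise IntegrationBlowUpError("force overflow")
            system.positions, system.velocities = x, v
            deposit_hill(bias, cv.value(system), step=step)
            grad = np.gradient(bias.V, bias.grid)
            f = force(x) * ENERGY_TO_AKMA
        elif step > freeze_at:
            s = x[pi, ax]
            if lo <= s <= hi:
                k = int((s - lo) * inv_dx + 0.5)
                blk = min(n_blocks - 1, (step - freeze_at - 1) // block_len)
                hists[blk][k] += 1.0
    system.positions, system.velocities = x, v
    return {"n_steps": n_steps, "n_hills": len(bias.hills),
            "n_rejected_hills": bias.n_rejected, "sampler": "langevin",
            "_block_hists": hists}


def _run_mc(system, cfg, bias, n_steps, extra_potential, movable_bodies,
            freeze_at):
    rng = random.Random(cfg.seed)
    movable = list(movable_bodies) if movable_bodies is not None \
        else list(range(1, len(system.bodies)))
    if not movable:
        raise ValueError("no movable bodies")
    kT = KB_KCAL_MOL_K * cfg.temperature
    cv = cfg.cv
    extra = extra_potential or (lambda pos: 0.0)

    pos = system.bead_positions()
    e_pot = system.pair_energy(pos) + extra(pos)
    s = cv.value_from_positions(pos)
    accepted = 0
    n_blocks = 4
    hists = [np.zeros(cfg.n_grid) for _ in range(n_blocks)]
    block_len = max(1, (n_steps - freeze_at) // n_blocks)
    inv_dx = (cfg.n_grid - 1) / (cfg.grid_max - cfg.grid_min)

    for step in range(1, n_steps + 1):
        body_idx = movable[rng.randrange(len(movable))]
        body = system.bodies[body_idx]
        if rng.random() < 0.5:
            c = body.center
            sig = cfg.mc_translation
            new_center = (c[0] + rng.gauss(0.0, sig),
                          c[1] + rng.gauss(0.0, sig),
                          c[2] + rng.gauss(0.0, sig))
            trial = body.moved(center=new_center)
        else:
            axis = (rng.gauss(0.0, 1.0), rng.gauss(0.0, 1.0), rng.gauss(0.0, 1.0))
            dR = rotation_about_axis(axis, rng.gauss(0.0, cfg.mc_rotation))
            trial = body.moved(R=mat_mul(dR, body.R))
        old_body = system.bodies[body_idx]
        system.bodies[body_idx] = trial
        new_pos = system.bead_positions()
        new_s = cv.value_from_positions(new_pos)
        if cfg.wall == "reject" and not (cfg.grid_min <= new_s <= cfg.grid_max):
            system.bodies[body_idx] = old_body
        else:
            new_e = system.pair_energy(new_pos) + extra(new_pos)
            d_total = (new_e + bias.bias_at(new_s)) - (e_pot + bias.bias_at(s))
            if d_total <= 0.0 or rng.random() < math.exp(-d_total / kT):
                pos, e_pot, s = new_pos, new_e, new_s
                accepted += 1
            else:
                system.bodies[body_idx] = old_body
        if step % cfg.stride == 0 and step <= freeze_at:
            deposit_hill(bias, s, step=step)
        elif step > freeze_at:
            if cfg.grid_min <= s <= cfg.grid_max:
                k = int((s - cfg.grid_min) * inv_dx + 0.5)
                blk = min(n_blocks - 1, (step - freeze_at - 1) // block_len)
                hists[blk][k] += 1.0
    return {"n_steps": n_steps, "n_hills": len(bias.hills),
            "n_rejected_hills": bias.n_rejected, "sampler": "mc",
            "acceptance": accepted / n_steps, "_block_hists": hists}
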