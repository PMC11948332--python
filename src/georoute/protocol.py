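"""End-to-end geometrical route on toy rigid-body systems.

For each helix-removal step the driver measures the bound-pose Boresch
degrees of freedom, then runs the sequential well-tempered metadynamics
PMFs of the protocol:

1. (optional) receptor conformational restraint: PMF along the receptor
   internal distance, imposition in the bound state;
2. orientational restraints: PMFs along theta_B, phi_B, phi_C, imposing
   each harmonic restraint in turn (telescoping product);
3. positional restraints: PMFs along theta_A, phi_A;
4. separation PMF along the anchor distance r with all restraints active,

and finally assembles the step with the analytic corrections (S*, bulk
orientational release, standard state) via :func:`georoute.assembly.assemble_step`.
Bound-state PMFs run inside a flat-bottom site wall at ``site_radius`` on
the separation CV; the same radius bounds the I* site integral, so the
"site" species is defined identically throughout (and in the brute-force
oracle).

The receptor body carrying the anchors is held fixed (the binding constant
integrates relative degrees of freedom only); everything else moves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .assembly import (AssemblyResult, DissociationScheme, DissociationStep,
                       StepFreeEnergy, assemble_step, assemble_scheme)
from .corrections import ThermoContext, bulk_orientational_term
import numpy as np

from .metad import (AngleCV, DistanceCV, MetaDConfig, WrappedDihedralCV,
                    restraint_terms_potential, run_wtmetad, sample_mc)
from .pmf import average_profiles, imposition_free_energy
from .umbrella import umbrella_pmf
from .restraints import HarmonicTerm, RestraintSpec
from .toysys import RigidBodySystem, scalar_angle_deg, scalar_dihedral_deg

__all__ = ["ToyAnchors", "StepSpec", "run_georoute_protocol",
           "default_dimer_step", "default_trimer_steps"]

_SITE_WALL_K = 200.0


@dataclass(frozen=True)
class ToyAnchors:
    """Boresch anchors on toy bodies, by body name and bead index.

    receptor = (c, b, a), ligand = (A, B, C); each entry (body name, bead).
    Bead a and bead A are the separation anchors (bead 0 = body centre in
    the stock fixtures).
    """

    receptor: tuple
    ligand: tuple


@dataclass(frozen=True)
class StepSpec:
    """One helix-removal step of a toy dissociation scheme."""

    ligand_body: str
    anchors: ToyAnchors
    k_angle: float = 50.0          # kcal/mol/rad^2 on all five angular DOFs
    site_radius: float = 7.0       # A, site wall and I* upper bound
    r_star: float = 10.0           # A, bulk reference distance
    sep_method: str = "umbrella"   # "umbrella" (WHAM ladder) or "metad"
    umbrella_span: tuple = (2.0, 10.5, 0.5)  # ladder start, stop, spacing (A)
    k_umbrella: float = 20.0       # kcal/mol/A^2 window force constant
    steps_umbrella: int = 60_000   # MC moves per umbrella window
    n_sep_replicas: int = 2
    sep_grid: tuple = (1.5, 18.0, 661)          # metad route only
    steps_separation: int = 500_000             # metad route only
    steps_angle: int = 200_000                  # pmf imposition route only
    angle_window: float | None = None     # deg half-width; None = full range
    dihedral_window: float | None = None  # deg half-width; None = periodic
    hill_angle: tuple = (0.25, 3.0, 10.0, 25)   # h0, width(deg), gamma, stride
    hill_sep: tuple = (0.4, 0.15, 15.0, 30)     # h0, width(A), gamma, stride
    bulk_fit_margin: tuple = (1.7, -0.3)  # fit window r* - [1.7, -0.3] A
    imposition_method: str = "staircase"  # "staircase" (FEP) or "pmf"
    steps_fep: int = 30_000               # MC moves per staircase stage
    fep_lambdas: tuple = (0.0, 1/128, 1/64, 1/32, 1/16, 1/8, 1/4, 1/2, 1.0)
    receptor_restraint: tuple | None = None
    # ("wall", bodyX, bodyY, bound, k) site-definition wall, no compensation
    # ("flat_bottom", bodyX, bodyY, eq, half_width, k) compensated restraint
    label: str = ""


def _resolve(system: RigidBodySystem, name: str) -> int:
    for i, b in enumerate(system.bodies):
        if b.name == name:
            return i
    raise KeyError(f"body {name!r} not in system")


def _copy_system(system: RigidBodySystem) -> RigidBodySystem:
    return RigidBodySystem(list(system.bodies), system.pair_terms,
                           system.temperature)


_DOF_ORDER = ("thetaB", "phiB", "phiC", "thetaA", "phiA")


def _dof_refs(rec, lig, dof: str):
    c, b, a = rec
    A, B, C = lig
    return {"thetaA": (b, a, A), "thetaB": (a, A, B),
            "phiA": (c, b, a, A), "phiB": (b, a, A, B),
            "phiC": (a, A, B, C)}[dof]


def _measure_dof(pos, refs):
    pts = [pos[r[0]][r[1]] for r in refs]
    if len(pts) == 3:
        return scalar_angle_deg(*pts)
    return scalar_dihedral_deg(*pts)


def _angle_cfg(dof: str, refs, equilibrium: float, spec: StepSpec, seed: int,
               temperature: float) -> MetaDConfig:
    """PMF grid for one angular DOF.

    By default the full range is scanned (theta on [1, 179] with reject
    walls, dihedrals periodic over 360 degrees), so the imposition
    integrals see the complete unrestrained site ensemble.  Optional
    windows restrict the grid around the restraint centre for systems
    whose bound basin is known to be localized.

    The hill width is capped at half the thermal width of the restraint
    being imposed (sqrt(kT/K)), so the reconstructed profile resolves the
    region that dominates the imposition integral.
    """
    h0, width, gamma, stride = spec.hill_angle
    kT = 1.987204259e-3 * temperature
    width = min(width, 0.5 * math.degrees(math.sqrt(kT / spec.k_angle)))
    if dof.startswith("theta"):
        cv = AngleCV(refs=refs, name=dof)
        if spec.angle_window is None:
            lo, hi = 1.0, 179.0
        else:
            lo = max(1.0, equilibrium - spec.angle_window)
            hi = min(179.0, equilibrium + spec.angle_window)
    elif spec.dihedral_window is None:
        from .metad import DihedralCV
        cv = DihedralCV(refs=refs, name=dof)
        lo, hi = -180.0, 180.0
    else:
        cv = WrappedDihedralCV(refs=refs, center=equilibrium, name=dof)
        lo = equilibrium - spec.dihedral_window
        hi = equilibrium + spec.dihedral_window
    return MetaDConfig(cv=cv, h0=h0, width=width, stride=stride, gamma=gamma,
                       grid_min=lo, grid_max=hi,
                       n_grid=2 * int(round((hi - lo) / 1.0)) + 1,
                       temperature=temperature, seed=seed)


def _scale_terms(terms, lam: float):
    """Scale the force constant (last tuple element) of restraint terms."""
    return [t[:-1] + (t[-1] * lam,) for t in terms]


def _staircase_imposition(system: RigidBodySystem, static_terms, new_terms,
                          movable, spec: StepSpec, ctx: ThermoContext,
                          seed: int) -> tuple[float, float]:
    """Free energy of imposing `new_terms` by staircase perturbation.

    The force constants are switched on over a geometric schedule; each
    stage samples the lambda_i ensemble by plain Metropolis MC and
    estimates -kT ln < exp(-beta (lambda_{i+1}-lambda_i) u) >.  Adjacent
    stages overlap well because each doubling perturbs the restrained
    fluctuations by ~kT/2.  Returns (dG, standard error from 5-block
    spread, stages combined in quadrature).
    """
    beta, kT = ctx.beta, ctx.kT
    u_full = restraint_terms_potential(new_terms)
    lambdas = spec.fep_lambdas
    dg, var = 0.0, 0.0
    for i in range(len(lambdas) - 1):
        lam, nxt = lambdas[i], lambdas[i + 1]
        extra = restraint_terms_potential(
            list(static_terms) + _scale_terms(new_terms, lam))
        samples: list[float] = []
        # weak-restraint stages sample the widest ensembles: double budget
        n_moves = spec.steps_fep * (2 if nxt <= 1 / 16 else 1)
        sample_mc(_copy_system(system), extra, n_moves,
                  seed=(seed + 131 * i) % (2 ** 31 - 1),
                  movable_bodies=movable,
                  callback=lambda pos, s=samples: s.append(u_full(pos)),
                  callback_stride=5)
        arr = np.asarray(samples[len(samples) // 5:])  # drop burn-in fifth
        w = np.exp(-beta * (nxt - lam) * arr)
        dg += -kT * math.log(float(w.mean()))
        blocks = np.array_split(w, 5)
        bvals = [-kT * math.log(float(b.mean())) for b in blocks]
        var += float(np.var(bvals, ddof=1)) / len(bvals)
    return dg, math.sqrt(var)


def run_step(system: RigidBodySystem, spec: StepSpec, ctx: ThermoContext,
             seed: int) -> StepFreeEnergy:
    """Run all PMFs of one removal step and assemble its free energy."""
    lig_i = _resolve(system, spec.ligand_body)
    rec_names = {r[0] for r in spec.anchors.receptor}
    rec_anchor_body = spec.anchors.receptor[2][0]  # body carrying anchor "a"
    rec_i = _resolve(system, rec_anchor_body)

    def ref(entry):
        return (_resolve(system, entry[0]), entry[1])

    rec = tuple(ref(e) for e in spec.anchors.receptor)
    lig = tuple(ref(e) for e in spec.anchors.ligand)
    a_ref, A_ref = rec[2], lig[0]
    movable = [i for i in range(len(system.bodies)) if i != rec_i]

    pos0 = system.bead_positions()
    equilibria = {dof: _measure_dof(pos0, _dof_refs(rec, lig, dof))
                  for dof in _DOF_ORDER}
    restraint_spec = RestraintSpec(
        HarmonicTerm(dof, equilibria[dof], spec.k_angle) for dof in _DOF_ORDER)

    site_wall = ("flat_max", a_ref, A_ref, spec.site_radius, _SITE_WALL_K)
    receptor_terms: list[tuple] = []
    compensated = None
    if spec.receptor_restraint is not None:
        kind = spec.receptor_restraint[0]
        if kind == "wall":
            _, bx, by, bound, k = spec.receptor_restraint
            receptor_terms.append(("flat_max", ref((bx, 0)), ref((by, 0)),
                                   bound, k))
        elif kind == "flat_bottom":
            _, bx, by, eq, hw, k = spec.receptor_restraint
            compensated = ("flat_bottom", ref((bx, 0)), ref((by, 0)), eq, hw, k)
        else:
            raise ValueError(f"unknown receptor restraint {kind!r}")

    temperature = system.temperature
    active: list[tuple] = list(receptor_terms)
    sub_seed = (seed * 1009) % (2 ** 31 - 1)

    dg_rmsd_site = dg_rmsd_bulk = None
    if compensated is not None:
        # impose the receptor conformational restraint first, in the site...
        _, rx, ry, eq, hw, k = compensated
        dg_rmsd_site = _staircase_imposition(system, [site_wall] + active,
                                             [compensated], movable, spec,
                                             ctx, sub_seed + 11)
        # ... and account for its release in the bulk receptor complex
        rec_bodies = [i for i in range(len(system.bodies)) if i != lig_i]
        sub = system.subsystem(rec_bodies)
        rx_s = (rec_bodies.index(rx[0]), rx[1])
        ry_s = (rec_bodies.index(ry[0]), ry[1])
        wall_b = ("flat_max", rx_s, ry_s, spec.site_radius, _SITE_WALL_K)
        comp_b = ("flat_bottom", rx_s, ry_s, eq, hw, k)
        movable_b = [i for i in range(len(sub.bodies)) if i != 0]
        dg_rmsd_bulk = _staircase_imposition(sub, [wall_b], [comp_b],
                                             movable_b, spec, ctx,
                                             sub_seed + 13)
        active.append(compensated)

    # sequential restraint impositions in the site: orientational
    # (thetaB, phiB, phiC), then positional (thetaA, phiA)
    def angular_terms(dofs):
        out = []
        for dof in dofs:
            kind = "angle" if dof.startswith("theta") else "dihedral"
            out.append((kind, *_dof_refs(rec, lig, dof), equilibria[dof],
                        spec.k_angle))
        return out

    if spec.imposition_method == "staircase":
        o_terms = angular_terms(_DOF_ORDER[:3])
        dg_o_site = _staircase_imposition(system, [site_wall] + active,
                                          o_terms, movable, spec, ctx,
                                          sub_seed + 17)
        active.extend(o_terms)
        a_terms = angular_terms(_DOF_ORDER[3:])
        dg_a_site = _staircase_imposition(system, [site_wall] + active,
                                          a_terms, movable, spec, ctx,
                                          sub_seed + 23)
        active.extend(a_terms)
    elif spec.imposition_method == "pmf":
        dg_angular = {}
        for k_dof, dof in enumerate(_DOF_ORDER):
            refs = _dof_refs(rec, lig, dof)
            cfg = _angle_cfg(dof, refs, equilibria[dof], spec,
                             sub_seed + 17 + k_dof, temperature)
            extra = restraint_terms_potential([site_wall] + active)
            _, _, prof = run_wtmetad(_copy_system(system), cfg,
                                     spec.steps_angle,
                                     extra_potential=extra,
                                     movable_bodies=movable)
            eq, k_ang = equilibria[dof], spec.k_angle

            def u(s, eq=eq, k=k_ang):
                d = math.radians((s - eq + 180.0) % 360.0 - 180.0)
                return 0.5 * k * d * d

            dg_angular[dof] = imposition_free_energy(prof, u, ctx)
            active.extend(angular_terms([dof]))

        def comb(*names):
            vals = [dg_angular[n] for n in names]
            return (sum(v for v, _ in vals),
                    math.sqrt(sum(e ** 2 for _, e in vals)))

        dg_o_site = comb("thetaB", "phiB", "phiC")
        dg_a_site = comb("thetaA", "phiA")
    else:
        raise ValueError("imposition_method must be 'staircase' or 'pmf'")

    # separation PMF with all restraints on (no site wall), replicate-averaged
    sep_extra = restraint_terms_potential(active)
    sep_cv = DistanceCV(i=a_ref, j=A_ref, name="r")
    replicas = []
    for k_rep in range(spec.n_sep_replicas):
        rep_seed = (sub_seed + 31 + 7 * k_rep) % (2 ** 31 - 1)
        if spec.sep_method == "umbrella":
            lo, hi, spacing = spec.umbrella_span
            centers = np.arange(lo, hi + 0.5 * spacing, spacing)
            prof = umbrella_pmf(_copy_system(system), sep_cv, centers,
                                k_umbrella=spec.k_umbrella,
                                moves_per_window=spec.steps_umbrella,
                                seed=rep_seed, extra_potential=sep_extra,
                                movable_bodies=movable)
        elif spec.sep_method == "metad":
            h0, width, gamma, stride = spec.hill_sep
            lo, hi, n = spec.sep_grid
            cfg_sep = MetaDConfig(cv=sep_cv, h0=h0, width=width,
                                  stride=stride, gamma=gamma, grid_min=lo,
                                  grid_max=hi, n_grid=int(n),
                                  temperature=temperature, seed=rep_seed,
                                  mc_translation=0.45)
            _, _, prof = run_wtmetad(_copy_system(system), cfg_sep,
                                     spec.steps_separation,
                                     extra_potential=sep_extra,
                                     movable_bodies=movable)
        else:
            raise ValueError("sep_method must be 'umbrella' or 'metad'")
        replicas.append(prof)
    sep_prof = average_profiles(replicas).with_r_star(spec.r_star)

    dg_o_bulk = bulk_orientational_term(restraint_spec, ctx, mode="numeric")
    return assemble_step(
        sep_prof, restraint_spec, ctx,
        dg_c_site=0.0, dg_c_bulk=0.0,
        dg_o_site=dg_o_site,
        dg_a_site=dg_a_site,
        dg_o_bulk=dg_o_bulk,
        dg_rmsd_site=dg_rmsd_site, dg_rmsd_bulk=dg_rmsd_bulk,
        site_upper=spec.site_radius,
        bulk_fit_window=(spec.r_star - spec.bulk_fit_margin[0],
                         spec.r_star - spec.bulk_fit_margin[1]),
        label=spec.label or f"remove {spec.ligand_body}")


def run_georoute_protocol(system: RigidBodySystem, steps, ctx: ThermoContext,
                          oligomer_n: int | None = None,
                          sigma: float | None = None,
                          seed: int = 7) -> AssemblyResult:
    """Run the sequential removal protocol and assemble the total.

    ``steps`` is an ordered list of :class:`StepSpec`; after each step the
    removed body is deleted from the working system.  The symmetry
    correction is applied once at the scheme level (sigma defaults to the
    cyclic homomultimer rule 1/n).
    """
    work = _copy_system(system)
    n = oligomer_n or len(system.bodies)
    results = []
    for i, spec in enumerate(steps):
        res = run_step(work, spec, ctx, seed=seed + 101 * i)
        results.append(DissociationStep(spec.ligand_body, res))
        keep = [j for j in range(len(work.bodies))
                if work.bodies[j].name != spec.ligand_body]
        work = work.subsystem(keep)
    scheme = DissociationScheme(oligomer_size=n, steps=tuple(results),
                                sigma=sigma)
    return assemble_scheme(scheme, ctx)


def default_dimer_step(alt_anchors: bool = False, **overrides) -> StepSpec:
    """Stock removal step for the toy homodimer fixture.

    Anchors sit on the axis bead (1), side bead (2) and centre bead (0) of
    each body; the alternative set permutes the outer anchors, leaving the
    separation anchors (a, A) on the body centres.
    """
    if not alt_anchors:
        anchors = ToyAnchors(receptor=(("R", 1), ("R", 2), ("R", 0)),
                             ligand=(("L", 0), ("L", 2), ("L", 1)))
    else:
        # swap the outer receptor anchors (c <-> b): thetaA, phiA and phiB
        # take different equilibria, all still >= 45 deg from 0/180
        anchors = ToyAnchors(receptor=(("R", 2), ("R", 1), ("R", 0)),
                             ligand=(("L", 0), ("L", 2), ("L", 1)))
    return StepSpec(ligand_body="L", anchors=anchors, label="dimer step",
                    **overrides)


def default_trimer_steps(order=("A", "C"), receptor_mode: str = "flat_bottom",
                         **overrides) -> list[StepSpec]:
    """Two removal steps for the toy homotrimer, in the given order.

    ``receptor_mode`` selects how the two-body receptor is kept assembled
    during the first step: a compensated flat-bottom distance restraint
    ("flat_bottom", imposition terms computed in site and bulk) or a plain
    site-definition wall ("wall", part of the species definition, no
    compensation).

    The first step separates a helix from a deeper two-body well, so its
    umbrella ladder defaults to denser, stiffer windows than the dimer's.
    """
    defaults = dict(umbrella_span=(2.0, 10.5, 0.35), k_umbrella=30.0)
    defaults.update(overrides)
    overrides = defaults
    first, second = order
    names = {"A", "B", "C"}
    receptors = sorted(names - {first})
    rec1 = receptors[0]          # anchor-carrying receptor body, step 1
    other1 = receptors[1]
    if receptor_mode == "flat_bottom":
        rr = ("flat_bottom", rec1, other1, 4.0, 0.5, 25.0)
    elif receptor_mode == "wall":
        rr = ("wall", rec1, other1, 7.0, _SITE_WALL_K)
    else:
        raise ValueError("receptor_mode must be 'flat_bottom' or 'wall'")
    rec2 = sorted(names - {first, second})[0]
    step1 = StepSpec(
        ligand_body=first,
        anchors=ToyAnchors(receptor=((rec1, 1), (rec1, 2), (rec1, 0)),
                           ligand=((first, 0), (first, 2), (first, 1))),
        receptor_restraint=rr, label=f"trimer: remove {first}", **overrides)
    step2 = StepSpec(
        ligand_body=second,
        anchors=ToyAnchors(receptor=((rec2, 1), (rec2, 2), (rec2, 0)),
                           ligand=((second, 0), (second, 2), (second, 1))),
        label=f"dimer: remove {second}", **overrides)
    return [step1, step2]
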