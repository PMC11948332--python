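"""Assembly of standard binding free energies from PMFs and corrections.

One dissociation step removes one helix ("ligand") from the remaining
assembly ("receptor").  Its standard binding free energy combines the
sampled PMF contributions with the analytic restraint-release terms:

    dG_bind = -kT ln(S* I* C0)
              - (dG_c^site + dG_o^site + dG_a^site + dG_RMSD^site)
              + (dG_c^bulk + dG_o^bulk + dG_RMSD^bulk)
              + dG_symmetry

where every restraint component is the free energy of *imposing* that
restraint in the named state (site = bound, bulk = dissociated), S* is the
positional surface integral at the bulk reference distance r*, I* the
separation integral of the PMF W(r), C0 the standard concentration and
dG_o^bulk the analytic bulk orientational release term.  The signs follow a
dissociation path restrained in the site, separated to r*, and released in
bulk; they are locked by the toy-system partition-function oracle in the
test suite.

For oligomers larger than dimers the association is decomposed into
sequential one-helix removal steps; the total is the sum over steps plus a
single symmetry correction, and the per-helix value divides by the number
of chains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .corrections import (SymmetryCorrection, ThermoContext, s_star_analytic,
                          s_star_numeric, symmetry_correction)
from .pmf import (PMFProfile, average_profiles, replicate_statistics,
                  separation_integral)
from .restraints import RestraintSpec

__all__ = [
    "Component",
    "StepFreeEnergy",
    "DissociationStep",
    "DissociationScheme",
    "AssemblyResult",
    "assemble_step",
    "assemble_scheme",
    "rmsd_reorganization_term",
]


@dataclass(frozen=True)
class Component:
    """A free-energy component with its standard error (kcal/mol)."""

    value: float
    error: float = 0.0

    @classmethod
    def coerce(cls, x) -> "Component":
        if isinstance(x, Component):
            return x
        if isinstance(x, (tuple, list)) and len(x) == 2:
            return cls(float(x[0]), float(x[1]))
        return cls(float(x))


@dataclass(frozen=True)
class StepFreeEnergy:
    """All free-energy components of one helix-removal step (kcal/mol).

    Restraint components are imposition free energies; ``separation_release``
    is -kT ln(S* I* C0); ``angular_corr`` is the combined release-in-bulk
    diagnostic of the five angular restraints (not part of the sum — its
    content enters through S* and ``dg_o_bulk``); ``symmetry`` is the
    -kT ln(sigma) term when applied at the step level.
    """

    dg_c_site: Component
    dg_o_site: Component
    dg_a_site: Component
    dg_c_bulk: Component
    dg_o_bulk: Component
    separation_release: Component
    s_star: float
    i_star: float
    r_star: float
    dg_rmsd_site: Component | None = None
    dg_rmsd_bulk: Component | None = None
    symmetry: float = 0.0
    angular_corr: float | None = None
    label: str = ""

    @property
    def total(self) -> float:
        t = (self.separation_release.value
             - self.dg_c_site.value - self.dg_o_site.value - self.dg_a_site.value
             + self.dg_c_bulk.value + self.dg_o_bulk.value + self.symmetry)
        if self.dg_rmsd_site is not None:
            t -= self.dg_rmsd_site.value
        if self.dg_rmsd_bulk is not None:
            t += self.dg_rmsd_bulk.value
        return t

    @property
    def error(self) -> float:
        comps = [self.dg_c_site, self.dg_o_site, self.dg_a_site,
                 self.dg_c_bulk, self.dg_o_bulk, self.separation_release]
        if self.dg_rmsd_site is not None:
            comps.append(self.dg_rmsd_site)
        if self.dg_rmsd_bulk is not None:
            comps.append(self.dg_rmsd_bulk)
        return math.sqrt(sum(c.error ** 2 for c in comps))

    def report(self) -> str:
        rows = [("separation + positional release", self.separation_release),
                ("conformational (site)", self.dg_c_site),
                ("orientational (site)", self.dg_o_site),
                ("positional (site)", self.dg_a_site),
                ("conformational (bulk)", self.dg_c_bulk),
                ("orientational (bulk)", self.dg_o_bulk)]
        if self.dg_rmsd_site is not None:
            rows.append(("RMSD (site)", self.dg_rmsd_site))
        if self.dg_rmsd_bulk is not None:
            rows.append(("RMSD (bulk)", self.dg_rmsd_bulk))
        lines = [f"step {self.label or '(unnamed)'}"]
        for name, c in rows:
            lines.append(f"  {name:32s} {c.value:+9.3f} +/- {c.error:.3f} kcal/mol")
        lines.append(f"  {'symmetry':32s} {self.symmetry:+9.3f}")
        lines.append(f"  S* = {self.s_star:.4g} A^2, I* = {self.i_star:.4g} A, "
                     f"r* = {self.r_star:.4g} A")
        lines.append(f"  dG_bind = {self.total:+.3f} +/- {self.error:.3f} kcal/mol")
        return "\n".join(lines)


class MissingComponentError(ValueError):
    pass


def assemble_step(separation: PMFProfile | list[PMFProfile],
                  spec: RestraintSpec,
                  ctx: ThermoContext,
                  *,
                  dg_c_site=None, dg_o_site=None, dg_a_site=None, dg_c_bulk=None,
                  dg_o_bulk=None,
                  dg_rmsd_site=None, dg_rmsd_bulk=None,
                  site_upper: float | None = None,
                  bulk_fit_window: tuple[float, float] | None = None,
                  s_star_mode: str = "numeric",
                  sigma: float | None = None,
                  oligomer_n: int | None = None,
                  label: str = "") -> StepFreeEnergy:
    """Combine PMF components and analytic corrections into one step.

    Required components: ``dg_c_site``, ``dg_o_site``, ``dg_a_site``,
    ``dg_c_bulk`` and ``dg_o_bulk`` (each a float, ``(value, error)`` pair or
    :class:`Component`; pass 0 explicitly for rigid species with no
    conformational freedom), plus the separation PMF (or replicate list) with
    its r*.  RMSD components are optional but must come as a site/bulk pair.
    A symmetry term is added here only when ``sigma`` or ``oligomer_n`` is
    given (single-step schemes); multi-step schemes apply it once at the
    scheme level instead.
    """
    required = {"dg_c_site": dg_c_site, "dg_o_site": dg_o_site,
                "dg_a_site": dg_a_site, "dg_c_bulk": dg_c_bulk,
                "dg_o_bulk": dg_o_bulk}
    missing = [k for k, v in required.items() if v is None]
    if missing:
        raise MissingComponentError(
            "missing required free-energy component(s): " + ", ".join(missing))
    if (dg_rmsd_site is None) != (dg_rmsd_bulk is None):
        raise MissingComponentError(
            "RMSD restraint components must be provided as a site/bulk pair")

    if isinstance(separation, (list, tuple)):
        separation = average_profiles(separation)
    if separation.r_star is None:
        raise ValueError("separation PMF must define r_star")

    i_star, i_err = separation_integral(separation, ctx, site_upper=site_upper,
                                        bulk_fit_window=bulk_fit_window)
    s_star = (s_star_analytic(spec, separation.r_star, ctx)
              if s_star_mode == "analytic"
              else s_star_numeric(spec, separation.r_star, ctx))
    sep_release = -ctx.kT * math.log(s_star * i_star * ctx.c_standard)
    sep_err = ctx.kT * i_err / i_star if i_star > 0 else 0.0

    sym = 0.0
    if sigma is not None or oligomer_n is not None:
        sym = symmetry_correction(oligomer_n or 2, ctx,
                                  sigma_override=sigma).energy

    from .corrections import angular_correction as _ang
    try:
        ang = _ang(spec, ctx, mode="numeric")
    except ValueError:
        ang = None

    return StepFreeEnergy(
        dg_c_site=Component.coerce(dg_c_site),
        dg_o_site=Component.coerce(dg_o_site),
        dg_a_site=Component.coerce(dg_a_site),
        dg_c_bulk=Component.coerce(dg_c_bulk),
        dg_o_bulk=Component.coerce(dg_o_bulk),
        separation_release=Component(sep_release, sep_err),
        s_star=s_star, i_star=i_star, r_star=separation.r_star,
        dg_rmsd_site=None if dg_rmsd_site is None else Component.coerce(dg_rmsd_site),
        dg_rmsd_bulk=None if dg_rmsd_bulk is None else Component.coerce(dg_rmsd_bulk),
        symmetry=sym, angular_corr=ang, label=label)


def rmsd_reorganization_term(step: StepFreeEnergy) -> float:
    """Receptor reorganization diagnostic dG_RMSD^bulk - dG_RMSD^site.

    Positive when imposing the receptor RMSD restraint costs more in the
    unbound state, i.e. the receptor helices rearrange more freely once a
    helix has been removed (loss of internal conformational freedom upon
    binding); negative when the bound receptor is the more mobile one.
    """
    if step.dg_rmsd_site is None or step.dg_rmsd_bulk is None:
        raise MissingComponentError("step has no RMSD restraint components")
    return step.dg_rmsd_bulk.value - step.dg_rmsd_site.value


@dataclass(frozen=True)
class DissociationStep:
    """One helix-removal step: the chain removed and its replicate results."""

    removed_chain: str
    results: tuple[StepFreeEnergy, ...]

    def __init__(self, removed_chain: str, results):
        if isinstance(results, StepFreeEnergy):
            results = (results,)
        object.__setattr__(self, "removed_chain", removed_chain)
        object.__setattr__(self, "results", tuple(results))
        if not self.results:
            raise ValueError("step needs at least one result")

    def combined(self) -> tuple[float, float]:
        """Replicate mean and combined standard error of the step total."""
        totals = [r.total for r in self.results]
        mean, se = replicate_statistics(totals)
        prop = math.sqrt(sum(r.error ** 2 for r in self.results)) / len(self.results)
        if se is None:
            return mean, prop
        return mean, max(se, prop)


@dataclass(frozen=True)
class DissociationScheme:
    """Ordered one-helix removal steps decomposing an n-mer dissociation.

    The last helix needs no step, so an n-mer has n-1 steps and each removed
    chain appears exactly once.
    """

    oligomer_size: int
    steps: tuple[DissociationStep, ...]
    sigma: float | None = None  # override for the symmetry factor

    def __post_init__(self):
        if self.oligomer_size < 2:
            raise ValueError("oligomer size must be >= 2")
        if len(self.steps) != self.oligomer_size - 1:
            raise ValueError(
                f"an n-mer scheme needs n-1 steps: got {len(self.steps)} for "
                f"n = {self.oligomer_size}")
        removed = [s.removed_chain for s in self.steps]
        if len(set(removed)) != len(removed):
            raise ValueError("each chain may be removed only once")


@dataclass(frozen=True)
class AssemblyResult:
    """Assembled association free energy of an n-mer (kcal/mol)."""

    scheme: DissociationScheme
    step_totals: tuple[tuple[float, float], ...]
    symmetry: SymmetryCorrection
    total: float
    total_error: float

    @property
    def per_helix(self) -> float:
        return self.total / self.scheme.oligomer_size

    @property
    def per_helix_error(self) -> float:
        return self.total_error / self.scheme.oligomer_size

    def report(self) -> str:
        lines = [f"dissociation scheme: n = {self.scheme.oligomer_size}"]
        for step, (v, e) in zip(self.scheme.steps, self.step_totals):
            lines.append(f"  remove chain {step.removed_chain}: "
                         f"{v:+8.3f} +/- {e:.3f} kcal/mol")
        lines.append(f"  symmetry (sigma = {self.symmetry.sigma:g}): "
                     f"{self.symmetry.energy:+8.3f} kcal/mol")
        lines.append(f"  total    dG_bind = {self.total:+8.3f} +/- "
                     f"{self.total_error:.3f} kcal/mol")
        lines.append(f"  per helix        = {self.per_helix:+8.3f} +/- "
                     f"{self.per_helix_error:.3f} kcal/mol")
        return "\n".join(lines)


def assemble_scheme(scheme: DissociationScheme, ctx: ThermoContext) -> AssemblyResult:
    """Sum the step free energies and apply the symmetry correction once.

    Step-level symmetry terms must be zero (the correction belongs to the
    assembled complex, not to an individual removal).  Replicate step results
    are averaged with standard-error combination.
    """
    if any(r.symmetry != 0.0 for s in scheme.steps for r in s.results):
        raise ValueError("steps inside a scheme must not carry their own "
                         "symmetry terms; the scheme applies it once")
    sym = symmetry_correction(scheme.oligomer_size, ctx,
                              sigma_override=scheme.sigma)
    combined = tuple(s.combined() for s in scheme.steps)
    total = sum(v for v, _ in combined) + sym.energy
    err = math.sqrt(sum(e ** 2 for _, e in combined))
    return AssemblyResult(scheme=scheme, step_totals=combined, symmetry=sym,
                          total=total, total_error=err)
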