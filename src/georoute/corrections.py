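"""Restraint-release corrections of the geometrical route.

This module evaluates every analytic term that accompanies the sampled PMFs
when assembling a standard binding free energy:

* ``S*`` — the surface-area integral describing the positional freedom of
  the ligand anchor on a sphere of radius ``r*`` under the theta_A/phi_A
  restraints,

      S* = (r*)^2 * Int exp(-beta*u_a) sin(theta_A) dtheta_A dphi_A,

* the bulk orientational integral over theta_B, phi_B, phi_C,

      Omega_o = Int exp(-beta*u_o) sin(theta_B) dtheta_B dphi_B dphi_C,

  whose unrestrained value is the full angular volume 8*pi^2,

* their stiff-restraint Gaussian closed forms
  (S* ~ (r*)^2 sin(theta_A0) * 2*pi*kT / sqrt(K_thetaA*K_phiA) and
  Omega_o ~ sin(theta_B0) * (2*pi*kT)^{3/2} / sqrt(K_thetaB*K_phiB*K_phiC)),

* the angular correction free energy combining the five angular restraint
  integrals against their unrestrained angular volumes,

* standard-state constants (V deg = 1661 A^3 per molecule at 1 M, the
  standard-state distance r deg and surface area A deg), and

* the symmetry correction for homomultimers of identical chains.

The closed forms assume the Gaussian integrals can be extended to +/-inf and
sin(theta) frozen at sin(theta_0); both hold for stiff, well-placed
restraints (equilibrium angles well away from 0/180 degrees).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate

from .restraints import RestraintSpec

__all__ = [
    "KB_KCAL_MOL_K",
    "ThermoContext",
    "standard_state",
    "s_star_numeric",
    "s_star_analytic",
    "orientational_integral_numeric",
    "orientational_analytic",
    "bulk_orientational_term",
    "angular_correction",
    "SymmetryCorrection",
    "symmetry_correction",
    "QuadratureError",
]

#: Boltzmann constant in kcal/mol/K
KB_KCAL_MOL_K = 1.987204259e-3

#: rounded standard-state volume (A^3 per molecule at 1 M), as printed
V_STANDARD_ROUNDED = 1661.0
#: unrounded value, 1e27 / N_A
V_STANDARD_EXACT = 1.0e27 / 6.02214076e23


class QuadratureError(RuntimeError):
    """Raised when an adaptive angular quadrature fails to converge."""


@dataclass(frozen=True)
class ThermoContext:
    """Temperature-dependent constants used throughout the assembly.

    Attributes
    ----------
    temperature : K
    kB : kcal/mol/K
    v_standard : standard-state volume per molecule (A^3; 1661 at 1 M)
    """

    temperature: float = 298.15
    kB: float = KB_KCAL_MOL_K
    v_standard: float = V_STANDARD_ROUNDED

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")

    @property
    def kT(self) -> float:
        return self.kB * self.temperature

    @property
    def beta(self) -> float:
        return 1.0 / self.kT

    @property
    def c_standard(self) -> float:
        """Standard concentration in molecules per A^3."""
        return 1.0 / self.v_standard

    @property
    def r_standard(self) -> float:
        """Radius of a sphere of standard-state volume (A)."""
        return (3.0 * self.v_standard / (4.0 * math.pi)) ** (1.0 / 3.0)

    @property
    def a_standard(self) -> float:
        """Surface area of a sphere of standard-state volume (A^2)."""
        return 4.0 * math.pi * self.r_standard ** 2


def standard_state(temperature: float = 298.15, rounded: bool = True) -> ThermoContext:
    """Thermodynamic context at the 1 M standard state.

    With ``rounded=True`` the per-molecule volume is the printed 1661 A^3;
    otherwise the unrounded 1e27/N_A value is used.
    """
    return ThermoContext(temperature=temperature,
                         v_standard=V_STANDARD_ROUNDED if rounded else V_STANDARD_EXACT)


# ---------------------------------------------------------------------------
# one-dimensional angular Boltzmann integrals (the restraint terms separate)

_REL_TOL = 1e-10


def _quad(fn, a, b, points=None) -> float:
    val, err = integrate.quad(fn, a, b, epsabs=0.0, epsrel=_REL_TOL,
                              limit=400, points=points)
    if not math.isfinite(val) or (val != 0.0 and err / abs(val) > 1e-8):
        # documented fallback: fixed 201-point Gauss-Legendre grid
        x, w = np.polynomial.legendre.leggauss(201)
        xs = 0.5 * (b - a) * x + 0.5 * (a + b)
        val_gl = 0.5 * (b - a) * float(np.sum(w * np.vectorize(fn)(xs)))
        if not math.isfinite(val_gl):
            raise QuadratureError(
                f"angular quadrature failed: adaptive value {val} (err {err}), "
                f"Gauss-Legendre value {val_gl}")
        return val_gl
    return val


def _theta_integral(ctx: ThermoContext, term) -> float:
    """Int_0^pi exp(-beta*0.5*K*(theta-theta0)^2) sin(theta) dtheta."""
    if term is None or term.k == 0.0:
        return 2.0
    beta_k = ctx.beta * term.k
    t0 = math.radians(term.equilibrium)

    def f(t):
        d = t - t0
        return math.exp(-0.5 * beta_k * d * d) * math.sin(t)

    return _quad(f, 0.0, math.pi, points=[t0])


def _dihedral_integral(ctx: ThermoContext, term) -> float:
    """Int over one period of exp(-beta*0.5*K*d(phi,phi0)^2) dphi.

    d is the minimum-image angular difference; by periodicity the value is
    independent of phi0.
    """
    if term is None or term.k == 0.0:
        return 2.0 * math.pi
    beta_k = ctx.beta * term.k

    def f(d):
        return math.exp(-0.5 * beta_k * d * d)

    # integrate the centred deviation over (-pi, pi]
    return _quad(f, -math.pi, math.pi, points=[0.0])


def s_star_numeric(spec: RestraintSpec, r_star: float, ctx: ThermoContext) -> float:
    """Surface-area integral S* in A^2 by adaptive quadrature.

    Only restraints on theta_A and phi_A enter; the result scales exactly as
    (r*)^2.
    """
    if r_star <= 0:
        raise ValueError("r_star must be > 0")
    return r_star ** 2 * _theta_integral(ctx, spec.get("thetaA")) * \
        _dihedral_integral(ctx, spec.get("phiA"))


def orientational_integral_numeric(spec: RestraintSpec, ctx: ThermoContext) -> float:
    """Orientational Boltzmann volume over theta_B, phi_B, phi_C.

    Unrestrained value is 8*pi^2 (= 4*pi * 2*pi).
    """
    return _theta_integral(ctx, spec.get("thetaB")) * \
        _dihedral_integral(ctx, spec.get("phiB")) * \
        _dihedral_integral(ctx, spec.get("phiC"))


def _require_stiff(spec: RestraintSpec, names) -> list:
    terms = []
    for n in names:
        t = spec.get(n)
        if t is None or t.k <= 0.0:
            raise ValueError(
                f"closed form requires a nonzero force constant on {n}; "
                "use the numeric route for unrestrained DOFs")
        terms.append(t)
    return terms


def s_star_analytic(spec: RestraintSpec, r_star: float, ctx: ThermoContext) -> float:
    """Gaussian closed form of S* (stiff-restraint limit)."""
    if r_star <= 0:
        raise ValueError("r_star must be > 0")
    t_theta, t_phi = _require_stiff(spec, ("thetaA", "phiA"))
    sin0 = math.sin(math.radians(t_theta.equilibrium))
    return r_star ** 2 * sin0 * 2.0 * math.pi * ctx.kT / \
        math.sqrt(t_theta.k * t_phi.k)


def orientational_analytic(spec: RestraintSpec, ctx: ThermoContext) -> float:
    """Gaussian closed form of the orientational integral."""
    t_theta, t_phib, t_phic = _require_stiff(spec, ("thetaB", "phiB", "phiC"))
    sin0 = math.sin(math.radians(t_theta.equilibrium))
    return sin0 * (2.0 * math.pi * ctx.kT) ** 1.5 / \
        math.sqrt(t_theta.k * t_phib.k * t_phic.k)


def bulk_orientational_term(spec: RestraintSpec, ctx: ThermoContext,
                            mode: str = "numeric") -> float:
    """Free energy of imposing the orientational restraints in bulk (kcal/mol).

    Delta G_o^bulk = -kT * ln(Omega_o / 8 pi^2);  positive for stiff
    restraints (restraining costs free energy), zero when unrestrained.  In
    the assembled binding free energy this term enters with a plus sign: the
    restraints are released in the bulk after dissociation.
    """
    omega = (orientational_analytic(spec, ctx) if mode == "analytic"
             else orientational_integral_numeric(spec, ctx))
    return -ctx.kT * math.log(omega / (8.0 * math.pi ** 2))


def angular_correction(spec: RestraintSpec, ctx: ThermoContext,
                       mode: str = "numeric") -> float:
    """Free energy of releasing all five angular restraints in bulk (kcal/mol).

    Combines the positional-angle integral (theta_A, phi_A, against the full
    solid angle 4*pi) and the orientational integral (theta_B, phi_B, phi_C,
    against 8*pi^2):

        dG_corr = -kT ln[(Omega_a / 4 pi) * (Omega_o / 8 pi^2)]

    It is zero when unrestrained, positive and monotonically increasing in
    every force constant, and independent of the dihedral equilibrium values.
    """
    if mode == "analytic":
        omega_a = s_star_analytic(spec, 1.0, ctx)
        omega_o = orientational_analytic(spec, ctx)
    else:
        omega_a = s_star_numeric(spec, 1.0, ctx)
        omega_o = orientational_integral_numeric(spec, ctx)
    return -ctx.kT * math.log((omega_a / (4.0 * math.pi)) *
                              (omega_o / (8.0 * math.pi ** 2)))


# ---------------------------------------------------------------------------
# symmetry correction


@dataclass(frozen=True)
class SymmetryCorrection:
    """Indistinguishability correction for a homomultimer of n identical chains.

    ``sigma`` multiplies the labelled (simulation) binding constant to give
    the physical one; the additive free-energy correction is -kT * ln(sigma).
    For a cyclic (C_n) homomultimer sigma = 1/n, so the correction is
    +kT * ln(n): indistinguishability makes association less favourable than
    the labelled calculation suggests.
    """

    n: int
    sigma: float
    energy: float  # kcal/mol, add to the assembled binding free energy


def symmetry_correction(n: int, ctx: ThermoContext,
                        sigma_override: float | None = None) -> SymmetryCorrection:
    """Symmetry correction for an n-mer of identical chains.

    The default rule is the cyclic-homomultimer count sigma = 1/n (for a
    homodimer sigma = 1/2, giving |correction| = kT*ln 2 ~ 0.41 kcal/mol at
    298.15 K).  Complexes with a different point group can override sigma;
    sigma = 1 yields no correction.
    """
    if n < 2:
        raise ValueError("oligomer size n must be >= 2")
    sigma = (1.0 / n) if sigma_override is None else float(sigma_override)
    if sigma <= 0:
        raise ValueError("symmetry factor sigma must be > 0")
    return SymmetryCorrection(n=n, sigma=sigma, energy=-ctx.kT * math.log(sigma))
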