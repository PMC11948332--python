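"""One-dimensional PMF profiles: container, text I/O and window integrals.

A :class:`PMFProfile` is a tabulated free-energy profile W(s) over a strictly
increasing grid of one collective variable, with optional per-point standard
errors and, for separation PMFs, the bulk reference distance ``r*``.

File format: UTF-8 delimited text, ``#`` comment lines carrying metadata
(cv name, units, r_star), then four whitespace-separated columns
``cv  value  free_energy  error`` (point grid, not bins).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .corrections import ThermoContext

__all__ = [
    "PMFProfile",
    "read_pmf",
    "write_pmf",
    "pmf_delta",
    "bulk_reference_value",
    "separation_integral",
    "imposition_free_energy",
    "average_profiles",
    "replicate_statistics",
]


@dataclass(frozen=True)
class PMFProfile:
    """Free energy W (kcal/mol) tabulated over one collective variable."""

    cv: str
    units: str
    grid: np.ndarray
    w: np.ndarray
    error: np.ndarray | None = None
    r_star: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "grid", np.asarray(self.grid, dtype=float))
        object.__setattr__(self, "w", np.asarray(self.w, dtype=float))
        if self.grid.ndim != 1 or self.grid.size < 2:
            raise ValueError("PMF grid must be 1-D with at least two points")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("PMF grid must be strictly increasing")
        if self.w.shape != self.grid.shape or not np.all(np.isfinite(self.w)):
            raise ValueError("free energies must be finite and match the grid")
        if self.error is not None:
            err = np.asarray(self.error, dtype=float)
            if err.shape != self.grid.shape:
                raise ValueError("error array must match the grid")
            object.__setattr__(self, "error", err)
        if self.r_star is not None:
            if not (self.grid[0] <= self.r_star <= self.grid[-1]):
                raise ValueError("r_star must lie within the grid")

    def value_at(self, s: float) -> float:
        return float(np.interp(s, self.grid, self.w))

    def error_at(self, s: float) -> float:
        if self.error is None:
            return 0.0
        return float(np.interp(s, self.grid, self.error))

    def shifted(self, offset: float) -> "PMFProfile":
        return replace(self, w=self.w + offset)

    def with_r_star(self, r_star: float) -> "PMFProfile":
        return replace(self, r_star=r_star)


def write_pmf(profile: PMFProfile, path) -> None:
    lines = [f"# cv_name: {profile.cv}", f"# units: {profile.units}"]
    if profile.r_star is not None:
        lines.append(f"# r_star: {profile.r_star!r}")
    lines.append("# columns: cv value free_energy error")
    err = profile.error if profile.error is not None else np.zeros_like(profile.grid)
    for s, w, e in zip(profile.grid, profile.w, err):
        lines.append(f"{profile.cv} {s:.10g} {w:.10g} {e:.10g}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_pmf(path) -> PMFProfile:
    cv_name, units, r_star = "cv", "", None
    grid, w, err = [], [], []
    text = Path(path).read_text(encoding="utf-8")
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, val = body.partition(":")
                key = key.strip().lower()
                if key == "cv_name":
                    cv_name = val.strip()
                elif key == "units":
                    units = val.strip()
                elif key == "r_star":
                    r_star = float(val)
            continue
        parts = line.split()
        if len(parts) != 4:
            raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
        try:
            grid.append(float(parts[1]))
            w.append(float(parts[2]))
            err.append(float(parts[3]))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed record: {exc}") from None
    error = np.asarray(err) if any(e != 0.0 for e in err) else None
    return PMFProfile(cv=cv_name, units=units, grid=np.asarray(grid),
                      w=np.asarray(w), error=error, r_star=r_star)


def _window_mask(profile: PMFProfile, window: tuple[float, float]) -> np.ndarray:
    lo, hi = min(window), max(window)
    mask = (profile.grid >= lo) & (profile.grid <= hi)
    if not np.any(mask):
        raise ValueError(f"window {window} contains no grid points")
    return mask


def _window_free_energy(profile: PMFProfile, window, ctx: ThermoContext,
                        convention: str) -> tuple[float, float]:
    mask = _window_mask(profile, window)
    w = profile.w[mask]
    s = profile.grid[mask]
    e = profile.error[mask] if profile.error is not None else np.zeros_like(w)
    if convention == "min":
        i = int(np.argmin(w))
        return float(w[i]), float(e[i])
    if convention != "boltzmann":
        raise ValueError("convention must be 'boltzmann' or 'min'")
    # Boltzmann-averaged window free energy, robust to grid noise
    wmin = w.min()
    bw = np.exp(-ctx.beta * (w - wmin))
    if s.size > 1:
        z = np.trapezoid(bw, s)
        p = bw * np.gradient(s) / z
    else:
        z = bw.sum()
        p = bw / z
    f = wmin - ctx.kT * math.log(z)
    sigma = math.sqrt(float(np.sum((p * e) ** 2)))
    return float(f), sigma


def pmf_delta(profile: PMFProfile, bound_window: tuple[float, float],
              unbound_window: tuple[float, float],
              ctx: ThermoContext | None = None,
              convention: str = "boltzmann") -> tuple[float, float]:
    """Free-energy difference F(unbound window) - F(bound window).

    Each window free energy is a Boltzmann average over the window by
    default ("min" selects the pointwise minimum instead).  Returns
    (delta, standard error).
    """
    ctx = ctx or ThermoContext()
    fb, eb = _window_free_energy(profile, bound_window, ctx, convention)
    fu, eu = _window_free_energy(profile, unbound_window, ctx, convention)
    return fu - fb, math.hypot(eb, eu)


def bulk_reference_value(profile: PMFProfile, r_star: float,
                         fit_window: tuple[float, float],
                         ctx: ThermoContext,
                         jacobian_power: float = 2.0) -> float:
    """W(r*) from a fit of the analytic bulk law over a plateau window.

    Beyond the interaction range, a radial separation PMF with
    r-independent angular restraints follows W(r) = -p kT ln(r) + c exactly
    (p = 2 for the spherical-shell Jacobian).  Fitting c over a bulk window
    and evaluating at r* is far more robust than reading a single noisy
    grid value, especially near grid edges.
    """
    lo, hi = min(fit_window), max(fit_window)
    mask = (profile.grid >= lo) & (profile.grid <= hi)
    if mask.sum() < 2:
        raise ValueError("bulk fit window contains fewer than two grid points")
    c = float(np.mean(profile.w[mask]
                      + jacobian_power * ctx.kT * np.log(profile.grid[mask])))
    return c - jacobian_power * ctx.kT * math.log(r_star)


def separation_integral(profile: PMFProfile, ctx: ThermoContext,
                        site_upper: float | None = None,
                        bulk_fit_window: tuple[float, float] | None = None) -> tuple[float, float]:
    """I* = Int_site exp(-beta [W(r) - W(r*)]) dr on the tabulated grid (A).

    The site region runs from the start of the grid to ``site_upper``
    (default: r* itself).  W(r*) is interpolated from the profile, or, if
    ``bulk_fit_window`` is given, taken from the analytic bulk-law fit of
    :func:`bulk_reference_value`.  Returns (I*, standard error); adding a
    constant to W leaves I* unchanged.
    """
    if profile.r_star is None:
        raise ValueError("separation PMF requires r_star")
    upper = profile.r_star if site_upper is None else float(site_upper)
    mask = profile.grid <= upper
    if mask.sum() < 2:
        raise ValueError("site region contains fewer than two grid points")
    r = profile.grid[mask]
    if bulk_fit_window is not None:
        w_ref = bulk_reference_value(profile, profile.r_star, bulk_fit_window, ctx)
    else:
        w_ref = profile.value_at(profile.r_star)
    dw = profile.w[mask] - w_ref
    integrand = np.exp(-ctx.beta * dw)
    i_star = float(np.trapezoid(integrand, r))
    # error: quadrature sum over independent per-point errors + r* reference
    if profile.error is not None:
        weights = integrand * np.gradient(r)
        sig2 = float(np.sum((ctx.beta * weights * profile.error[mask]) ** 2))
        sig2 += (ctx.beta * i_star * profile.error_at(profile.r_star)) ** 2
        err = math.sqrt(sig2)
    else:
        err = 0.0
    return i_star, err


def imposition_free_energy(profile: PMFProfile, potential,
                           ctx: ThermoContext) -> tuple[float, float]:
    """Free energy of imposing a restraint u(s) on the ensemble behind W(s).

        dG = -kT ln [ Int exp(-beta (W + u)) ds / Int exp(-beta W) ds ]

    ``potential`` maps a CV value (grid units) to kcal/mol.  The PMF is
    assumed to carry the full Jacobian of its ensemble, as profiles
    reconstructed from biased sampling along the CV do.  Returns
    (dG, standard error).
    """
    u = np.asarray([potential(s) for s in profile.grid], dtype=float)
    wmin = profile.w.min()
    a = np.exp(-ctx.beta * (profile.w - wmin))
    b = np.exp(-ctx.beta * (profile.w + u - wmin - u.min()))
    ds = np.gradient(profile.grid)
    za = float(np.sum(a * ds))
    zb = float(np.sum(b * ds))
    dg = -ctx.kT * math.log(zb / za) + u.min()
    if profile.error is not None:
        pa = a * ds / za
        pb = b * ds / zb
        err = math.sqrt(float(np.sum(((pb - pa) * profile.error) ** 2)))
    else:
        err = 0.0
    return dg, err


def average_profiles(profiles, n_grid: int | None = None) -> PMFProfile:
    """Average replicate PMFs on a common linearly interpolated grid.

    The common grid spans the overlap of all replicates; the per-point error
    is the standard error over replicates (combined in quadrature with the
    mean of any per-replicate errors).
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no profiles to average")
    if len(profiles) == 1:
        return profiles[0]
    lo = max(p.grid[0] for p in profiles)
    hi = min(p.grid[-1] for p in profiles)
    if hi <= lo:
        raise ValueError("replicate PMFs do not overlap")
    n = n_grid or max(p.grid.size for p in profiles)
    grid = np.linspace(lo, hi, n)
    ws = np.stack([np.interp(grid, p.grid, p.w) for p in profiles])
    # each replicate is defined up to an additive constant: align on the mean
    ws = ws - ws.mean(axis=1, keepdims=True)
    mean = ws.mean(axis=0)
    se = ws.std(axis=0, ddof=1) / math.sqrt(len(profiles))
    reps_err = [np.interp(grid, p.grid, p.error) for p in profiles
                if p.error is not None]
    if reps_err:
        se = np.sqrt(se ** 2 + (np.stack(reps_err).mean(axis=0) ** 2) / len(profiles))
    first = profiles[0]
    return PMFProfile(cv=first.cv, units=first.units, grid=grid, w=mean,
                      error=se, r_star=first.r_star)


def replicate_statistics(values) -> tuple[float, float | None]:
    """Mean and standard error (SD/sqrt(n)) over replicate estimates.

    With fewer than two replicates the standard error is None (flagged
    absent) rather than zero.
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("no replicate values")
    mean = float(vals.mean())
    if vals.size < 2:
        return mean, None
    return mean, float(vals.std(ddof=1) / math.sqrt(vals.size))
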