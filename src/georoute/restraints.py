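"""Restraint potentials of the geometrical-route protocol and anchor selection.

Implements the harmonic Boresch restraint set on the six external degrees of
freedom, flat-bottom torsion restraints preserving helicity, flat-bottom RMSD
restraints preventing receptor rearrangement, the funnel (cone + cylinder)
wall confining a dissociating partner, and automated anchor-point selection
with circular-statistics stability diagnostics.

Units: force constants are kcal/mol/A^2 for distances and kcal/mol/rad^2 for
angles and dihedrals; equilibrium values are given in angstrom / degrees.
All restraint energies are >= 0, zero at the reference configuration, and
continuous in value and first derivative at flat-bottom boundaries.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .geometry import (AnchorSet, AtomRef, BoreschDOF, Coordinates,
                       DegenerateGeometryError, measure_angle,
                       measure_boresch, measure_dihedral, optimal_rmsd,
                       wrap_deg)

__all__ = [
    "HarmonicTerm",
    "RestraintSpec",
    "TorsionRestraint",
    "TorsionRestraintSet",
    "RMSDRestraint",
    "FunnelSpec",
    "AnchorDiagnostics",
    "NoValidAnchorsError",
    "boresch_energy",
    "torsion_restraint_energy",
    "rmsd_restraint_energy",
    "funnel_energy",
    "select_anchors",
    "circular_mean_deg",
    "circular_std_deg",
]

BORESCH_DOF_NAMES = ("r", "thetaA", "thetaB", "phiA", "phiB", "phiC")
_ANGULAR = {"thetaA", "thetaB"}
_DIHEDRAL = {"phiA", "phiB", "phiC"}


@dataclass(frozen=True)
class HarmonicTerm:
    """One restrained degree of freedom: 0.5*K*(x - x0)^2.

    `equilibrium` in angstrom (r) or degrees (angles/dihedrals); `k` in
    kcal/mol/A^2 or kcal/mol/rad^2 respectively.
    """

    dof: str
    equilibrium: float
    k: float

    def __post_init__(self):
        if self.dof not in BORESCH_DOF_NAMES:
            raise ValueError(f"unknown Boresch DOF {self.dof!r}")
        if self.k < 0:
            raise ValueError("force constant must be >= 0")
        if self.dof in _ANGULAR and not (0.0 < self.equilibrium < 180.0):
            raise ValueError(
                f"{self.dof} equilibrium must lie in (0, 180) degrees "
                "(the sine factor must be nonzero)")


class RestraintSpec:
    """Force constants and equilibrium values for the Boresch restraint set."""

    def __init__(self, terms: Iterable[HarmonicTerm]):
        self.terms: dict[str, HarmonicTerm] = {}
        for t in terms:
            if t.dof in self.terms:
                raise ValueError(f"duplicate restraint on {t.dof}")
            self.terms[t.dof] = t

    @classmethod
    def from_dict(cls, entries: Mapping[str, tuple[float, float]]) -> "RestraintSpec":
        """Build from {dof: (equilibrium, force constant)}."""
        return cls(HarmonicTerm(dof, eq, k) for dof, (eq, k) in entries.items())

    @classmethod
    def from_config(cls, entries: Mapping[str, Mapping[str, float]]) -> "RestraintSpec":
        """Build from {dof: {"equilibrium": ..., "k": ...}} (config files)."""
        return cls(HarmonicTerm(dof, float(v["equilibrium"]), float(v["k"]))
                   for dof, v in entries.items())

    @classmethod
    def from_dof(cls, dof: BoreschDOF, k_r: float = 10.0, k_ang: float = 100.0) -> "RestraintSpec":
        """Restrain every Boresch DOF at its current value."""
        vals = dof.as_dict()
        return cls(HarmonicTerm(n, vals[n], k_r if n == "r" else k_ang)
                   for n in BORESCH_DOF_NAMES)

    def get(self, dof: str) -> HarmonicTerm | None:
        return self.terms.get(dof)

    def scaled(self, factor: float) -> "RestraintSpec":
        """Return a copy with every force constant multiplied by `factor`."""
        return RestraintSpec(HarmonicTerm(t.dof, t.equilibrium, t.k * factor)
                             for t in self.terms.values())

    def to_dict(self) -> dict[str, dict[str, float]]:
        return {t.dof: {"equilibrium": t.equilibrium, "k": t.k}
                for t in self.terms.values()}

    def __repr__(self):
        items = ", ".join(f"{t.dof}={t.equilibrium:g}(k={t.k:g})"
                          for t in self.terms.values())
        return f"RestraintSpec({items})"


def _deviation(dof_name: str, value: float, equilibrium: float) -> float:
    """Deviation in radians (r term: angstrom), minimum-image for dihedrals."""
    if dof_name == "r":
        return value - equilibrium
    if dof_name in _DIHEDRAL:
        return math.radians(wrap_deg(value - equilibrium))
    return math.radians(value - equilibrium)


def boresch_energy(dof: BoreschDOF, spec: RestraintSpec) -> float:
    """Total harmonic Boresch restraint energy in kcal/mol.

    Dihedral deviations are taken as the minimum-image angular difference in
    (-180, 180], so a +190 degree deviation scores identically to -170.
    """
    vals = dof.as_dict()
    e = 0.0
    for t in spec.terms.values():
        d = _deviation(t.dof, vals[t.dof], t.equilibrium)
        e += 0.5 * t.k * d * d
    return e


@dataclass(frozen=True)
class TorsionRestraint:
    chain: str
    residue: int
    torsion: str  # "phi" | "psi"
    center: float  # degrees
    k: float  # kcal/mol/rad^2
    half_width: float = 0.0  # degrees; 0 => pure harmonic

    def __post_init__(self):
        if self.torsion not in ("phi", "psi"):
            raise ValueError("torsion must be 'phi' or 'psi'")
        if self.half_width < 0 or self.k < 0:
            raise ValueError("half_width and k must be >= 0")


class TorsionRestraintSet:
    """Flat-bottom harmonic restraints on backbone phi/psi torsions."""

    def __init__(self, restraints: Iterable[TorsionRestraint]):
        self.restraints = list(restraints)

    @classmethod
    def helical(cls, coords: Coordinates, chains: Iterable[str],
                phi0: float = -57.0, psi0: float = -47.0,
                k: float = 100.0, half_width: float = 0.0) -> "TorsionRestraintSet":
        """Restrain every measurable phi/psi of the given chains to helix values."""
        from .geometry import backbone_torsions
        out = []
        for ch in chains:
            for rec in backbone_torsions(coords, ch):
                if rec.phi is not None:
                    out.append(TorsionRestraint(ch, rec.residue, "phi", phi0, k, half_width))
                if rec.psi is not None:
                    out.append(TorsionRestraint(ch, rec.residue, "psi", psi0, k, half_width))
        return cls(out)


def flat_bottom_energy(deviation_rad: float, k: float, half_width_rad: float) -> float:
    """0 inside |d| <= w, half-harmonic 0.5*K*(|d|-w)^2 outside."""
    excess = abs(deviation_rad) - half_width_rad
    return 0.5 * k * excess * excess if excess > 0.0 else 0.0


def torsion_restraint_energy(coords: Coordinates, restraint_set: TorsionRestraintSet) -> float:
    """Total flat-bottom torsion restraint energy in kcal/mol."""
    from .geometry import backbone_torsions
    by_chain: dict[str, dict[int, object]] = {}
    e = 0.0
    for r in restraint_set.restraints:
        if r.chain not in by_chain:
            by_chain[r.chain] = {rec.residue: rec
                                 for rec in backbone_torsions(coords, r.chain)}
        rec = by_chain[r.chain].get(r.residue)
        value = getattr(rec, r.torsion, None) if rec is not None else None
        if value is None:
            raise ValueError(
                f"torsion {r.torsion} of chain {r.chain} residue {r.residue} "
                "is not measurable")
        d = math.radians(wrap_deg(value - r.center))
        e += flat_bottom_energy(d, r.k, math.radians(r.half_width))
    return e


@dataclass
class RMSDRestraint:
    """Flat-bottom restraint on the optimal-superposition RMSD to a reference."""

    reference: Coordinates
    selection: np.ndarray  # atom indices, matched order in reference & mobile
    k: float  # kcal/mol/A^2
    flat_radius: float = 0.0  # angstrom

    def __post_init__(self):
        if self.k < 0 or self.flat_radius < 0:
            raise ValueError("k and flat_radius must be >= 0")
        self.selection = np.asarray(self.selection, dtype=int)


def rmsd_restraint_energy(coords: Coordinates, restraint: RMSDRestraint) -> float:
    """0.5*K*max(0, RMSD - flat_radius)^2 in kcal/mol."""
    rmsd = optimal_rmsd(coords, restraint.reference,
                        selection=restraint.selection,
                        reference_selection=restraint.selection)
    excess = rmsd - restraint.flat_radius
    return 0.5 * restraint.k * excess * excess if excess > 0.0 else 0.0


@dataclass(frozen=True)
class FunnelSpec:
    """Cone + cylinder wall confining the translational space of a ligand.

    The funnel axis runs from `p0` (binding site) towards `p1` (bulk).  For
    axial distances z below `switch_distance` the boundary radius follows the
    cone law  R(z) = cylinder_radius + tan(half_angle) * (switch_distance - z),
    beyond it the constant `cylinder_radius`; the two meet continuously at the
    switch.  Outside the boundary a half-harmonic wall of force constant
    `wall_k` acts on the radial excess.
    """

    p0: tuple[float, float, float]
    p1: tuple[float, float, float]
    half_angle: float  # degrees
    cylinder_radius: float  # angstrom
    switch_distance: float  # angstrom along the axis
    wall_k: float  # kcal/mol/A^2

    def __post_init__(self):
        if np.allclose(self.p0, self.p1):
            raise ValueError("funnel axis points must be distinct")
        if self.cylinder_radius <= 0:
            raise ValueError("cylinder radius must be > 0")
        if self.wall_k < 0:
            raise ValueError("wall force constant must be >= 0")

    def boundary_radius(self, z: float) -> float:
        if z < self.switch_distance:
            return self.cylinder_radius + math.tan(math.radians(self.half_angle)) * \
                (self.switch_distance - z)
        return self.cylinder_radius


def funnel_energy(position, spec: FunnelSpec) -> float:
    """Half-harmonic wall penalty on the radial excess outside the funnel."""
    p0 = np.asarray(spec.p0, dtype=float)
    p1 = np.asarray(spec.p1, dtype=float)
    axis = p1 - p0
    axis = axis / np.linalg.norm(axis)
    rel = np.asarray(position, dtype=float) - p0
    z = float(rel @ axis)
    rho = float(np.linalg.norm(rel - z * axis))
    excess = rho - spec.boundary_radius(z)
    return 0.5 * spec.wall_k * excess * excess if excess > 0.0 else 0.0


# ---------------------------------------------------------------------------
# anchor selection


def circular_mean_deg(values_deg) -> float:
    v = np.radians(np.asarray(values_deg, dtype=float))
    return float(np.degrees(np.arctan2(np.sin(v).mean(), np.cos(v).mean())))


def circular_std_deg(values_deg) -> float:
    v = np.radians(np.asarray(values_deg, dtype=float))
    R = float(np.hypot(np.sin(v).mean(), np.cos(v).mean()))
    R = min(max(R, 1e-300), 1.0)
    return float(np.degrees(math.sqrt(-2.0 * math.log(R))))


_DIAG_DOFS = ("thetaA", "thetaB", "phiA", "phiB", "phiC", "angle_cba", "angle_ABC")


@dataclass
class AnchorDiagnostics:
    """Per-DOF circular statistics over frames plus the pass/fail verdict.

    `margin` is the minimum distance of the circular mean to 0/180 degrees
    (for angles) or the wrap-aware spread criterion for dihedrals.
    """

    means: dict[str, float]
    stds: dict[str, float]
    margins: dict[str, float]
    min_separation: float
    verdict: bool
    reasons: list[str] = field(default_factory=list)


class NoValidAnchorsError(RuntimeError):
    def __init__(self, message: str, best_diagnostics: AnchorDiagnostics | None = None):
        super().__init__(message)
        self.best_diagnostics = best_diagnostics


@dataclass(frozen=True)
class AnchorSearchConfig:
    margin_deg: float = 30.0       # circular mean distance from 0/180
    max_std_deg: float = 20.0      # circular standard deviation ceiling
    min_separation: float = 5.0    # pairwise anchor distance within a triple
    candidate_stride: int = 1      # subsample candidate CA atoms


def _angle_margin(mean_deg: float) -> float:
    """Distance of an angle mean in [0,180] from the nearest of 0/180."""
    m = abs(mean_deg)
    return min(m, 180.0 - m)


def _evaluate_anchor_set(frames: Sequence[Coordinates], anchors: AnchorSet,
                         cfg: AnchorSearchConfig) -> AnchorDiagnostics | None:
    samples: dict[str, list[float]] = {k: [] for k in _DIAG_DOFS}
    for fr in frames:
        try:
            dof = measure_boresch(fr, anchors)
            pc, pb, pa = (fr.position(r) for r in anchors.receptor_refs())
            pA, pB, pC = (fr.position(r) for r in anchors.ligand_refs())
            samples["angle_cba"].append(measure_angle(pc, pb, pa))
            samples["angle_ABC"].append(measure_angle(pA, pB, pC))
        except DegenerateGeometryError:
            return None  # collinear candidate: excluded from search space
        d = dof.as_dict()
        for k in ("thetaA", "thetaB", "phiA", "phiB", "phiC"):
            samples[k].append(d[k])

    means = {k: circular_mean_deg(v) for k, v in samples.items()}
    stds = {k: circular_std_deg(v) for k, v in samples.items()}
    margins = {k: _angle_margin(means[k]) for k in means}

    first = frames[0]
    seps = []
    for triple in (anchors.receptor_refs(), anchors.ligand_refs()):
        pts = [first.position(r) for r in triple]
        for i, j in itertools.combinations(range(3), 2):
            seps.append(float(np.linalg.norm(pts[i] - pts[j])))
    min_sep = min(seps)

    reasons = []
    for k in _DIAG_DOFS:
        if margins[k] < cfg.margin_deg:
            reasons.append(f"{k} mean {means[k]:.1f} within {cfg.margin_deg} deg of 0/180")
        if stds[k] > cfg.max_std_deg:
            reasons.append(f"{k} circular SD {stds[k]:.1f} exceeds {cfg.max_std_deg} deg")
    if min_sep < cfg.min_separation:
        reasons.append(f"anchor separation {min_sep:.2f} A below {cfg.min_separation} A")
    return AnchorDiagnostics(means=means, stds=stds, margins=margins,
                             min_separation=min_sep, verdict=not reasons,
                             reasons=reasons)


def _stability_score(diag: AnchorDiagnostics) -> float:
    """Higher is more stable: worst angular margin minus mean circular SD."""
    worst_margin = min(diag.margins.values())
    mean_std = sum(diag.stds.values()) / len(diag.stds)
    return worst_margin - mean_std


def select_anchors(frames: Sequence[Coordinates], receptor_chains: Iterable[str],
                   ligand_chain: str,
                   config: AnchorSearchConfig | None = None) -> tuple[AnchorSet, AnchorDiagnostics]:
    """Pick the six CA anchor atoms maximising a stability score.

    Hard criteria: all five restrained angles/dihedrals plus the two
    unrestrained angles c-b-a and A-B-C must keep their circular means at
    least `margin_deg` away from 0/180 degrees, per-DOF circular SD must stay
    below `max_std_deg`, and anchors within each triple must be pairwise
    separated by `min_separation`.  The search is exhaustive over the
    candidate CA pools (optionally strided) and deterministic: ties are broken
    by the lexicographic order of the candidate tuples.
    """
    if not frames:
        raise ValueError("need at least one frame")
    cfg = config or AnchorSearchConfig()
    first = frames[0]
    rec_chains = list(receptor_chains)

    def ca_refs(chains):
        refs = []
        for i in range(len(first)):
            if first.names[i] == "CA" and first.chains[i] in chains:
                refs.append(AtomRef(first.chains[i], first.residues[i], "CA"))
        return refs[::max(1, cfg.candidate_stride)]

    rec = ca_refs(set(rec_chains))
    lig = ca_refs({ligand_chain})
    if len(rec) < 3 or len(lig) < 3:
        raise ValueError("need at least three CA atoms on each side")

    best = None  # (score, key, anchors, diag)
    best_failing = None
    for r3 in itertools.combinations(rec, 3):
        for l3 in itertools.combinations(lig, 3):
            # convention: triples ordered c, b, a and A, B, C
            anchors = AnchorSet(c=r3[0], b=r3[1], a=r3[2],
                                A=l3[0], B=l3[1], C=l3[2])
            diag = _evaluate_anchor_set(frames, anchors, cfg)
            if diag is None:
                continue
            key = tuple(ref.as_tuple() for ref in (r3 + l3))
            if diag.verdict:
                score = _stability_score(diag)
                if best is None or score > best[0] or \
                        (score == best[0] and key < best[1]):
                    best = (score, key, anchors, diag)
            else:
                score = _stability_score(diag)
                if best_failing is None or score > best_failing[0]:
                    best_failing = (score, diag)
    if best is None:
        raise NoValidAnchorsError(
            "no anchor set satisfies the stability criteria",
            best_diagnostics=None if best_failing is None else best_failing[1])
    return best[2], best[3]
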