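"""Restraint potentials and anchor selection."""

import itertools
import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from georoute import (AnchorSearchConfig, BoreschDOF, Coordinates, FunnelSpec,
                      HarmonicTerm, RestraintSpec, RMSDRestraint,
                      TorsionRestraint, TorsionRestraintSet, boresch_energy,
                      build_ideal_helix, funnel_energy, rmsd_restraint_energy,
                      select_anchors, torsion_restraint_energy)
from georoute.geometry import measure_boresch, wrap_deg
from georoute.restraints import (NoValidAnchorsError, _evaluate_anchor_set,
                                 _stability_score, circular_mean_deg,
                                 circular_std_deg, flat_bottom_energy)


def random_dof(rng):
    return BoreschDOF(r=float(rng.uniform(2, 12)),
                      thetaA=float(rng.uniform(1, 179)),
                      thetaB=float(rng.uniform(1, 179)),
                      phiA=float(rng.uniform(-180, 180)),
                      phiB=float(rng.uniform(-180, 180)),
                      phiC=float(rng.uniform(-180, 180)))


def random_spec(rng):
    return RestraintSpec([
        HarmonicTerm("r", float(rng.uniform(2, 10)), float(rng.uniform(0, 20))),
        HarmonicTerm("thetaA", float(rng.uniform(30, 150)), float(rng.uniform(0, 200))),
        HarmonicTerm("thetaB", float(rng.uniform(30, 150)), float(rng.uniform(0, 200))),
        HarmonicTerm("phiA", float(rng.uniform(-180, 180)), float(rng.uniform(0, 200))),
        HarmonicTerm("phiB", float(rng.uniform(-180, 180)), float(rng.uniform(0, 200))),
        HarmonicTerm("phiC", float(rng.uniform(-180, 180)), float(rng.uniform(0, 200))),
    ])


def hand_summed_energy(dof, spec):
    vals = dof.as_dict()
    total = 0.0
    for name, term in spec.terms.items():
        if name == "r":
            d = vals["r"] - term.equilibrium
        else:
            d = math.radians(((vals[name] - term.equilibrium + 180.0) % 360.0)
                             - 180.0)
        total += 0.5 * term.k * d * d
    return total


def test_boresch_energy_zero_at_equilibrium(rng):
    dof = random_dof(rng)
    spec = RestraintSpec.from_dof(dof)
    assert boresch_energy(dof, spec) == pytest.approx(0.0, abs=1e-12)


def test_boresch_energy_periodic_wrap():
    spec = RestraintSpec([HarmonicTerm("phiB", 170.0, 50.0)])
    base = dict(r=5.0, thetaA=90.0, thetaB=90.0, phiA=0.0, phiC=0.0)
    # deviation of +190 degrees wraps to -170
    e_plus = boresch_energy(BoreschDOF(phiB=wrap_deg(170.0 + 190.0), **base), spec)
    e_minus = boresch_energy(BoreschDOF(phiB=wrap_deg(170.0 - 170.0), **base), spec)
    assert e_plus == pytest.approx(e_minus, abs=1e-10)


def test_boresch_energy_matches_hand_summation(rng):
    for _ in range(200):
        dof, spec = random_dof(rng), random_spec(rng)
        assert boresch_energy(dof, spec) == pytest.approx(
            hand_summed_energy(dof, spec), abs=1e-10)


def test_boresch_energy_rigid_motion_invariant(rng):
    from georoute.toysys import make_toy_dimer
    sys_ = make_toy_dimer()
    coords = sys_.coordinates()
    from georoute.geometry import AnchorSet, AtomRef
    anchors = AnchorSet(c=AtomRef("R", 2, "CA"), b=AtomRef("R", 3, "CA"),
                        a=AtomRef("R", 1, "CA"), A=AtomRef("L", 1, "CA"),
                        B=AtomRef("L", 3, "CA"), C=AtomRef("L", 2, "CA"))
    spec = RestraintSpec.from_dof(measure_boresch(coords, anchors))
    jost = coords.transformed(translation=np.array([1.0, -2.0, 0.5]))
    e0 = boresch_energy(measure_boresch(jost, anchors), spec)
    for k in range(10):
        R = Rotation.random(random_state=k).as_matrix()
        moved = jost.transformed(rotation=R, translation=np.array([3.0, 1.0, -8.0]))
        e = boresch_energy(measure_boresch(moved, anchors), spec)
        assert e == pytest.approx(e0, abs=1e-9)


def test_angular_equilibrium_bounds():
    with pytest.raises(ValueError):
        HarmonicTerm("thetaA", 0.0, 10.0)
    with pytest.raises(ValueError):
        HarmonicTerm("thetaB", 180.0, 10.0)
    with pytest.raises(ValueError):
        HarmonicTerm("r", 5.0, -1.0)


# --------------------------------------------------------------------------
# torsion restraints


def test_torsion_restraint_zero_at_center_and_boundary():
    helix = build_ideal_helix(6, phi0=-57.0, psi0=-47.0)
    rset = TorsionRestraintSet.helical(helix, ["A"], k=80.0, half_width=10.0)
    assert torsion_restraint_energy(helix, rset) == pytest.approx(0.0, abs=1e-12)
    # exactly at the flat-bottom edge the energy is still zero
    assert flat_bottom_energy(math.radians(10.0), 80.0, math.radians(10.0)) == 0.0


def test_torsion_restraint_beyond_boundary_closed_form():
    helix = build_ideal_helix(6, phi0=-57.0, psi0=-47.0)
    k, w = 80.0, 5.0
    rset = TorsionRestraintSet([TorsionRestraint("A", 3, "phi", -57.0 + 20.0, k, w)])
    # deviation is 20 deg, 15 deg beyond the flat width
    expected = 0.5 * k * math.radians(20.0 - w) ** 2
    assert torsion_restraint_energy(helix, rset) == pytest.approx(expected, rel=1e-9)


def test_torsion_restraint_unmeasurable_errors():
    helix = build_ideal_helix(6)
    rset = TorsionRestraintSet([TorsionRestraint("A", 1, "phi", -57.0, 10.0)])
    with pytest.raises(ValueError, match="residue 1"):
        torsion_restraint_energy(helix, rset)


def test_flat_bottom_first_derivative_continuity():
    k, w = 50.0, math.radians(12.0)
    h = 1e-7
    slope_inside = (flat_bottom_energy(w, k, w) - flat_bottom_energy(w - h, k, w)) / h
    slope_outside = (flat_bottom_energy(w + h, k, w) - flat_bottom_energy(w, k, w)) / h
    assert abs(slope_inside) < 1e-5 and abs(slope_outside) < 1e-4


# --------------------------------------------------------------------------
# RMSD restraint


def test_rmsd_restraint_reference_flat_and_closed_form(rng):
    helix = build_ideal_helix(6)
    sel = np.arange(len(helix))
    r = RMSDRestraint(reference=helix, selection=sel, k=10.0, flat_radius=0.5)
    assert rmsd_restraint_energy(helix, r) == 0.0
    # small perturbation below the flat radius
    tiny = Coordinates(helix.chains, helix.residues, helix.names,
                       helix.xyz + rng.normal(scale=0.02, size=helix.xyz.shape))
    assert rmsd_restraint_energy(tiny, r) == 0.0


def test_rmsd_restraint_one_angstrom_excess():
    # deform so the optimal RMSD is flat_radius + 1 exactly, K = 10 -> 5 kcal/mol
    helix = build_ideal_helix(6)
    from georoute.geometry import optimal_rmsd
    rng = np.random.default_rng(4)
    direction = rng.normal(size=helix.xyz.shape)
    direction -= direction.mean(axis=0)
    moved = Coordinates(helix.chains, helix.residues, helix.names,
                        helix.xyz + direction)
    base_rmsd = optimal_rmsd(moved, helix)
    r = RMSDRestraint(reference=helix, selection=np.arange(len(helix)),
                      k=10.0, flat_radius=base_rmsd - 1.0)
    assert rmsd_restraint_energy(moved, r) == pytest.approx(5.0, rel=1e-9)


# --------------------------------------------------------------------------
# funnel


def make_funnel(**kw):
    defaults = dict(p0=(0.0, 0.0, 0.0), p1=(0.0, 0.0, 1.0), half_angle=35.0,
                    cylinder_radius=2.0, switch_distance=10.0, wall_k=40.0)
    defaults.update(kw)
    return FunnelSpec(**defaults)


def test_funnel_zero_on_axis_and_inside():
    f = make_funnel()
    assert funnel_energy((0, 0, 5.0), f) == 0.0
    assert funnel_energy((1.5, 0, 20.0), f) == 0.0  # inside cylinder


def test_funnel_wall_closed_form():
    f = make_funnel()
    excess = 1.3
    e = funnel_energy((f.cylinder_radius + excess, 0.0, 15.0), f)
    assert e == pytest.approx(0.5 * f.wall_k * excess ** 2, rel=1e-12)


def test_funnel_boundary_continuous_at_switch():
    f = make_funnel()
    eps = 1e-7
    assert abs(f.boundary_radius(f.switch_distance - eps)
               - f.boundary_radius(f.switch_distance + eps)) < 1e-5
    # energy continuity across the switch plane at fixed radius
    rho = f.cylinder_radius + 0.8
    e_before = funnel_energy((rho, 0, f.switch_distance - eps), f)
    e_after = funnel_energy((rho, 0, f.switch_distance + eps), f)
    assert e_before == pytest.approx(e_after, abs=1e-4)


def test_funnel_cone_widens_towards_site():
    f = make_funnel()
    assert f.boundary_radius(0.0) > f.boundary_radius(5.0) > f.cylinder_radius


# --------------------------------------------------------------------------
# anchor selection


def two_helix_frames(n_frames=4, noise=0.05):
    rng = np.random.default_rng(11)
    a = build_ideal_helix(10, chain="A")
    b = build_ideal_helix(10, chain="B")
    b = b.transformed(rotation=Rotation.from_euler("z", 180, degrees=True).as_matrix(),
                      translation=np.array([9.5, 2.0, 2.5]))
    chains = a.chains + b.chains
    residues = a.residues + b.residues
    names = a.names + b.names
    xyz = np.vstack([a.xyz, b.xyz])
    frames = []
    for _ in range(n_frames):
        frames.append(Coordinates(chains, residues, names,
                                  xyz + rng.normal(scale=noise, size=xyz.shape)))
    return frames


def test_select_anchors_on_rigid_helices_passes():
    frames = two_helix_frames()
    cfg = AnchorSearchConfig(candidate_stride=2)
    anchors, diag = select_anchors(frames, ["A"], "B", cfg)
    assert diag.verdict
    for name in ("thetaA", "thetaB", "angle_cba", "angle_ABC"):
        assert 30.0 <= abs(diag.means[name]) <= 150.0


def test_select_anchors_deterministic():
    frames = two_helix_frames()
    cfg = AnchorSearchConfig(candidate_stride=2)
    a1, _ = select_anchors(frames, ["A"], "B", cfg)
    a2, _ = select_anchors(frames, ["A"], "B", cfg)
    assert a1.to_dict() == a2.to_dict()


def test_select_anchors_matches_exhaustive_enumeration():
    """Independent brute force over all CA triples on a tiny two-chain toy."""
    frames = two_helix_frames(n_frames=2)
    cfg = AnchorSearchConfig(candidate_stride=3)
    anchors, diag = select_anchors(frames, ["A"], "B", cfg)

    from georoute.geometry import AnchorSet, AtomRef
    first = frames[0]
    cas_a = [AtomRef("A", first.residues[i], "CA") for i in range(len(first))
             if first.names[i] == "CA" and first.chains[i] == "A"][::3]
    cas_b = [AtomRef("B", first.residues[i], "CA") for i in range(len(first))
             if first.names[i] == "CA" and first.chains[i] == "B"][::3]
    best = None
    for r3 in itertools.combinations(cas_a, 3):
        for l3 in itertools.combinations(cas_b, 3):
            cand = AnchorSet(c=r3[0], b=r3[1], a=r3[2],
                             A=l3[0], B=l3[1], C=l3[2])
            d = _evaluate_anchor_set(frames, cand, cfg)
            if d is not None and d.verdict:
                score = _stability_score(d)
                if best is None or score > best:
                    best = score
    assert best is not None
    assert _stability_score(diag) == pytest.approx(best, abs=1e-12)


def test_select_anchors_no_candidates_raises_with_diagnostics():
    # collinear chains: every triple is degenerate or fails the margins
    xyz_a = np.array([[0, 0, z] for z in range(6)], dtype=float)
    xyz_b = xyz_a + np.array([8.0, 0.0, 0.0])
    coords = Coordinates(["A"] * 6 + ["B"] * 6, list(range(1, 7)) * 2,
                         ["CA"] * 12, np.vstack([xyz_a, xyz_b]))
    with pytest.raises(NoValidAnchorsError):
        select_anchors([coords], ["A"], "B")


def test_circular_statistics_wraparound():
    vals = [179.0, -179.0, 178.0, -178.0]
    assert abs(abs(circular_mean_deg(vals)) - 179.5) < 1.0
    assert circular_std_deg(vals) < 2.0
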