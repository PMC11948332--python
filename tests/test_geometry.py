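"""Geometric primitives: angles, dihedrals, Boresch DOFs, torsions, RMSD."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from georoute import (AnchorSet, AtomRef, Coordinates, DegenerateGeometryError,
                      backbone_torsions, build_ideal_helix, measure_angle,
                      measure_boresch, measure_dihedral, optimal_rmsd)
from georoute.geometry import measure_distance, wrap_deg


def arccos_angle(p1, p2, p3):
    """Independent oracle: arccos of the normalized dot product."""
    v1 = np.asarray(p1, float) - np.asarray(p2, float)
    v2 = np.asarray(p3, float) - np.asarray(p2, float)
    c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return math.degrees(math.acos(np.clip(c, -1.0, 1.0)))


def projection_dihedral(p1, p2, p3, p4):
    """Independent oracle: praxeolitic projection formulation."""
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b0, b1, b2 = p1 - p2, p3 - p2, p4 - p3
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return math.degrees(math.atan2(y, x))


@pytest.mark.parametrize("pts, expected", [
    (((0, 0, 0), (0, 0, 1), (0, 1, 1)), 90.0),
    (((0, 0, 0), (0, 0, 1), (0, 0, 2)), 180.0),
    (((1, 0, 0), (0, 0, 0), (2, 0, 0)), 0.0),
])
def test_angle_special_cases(pts, expected):
    assert measure_angle(*pts) == pytest.approx(expected, abs=1e-12)


def test_angle_matches_arccos_oracle(rng):
    for _ in range(1000):
        pts = rng.normal(size=(3, 3)) * 5.0
        assert measure_angle(*pts) == pytest.approx(
            arccos_angle(*pts), abs=1e-9)


@pytest.mark.parametrize("p4, expected", [
    ((1, 0, 1), 0.0),     # planar cis
    ((-1, 0, 1), 180.0),  # planar trans
    ((0, 1, 1), 90.0),
    ((0, -1, 1), -90.0),
])
def test_dihedral_planar_and_sign(p4, expected):
    val = measure_dihedral((1, 0, 0), (0, 0, 0), (0, 0, 1), p4)
    assert abs(wrap_deg(val - expected)) < 1e-12


def test_dihedral_matches_projection_oracle(rng):
    for _ in range(1000):
        pts = rng.normal(size=(4, 3)) * 4.0
        assert measure_dihedral(*pts) == pytest.approx(
            projection_dihedral(*pts), abs=1e-9)


def test_dihedral_reversal_and_mirror_identities(rng):
    # reversing the point order leaves the dihedral unchanged; a mirror
    # reflection negates it (chirality flip)
    for _ in range(200):
        pts = rng.normal(size=(4, 3)) * 3.0
        fwd = measure_dihedral(*pts)
        rev = measure_dihedral(*pts[::-1])
        assert abs(wrap_deg(fwd - rev)) < 1e-9
        mirrored = pts * np.array([1.0, 1.0, -1.0])
        assert abs(wrap_deg(fwd + measure_dihedral(*mirrored))) < 1e-9


def test_degenerate_geometry_raises():
    with pytest.raises(DegenerateGeometryError):
        measure_angle((0, 0, 0), (0, 0, 0), (1, 0, 0))
    with pytest.raises(DegenerateGeometryError):
        measure_dihedral((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))


def test_measurements_invariant_under_rigid_motion(rng):
    pts = rng.normal(size=(4, 3)) * 4.0
    ang0 = measure_angle(*pts[:3])
    dih0 = measure_dihedral(*pts)
    for k in range(20):
        R = Rotation.random(random_state=k).as_matrix()
        t = rng.normal(size=3) * 10.0
        moved = pts @ R.T + t
        assert measure_angle(*moved[:3]) == pytest.approx(ang0, abs=1e-9)
        assert measure_dihedral(*moved) == pytest.approx(dih0, abs=1e-9)


def _toy_coordinates(rng, n_chain_atoms=4):
    xyz = rng.normal(size=(2 * n_chain_atoms, 3)) * 4.0
    chains = ["R"] * n_chain_atoms + ["L"] * n_chain_atoms
    residues = list(range(1, n_chain_atoms + 1)) * 2
    names = ["CA"] * (2 * n_chain_atoms)
    return Coordinates(chains, residues, names, xyz)


def test_boresch_components_match_primitive_measurements(rng):
    for _ in range(50):
        coords = _toy_coordinates(rng)
        anchors = AnchorSet(c=AtomRef("R", 1, "CA"), b=AtomRef("R", 2, "CA"),
                            a=AtomRef("R", 3, "CA"), A=AtomRef("L", 1, "CA"),
                            B=AtomRef("L", 2, "CA"), C=AtomRef("L", 3, "CA"))
        try:
            dof = measure_boresch(coords, anchors)
        except DegenerateGeometryError:
            continue
        pc, pb, pa = (coords.position(r) for r in anchors.receptor_refs())
        pA, pB, pC = (coords.position(r) for r in anchors.ligand_refs())
        assert dof.r == pytest.approx(measure_distance(pa, pA), abs=1e-12)
        assert dof.thetaA == pytest.approx(measure_angle(pb, pa, pA), abs=1e-12)
        assert dof.thetaB == pytest.approx(measure_angle(pa, pA, pB), abs=1e-12)
        assert dof.phiA == pytest.approx(measure_dihedral(pc, pb, pa, pA), abs=1e-12)
        assert dof.phiB == pytest.approx(measure_dihedral(pb, pa, pA, pB), abs=1e-12)
        assert dof.phiC == pytest.approx(measure_dihedral(pa, pA, pB, pC), abs=1e-12)


def test_boresch_axis_aligned_values():
    coords = Coordinates(["R", "R", "R", "L", "L", "L"], [1, 2, 3, 1, 2, 3],
                         ["CA"] * 6,
                         np.array([[0, 0, 5], [0, 1, 0], [0, 0, 0],
                                   [5, 0, 0], [5, 5, 5], [9, 9, 0.0]]))
    anchors = AnchorSet(c=AtomRef("R", 1, "CA"), b=AtomRef("R", 2, "CA"),
                        a=AtomRef("R", 3, "CA"), A=AtomRef("L", 1, "CA"),
                        B=AtomRef("L", 2, "CA"), C=AtomRef("L", 3, "CA"))
    dof = measure_boresch(coords, anchors)
    assert dof.r == pytest.approx(5.0)
    assert dof.thetaA == pytest.approx(90.0)


def test_anchorset_requires_distinct_chains_and_atoms():
    with pytest.raises(ValueError):
        AnchorSet(c=AtomRef("R", 1, "CA"), b=AtomRef("R", 2, "CA"),
                  a=AtomRef("R", 3, "CA"), A=AtomRef("R", 4, "CA"),
                  B=AtomRef("L", 2, "CA"), C=AtomRef("L", 3, "CA"))


def test_backbone_torsions_roundtrip_and_boundaries():
    helix = build_ideal_helix(8, phi0=-57.0, psi0=-47.0)
    tors = backbone_torsions(helix, "A")
    assert tors[0].phi is None and tors[-1].psi is None
    for rec in tors[1:-1]:
        assert rec.phi == pytest.approx(-57.0, abs=1e-6)
        assert rec.psi == pytest.approx(-47.0, abs=1e-6)


def test_backbone_torsions_two_residue_chain():
    helix = build_ideal_helix(3)
    two = Coordinates(*zip(*[(helix.chains[i], helix.residues[i],
                              helix.names[i], helix.xyz[i])
                             for i in range(len(helix))
                             if helix.residues[i] <= 2]))
    tors = backbone_torsions(two, "A")
    assert len(tors) == 2
    assert tors[0].phi is None and tors[0].psi is not None
    assert tors[1].phi is not None and tors[1].psi is None


def test_backbone_torsions_match_dihedral_composition(rng):
    helix = build_ideal_helix(6)
    jostled = Coordinates(helix.chains, helix.residues, helix.names,
                          helix.xyz + rng.normal(scale=0.05, size=helix.xyz.shape))
    for rec in backbone_torsions(jostled, "A"):
        res = rec.residue
        if rec.phi is not None:
            expected = measure_dihedral(jostled.position(("A", res - 1, "C")),
                                        jostled.position(("A", res, "N")),
                                        jostled.position(("A", res, "CA")),
                                        jostled.position(("A", res, "C")))
            assert rec.phi == pytest.approx(expected, abs=1e-12)
        if rec.psi is not None:
            expected = measure_dihedral(jostled.position(("A", res, "N")),
                                        jostled.position(("A", res, "CA")),
                                        jostled.position(("A", res, "C")),
                                        jostled.position(("A", res + 1, "N")))
            assert rec.psi == pytest.approx(expected, abs=1e-12)


# --------------------------------------------------------------------------
# optimal superposition


def brute_force_rmsd(mobile, reference, levels=3, n_grid=14):
    """Zoomed exhaustive search over rotations (+ centroid translation)."""
    P = np.asarray(mobile, float)
    Q = np.asarray(reference, float)
    P = P - P.mean(axis=0)
    Q = Q - Q.mean(axis=0)
    center = np.zeros(3)
    span = math.pi
    best = math.inf
    for _ in range(levels):
        axes = [np.linspace(c - span, c + span, n_grid) for c in center]
        grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
        mats = Rotation.from_euler("zyz", grid).as_matrix()
        moved = np.einsum("rij,nj->rni", mats, P)
        rmsds = np.sqrt(((moved - Q) ** 2).sum(axis=(1, 2)) / P.shape[0])
        k = int(np.argmin(rmsds))
        if rmsds[k] < best:
            best = float(rmsds[k])
            center = grid[k]
        span /= n_grid / 2.5
    return best


def test_rmsd_identity_and_rigid_copy(rng):
    X = rng.normal(size=(10, 3)) * 3.0
    assert optimal_rmsd(X, X) == pytest.approx(0.0, abs=1e-12)
    R = Rotation.random(random_state=5).as_matrix()
    assert optimal_rmsd(X @ R.T + 7.5, X) == pytest.approx(0.0, abs=1e-9)


def test_rmsd_symmetric(rng):
    X = rng.normal(size=(8, 3)) * 3.0
    Y = X + rng.normal(scale=0.4, size=X.shape)
    assert optimal_rmsd(X, Y) == pytest.approx(optimal_rmsd(Y, X), abs=1e-9)


def test_rmsd_matches_rotation_grid_brute_force(rng):
    for _ in range(3):
        X = rng.normal(size=(4, 3)) * 2.0
        Y = rng.normal(size=(4, 3)) * 2.0
        assert optimal_rmsd(X, Y) == pytest.approx(
            brute_force_rmsd(X, Y), abs=1e-4)


def test_rmsd_excludes_reflections():
    # a chiral 4-point set vs its mirror image: a proper rotation cannot
    # superpose them, so the RMSD must stay strictly positive
    X = np.array([[0, 0, 0], [1.5, 0, 0], [0, 1.2, 0], [0, 0, 1.0]])
    mirror = X * np.array([1, 1, -1.0])
    assert optimal_rmsd(mirror, X) > 0.3


def test_rmsd_mismatched_selection_errors(rng):
    X = rng.normal(size=(5, 3))
    with pytest.raises(ValueError):
        optimal_rmsd(X, X[:4])


def test_coordinates_invariants():
    with pytest.raises(ValueError):
        Coordinates(["A", "A"], [1, 1], ["CA", "CA"], np.zeros((2, 3)))
    with pytest.raises(ValueError):
        Coordinates(["A"], [1], ["CA"], np.array([[np.nan, 0, 0]]))
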