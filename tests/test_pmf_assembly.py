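"""PMF profiles, window free energies, separation integral, step assembly."""

import math

import numpy as np
import pytest
from scipy import integrate

from georoute import (Component, DissociationScheme, DissociationStep,
                      PMFProfile, assemble_scheme, assemble_step,
                      average_profiles, imposition_free_energy, pmf_delta,
                      read_pmf, replicate_statistics, rmsd_reorganization_term,
                      separation_integral, standard_state, synth_pmf,
                      write_pmf, RestraintSpec)
from georoute.assembly import MissingComponentError, StepFreeEnergy
from georoute.pmf import bulk_reference_value

from georoute import Component  # noqa: F811  (re-export check)


def test_pmf_file_roundtrip(tmp_path):
    grid = np.linspace(2.0, 20.0, 91)
    prof = synth_pmf("harmonic", grid, {"k": 2.0, "s0": 8.0}, noise=0.05,
                     seed=3).with_r_star(18.0)
    path = tmp_path / "sep.pmf"
    write_pmf(prof, path)
    back = read_pmf(path)
    assert back.cv == prof.cv and back.units == prof.units
    assert back.r_star == pytest.approx(18.0)
    np.testing.assert_allclose(back.grid, prof.grid, rtol=1e-9)
    np.testing.assert_allclose(back.w, prof.w, rtol=1e-8)
    np.testing.assert_allclose(back.error, prof.error, rtol=1e-8)


def test_pmf_file_malformed_reports_line(tmp_path):
    path = tmp_path / "bad.pmf"
    path.write_text("# cv_name: r\nr 1.0 0.0 0.0\nr oops 0.0 0.0\n")
    with pytest.raises(ValueError, match=":3"):
        read_pmf(path)


def test_pmf_grid_invariants():
    with pytest.raises(ValueError):
        PMFProfile(cv="r", units="A", grid=[1.0, 1.0, 2.0], w=[0, 0, 0])
    with pytest.raises(ValueError):
        PMFProfile(cv="r", units="A", grid=[1.0, 2.0], w=[0.0, np.inf])
    with pytest.raises(ValueError):
        PMFProfile(cv="r", units="A", grid=[1.0, 2.0], w=[0, 0], r_star=5.0)


def test_pmf_delta_flat_and_step(ctx):
    grid = np.linspace(0.0, 10.0, 201)
    flat = synth_pmf("flat", grid)
    d, _ = pmf_delta(flat, (0.0, 4.0), (6.0, 10.0), ctx)
    assert d == pytest.approx(0.0, abs=1e-12)
    step = synth_pmf("step", grid, {"edge": 5.0, "height": 2.5})
    d, _ = pmf_delta(step, (0.0, 4.0), (6.0, 10.0), ctx)
    assert d == pytest.approx(2.5, abs=1e-12)


def test_pmf_delta_harmonic_window_matches_quadrature(ctx):
    k, s0 = 3.0, 5.0
    grid = np.linspace(0.0, 10.0, 2001)
    prof = synth_pmf("harmonic", grid, {"k": k, "s0": s0})
    win_a, win_b = (4.0, 6.0), (7.0, 9.0)

    def window_f(win):
        z, _ = integrate.quad(
            lambda s: math.exp(-ctx.beta * 0.5 * k * (s - s0) ** 2), *win)
        return -ctx.kT * math.log(z)

    expected = window_f(win_b) - window_f(win_a)
    d, _ = pmf_delta(prof, win_a, win_b, ctx)
    assert d == pytest.approx(expected, abs=2e-3)
    # min-to-min convention instead
    d_min, _ = pmf_delta(prof, win_a, win_b, ctx, convention="min")
    assert d_min == pytest.approx(0.5 * k * (7.0 - s0) ** 2
                                  - 0.5 * k * (5.0 - s0) ** 2, abs=1e-6)


def test_pmf_delta_empty_window_errors(ctx):
    prof = synth_pmf("flat", np.linspace(0, 1, 11))
    with pytest.raises(ValueError):
        pmf_delta(prof, (2.0, 3.0), (0.0, 1.0), ctx)


def test_separation_integral_flat_gives_interval(ctx):
    grid = np.linspace(10.0, 20.0, 501)
    prof = synth_pmf("flat", grid).with_r_star(20.0)
    i_star, err = separation_integral(prof, ctx)
    assert i_star == pytest.approx(10.0, rel=1e-6)
    # adding a constant leaves I* unchanged
    shifted = prof.shifted(7.3)
    assert separation_integral(shifted, ctx)[0] == pytest.approx(i_star, rel=1e-12)


def test_separation_integral_deep_harmonic_well(ctx):
    # deep harmonic well whose minimum sits at the bulk level: the site
    # integral reduces to the Gaussian mass sqrt(2 pi kT / k)
    k, r0 = 10.0, 10.0
    grid = np.linspace(6.0, 25.0, 4001)
    w = np.where(np.abs(grid - r0) <= 4.0,
                 0.5 * k * (grid - r0) ** 2, 0.0)
    prof = PMFProfile(cv="r", units="A", grid=grid, w=w, r_star=20.0)
    i_star, _ = separation_integral(prof, ctx, site_upper=r0 + 4.0)
    # the flat ledge [6, 6+eps) and the well walls contribute ~ e^{-80 beta}
    expected = math.sqrt(2 * math.pi * ctx.kT / k)
    assert i_star == pytest.approx(expected, rel=5e-3)


def test_bulk_reference_fit(ctx):
    grid = np.linspace(2.0, 16.0, 701)
    rng = np.random.default_rng(1)
    w = -2 * ctx.kT * np.log(grid) + 3.0 + rng.normal(0, 0.05, grid.shape)
    prof = PMFProfile(cv="r", units="A", grid=grid, w=w, r_star=14.0)
    ref = bulk_reference_value(prof, 14.0, (8.0, 13.0), ctx)
    assert ref == pytest.approx(3.0 - 2 * ctx.kT * math.log(14.0), abs=0.01)


def test_imposition_free_energy_matches_quadrature(ctx):
    kw, k_r = 1.2, 35.0
    grid = np.linspace(-6.0, 6.0, 2001)
    prof = synth_pmf("harmonic", grid, {"k": kw, "s0": 0.5})

    def u(s):
        return 0.5 * k_r * (s - 0.2) ** 2

    num, _ = integrate.quad(lambda s: math.exp(-ctx.beta * (0.5 * kw * (s - 0.5) ** 2 + u(s))), -6, 6)
    den, _ = integrate.quad(lambda s: math.exp(-ctx.beta * 0.5 * kw * (s - 0.5) ** 2), -6, 6)
    expected = -ctx.kT * math.log(num / den)
    value, _ = imposition_free_energy(prof, u, ctx)
    assert value == pytest.approx(expected, abs=2e-3)


def test_average_profiles_and_replicates(ctx):
    grid = np.linspace(0, 10, 101)
    reps = [synth_pmf("harmonic", grid, {"k": 1.0, "s0": 5.0}, noise=0.1, seed=s)
            for s in (1, 2, 3)]
    avg = average_profiles(reps)
    ref = 0.5 * (grid - 5.0) ** 2
    aligned = avg.w - (avg.w - ref).mean()
    assert np.abs(aligned - ref).max() < 0.35
    assert avg.error is not None and np.all(avg.error >= 0)

    mean, se = replicate_statistics([1.0, 2.0, 3.0])
    assert mean == pytest.approx(2.0)
    assert se == pytest.approx(1.0 / math.sqrt(3.0))
    mean, se = replicate_statistics([4.2])
    assert se is None  # flagged absent, not zero


def test_replicate_statistics_gaussian_sampling(ctx):
    rng = np.random.default_rng(8)
    covered = 0
    for _ in range(200):
        sample = rng.normal(loc=1.5, scale=0.8, size=6)
        m, se = replicate_statistics(sample)
        if abs(m - 1.5) <= 2.0 * se:
            covered += 1
    assert 160 <= covered <= 200  # ~95% nominal coverage


# --------------------------------------------------------------------------
# step assembly


def flat_separation(ctx, length=10.0, r_star=20.0):
    grid = np.linspace(r_star - length, r_star, 801)
    return synth_pmf("flat", grid).with_r_star(r_star)


def test_assemble_step_null_case_is_zero(ctx):
    """With no restraints and S* I* equal to the standard-state volume the
    standard binding free energy vanishes exactly."""
    spec = RestraintSpec([])
    length = ctx.v_standard / (4.0 * math.pi * 1.0 ** 2)  # S* = 4 pi r*^2
    grid = np.linspace(1.0 - length, 1.0, 801)
    sep = synth_pmf("flat", grid).with_r_star(1.0)
    step = assemble_step(sep, spec, ctx, dg_c_site=0.0, dg_c_bulk=0.0,
                         dg_o_site=0.0, dg_a_site=0.0, dg_o_bulk=0.0)
    assert step.s_star * step.i_star == pytest.approx(ctx.v_standard, rel=1e-6)
    assert step.total == pytest.approx(0.0, abs=1e-6)


def test_assemble_step_signed_sum_regression(ctx):
    spec = RestraintSpec.from_dict({"thetaA": (60.0, 100.0), "phiA": (30.0, 100.0),
                                    "thetaB": (70.0, 100.0), "phiB": (-40.0, 100.0),
                                    "phiC": (100.0, 100.0)})
    step = assemble_step(flat_separation(ctx), spec, ctx,
                         dg_c_site=(0.4, 0.05), dg_c_bulk=(0.9, 0.1),
                         dg_o_site=(1.2, 0.1), dg_a_site=(0.7, 0.1),
                         dg_o_bulk=(4.0, 0.0),
                         dg_rmsd_site=(0.3, 0.02), dg_rmsd_bulk=(0.8, 0.02),
                         sigma=0.5)
    expected = (step.separation_release.value
                - 0.4 - 1.2 - 0.7 - 0.3 + 0.9 + 4.0 + 0.8 + step.symmetry)
    assert step.total == pytest.approx(expected, abs=1e-12)
    assert step.symmetry == pytest.approx(ctx.kT * math.log(2.0))
    assert step.error == pytest.approx(
        math.sqrt(0.05 ** 2 + 0.1 ** 2 + 0.1 ** 2 + 0.1 ** 2 + 0.02 ** 2
                  + 0.02 ** 2 + step.separation_release.error ** 2), rel=1e-9)


def test_assemble_step_missing_components_named(ctx):
    spec = RestraintSpec([])
    with pytest.raises(MissingComponentError, match="dg_o_site"):
        assemble_step(flat_separation(ctx), spec, ctx, dg_c_site=0.0,
                      dg_c_bulk=0.0, dg_a_site=0.0, dg_o_bulk=0.0)
    with pytest.raises(MissingComponentError, match="site/bulk pair"):
        assemble_step(flat_separation(ctx), spec, ctx, dg_c_site=0.0,
                      dg_c_bulk=0.0, dg_o_site=0.0, dg_a_site=0.0,
                      dg_o_bulk=0.0, dg_rmsd_site=0.5)


def test_rmsd_reorganization_sign_convention(ctx):
    spec = RestraintSpec([])
    kwargs = dict(dg_c_site=0.0, dg_c_bulk=0.0, dg_o_site=0.0, dg_a_site=0.0,
                  dg_o_bulk=0.0)
    equal = assemble_step(flat_separation(ctx), spec, ctx,
                          dg_rmsd_site=0.6, dg_rmsd_bulk=0.6, **kwargs)
    assert rmsd_reorganization_term(equal) == pytest.approx(0.0, abs=1e-12)
    # receptor freer in the unbound state -> positive reorganization
    bulk_dom = assemble_step(flat_separation(ctx), spec, ctx,
                             dg_rmsd_site=0.2, dg_rmsd_bulk=1.4, **kwargs)
    assert rmsd_reorganization_term(bulk_dom) > 0
    bare = assemble_step(flat_separation(ctx), spec, ctx, **kwargs)
    with pytest.raises(MissingComponentError):
        rmsd_reorganization_term(bare)


def make_step(ctx, bump=0.0, sym=None):
    spec = RestraintSpec([])
    return assemble_step(flat_separation(ctx), spec, ctx,
                         dg_c_site=0.0, dg_c_bulk=bump, dg_o_site=0.0,
                         dg_a_site=0.0, dg_o_bulk=0.0, sigma=sym)


def test_assemble_scheme_totals_and_per_helix(ctx):
    s1 = make_step(ctx, bump=1.0)
    s2 = make_step(ctx, bump=0.5)
    scheme = DissociationScheme(oligomer_size=3, steps=(
        DissociationStep("A", s1), DissociationStep("C", s2)))
    result = assemble_scheme(scheme, ctx)
    expected = s1.total + s2.total + result.symmetry.energy
    assert result.total == pytest.approx(expected, abs=1e-12)
    assert result.symmetry.sigma == pytest.approx(1.0 / 3.0)
    assert result.per_helix == pytest.approx(result.total / 3.0, abs=1e-15)


def test_assemble_scheme_single_step_dimer(ctx):
    s = make_step(ctx)
    scheme = DissociationScheme(oligomer_size=2, steps=(DissociationStep("L", s),),
                                sigma=1.0)
    result = assemble_scheme(scheme, ctx)
    assert result.total == pytest.approx(s.total, abs=1e-12)


def test_assemble_scheme_replicates_combined(ctx):
    reps = [make_step(ctx, bump=b) for b in (0.9, 1.0, 1.1)]
    scheme = DissociationScheme(oligomer_size=2,
                                steps=(DissociationStep("L", reps),), sigma=1.0)
    result = assemble_scheme(scheme, ctx)
    mean_total = sum(r.total for r in reps) / 3.0
    assert result.total == pytest.approx(mean_total, abs=1e-12)
    assert result.total_error >= 0.1 / math.sqrt(3.0) - 1e-6


def test_scheme_validation(ctx):
    s = make_step(ctx)
    with pytest.raises(ValueError, match="n-1 steps"):
        DissociationScheme(oligomer_size=3, steps=(DissociationStep("A", s),))
    with pytest.raises(ValueError, match="once"):
        DissociationScheme(oligomer_size=3, steps=(
            DissociationStep("A", s), DissociationStep("A", s)))
    with_sym = make_step(ctx, sym=0.5)
    with pytest.raises(ValueError, match="symmetry"):
        assemble_scheme(DissociationScheme(
            oligomer_size=2, steps=(DissociationStep("L", with_sym),)), ctx)
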