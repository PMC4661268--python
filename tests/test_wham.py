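"""WHAM unbiasing: oracle identities, symmetry, projection, state analysis."""
import numpy as np
import pytest

from porepmf.constants import kT
from porepmf.synthetic.sampler import SamplerConfig, sample_biased
from porepmf.synthetic.surfaces import ModelSurfaceSpec
from porepmf.trajectory import RCTrajectory
from porepmf.umbrella import BiasPotential, plan_windows, run_umbrella_set, strip_burn_in
from porepmf.wham import (
    DisconnectedWindowsError,
    EmptyProfileError,
    PMFProfile1D,
    PMFSurface,
    histogram_windows,
    locate_states,
    project_diagonal,
    symmetrize,
    wham_solve,
)

from conftest import run_diagonal_wham


# ---------------------------------------------------------------- histograms


def test_histogram_conserves_counts_and_reports_outside():
    traj = RCTrajectory(np.array([[9.05, 9.05]] * 100 + [[7.0, 7.0]] * 3))
    (h,) = histogram_windows([traj], bin_width=0.1, domain=(8.0, 13.5))
    assert h.total == 100
    assert h.n_outside == 3
    assert h.counts.max() == 100


def test_histogram_degenerate_single_bin():
    traj = RCTrajectory(np.random.default_rng(0).uniform(8.5, 13.0, (500, 2)))
    (h,) = histogram_windows([traj], bin_width=10.0, domain=(8.0, 13.5))
    assert h.counts.shape == (1, 1)
    assert h.total == 500


def test_histogram_rejects_empty_window():
    with pytest.raises(ValueError, match="empty"):
        histogram_windows([RCTrajectory(np.empty((0, 2)))])


# ------------------------------------------------------------------- solver


def test_single_unbiased_window_equals_boltzmann_inversion(harmonic_well):
    """With one zero-strength window WHAM reduces exactly to -kT ln(histogram)."""
    cfg = SamplerConfig(n_steps=40_000, seed=3, step_size=0.5)
    traj = sample_biased(harmonic_well, None, cfg)
    hists = histogram_windows([traj], bin_width=0.1)
    surface, report = wham_solve(hists, [BiasPotential(9.5, 9.5, 0.0, 0.0)])
    counts = hists[0].counts.astype(float)
    with np.errstate(divide="ignore"):
        inversion = -kT(300.0) * np.log(counts)
    inversion[counts == 0] = np.nan
    inversion -= np.nanmin(inversion)
    np.testing.assert_allclose(
        surface.values[surface.sampled], inversion[surface.sampled], atol=1e-10
    )
    assert report.converged


def test_probabilities_normalized_and_min_zero(flat_surface):
    surface, _ = run_diagonal_wham(flat_surface, n_steps=4000, seed=1)
    p = np.exp(-surface.values[surface.sampled] / kT(300.0))
    # PMF zero-reference: min of sampled bins is exactly zero
    assert np.nanmin(surface.values) == 0.0
    assert np.all(np.isnan(surface.values[~surface.sampled]))
    assert p.max() <= 1.0


def test_window_order_invariance(flat_surface, diagonal_plan):
    cfg = SamplerConfig(n_steps=4000, seed=9, proposal="bias")
    windows = run_umbrella_set(diagonal_plan, flat_surface, cfg)
    stripped = [strip_burn_in(w) for w in windows]
    hists = histogram_windows(stripped)
    biases = [w.bias for w in windows]
    surf_a, _ = wham_solve(hists, biases)
    order = np.random.default_rng(0).permutation(len(hists))
    surf_b, _ = wham_solve([hists[i] for i in order], [biases[i] for i in order])
    np.testing.assert_allclose(
        surf_a.values[surf_a.sampled], surf_b.values[surf_b.sampled], atol=1e-8
    )


def test_mirrored_trajectories_give_transposed_pmf(opening_surface, diagonal_plan):
    """Exchanging zeta1 and zeta2 in every input transposes the output PMF."""
    cfg = SamplerConfig(n_steps=4000, seed=4)
    windows = run_umbrella_set(diagonal_plan, opening_surface, cfg)
    stripped = [strip_burn_in(w) for w in windows]
    biases = [w.bias for w in windows]
    surf, _ = wham_solve(histogram_windows(stripped), biases)
    mirrored = [t.mirrored() for t in stripped]
    m_biases = [BiasPotential(b.center2, b.center1, b.k2, b.k1) for b in biases]
    surf_m, _ = wham_solve(histogram_windows(mirrored), m_biases)
    np.testing.assert_allclose(surf_m.values, surf.values.T, atol=1e-8)
    assert np.array_equal(surf_m.sampled, surf.sampled.T)


def test_surface_constant_offset_invariance(diagonal_plan):
    """F -> F + c leaves the trajectories (identical seeds) and hence the
    zero-referenced PMF unchanged: only energy differences enter Metropolis
    and WHAM, and the zero-reference removes the remaining constant."""
    rng = np.random.default_rng(0)
    grid = rng.uniform(0.0, 3.0, size=(12, 12))
    base = ModelSurfaceSpec("tabulated_grid", {"values": grid})
    shifted = ModelSurfaceSpec("tabulated_grid", {"values": grid + 7.0})
    cfg = SamplerConfig(n_steps=3000, seed=8)
    wa = run_umbrella_set(diagonal_plan, base, cfg)
    wb = run_umbrella_set(diagonal_plan, shifted, cfg)
    for a, b in zip(wa, wb):
        assert np.array_equal(a.trajectory.zeta, b.trajectory.zeta)
    sa, _ = wham_solve(
        histogram_windows([strip_burn_in(w) for w in wa]), [w.bias for w in wa]
    )
    sb, _ = wham_solve(
        histogram_windows([strip_burn_in(w) for w in wb]), [w.bias for w in wb]
    )
    np.testing.assert_allclose(
        sa.values[sa.sampled], sb.values[sb.sampled], atol=1e-10
    )


def test_disconnected_windows_detected():
    a = RCTrajectory(np.full((100, 2), 9.05))
    b = RCTrajectory(np.full((100, 2), 13.05))
    hists = histogram_windows([a, b], bin_width=0.1)
    with pytest.raises(DisconnectedWindowsError):
        wham_solve(hists, [BiasPotential(9.0, 9.0), BiasPotential(13.0, 13.0)])


def test_nonconvergence_flagged_not_raised(flat_surface, diagonal_plan):
    cfg = SamplerConfig(n_steps=2000, seed=1)
    windows = run_umbrella_set(diagonal_plan, flat_surface, cfg)
    stripped = [strip_burn_in(w) for w in windows]
    hists = histogram_windows(stripped)
    surface, report = wham_solve(hists, [w.bias for w in windows], max_iter=2)
    assert not report.converged
    assert report.iterations == 2
    assert np.isfinite(surface.values[surface.sampled]).all()


def test_recovery_error_decreases_with_sample_size(opening_surface):
    """PMF recovery improves with per-window sampling (5k vs 50k steps)."""
    from porepmf.synthetic.surfaces import diagonal_reference

    errs = {}
    for n in (5000, 50_000):
        surface, _ = run_diagonal_wham(opening_surface, n_steps=n, seed=6)
        prof = project_diagonal(surface)
        ref = diagonal_reference(opening_surface, prof.zeta)
        resid = prof.values - ref
        resid -= resid.mean()
        errs[n] = float(np.sqrt(np.mean(resid**2)))
    assert errs[50_000] < errs[5000]


# ------------------------------------------------- symmetrize / project / states


def _tiny_surface(values, sampled=None):
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    centers = 8.05 + 0.1 * np.arange(n)
    if sampled is None:
        sampled = np.isfinite(values)
    return PMFSurface(values, sampled, centers, centers, 0.1, 300.0)


def test_symmetrize_averages_mirror_bins():
    vals = np.full((3, 3), np.nan)
    vals[1, 2], vals[2, 1] = 2.0, 4.0
    vals[0, 0] = 0.0
    s = symmetrize(_tiny_surface(vals))
    assert s.values[1, 2] == s.values[2, 1] == pytest.approx(3.0)


def test_symmetrize_copies_one_sided_bins_and_is_idempotent():
    vals = np.full((3, 3), np.nan)
    vals[0, 0] = 0.0
    vals[0, 2] = 1.5  # mirror bin (2, 0) unsampled
    s = symmetrize(_tiny_surface(vals))
    assert s.values[2, 0] == pytest.approx(1.5)
    s2 = symmetrize(s)
    np.testing.assert_allclose(
        s2.values[s2.sampled], s.values[s.sampled], atol=1e-12
    )


def test_project_diagonal_counts_and_constructed_values():
    n = 12
    vals = np.full((n, n), np.nan)
    for i in range(n):
        vals[i, i] = float(i)
    prof = project_diagonal(_tiny_surface(vals))
    assert len(prof.zeta) == n
    np.testing.assert_allclose(prof.values, np.arange(n, dtype=float))
    assert np.all(np.diff(prof.zeta) > 0)


def test_project_requires_sampled_diagonal():
    vals = np.full((4, 4), np.nan)
    vals[0, 1] = 1.0
    with pytest.raises(EmptyProfileError):
        project_diagonal(_tiny_surface(vals))


def test_locate_states_constructed_opening_gap():
    """A profile with min 0 at 9.5 A and 5.3 kcal/mol at 11.5 A reports
    delta-G_open = 5.3."""
    zeta = np.arange(8.0, 13.0, 0.5)
    vals = np.interp(zeta, [8.0, 9.5, 11.5, 13.0], [2.0, 0.0, 5.3, 5.3])
    s = locate_states(PMFProfile1D(zeta, vals), open_zeta=11.5)
    assert s.minimum == (9.5, 0.0)
    assert s.delta_g_open == pytest.approx(5.3)
    assert s.barrier is None  # monotone rise between the states


def test_locate_states_finds_highest_interior_barrier():
    zeta = np.arange(8.0, 13.1, 0.5)
    vals = np.interp(
        zeta, [8.0, 9.0, 10.0, 10.5, 11.0, 12.0, 13.0], [3, 0, 4, 2, 4.5, 1, 1]
    )
    s = locate_states(PMFProfile1D(zeta, vals), open_zeta=12.0)
    assert s.minimum[0] == 9.0
    assert s.barrier == (11.0, 4.5)
    assert s.barrier_height == pytest.approx(4.5)
    assert s.delta_g_open == pytest.approx(1.0)


def test_locate_states_flat_profile_and_errors():
    zeta = np.arange(9.0, 12.1, 0.5)
    s = locate_states(PMFProfile1D(zeta, np.zeros_like(zeta)), open_zeta=11.5)
    assert s.delta_g_open == 0.0
    with pytest.raises(ValueError):
        locate_states(PMFProfile1D(zeta, np.zeros_like(zeta)), open_zeta=20.0)
    with pytest.raises(ValueError):
        locate_states(PMFProfile1D(zeta[:2], np.zeros(2)), open_zeta=9.0)
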