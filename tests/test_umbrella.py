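"""Window planning, bias evaluation, the umbrella driver and burn-in removal."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from porepmf.synthetic.sampler import SamplerConfig
from porepmf.synthetic.surfaces import ModelSurfaceSpec
from porepmf.trajectory import RCTrajectory
from porepmf.umbrella import (
    BiasPotential,
    UmbrellaWindow,
    WindowPlan,
    bias_energy,
    plan_windows,
    read_manifest,
    run_umbrella_set,
    strip_burn_in,
    write_manifest,
)

KT300 = 0.0019872 * 300.0


def test_bias_zero_at_center_and_hand_value():
    b = BiasPotential(9.5, 9.5, 3.0, 3.0)
    assert bias_energy(b, (9.5, 9.5)) == 0.0
    # half k dz^2 = 0.5 * 3 * 1^2
    assert bias_energy(b, (10.5, 9.5)) == pytest.approx(1.5)
    assert bias_energy(b, (9.0, 10.0)) > 0.0


@settings(deadline=None, derandomize=True)
@given(
    a=st.floats(-5, 5), b=st.floats(-5, 5), c=st.floats(8, 13), d=st.floats(8, 13)
)
def test_bias_exchange_symmetry_when_isotropic(a, b, c, d):
    """With k1 = k2, swapping both point and center coordinates leaves V unchanged."""
    bias = BiasPotential(c, d, 3.0, 3.0)
    mirrored = BiasPotential(d, c, 3.0, 3.0)
    assert bias_energy(bias, (a, b)) == pytest.approx(bias_energy(mirrored, (b, a)))


@pytest.mark.parametrize(
    "mode,expected",
    [("full_grid", 144), ("symmetric_half", 72), ("diagonal", 12)],
)
def test_default_plan_counts(mode, expected):
    """0.5 A spacing over (8.0, 13.5): 12 lattice points per axis."""
    assert len(plan_windows(mode=mode)) == expected


@pytest.mark.parametrize("n_pts", [3, 5, 8])
def test_plan_count_laws(n_pts):
    """full = n^2, diagonal = n, symmetric_half = floor(n^2/2) on any lattice."""
    domain = (8.0, 8.0 + 0.5 * (n_pts - 1))
    assert len(plan_windows(domain, mode="full_grid")) == n_pts**2
    assert len(plan_windows(domain, mode="diagonal")) == n_pts
    assert len(plan_windows(domain, mode="symmetric_half")) == n_pts**2 // 2


def test_exact_pair_count_variant():
    """Unordered-pair counting keeps n(n+1)/2 windows (78 on the 12-point grid)."""
    assert len(plan_windows(mode="symmetric_half", pair_count=True)) == 78


def test_symmetric_half_covers_grid_under_reflection():
    full = {
        (w.bias.center1, w.bias.center2) for w in plan_windows(mode="full_grid").windows
    }
    half = {
        (w.bias.center1, w.bias.center2)
        for w in plan_windows(mode="symmetric_half").windows
    }
    reflected = half | {(b, a) for a, b in half}
    off_diagonal = {(a, b) for a, b in full if a != b}
    assert off_diagonal <= reflected


def test_plan_argument_errors():
    with pytest.raises(ValueError):
        plan_windows(spacing=0.0)
    with pytest.raises(ValueError):
        plan_windows(domain=(9.0, 9.1), spacing=0.5)
    with pytest.raises(ValueError):
        plan_windows(mode="spiral")
    with pytest.raises(ValueError):
        plan_windows(k=0.0)


def test_single_window_on_harmonic_well_gaussian_product(harmonic_well):
    """Bias at the well minimum: variance is kT/(k_well + k_bias) per axis."""
    plan = WindowPlan(
        [UmbrellaWindow("w0", BiasPotential(9.5, 9.5, 3.0, 3.0))],
        mode="diagonal",
        spacing=0.5,
        domain=(8.0, 13.5),
    )
    cfg = SamplerConfig(n_steps=60_000, seed=21, step_size=0.4)
    (w,) = run_umbrella_set(plan, harmonic_well, cfg)
    traj = strip_burn_in(w)
    assert traj.zeta.mean(axis=0) == pytest.approx([9.5, 9.5], abs=0.01)
    assert traj.zeta.var(axis=0) == pytest.approx(KT300 / 6.0, rel=0.07)


def test_umbrella_set_deterministic_under_master_seed(flat_surface, diagonal_plan):
    cfg = SamplerConfig(n_steps=1500, seed=5)
    a = run_umbrella_set(diagonal_plan, flat_surface, cfg)
    b = run_umbrella_set(diagonal_plan, flat_surface, cfg)
    for wa, wb in zip(a, b):
        assert np.array_equal(wa.trajectory.zeta, wb.trajectory.zeta)
    # different windows get different seeds
    assert not np.array_equal(a[0].trajectory.zeta, a[1].trajectory.zeta)


def test_flat_surface_each_window_matches_its_bias(flat_surface, diagonal_plan):
    """On a flat surface each window is the pure bias Gaussian: mean at the
    center, per-axis variance kT/k."""
    cfg = SamplerConfig(n_steps=30_000, seed=2, proposal="bias")
    windows = run_umbrella_set(diagonal_plan, flat_surface, cfg)
    # windows within ~3 sigma of a domain edge are truncated Gaussians
    for w in windows[3:-3]:
        traj = strip_burn_in(w)
        center = (w.bias.center1, w.bias.center2)
        assert traj.zeta.mean(axis=0) == pytest.approx(center, abs=0.03)
        assert traj.zeta.var(axis=0) == pytest.approx(KT300 / 3.0, rel=0.12)


def test_strip_burn_in_contract():
    traj = RCTrajectory(np.random.default_rng(0).uniform(9, 10, (5000, 2)))
    w = UmbrellaWindow("w0", BiasPotential(9.5, 9.5), traj, burn_in_frames=1000)
    stripped = strip_burn_in(w)
    assert len(stripped) == 4000
    assert stripped.frames[0] == 1000
    w0 = UmbrellaWindow("w0", BiasPotential(9.5, 9.5), traj, burn_in_frames=0)
    assert len(strip_burn_in(w0)) == 5000
    with pytest.raises(ValueError):
        UmbrellaWindow("w0", BiasPotential(9.5, 9.5), traj, burn_in_frames=5000)


def test_manifest_round_trip(tmp_path, flat_surface):
    plan = plan_windows(domain=(9.0, 10.0), mode="diagonal")
    cfg = SamplerConfig(n_steps=500, seed=1)
    windows = run_umbrella_set(plan, flat_surface, cfg)
    path = write_manifest(windows, tmp_path, 300.0)
    back, temperature = read_manifest(path)
    assert temperature == 300.0
    assert [w.id for w in back] == [w.id for w in windows]
    for wa, wb in zip(windows, back):
        assert wa.bias == wb.bias
        np.testing.assert_allclose(wa.trajectory.zeta, wb.trajectory.zeta, atol=1e-6)


def test_plan_json_round_trip(tmp_path):
    plan = plan_windows(mode="diagonal")
    plan.to_json(tmp_path / "plan.json")
    back = WindowPlan.from_json(tmp_path / "plan.json")
    assert len(back) == len(plan)
    assert back.mode == plan.mode
    assert [w.bias for w in back.windows] == [w.bias for w in plan.windows]
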