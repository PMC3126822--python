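import numpy as np
import pytest

from mucotrack import (
    Trajectory,
    classify_immobile,
    effective_diffusivity,
    fit_alpha,
    summarize_ensemble,
    time_averaged_msd,
)
from mucotrack.msd import MSDProfile, summarize_particle


def _traj(x, y, dt=1.0, pid="P1"):
    n = len(x)
    return Trajectory("S1", "control", pid, np.arange(n) * dt, x, y)


def _msd_brute(x, y, k):
    """Independent double-loop oracle for the time-averaged MSD at lag k."""
    vals = [
        (x[i + k] - x[i]) ** 2 + (y[i + k] - y[i]) ** 2 for i in range(len(x) - k)
    ]
    return sum(vals) / len(vals)


def test_matches_brute_force_oracle_on_random_trajectories(rng):
    for _ in range(100):
        x = rng.normal(size=50)
        y = rng.normal(size=50)
        prof = time_averaged_msd(_traj(x, y), max_tau=12)
        for j, k in enumerate(range(1, 13)):
            assert prof.msd[j] == pytest.approx(_msd_brute(x, y, k), rel=1e-12)
            assert prof.n_pairs[j] == 50 - k


def test_unit_square_path():
    prof = time_averaged_msd(_traj([0, 1, 1, 0], [0, 0, 1, 1]), max_tau=3)
    np.testing.assert_allclose(prof.msd, [1.0, 2.0, 1.0])


def test_constant_trajectory_msd_zero():
    prof = time_averaged_msd(_traj([2.0] * 10, [-1.0] * 10))
    np.testing.assert_array_equal(prof.msd, 0.0)


def test_ballistic_drift_closed_form():
    v = 0.7
    t = np.arange(40) * 0.5
    prof = time_averaged_msd(_traj(v * t, np.zeros_like(t), dt=0.5), max_tau=5.0)
    np.testing.assert_allclose(prof.msd, v**2 * prof.tau**2, rtol=1e-12)


def test_max_tau_below_frame_interval_rejected():
    with pytest.raises(ValueError, match="max_tau"):
        time_averaged_msd(_traj([0.0, 1.0, 2.0], [0.0] * 3), max_tau=0.5)


def test_effective_diffusivity_formula():
    prof = MSDProfile("S1", "c", "P1", np.array([1.0]), np.array([1.0]),
                      np.array([10]), 1.0)
    assert effective_diffusivity(prof, 1.0) == pytest.approx(0.25)
    zero = MSDProfile("S1", "c", "P1", np.array([1.0]), np.array([0.0]),
                      np.array([10]), 1.0)
    assert effective_diffusivity(zero, 1.0) == 0.0


def test_tau_ref_snaps_to_nearest_grid_lag():
    # 66.7 ms frames: lag 15 (1.0005 s) represents tau_ref = 1 s
    dt = 0.0667
    tau = np.arange(1, 30) * dt
    msd = 4.0 * 0.5 * tau  # Brownian, D = 0.5
    prof = MSDProfile("S1", "c", "P1", tau, msd, np.ones_like(tau, dtype=int), dt)
    assert prof._index_of(1.0) == 14
    assert effective_diffusivity(prof, 1.0) == pytest.approx(0.5)
    with pytest.raises(ValueError, match="outside"):
        effective_diffusivity(prof, 10.0)


def test_fit_alpha_trivial_cases():
    tau = np.linspace(0.2, 2.0, 10)
    assert fit_alpha((tau, 4 * 0.3 * tau)) == pytest.approx(1.0)
    assert fit_alpha((tau, np.full_like(tau, 1e-4))) == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(ValueError, match="floor"):
        fit_alpha((tau, np.zeros_like(tau)))
    with pytest.raises(ValueError, match="3 lags"):
        fit_alpha((tau[:2], tau[:2]))


def test_classify_immobile_threshold():
    dt = 0.0667
    tau = np.arange(1, 30) * dt
    static = MSDProfile("S1", "c", "P1", tau, np.full_like(tau, 5e-5),
                        np.ones_like(tau, dtype=int), dt)
    mobile = MSDProfile("S1", "c", "P2", tau, np.full_like(tau, 1.0),
                        np.ones_like(tau, dtype=int), dt)
    assert classify_immobile(static)
    assert not classify_immobile(mobile)


def test_geometric_mean_of_two_particles():
    dt = 0.0667
    n = 300
    times = np.arange(n) * dt
    # deterministic curves via ballistic paths of different speeds won't give
    # constant msd ratio; instead summarize directly from profiles
    tau = np.arange(1, 20) * dt
    p1 = MSDProfile("S1", "c", "P1", tau, np.full_like(tau, 1.0),
                    np.ones_like(tau, dtype=int), dt)
    p2 = MSDProfile("S1", "c", "P2", tau, np.full_like(tau, 4.0),
                    np.ones_like(tau, dtype=int), dt)
    ens = summarize_ensemble([p1, p2])
    np.testing.assert_allclose(ens.msd_geo, 2.0)
    assert ens.n_particles == 2


def test_single_particle_ensemble_equals_own_msd(rng):
    x, y = rng.normal(size=(2, 300))
    prof = time_averaged_msd(_traj(x, y, dt=0.0667))
    ens = summarize_ensemble([prof])
    np.testing.assert_allclose(ens.msd_geo, np.maximum(prof.msd, 1e-4))


def test_empty_group_rejected():
    with pytest.raises(ValueError, match="empty"):
        summarize_ensemble([])


def test_geometric_le_arithmetic_mean(rng):
    """AM-GM: the ensemble geometric-mean curve never exceeds the arithmetic mean."""
    profs = []
    for i in range(20):
        x, y = np.cumsum(rng.normal(size=(2, 200)), axis=1)
        profs.append(time_averaged_msd(_traj(x, y, dt=0.1, pid=f"P{i}")))
    ens = summarize_ensemble(profs)
    arith = np.mean([p.msd[: ens.tau.size] for p in profs], axis=0)
    assert np.all(ens.msd_geo <= arith + 1e-12)


def test_deff_invariant_under_rigid_motion(rng):
    """D_eff depends on displacements only: translation/rotation leave it fixed."""
    x, y = np.cumsum(rng.normal(size=(2, 200)), axis=1)
    theta = 0.77
    xr = np.cos(theta) * x - np.sin(theta) * y + 13.0
    yr = np.sin(theta) * x + np.cos(theta) * y - 4.2
    d0 = effective_diffusivity(time_averaged_msd(_traj(x, y, dt=0.1)), 1.0)
    d1 = effective_diffusivity(time_averaged_msd(_traj(xr, yr, dt=0.1)), 1.0)
    assert d1 == pytest.approx(d0, rel=1e-10)


def test_summarize_particle_immobile_reports_flat_alpha():
    dt = 0.0667
    tau = np.arange(1, 40) * dt
    prof = MSDProfile("S1", "c", "P1", tau, np.full_like(tau, 5e-5),
                      np.ones_like(tau, dtype=int), dt)
    s = summarize_particle(prof)
    assert s.immobile
    assert s.alpha == pytest.approx(0.0, abs=1e-12)  # floored flat curve
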