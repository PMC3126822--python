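import numpy as np
import pytest

from mucotrack import (
    ConditionParams,
    StudyDesign,
    SyntheticParticleSpec,
    fgn_increments,
    generate_study,
    generate_trajectory,
    summarize_ensemble,
    time_averaged_msd,
)
from mucotrack.synthetic import _fgn_davies_harte


def _ensemble_profiles(spec, n, seed0=0):
    return [
        time_averaged_msd(generate_trajectory(spec, seed0 + s, particle_id=f"P{s}"))
        for s in range(n)
    ]


def test_immobile_zero_noise_is_static():
    spec = SyntheticParticleSpec("immobile", noise_sd=0.0, n_frames=50)
    traj = generate_trajectory(spec, 0)
    assert np.all(traj.x == traj.x[0]) and np.all(traj.y == traj.y[0])
    assert np.all(time_averaged_msd(traj).msd == 0.0)


def test_brownian_ensemble_msd_anchored_at_one_second():
    """2-D Brownian motion: expected MSD(1 s) = 4*D = 2.0 µm² at D = 0.5."""
    spec = SyntheticParticleSpec("brownian", d_eff_1s=0.5, noise_sd=0.0)
    profs = _ensemble_profiles(spec, 200)
    msd_1s = np.mean([p.msd_at(1.0) for p in profs])
    assert msd_1s == pytest.approx(2.0, rel=0.10)


def test_subdiffusive_ensemble_loglog_slope():
    spec = SyntheticParticleSpec("subdiffusive", d_eff_1s=0.02, alpha=0.68, noise_sd=0.0)
    ens = summarize_ensemble(_ensemble_profiles(spec, 200))
    assert abs(ens.alpha - 0.68) <= 0.06


@pytest.mark.parametrize("alpha", [0.36, 0.68, 1.0])
def test_noiseless_ensembles_recover_planted_parameters(alpha):
    """Fitted alpha within ±0.06 and D_eff within ±15% (n = 200 particles)."""
    cls = "brownian" if alpha == 1.0 else "subdiffusive"
    spec = SyntheticParticleSpec(cls, d_eff_1s=0.1, alpha=alpha, noise_sd=0.0)
    ens = summarize_ensemble(_ensemble_profiles(spec, 200))
    assert abs(ens.alpha - alpha) <= 0.06
    assert ens.mean_deff_1s == pytest.approx(0.1, rel=0.15)


def test_noise_floor_of_immobile_ensemble():
    """Static particles with 0.01 µm noise sit at MSD = 4*sd² = 4e-4, flat in tau."""
    spec = SyntheticParticleSpec("immobile", noise_sd=0.01)
    profs = _ensemble_profiles(spec, 100)
    mean_curve = np.mean([p.msd for p in profs], axis=0)
    np.testing.assert_allclose(mean_curve, 4e-4, rtol=0.20)


def test_fgn_brownian_increments_uncorrelated(rng):
    x = fgn_increments(10_000, 0.5, rng)
    lag1 = np.mean(x[:-1] * x[1:]) / np.var(x)
    assert abs(lag1) < 0.05


@pytest.mark.parametrize("hurst", [0.18, 0.34])
def test_fgn_generators_agree_with_theory(hurst):
    """Cholesky and Davies-Harte paths both match the fGn autocovariance."""
    h2 = 2 * hurst
    theory_lag1 = 0.5 * (2**h2 - 2)
    chol = np.stack([fgn_increments(400, hurst, np.random.default_rng(s)) for s in range(300)])
    dh = np.stack([_fgn_davies_harte(2000, hurst, np.random.default_rng(s)) for s in range(100)])
    for sample in (chol, dh):
        assert np.var(sample) == pytest.approx(1.0, rel=0.05)
        lag1 = np.mean(sample[:, :-1] * sample[:, 1:])
        assert lag1 == pytest.approx(theory_lag1, abs=0.02)


@pytest.mark.parametrize(
    "kwargs, field",
    [
        (dict(motion_class="warp"), "motion_class"),
        (dict(motion_class="brownian", d_eff_1s=-1), "d_eff_1s"),
        (dict(motion_class="subdiffusive", alpha=0.0), "alpha"),
        (dict(motion_class="subdiffusive", alpha=1.5), "alpha"),
        (dict(motion_class="immobile", noise_sd=-0.1), "noise_sd"),
        (dict(motion_class="immobile", n_frames=1), "n_frames"),
        (dict(motion_class="immobile", frame_interval=0.0), "frame_interval"),
    ],
)
def test_spec_validation_names_offending_field(kwargs, field):
    with pytest.raises(ValueError, match=field):
        SyntheticParticleSpec(**kwargs)


def test_study_determinism_byte_identical(tmp_path):
    from mucotrack import write_trajectories

    design = StudyDesign(n_samples=2, n_particles_per_sample=5, n_frames=40, seed=7)
    paths = []
    for i in range(2):
        p = tmp_path / f"run{i}.csv"
        write_trajectories(generate_study(design), p)
        paths.append(p)
    assert paths[0].read_bytes() == paths[1].read_bytes()


def test_study_layout_and_pairing(default_study):
    experiment, truth = default_study
    groups = experiment.groups()
    assert len(groups) == 12  # 6 samples x 2 conditions
    assert all(len(g) == 100 for g in groups.values())
    samples = {sid for sid, _ in groups}
    for sid in samples:  # paired design: every sample in both conditions
        assert (sid, "control") in groups and (sid, "treated") in groups


def test_planted_immobile_fractions(default_study):
    _, truth = default_study
    for cond, expected in [("control", 0.33), ("treated", 0.20)]:
        frac = (truth.loc[truth.condition == cond, "motion_class"] == "immobile").mean()
        assert frac == pytest.approx(expected, abs=0.08)


def test_condition_params_validation():
    with pytest.raises(ValueError, match="immobile_fraction"):
        ConditionParams(immobile_fraction=1.2, alpha=0.5, d_eff_log_mean=0, d_eff_log_sd=1)
    with pytest.raises(ValueError, match="exceeds 1"):
        ConditionParams(immobile_fraction=0.5, alpha=0.9, d_eff_log_mean=0, d_eff_log_sd=1)
    # mobile alpha compensates for the flat immobile subpopulation
    cp = ConditionParams(immobile_fraction=0.33, alpha=0.36, d_eff_log_mean=0, d_eff_log_sd=1)
    assert cp.alpha_mobile == pytest.approx(0.36 / 0.67)


def test_null_design_gives_no_systematic_direction():
    """Identical conditions, no sample effects: one-tailed p > 0.05 in >= 90% of seeds."""
    from mucotrack import wilcoxon_signed_rank_one_tailed

    params = ConditionParams(
        immobile_fraction=0.0, alpha=1.0, d_eff_log_mean=np.log(0.01), d_eff_log_sd=0.5
    )
    design_base = dict(
        n_samples=6, n_particles_per_sample=8, n_frames=60,
        condition_params={"control": params, "treated": params},
        per_sample_effect_sd=0.0,
    )
    rejected = 0
    n_seeds = 50
    for seed in range(n_seeds):
        _, truth = generate_study(StudyDesign(seed=seed, **design_base), return_truth=True)
        means = truth.groupby(["sample_id", "condition"])["d_eff_1s"].mean().unstack()
        p = wilcoxon_signed_rank_one_tailed(
            means["control"].to_numpy(), means["treated"].to_numpy()
        )
        rejected += p <= 0.05
    assert rejected <= 0.10 * n_seeds
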