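"""Synthetic particle-tracking ensembles with planted transport parameters.

Emulates multiple-particle-tracking (MPT) experiments on muco-inert probe
particles in a heterogeneous gel: an immobile subpopulation pinned at the
localization-noise floor, and a mobile subpopulation undergoing fractional
Brownian motion (fBm) with anomalous exponent ``alpha`` and a log-normal
spread of effective diffusivities. A paired study design plants a shared
per-sample multiplicative effect in both conditions so that paired
statistics downstream act on real pairing.

Scaling convention: a mobile particle's position per coordinate is fBm with
Hurst index H = alpha/2 and Var[X(t)] = 2*d_eff_1s * t**alpha, so the
expected 2-D MSD is 4*d_eff_1s*tau**alpha — anchored at tau = 1 s, the
reference time scale of the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .io import Trajectory, TrackingExperiment

MOTION_CLASSES = ("immobile", "subdiffusive", "brownian")

#: defaults matching the reference experiment: 66.7 ms frames for 20 s
DEFAULT_FRAME_INTERVAL = 0.0667
DEFAULT_N_FRAMES = 300
#: per-coordinate localization noise (µm); static-probe apparent MSD is
#: 4*sigma^2 = 6.4e-5 µm², just under the (10 nm)^2 tracking-resolution floor
DEFAULT_NOISE_SD = 0.004


@dataclass(frozen=True)
class SyntheticParticleSpec:
    """Parameters of one synthetic particle's motion."""

    motion_class: str
    d_eff_1s: float = 0.0  # µm²/s at tau = 1 s
    alpha: float = 1.0  # in (0, 1]
    noise_sd: float = DEFAULT_NOISE_SD  # µm per coordinate
    n_frames: int = DEFAULT_N_FRAMES
    frame_interval: float = DEFAULT_FRAME_INTERVAL  # s

    def __post_init__(self) -> None:
        if self.motion_class not in MOTION_CLASSES:
            raise ValueError(
                f"motion_class must be one of {MOTION_CLASSES}, got {self.motion_class!r}"
            )
        if not self.d_eff_1s >= 0:
            raise ValueError(f"d_eff_1s must be >= 0, got {self.d_eff_1s}")
        if not 0 < self.alpha <= 1:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if not self.noise_sd >= 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if not self.n_frames >= 2:
            raise ValueError(f"n_frames must be >= 2, got {self.n_frames}")
        if not self.frame_interval > 0:
            raise ValueError(f"frame_interval must be > 0, got {self.frame_interval}")


# ---------------------------------------------------------------------------
# fractional Gaussian noise
# ---------------------------------------------------------------------------

_CHOLESKY_CACHE: dict[tuple[int, float], np.ndarray] = {}
_EIGVAL_CACHE: dict[tuple[int, float], np.ndarray] = {}
_CHOLESKY_MAX_N = 1024


def _fgn_autocov(n: int, hurst: float) -> np.ndarray:
    """Autocovariance gamma(0..n) of unit-step-variance fGn."""
    k = np.arange(n + 1, dtype=float)
    h2 = 2.0 * hurst
    return 0.5 * ((k + 1.0) ** h2 - 2.0 * k**h2 + np.abs(k - 1.0) ** h2)


def fgn_increments(n: int, hurst: float, rng: np.random.Generator) -> np.ndarray:
    """Sample ``n`` unit-step-variance fractional Gaussian noise increments.

    Uses an exact Cholesky factor of the Toeplitz covariance for short
    series and Davies–Harte circulant embedding for long ones. ``hurst``
    must lie in (0, 0.5], where the circulant embedding is non-negative
    definite; H = 0.5 short-circuits to i.i.d. Gaussians.
    """
    if not 0 < hurst <= 0.5:
        raise ValueError(f"hurst must be in (0, 0.5], got {hurst}")
    if abs(hurst - 0.5) < 1e-12:
        return rng.standard_normal(n)
    if n <= _CHOLESKY_MAX_N:
        key = (n, round(hurst, 12))
        chol = _CHOLESKY_CACHE.get(key)
        if chol is None:
            gamma = _fgn_autocov(n - 1, hurst)
            from scipy.linalg import toeplitz

            chol = np.linalg.cholesky(toeplitz(gamma))
            _CHOLESKY_CACHE[key] = chol
        return chol @ rng.standard_normal(n)
    return _fgn_davies_harte(n, hurst, rng)


def _fgn_davies_harte(n: int, hurst: float, rng: np.random.Generator) -> np.ndarray:
    key = (n, round(hurst, 12))
    lam = _EIGVAL_CACHE.get(key)
    if lam is None:
        gamma = _fgn_autocov(n, hurst)
        row = np.concatenate([gamma, gamma[-2:0:-1]])  # circulant first row, length 2n
        lam = np.fft.fft(row).real
        if lam.min() < -1e-8 * lam.max():  # pragma: no cover - guaranteed NND for H <= 1/2
            raise RuntimeError("circulant embedding not non-negative definite")
        lam = np.clip(lam, 0.0, None)
        _EIGVAL_CACHE[key] = lam
    m = 2 * n
    u = rng.standard_normal(n + 1)
    v = rng.standard_normal(n - 1)
    w = np.empty(m, dtype=complex)
    w[0] = np.sqrt(lam[0] / m) * u[0]
    w[1:n] = np.sqrt(lam[1:n] / (2 * m)) * (u[1:n] + 1j * v)
    w[n] = np.sqrt(lam[n] / m) * u[n]
    w[n + 1 :] = np.conj(w[n - 1 : 0 : -1])
    return np.fft.fft(w)[:n].real


def _mobile_positions(spec: SyntheticParticleSpec, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """True (noise-free) x, y for a mobile particle, starting at the origin."""
    n_steps = spec.n_frames - 1
    hurst = spec.alpha / 2.0
    # per-coordinate Var over lag tau is 2*d*tau^alpha -> step sd:
    step_sd = np.sqrt(2.0 * spec.d_eff_1s) * spec.frame_interval**hurst
    xy = []
    for _ in range(2):
        inc = step_sd * fgn_increments(n_steps, hurst, rng)
        xy.append(np.concatenate([[0.0], np.cumsum(inc)]))
    return xy[0], xy[1]


def generate_trajectory(
    spec: SyntheticParticleSpec,
    seed: int | np.random.SeedSequence | np.random.Generator,
    sample_id: str = "S1",
    condition: str = "control",
    particle_id: str = "P1",
) -> Trajectory:
    """Generate one observed trajectory: true motion plus localization noise.

    Immobile particles have a constant true position; observed positions are
    the true position plus independent Gaussian noise per coordinate per
    frame. Brownian motion is the alpha = 1 special case of fBm.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    times = np.arange(spec.n_frames) * spec.frame_interval
    if spec.motion_class == "immobile":
        x = np.zeros(spec.n_frames)
        y = np.zeros(spec.n_frames)
    else:
        eff = spec if spec.motion_class != "brownian" else replace(spec, alpha=1.0)
        x, y = _mobile_positions(eff, rng)
    if spec.noise_sd > 0:
        x = x + spec.noise_sd * rng.standard_normal(spec.n_frames)
        y = y + spec.noise_sd * rng.standard_normal(spec.n_frames)
    return Trajectory(
        sample_id=sample_id, condition=condition, particle_id=particle_id,
        times=times, x=x, y=y,
    )


# ---------------------------------------------------------------------------
# paired study design
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConditionParams:
    """Population parameters for one experimental condition.

    ``alpha`` is the target *ensemble* anomalous exponent (slope of the
    geometric-mean MSD curve including the flat immobile subpopulation);
    mobile particles are planted with alpha/(1 - immobile_fraction) so that
    the recovered ensemble slope matches the target.
    """

    immobile_fraction: float
    alpha: float
    d_eff_log_mean: float  # natural log of µm²/s
    d_eff_log_sd: float

    def __post_init__(self) -> None:
        if not 0 <= self.immobile_fraction <= 1:
            raise ValueError(f"immobile_fraction must be in [0, 1], got {self.immobile_fraction}")
        if not 0 < self.alpha <= 1:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if not self.d_eff_log_sd >= 0:
            raise ValueError(f"d_eff_log_sd must be >= 0, got {self.d_eff_log_sd}")
        if self.immobile_fraction < 1 and (
            self.alpha / (1.0 - self.immobile_fraction) > 1 + 1e-9
        ):
            raise ValueError(
                "ensemble alpha / (1 - immobile_fraction) exceeds 1; "
                "reduce alpha or immobile_fraction"
            )

    @property
    def alpha_mobile(self) -> float:
        if self.immobile_fraction >= 1:
            return 1.0
        return min(self.alpha / (1.0 - self.immobile_fraction), 1.0)


#: study-scale defaults: ~100-fold hindrance of 1 µm probes in the control
#: gel, a 10-fold diffusivity shift on treatment, immobile fraction dropping
#: from 33% to 20%, ensemble alpha rising from 0.36 to 0.68
DEFAULT_CONDITION_PARAMS: Mapping[str, ConditionParams] = {
    "control": ConditionParams(
        immobile_fraction=0.33, alpha=0.36,
        d_eff_log_mean=float(np.log(5.0e-3)), d_eff_log_sd=1.8,
    ),
    "treated": ConditionParams(
        immobile_fraction=0.20, alpha=0.68,
        d_eff_log_mean=float(np.log(5.0e-2)), d_eff_log_sd=1.8,
    ),
}


@dataclass(frozen=True)
class StudyDesign:
    """Paired multi-donor study layout: every sample appears in every condition."""

    n_samples: int = 6
    n_particles_per_sample: int = 100
    condition_params: Mapping[str, ConditionParams] = field(
        default_factory=lambda: dict(DEFAULT_CONDITION_PARAMS)
    )
    per_sample_effect_sd: float = 0.4  # log-scale donor heterogeneity, shared across conditions
    noise_sd: float = DEFAULT_NOISE_SD
    n_frames: int = DEFAULT_N_FRAMES
    frame_interval: float = DEFAULT_FRAME_INTERVAL
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_samples >= 1:
            raise ValueError(f"n_samples must be >= 1, got {self.n_samples}")
        if not self.n_particles_per_sample >= 1:
            raise ValueError(
                f"n_particles_per_sample must be >= 1, got {self.n_particles_per_sample}"
            )
        if not self.condition_params:
            raise ValueError("condition_params must name at least one condition")
        if not self.per_sample_effect_sd >= 0:
            raise ValueError(f"per_sample_effect_sd must be >= 0, got {self.per_sample_effect_sd}")


def generate_study(
    design: StudyDesign, return_truth: bool = False
) -> TrackingExperiment | tuple[TrackingExperiment, pd.DataFrame]:
    """Generate a full paired study, reproducible from ``design.seed``.

    Per-sample multiplicative D_eff effects (log-normal,
    ``per_sample_effect_sd``) are drawn once per sample and applied to all
    of that sample's conditions, so the paired structure is real. Every
    particle has its own deterministic random substream keyed by
    (sample, condition, particle) index.

    With ``return_truth`` the planted per-particle ground truth (motion
    class, d_eff_1s, alpha) is returned as a second value.
    """
    master = design.seed
    sample_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=master, spawn_key=(0,))
    )
    sample_effects = design.per_sample_effect_sd * sample_rng.standard_normal(design.n_samples)
    trajectories: list[Trajectory] = []
    truth_rows: list[dict] = []
    for s_idx in range(design.n_samples):
        sample_id = f"S{s_idx + 1}"
        for c_idx, (condition, params) in enumerate(design.condition_params.items()):
            for p_idx in range(design.n_particles_per_sample):
                rng = np.random.default_rng(
                    np.random.SeedSequence(
                        entropy=master, spawn_key=(1, s_idx, c_idx, p_idx)
                    )
                )
                immobile = rng.random() < params.immobile_fraction
                if immobile:
                    spec = SyntheticParticleSpec(
                        motion_class="immobile",
                        noise_sd=design.noise_sd,
                        n_frames=design.n_frames,
                        frame_interval=design.frame_interval,
                    )
                    d_true, a_true = 0.0, 0.0
                else:
                    d_true = float(
                        np.exp(
                            params.d_eff_log_mean
                            + sample_effects[s_idx]
                            + params.d_eff_log_sd * rng.standard_normal()
                        )
                    )
                    a_true = params.alpha_mobile
                    spec = SyntheticParticleSpec(
                        motion_class="brownian" if a_true >= 1.0 else "subdiffusive",
                        d_eff_1s=d_true,
                        alpha=a_true,
                        noise_sd=design.noise_sd,
                        n_frames=design.n_frames,
                        frame_interval=design.frame_interval,
                    )
                particle_id = f"P{p_idx + 1:04d}"
                trajectories.append(
                    generate_trajectory(
                        spec, rng, sample_id=sample_id, condition=condition,
                        particle_id=particle_id,
                    )
                )
                truth_rows.append(
                    {
                        "sample_id": sample_id,
                        "condition": condition,
                        "particle_id": particle_id,
                        "motion_class": spec.motion_class,
                        "d_eff_1s": d_true,
                        "alpha": a_true,
                    }
                )
    experiment = TrackingExperiment(trajectories)
    if return_truth:
        return experiment, pd.DataFrame(truth_rows)
    return experiment
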