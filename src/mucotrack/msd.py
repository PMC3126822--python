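"""Time-averaged MSD, effective diffusivity, anomalous exponent, immobility.

For a trajectory sampled at uniform interval dt, the time-averaged mean
squared displacement at lag tau = k*dt is

    MSD(tau) = < [x(t+tau) - x(t)]^2 + [y(t+tau) - y(t)]^2 >_t

averaged over all n-k overlapping start times. The effective diffusivity at
a reference lag is D_eff = MSD(tau)/(4*tau) (2-D tracking), and the
anomalous exponent alpha is the least-squares slope of log MSD vs log tau.
Particles whose MSD at 1 s lies below the square of the tracking resolution
(default 10 nm) are classified immobile.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import SUMMARY_COLUMNS, Trajectory, TrackingExperiment

#: tracking resolution (µm); MSD floor and immobile threshold are its square
DEFAULT_RESOLUTION = 0.01
DEFAULT_TAU_REF = 1.0
DEFAULT_ALPHA_FIT_RANGE = (0.2, 2.0)
#: lags beyond this fraction of the track duration are too noisy to report
MAX_LAG_FRACTION = 0.25


@dataclass(frozen=True)
class MSDProfile:
    """Per-particle time-averaged MSD versus lag time."""

    sample_id: str
    condition: str
    particle_id: str
    tau: np.ndarray  # s
    msd: np.ndarray  # µm²
    n_pairs: np.ndarray  # overlapping displacement pairs per lag
    frame_interval: float

    def msd_at(self, tau_ref: float) -> float:
        """MSD at the grid lag nearest to ``tau_ref`` (error if out of range)."""
        return float(self.msd[self._index_of(tau_ref)])

    def _index_of(self, tau_ref: float) -> int:
        if tau_ref < self.tau[0] - 0.5 * self.frame_interval or tau_ref > self.tau[-1] + 0.5 * self.frame_interval:
            raise ValueError(
                f"tau_ref={tau_ref} s outside profile range "
                f"[{self.tau[0]:.4g}, {self.tau[-1]:.4g}] s"
            )
        return int(np.argmin(np.abs(self.tau - tau_ref)))


@dataclass(frozen=True)
class ParticleSummary:
    sample_id: str
    condition: str
    particle_id: str
    deff_1s: float  # µm²/s
    alpha: float  # NaN when the fit is undefined (e.g. zero MSD)
    immobile: bool


@dataclass(frozen=True)
class EnsembleSummary:
    """Geometric-mean MSD curve and scalar summaries for one particle group."""

    sample_id: str
    condition: str
    tau: np.ndarray
    msd_geo: np.ndarray  # µm², geometric mean (floored at resolution²)
    mean_deff_1s: float  # arithmetic mean over particles
    alpha: float  # fitted on the geometric-mean curve
    immobile_fraction: float
    n_particles: int


def time_averaged_msd(trajectory: Trajectory, max_tau: float | None = None) -> MSDProfile:
    """Time-averaged MSD over all overlapping displacement pairs.

    ``max_tau`` defaults to a quarter of the track duration (longer lags
    average too few pairs to be reliable).
    """
    dt = trajectory.frame_interval
    if max_tau is None:
        max_tau = MAX_LAG_FRACTION * trajectory.duration
    if max_tau < dt:
        raise ValueError(f"max_tau={max_tau} s is below the frame interval {dt} s")
    max_lag = min(int(np.floor(max_tau / dt + 1e-9)), trajectory.n_frames - 1)
    x, y = trajectory.x, trajectory.y
    msd = np.empty(max_lag)
    n_pairs = np.empty(max_lag, dtype=int)
    for k in range(1, max_lag + 1):
        dx = x[k:] - x[:-k]
        dy = y[k:] - y[:-k]
        msd[k - 1] = np.mean(dx * dx + dy * dy)
        n_pairs[k - 1] = dx.size
    return MSDProfile(
        sample_id=trajectory.sample_id,
        condition=trajectory.condition,
        particle_id=trajectory.particle_id,
        tau=np.arange(1, max_lag + 1) * dt,
        msd=msd,
        n_pairs=n_pairs,
        frame_interval=dt,
    )


def effective_diffusivity(profile: MSDProfile, tau_ref: float = DEFAULT_TAU_REF) -> float:
    """D_eff = MSD(tau_ref)/(4*tau_ref), with tau_ref snapped to the lag grid."""
    i = profile._index_of(tau_ref)
    return float(profile.msd[i] / (4.0 * profile.tau[i]))


def fit_alpha(
    profile_or_curve: MSDProfile | tuple[np.ndarray, np.ndarray],
    tau_range: tuple[float, float] = DEFAULT_ALPHA_FIT_RANGE,
) -> float:
    """Least-squares slope of log MSD vs log tau over ``tau_range``.

    alpha = 1 is unconstrained Brownian transport; alpha = 0 a flat
    (noise-floor or static) curve. Accepts a per-particle profile or a bare
    (tau, msd) curve such as an ensemble geometric mean.
    """
    if isinstance(profile_or_curve, MSDProfile):
        tau, msd = profile_or_curve.tau, profile_or_curve.msd
    else:
        tau, msd = (np.asarray(a, dtype=float) for a in profile_or_curve)
    lo, hi = tau_range
    mask = (tau >= lo - 1e-12) & (tau <= hi + 1e-12)
    if mask.sum() < 3:
        raise ValueError(
            f"need >= 3 lags inside tau_range {tau_range}, got {int(mask.sum())}"
        )
    if np.any(msd[mask] <= 0):
        raise ValueError(
            "MSD <= 0 inside the fit range; floor values at the resolution "
            "limit (resolution**2) before fitting, as done for ensemble curves"
        )
    slope, _ = np.polyfit(np.log(tau[mask]), np.log(msd[mask]), 1)
    return float(slope)


def classify_immobile(
    profile: MSDProfile,
    resolution: float = DEFAULT_RESOLUTION,
    tau_ref: float = DEFAULT_TAU_REF,
) -> bool:
    """Immobile iff MSD(tau_ref) < resolution²  (default (10 nm)² = 1e-4 µm²)."""
    return profile.msd_at(tau_ref) < resolution**2


def summarize_particle(
    profile: MSDProfile,
    tau_ref: float = DEFAULT_TAU_REF,
    alpha_fit_range: tuple[float, float] = DEFAULT_ALPHA_FIT_RANGE,
    resolution: float = DEFAULT_RESOLUTION,
) -> ParticleSummary:
    """Per-particle D_eff, alpha and immobility flag.

    The per-particle alpha is fitted on the resolution-floored curve so that
    immobile particles report alpha ~ 0 rather than a log-of-zero failure;
    a fully degenerate (all-zero) curve reports NaN.
    """
    deff = effective_diffusivity(profile, tau_ref)
    floored = np.maximum(profile.msd, resolution**2)
    if np.all(profile.msd <= 0):
        alpha = float("nan")
    else:
        alpha = fit_alpha((profile.tau, floored), alpha_fit_range)
    return ParticleSummary(
        sample_id=profile.sample_id,
        condition=profile.condition,
        particle_id=profile.particle_id,
        deff_1s=deff,
        alpha=alpha,
        immobile=classify_immobile(profile, resolution, tau_ref),
    )


def summarize_ensemble(
    trajectories_or_profiles: Sequence[Trajectory] | Sequence[MSDProfile],
    tau_ref: float = DEFAULT_TAU_REF,
    alpha_fit_range: tuple[float, float] = DEFAULT_ALPHA_FIT_RANGE,
    resolution: float = DEFAULT_RESOLUTION,
    max_tau: float | None = None,
) -> EnsembleSummary:
    """Ensemble summary of one (sample, condition) group.

    The headline curve is the geometric mean of per-particle MSDs at each
    lag, with values floored at resolution² before log-averaging (the
    measurement floor; keeps immobile particles from contributing -inf).
    The ensemble alpha is fitted on this curve; mean D_eff is the arithmetic
    mean over particles, immobile particles included.
    """
    items = list(trajectories_or_profiles)
    if not items:
        raise ValueError("cannot summarize an empty particle group")
    profiles = [
        p if isinstance(p, MSDProfile) else time_averaged_msd(p, max_tau) for p in items
    ]
    n_lags = min(p.tau.size for p in profiles)
    tau = profiles[0].tau[:n_lags]
    floored = np.stack([np.maximum(p.msd[:n_lags], resolution**2) for p in profiles])
    msd_geo = np.exp(np.mean(np.log(floored), axis=0))
    summaries = [
        summarize_particle(p, tau_ref, alpha_fit_range, resolution) for p in profiles
    ]
    return EnsembleSummary(
        sample_id=profiles[0].sample_id,
        condition=profiles[0].condition,
        tau=tau,
        msd_geo=msd_geo,
        mean_deff_1s=float(np.mean([s.deff_1s for s in summaries])),
        alpha=fit_alpha((tau, msd_geo), alpha_fit_range),
        immobile_fraction=float(np.mean([s.immobile for s in summaries])),
        n_particles=len(profiles),
    )


def analyze_experiment(
    experiment: TrackingExperiment,
    tau_ref: float = DEFAULT_TAU_REF,
    alpha_fit_range: tuple[float, float] = DEFAULT_ALPHA_FIT_RANGE,
    resolution: float = DEFAULT_RESOLUTION,
    max_tau: float | None = None,
) -> tuple[pd.DataFrame, dict[tuple[str, str], EnsembleSummary]]:
    """Per-particle summary table plus per-(sample, condition) ensembles."""
    rows = []
    ensembles: dict[tuple[str, str], EnsembleSummary] = {}
    for key, group in experiment.groups().items():
        profiles = [time_averaged_msd(t, max_tau) for t in group]
        for p in profiles:
            s = summarize_particle(p, tau_ref, alpha_fit_range, resolution)
            rows.append(
                {
                    "sample_id": s.sample_id,
                    "condition": s.condition,
                    "particle_id": s.particle_id,
                    "deff_1s_um2_s": s.deff_1s,
                    "alpha": s.alpha,
                    "immobile": int(s.immobile),
                }
            )
        ensembles[key] = summarize_ensemble(profiles, tau_ref, alpha_fit_range, resolution)
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS), ensembles


def pooled_ensemble(
    ensembles: Iterable[EnsembleSummary], condition: str,
    alpha_fit_range: tuple[float, float] = DEFAULT_ALPHA_FIT_RANGE,
) -> EnsembleSummary:
    """Pool per-sample ensembles of one condition (equal-weight log-average).

    Weighting samples equally (rather than particles) matches a per-donor
    experimental structure where every donor contributes one curve.
    """
    group = [e for e in ensembles if e.condition == condition]
    if not group:
        raise ValueError(f"no ensembles for condition {condition!r}")
    n_lags = min(e.tau.size for e in group)
    tau = group[0].tau[:n_lags]
    msd_geo = np.exp(np.mean(np.log([e.msd_geo[:n_lags] for e in group]), axis=0))
    return EnsembleSummary(
        sample_id="pooled",
        condition=condition,
        tau=tau,
        msd_geo=msd_geo,
        mean_deff_1s=float(np.mean([e.mean_deff_1s for e in group])),
        alpha=fit_alpha((tau, msd_geo), alpha_fit_range),
        immobile_fraction=float(np.mean([e.immobile_fraction for e in group])),
        n_particles=int(sum(e.n_particles for e in group)),
    )
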