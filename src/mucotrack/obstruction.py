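"""Obstruction-scaling model: hindered diffusivity <-> effective pore radius.

For a probe of radius r_s diffusing through a fiber gel (fiber radius r_f,
effective pore radius r_g), the obstruction-scaling model gives

    D_g / D_o = exp( -(pi/4) * ((r_s + r_f) / (r_g + r_f))**2 )

where D_g is the diffusivity in the gel and D_o in water. Inverting the
ratio measured for each particle yields a per-particle pore radius; the
reported "pore size" / mesh spacing is the diameter 2*r_g, the scale on
which probe diameters are quoted. Ratios >= 1 (apparent diffusion at or
above the water reference, i.e. measurement noise) are flagged censored
and count toward every ">= threshold" spacing fraction, never clamped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from scipy import constants

#: defaults for 1 µm probes in mucus: probe radius 500 nm, mucin fiber
#: radius 3.5 nm (biochemical/EM/AFM consensus estimate)
DEFAULT_PROBE_RADIUS_NM = 500.0
DEFAULT_FIBER_RADIUS_NM = 3.5
DEFAULT_TEMPERATURE_K = 298.15
DEFAULT_WATER_VISCOSITY_PA_S = 8.9e-4


@dataclass(frozen=True)
class ObstructionParams:
    r_s: float = DEFAULT_PROBE_RADIUS_NM  # probe radius, nm
    r_f: float = DEFAULT_FIBER_RADIUS_NM  # fiber radius, nm
    d_o: float = 0.0  # unobstructed (water) diffusivity, µm²/s

    def __post_init__(self) -> None:
        if not self.r_s > 0:
            raise ValueError(f"r_s must be > 0, got {self.r_s}")
        if not self.r_f >= 0:
            raise ValueError(f"r_f must be >= 0, got {self.r_f}")


@dataclass(frozen=True)
class PoreEstimate:
    """Per-particle pore-scale estimate; ``censored`` marks ratio >= 1."""

    particle_id: str
    ratio: float  # D_g/D_o
    r_g: float  # nm; NaN when censored
    spacing: float  # 2*r_g, nm; NaN when censored
    censored: bool
    sample_id: str | None = None


def water_diffusivity(
    radius_nm: float,
    temperature: float = DEFAULT_TEMPERATURE_K,
    viscosity: float = DEFAULT_WATER_VISCOSITY_PA_S,
) -> float:
    """Stokes–Einstein diffusivity D = k_B*T / (6*pi*eta*r), in µm²/s."""
    if radius_nm <= 0 or temperature <= 0 or viscosity <= 0:
        raise ValueError("radius, temperature and viscosity must all be positive")
    d_m2_s = constants.k * temperature / (6.0 * math.pi * viscosity * radius_nm * 1e-9)
    return d_m2_s * 1e12  # m²/s -> µm²/s


def forward_ratio(
    r_g: float | np.ndarray, params: ObstructionParams, log: bool = False
) -> float | np.ndarray:
    """D_g/D_o for pore radius ``r_g`` (nm); strictly increasing in r_g, in (0, 1).

    ``log=True`` returns ln(D_g/D_o) instead, which stays representable for
    very tight meshes where the ratio itself underflows float64.
    """
    r_g = np.asarray(r_g, dtype=float)
    if np.any(r_g <= 0):
        raise ValueError("r_g must be > 0")
    out = -(math.pi / 4.0) * ((params.r_s + params.r_f) / (r_g + params.r_f)) ** 2
    if not log:
        out = np.exp(out)
    return float(out) if out.ndim == 0 else out


def invert_pore_radius(
    ratio: float | None,
    params: ObstructionParams,
    particle_id: str = "",
    sample_id: str | None = None,
    *,
    log_ratio: float | None = None,
) -> PoreEstimate:
    """Closed-form inversion of the obstruction model for one particle.

    r_g = (r_s + r_f) * sqrt((pi/4) / (-ln ratio)) - r_f   for ratio < 1.

    ``log_ratio`` may be supplied instead of ``ratio`` for strongly hindered
    particles whose ratio underflows (matches ``forward_ratio(..., log=True)``).
    """
    if log_ratio is None:
        if ratio is None or not ratio > 0:
            raise ValueError(f"diffusivity ratio must be > 0, got {ratio}")
        log_ratio = math.log(ratio)
    else:
        ratio = math.exp(log_ratio)
    if log_ratio >= 0.0:
        return PoreEstimate(
            particle_id=particle_id, ratio=float(ratio),
            r_g=float("nan"), spacing=float("nan"), censored=True, sample_id=sample_id,
        )
    r_g = (params.r_s + params.r_f) * math.sqrt((math.pi / 4.0) / (-log_ratio)) - params.r_f
    return PoreEstimate(
        particle_id=particle_id, ratio=float(ratio),
        r_g=r_g, spacing=2.0 * r_g, censored=False, sample_id=sample_id,
    )


def estimates_from_summary(
    summary: pd.DataFrame, params: ObstructionParams
) -> list[PoreEstimate]:
    """Pore estimates for every particle in a per-particle summary table.

    D_g is the particle's measured deff_1s; D_o must be set on ``params``
    (e.g. from :func:`water_diffusivity`). Particles with deff_1s <= 0
    (static, below any meaningful ratio) are skipped.
    """
    if not params.d_o > 0:
        raise ValueError("params.d_o (water diffusivity) must be > 0")
    out = []
    for row in summary.itertuples():
        if row.deff_1s_um2_s <= 0:
            continue
        out.append(
            invert_pore_radius(
                row.deff_1s_um2_s / params.d_o, params,
                particle_id=str(row.particle_id), sample_id=str(row.sample_id),
            )
        )
    return out


def pore_statistics(estimates: Sequence[PoreEstimate]) -> dict:
    """Summary of a pore-estimate collection.

    Mean spacing is computed per sample first, then averaged across samples
    (mean ± SEM over samples; per-donor structure). Threshold fractions are
    pooled over particles; censored estimates (ratio >= 1, effectively
    unbounded pores) count toward every ">=" threshold but are excluded
    from the mean.
    """
    if not estimates:
        raise ValueError("no pore estimates supplied")
    uncensored = [e for e in estimates if not e.censored]
    n = len(estimates)
    frac_500 = sum(1 for e in estimates if e.censored or e.spacing >= 500.0) / n
    frac_1000 = sum(1 for e in estimates if e.censored or e.spacing >= 1000.0) / n
    if uncensored:
        by_sample: dict[str | None, list[float]] = {}
        for e in uncensored:
            by_sample.setdefault(e.sample_id, []).append(e.spacing)
        sample_means = np.array([np.mean(v) for v in by_sample.values()])
        mean_spacing = float(sample_means.mean())
        sem = (
            float(sample_means.std(ddof=1) / math.sqrt(sample_means.size))
            if sample_means.size > 1
            else float("nan")
        )
    else:
        mean_spacing, sem = float("nan"), float("nan")
    return {
        "mean_spacing_nm": mean_spacing,
        "sem_spacing_nm": sem,
        "frac_ge_500nm": frac_500,
        "frac_ge_1000nm": frac_1000,
        "n_particles": n,
        "n_censored": n - len(uncensored),
    }


def pore_table(estimates: Iterable[PoreEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": e.sample_id,
                "particle_id": e.particle_id,
                "ratio": e.ratio,
                "r_g_nm": e.r_g,
                "spacing_nm": e.spacing,
                "censored": int(e.censored),
            }
            for e in estimates
        ]
    )
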