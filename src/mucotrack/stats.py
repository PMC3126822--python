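"""Exposure-dose arithmetic, paired exact Wilcoxon test, rheology helper.

The dose calculation converts an occupational airborne-particulate exposure
into the resulting mass concentration in the tracheobronchial mucus blanket
(deposited mass over mucus volume, reported as % w/v = grams per 100 mL).
The paired comparison is a one-tailed Wilcoxon signed-rank test computed
exactly — for paired designs of ~6 donor samples the normal approximation
is invalid, so the null distribution is enumerated over all 2^n sign
assignments of the ranked absolute differences.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as _sps

_EXACT_N_MAX = 20


@dataclass(frozen=True)
class ExposureScenario:
    """Inhalation scenario mapping an airborne limit to a mucus dose."""

    airborne_concentration: float = 10.0  # mg/m³ (8 hr TWA permissible limit scale)
    breathing_rate: float = 3.2  # m³/hr, heavily active adult
    exposure_duration: float = 8.0  # hr
    deposition_fraction: float = 0.05  # tracheobronchial deposition, 0.1-1 µm particles
    airway_surface_area: float = 2741.0  # cm², tracheobronchial region
    mucus_thickness: float = 30.0  # µm, average TB mucus layer

    def __post_init__(self) -> None:
        for name in (
            "airborne_concentration", "breathing_rate", "exposure_duration",
            "airway_surface_area", "mucus_thickness",
        ):
            if not getattr(self, name) >= 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.deposition_fraction <= 1:
            raise ValueError(
                f"deposition_fraction must be in [0, 1], got {self.deposition_fraction}"
            )
        if self.airway_surface_area == 0 or self.mucus_thickness == 0:
            raise ValueError("airway surface area and mucus thickness must be positive")


def mucus_dose_concentration(scenario: ExposureScenario) -> float:
    """Deposited-particle concentration in the mucus layer, % w/v.

    deposited mass = airborne concentration x breathing rate x duration x
    deposition fraction; mucus volume = surface area x layer thickness.
    """
    mass_mg = (
        scenario.airborne_concentration
        * scenario.breathing_rate
        * scenario.exposure_duration
        * scenario.deposition_fraction
    )
    volume_ml = scenario.airway_surface_area * scenario.mucus_thickness * 1e-4  # cm³ = mL
    return (mass_mg / 1000.0) / volume_ml * 100.0  # g per 100 mL


def dilution_concentration(stock: float, added_volume_fraction: float) -> float:
    """Final % w/v after adding a stock at the given volume fraction (v/v)."""
    if stock < 0:
        raise ValueError(f"stock concentration must be >= 0, got {stock}")
    if not 0 <= added_volume_fraction <= 1:
        raise ValueError(
            f"added_volume_fraction must be in [0, 1], got {added_volume_fraction}"
        )
    return stock * added_volume_fraction


@dataclass(frozen=True)
class PairedConditionData:
    """Per-sample paired statistic values for two conditions."""

    sample_ids: tuple[str, ...]
    control: np.ndarray
    treated: np.ndarray

    def __post_init__(self) -> None:
        control = np.asarray(self.control, dtype=float)
        treated = np.asarray(self.treated, dtype=float)
        object.__setattr__(self, "control", control)
        object.__setattr__(self, "treated", treated)
        if not (len(self.sample_ids) == control.size == treated.size):
            raise ValueError("sample_ids, control and treated must have equal length")
        if control.size < 1:
            raise ValueError("need at least one pair")


def _signed_rank_p_exact(ranks: np.ndarray, w_obs: float) -> float:
    """P(W+ >= w_obs) under the null, by generating-polynomial enumeration.

    Mid-ranks may be half-integers; doubling makes every rank an integer so
    the distribution of 2*W+ is a convolution of {0, 2*r_i} point masses.
    """
    r2 = np.rint(2.0 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    w2_obs = int(np.rint(2.0 * w_obs))
    return float(counts[w2_obs:].sum() / counts.sum())


def wilcoxon_signed_rank_one_tailed(
    control: Sequence[float] | PairedConditionData,
    treated: Sequence[float] | None = None,
    alternative: str = "greater",
) -> float:
    """One-tailed Wilcoxon signed-rank p-value for paired data.

    ``alternative='greater'`` tests whether treated values exceed control
    (the p-value is small when the treated arm is systematically higher);
    ``'less'`` tests the opposite direction. Zero differences are dropped
    (standard signed-rank convention) and ties in the absolute differences
    receive mid-ranks. Exact enumeration over all 2^n sign assignments for
    n <= 20; the normal approximation with tie correction beyond that.
    """
    if isinstance(control, PairedConditionData):
        data = control
        control, treated = data.control, data.treated
    if treated is None:
        raise ValueError("treated values are required")
    if alternative not in ("greater", "less"):
        raise ValueError(f"alternative must be 'greater' or 'less', got {alternative!r}")
    diffs = np.asarray(treated, dtype=float) - np.asarray(control, dtype=float)
    if alternative == "less":
        diffs = -diffs
    diffs = diffs[diffs != 0]
    n = diffs.size
    if n == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return 1.0
    ranks = _sps.rankdata(np.abs(diffs))  # mid-ranks for ties
    w_pos = float(ranks[diffs > 0].sum())
    if n <= _EXACT_N_MAX:
        return _signed_rank_p_exact(ranks, w_pos)
    # normal approximation with tie-corrected variance
    mean = n * (n + 1) / 4.0
    var = (ranks**2).sum() / 4.0
    z = (w_pos - mean - 0.5) / math.sqrt(var)  # continuity corrected
    return float(_sps.norm.sf(z))


@dataclass(frozen=True)
class RheologyPoint:
    """One frequency point of an oscillatory shear measurement."""

    g_prime: float  # elastic (storage) modulus, Pa
    g_double_prime: float  # viscous (loss) modulus, Pa
    frequency: float = float("nan")  # rad/s

    def __post_init__(self) -> None:
        if self.g_prime < 0 or self.g_double_prime < 0:
            raise ValueError("moduli must be >= 0")

    @property
    def phase_angle_deg(self) -> float:
        return phase_angle(self.g_prime, self.g_double_prime)


def phase_angle(g_prime: float, g_double_prime: float) -> float:
    """Phase angle arctan(G''/G') in degrees: 0 elastic solid, 90 viscous liquid."""
    if g_prime < 0 or g_double_prime < 0:
        raise ValueError("moduli must be >= 0")
    if g_prime == 0 and g_double_prime == 0:
        raise ValueError("phase angle undefined when both moduli are zero")
    return math.degrees(math.atan2(g_double_prime, g_prime))
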