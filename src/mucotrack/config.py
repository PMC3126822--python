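"""Pipeline configuration: one YAML file drives every CLI command.

Schema (all keys optional; defaults reproduce the reference study scale)::

    seed: 0
    study:
      n_samples: 6
      n_particles_per_sample: 100
      per_sample_effect_sd: 0.4
      noise_sd: 0.004
      n_frames: 300
      frame_interval: 0.0667
      conditions:
        control: {immobile_fraction: 0.33, alpha: 0.36, d_eff_log_mean: -5.298, d_eff_log_sd: 1.8}
        treated: {immobile_fraction: 0.20, alpha: 0.68, d_eff_log_mean: -2.996, d_eff_log_sd: 1.8}
    analysis:
      tau_ref: 1.0
      alpha_fit_range: [0.2, 2.0]
      resolution: 0.01
    obstruction:
      probe_radius_nm: 500.0
      fiber_radius_nm: 3.5
      temperature_K: 298.15
      viscosity_Pa_s: 8.9e-4
    slab:
      thicknesses: [10.0, 30.0, 55.0]
      duration: 3600.0
      time_step: 1.0
      replicates_per_diffusivity: 30
      bridge_correction: false
      water_reference: null   # or a target fraction in (0,1), e.g. 0.64
      water_reference_thickness: 10.0

CLI flags override config keys; the config seed is the single source of
randomness for all commands unless overridden.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .msd import DEFAULT_ALPHA_FIT_RANGE, DEFAULT_RESOLUTION, DEFAULT_TAU_REF
from .obstruction import (
    DEFAULT_FIBER_RADIUS_NM,
    DEFAULT_PROBE_RADIUS_NM,
    DEFAULT_TEMPERATURE_K,
    DEFAULT_WATER_VISCOSITY_PA_S,
    ObstructionParams,
    water_diffusivity,
)
from .penetration import SlabConfig
from .synthetic import ConditionParams, StudyDesign


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    study: dict = field(default_factory=dict)
    analysis: dict = field(default_factory=dict)
    obstruction: dict = field(default_factory=dict)
    slab: dict = field(default_factory=dict)

    # -- derived, validated objects -------------------------------------
    def study_design(self, seed: int | None = None) -> StudyDesign:
        s = dict(self.study)
        conditions = s.pop("conditions", None)
        kwargs: dict[str, Any] = {}
        for key in (
            "n_samples", "n_particles_per_sample", "per_sample_effect_sd",
            "noise_sd", "n_frames", "frame_interval",
        ):
            if key in s:
                kwargs[key] = s[key]
        if conditions is not None:
            kwargs["condition_params"] = {
                name: ConditionParams(**params) for name, params in conditions.items()
            }
        return StudyDesign(seed=self.seed if seed is None else seed, **kwargs)

    @property
    def tau_ref(self) -> float:
        return float(self.analysis.get("tau_ref", DEFAULT_TAU_REF))

    @property
    def alpha_fit_range(self) -> tuple[float, float]:
        lo, hi = self.analysis.get("alpha_fit_range", DEFAULT_ALPHA_FIT_RANGE)
        return float(lo), float(hi)

    @property
    def resolution(self) -> float:
        return float(self.analysis.get("resolution", DEFAULT_RESOLUTION))

    def obstruction_params(self) -> ObstructionParams:
        o = self.obstruction
        d_o = water_diffusivity(
            radius_nm=float(o.get("probe_radius_nm", DEFAULT_PROBE_RADIUS_NM)),
            temperature=float(o.get("temperature_K", DEFAULT_TEMPERATURE_K)),
            viscosity=float(o.get("viscosity_Pa_s", DEFAULT_WATER_VISCOSITY_PA_S)),
        )
        return ObstructionParams(
            r_s=float(o.get("probe_radius_nm", DEFAULT_PROBE_RADIUS_NM)),
            r_f=float(o.get("fiber_radius_nm", DEFAULT_FIBER_RADIUS_NM)),
            d_o=d_o,
        )

    @property
    def thicknesses(self) -> list[float]:
        return [float(v) for v in self.slab.get("thicknesses", [10.0, 30.0, 55.0])]

    def slab_config(self, thickness: float, seed: int | None = None) -> SlabConfig:
        s = self.slab
        return SlabConfig(
            thickness=thickness,
            duration=float(s.get("duration", 3600.0)),
            time_step=float(s.get("time_step", 1.0)),
            replicates_per_diffusivity=int(s.get("replicates_per_diffusivity", 30)),
            seed=self.seed if seed is None else seed,
            bridge_correction=bool(s.get("bridge_correction", False)),
        )

    @property
    def water_reference(self) -> float | None:
        v = self.slab.get("water_reference")
        return None if v is None else float(v)

    @property
    def water_reference_thickness(self) -> float:
        return float(self.slab.get("water_reference_thickness", 10.0))

    def digest(self) -> str:
        """Short stable hash of the configuration, for output provenance."""
        payload = {
            "seed": self.seed, "study": self.study, "analysis": self.analysis,
            "obstruction": self.obstruction, "slab": self.slab,
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]

    def validate(self) -> None:
        """Construct every derived object so invalid keys fail before any work."""
        self.study_design()
        self.obstruction_params()
        for L in self.thicknesses:
            self.slab_config(L)
        lo, hi = self.alpha_fit_range
        if not 0 < lo < hi:
            raise ValueError(f"alpha_fit_range must satisfy 0 < lo < hi, got {(lo, hi)}")
        if not self.resolution > 0:
            raise ValueError("resolution must be > 0")


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML config (missing path or None -> all defaults)."""
    if path is None:
        cfg = PipelineConfig()
    else:
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a YAML mapping")
        cfg = PipelineConfig(
            seed=int(raw.get("seed", 0)),
            study=raw.get("study", {}) or {},
            analysis=raw.get("analysis", {}) or {},
            obstruction=raw.get("obstruction", {}) or {},
            slab=raw.get("slab", {}) or {},
        )
    cfg.validate()
    return cfg
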