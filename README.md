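# mucotrack

Multiple-particle-tracking (MPT) analysis of mucus barrier microstructure.

Mucus gels trap foreign particles in a mesh of entangled mucin fibers.
MPT experiments probe that mesh by video-tracking the thermal motion of
muco-inert (PEG-coated) probe particles: hindered probes report tight
pores, mobile probes report open ones. `mucotrack` is a library + CLI for
the complete downstream analysis of such experiments — from 2-D centroid
trajectories to transport summaries, pore-size estimates, and predicted
barrier penetration — together with a synthetic trajectory generator that
emulates a paired multi-donor study so the whole pipeline is testable
without raw video data. It is aimed at researchers in mucosal drug
delivery and nanotoxicology who need a reproducible MPT post-processing
chain.

## What it computes

- **Time-averaged MSD** per particle:
  ⟨Δr²(τ)⟩ = ⟨[x(t+τ) − x(t)]² + [y(t+τ) − y(t)]²⟩ₜ over all overlapping
  lags, and per-group geometric-mean curves.
- **Effective diffusivity** D_eff = MSD/(4τ) at a reference lag (τ = 1 s),
  and the **anomalous exponent** α — the log–log slope of MSD vs τ (α = 1
  is free Brownian motion; α < 1 indicates steric hindrance).
- **Immobile fraction**: particles with MSD(1 s) below the square of the
  tracking resolution (default 10 nm).
- **Pore sizes** by inverting the obstruction-scaling model
  D_g/D_o = exp(−(π/4)·((r_s + r_f)/(r_g + r_f))²), with the water
  reference D_o from Stokes–Einstein; mesh spacing is reported as the pore
  diameter 2·r_g.
- **Slab penetration**: a first-passage Monte Carlo of 1-D Brownian
  walkers (Gaussian steps of variance 2DΔt, absorbing level at the far
  face, open entry side) driven by the measured per-particle diffusivity
  ensemble, with the analytic oracle erfc(L/√(4Dt)) and a closed-form
  diffusivity calibration D = L²/(4t·erfc⁻¹(f)²).
- **Paired statistics**: one-tailed Wilcoxon signed-rank test computed
  exactly (all 2ⁿ sign assignments) — appropriate for ~6 paired donor
  samples — plus occupational exposure-dose arithmetic and the rheology
  phase angle δ = arctan(G″/G′).

## Worked example

Generate the default paired study (6 donor samples × 2 conditions ×
100 particles, 20 s tracks at 66.7 ms), analyze it, and predict slab
penetration:

```
$ mucotrack synth --seed 11 --out traj.csv
wrote 1200 trajectories (6 samples x 2 conditions x 100 particles) to traj.csv

$ mucotrack analyze --seed 11 --trajectories traj.csv --summary summary.csv --pores pores.csv
analyzed 1200 particles in 12 groups (tau_ref=1.0s, fit range=(0.2, 2.0), resolution=0.01um)
  control: mean D_eff(1s)=0.01215 um2/s, ensemble alpha=0.332, immobile fraction=0.367 (n=600)
  treated: mean D_eff(1s)=0.1303 um2/s, ensemble alpha=0.650, immobile fraction=0.220 (n=600)
  pores (all conditions pooled): mean spacing 483±21 nm, >=500nm 30.4%, >=1um 6.9%, censored 36/1200
  paired comparison (treated vs control, n=6 samples): mean D_eff fold change 10.72, one-tailed Wilcoxon p = 0.015625

$ mucotrack penetrate --seed 11 --summary summary.csv --out curves.csv
  control L=10.0um: 18000 walkers, fraction at 3600s = 0.1157
  treated L=10.0um: 18000 walkers, fraction at 3600s = 0.4036
  ...
```

Reading the numbers: the treated condition shows a ~10-fold higher mean
effective diffusivity, a higher ensemble α (less hindered scaling), a
smaller immobile fraction, and an exact one-tailed p of 1/64 — the
smallest attainable with six concordant pairs — so the planted barrier
disruption is recovered end to end. The penetration fractions are the
share of each measured ensemble predicted to cross a mucus layer of the
given thickness within one hour (30 Monte Carlo walkers per measured
diffusivity).

All commands accept a YAML config (`--config`); see
`src/mucotrack/config.py` for the schema. Every output table carries the
seed and config hash in a `#` header comment.

## Layout

- `src/mucotrack/synthetic.py` — fractional-Brownian-motion trajectory
  generator and paired study designs
- `src/mucotrack/io.py` — trajectory/summary table formats
- `src/mucotrack/msd.py` — MSD, D_eff, α, immobility, ensembles
- `src/mucotrack/obstruction.py` — pore-size model and statistics
- `src/mucotrack/penetration.py` — slab first-passage Monte Carlo
- `src/mucotrack/stats.py` — dose arithmetic, exact Wilcoxon, phase angle
- `src/mucotrack/cli.py`, `config.py` — `mucotrack synth|analyze|penetrate|report`

See `docs/methods.md` for the model assumptions, parameter defaults, and
known limitations.
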