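# Methods

This note documents the models behind `mucotrack`, the defaults and why
they were chosen, and what the synthetic-data tests do and do not show.

## Trajectory model and MSD estimation

A trajectory is a uniformly sampled 2-D centroid path (µm, s). The
time-averaged MSD at lag τ = k·Δt averages the squared displacement over
all n−k overlapping start times. Lags are reported up to a quarter of the
track duration (5 s of a 20 s track at the default 66.7 ms frame
interval): beyond that, too few quasi-independent displacement pairs
remain and single-track estimates are dominated by noise. The reference
lag for effective diffusivity, D_eff = MSD/(4τ), is τ = 1 s; since 1 s is
not an exact multiple of 66.7 ms, the nearest grid lag (lag 15, 1.0005 s)
is used. The anomalous exponent α is an ordinary least-squares slope of
log MSD vs log τ over τ ∈ [0.2, 2] s — inside the well-averaged part of
the curve and spanning a decade, which is enough to resolve the
subdiffusive scaling without touching the noisy tail.

Ensemble curves are geometric means of per-particle MSDs at each lag,
with values floored at the squared tracking resolution (10 nm → 10⁻⁴ µm²)
before log-averaging: the floor is the measurement limit, and it keeps
static particles from contributing −∞ while rendering them exactly flat,
which is what a tracking instrument would report. The ensemble α is
fitted on this geometric-mean curve (the headline value); per-particle α
fits are also computed on floored curves. The ensemble "mean D_eff" is
the arithmetic mean over particles, immobile particles included — the
penetration simulation consumes the raw per-particle diffusivity list
anyway, so the scalar is only a descriptive summary.

Immobility: a particle is immobile iff MSD(1 s) < (10 nm)². The
resolution enters squared because the criterion compares an MSD (µm²)
with a displacement scale (µm); the squared reading is the only
dimensionally consistent one.

## Synthetic data generator

The generator emulates the statistical structure of MPT data on 1 µm
muco-inert probes in a disrupted-vs-control mucus study:

- **Immobile particles** (pinned to the mesh): constant true position;
  observed positions add independent Gaussian localization noise per
  coordinate per frame. Default noise sd is 0.004 µm, so the apparent MSD
  floor 4σ² = 6.4×10⁻⁵ µm² sits just below the (10 nm)² immobility
  threshold. This is deliberate: the 10 nm "tracking resolution" of an
  MPT instrument is *measured* as the apparent displacement of immobilized
  beads, i.e. it is the noise floor itself, and immobilized beads must
  classify as immobile.
- **Mobile particles**: fractional Brownian motion per coordinate with
  Hurst index H = α/2 and Var[X(t)] = 2·d_eff·t^α, so the expected 2-D
  MSD is 4·d_eff·τ^α, anchored at the τ = 1 s reference. fBm is used
  because the data to emulate show a single power-law exponent per
  condition; continuous-time random walks and other anomalous models are
  out of scope. Increments are exact fractional Gaussian noise — Cholesky
  factorization of the Toeplitz covariance for tracks up to 1024 steps,
  Davies–Harte circulant embedding beyond (non-negative definite for
  H ≤ 1/2, the full subdiffusive range used here). Brownian motion is the
  α = 1 special case.
- **Population law**: mobile d_eff values are log-normal. The law is an
  implementation choice (no measured distribution is available to copy):
  log-normal is strictly positive, heavy-tailed, and the standard
  description of MPT heterogeneity.

Default paired study: 6 samples × 2 conditions × 100 particles, 300
frames at 66.7 ms. Condition parameters: immobile fraction 0.33
(control) / 0.20 (treated); ensemble α 0.36 / 0.68; mobile log-mean
diffusivity ln(5×10⁻³) / ln(5×10⁻²) µm²/s (a 10-fold shift); within-
condition log-sd 1.8; between-sample log-sd 0.4, shared by both
conditions of a sample so the pairing is real. The control level
5×10⁻³ µm²/s is ~100-fold below the Stokes–Einstein water value for 1 µm
spheres (0.49 µm²/s), the right order for strongly hindered micron probes
in cervicovaginal mucus, and a log-sd of 1.8 (~0.8 decades) reflects the
several-decade per-particle spread typical of MPT in mucus.

Two structural choices deserve emphasis:

- The per-condition `alpha` parameter is the target **ensemble** exponent.
  A mixture containing a fraction f of flat (immobile) curves has
  geometric-mean log-slope (1−f)·α_mobile, so mobile particles are
  planted with α_mobile = α/(1−f) (0.537 control, 0.85 treated). Planting
  α_mobile = 0.36 directly would produce an ensemble slope of ~0.24 and
  make the generator inconsistent with the ensemble statistics it is
  meant to emulate.
- Randomness: one master seed; per-particle substreams are derived
  deterministically from (sample, condition, particle) indices via
  `SeedSequence` spawn keys, so output tables are byte-identical across
  runs and insensitive to generation order.

What the generator does **not** emulate: static/dynamic localization
error correlations, motion blur, tracking dropouts and linking errors,
spatially correlated micro-environments (each particle's d_eff is i.i.d.
given its sample), and any physical coupling between α, d_eff and
immobility beyond the planted marginals. Passing recovery tests therefore
demonstrates that the estimators are correct and well-calibrated on
clean, in-model data — not that they are robust to every real-data
pathology.

## Obstruction-scaling pore model

D_g/D_o = exp(−(π/4)·((r_s+r_f)/(r_g+r_f))²) with probe radius
r_s = 500 nm and mucin fiber radius r_f = 3.5 nm. D_g is a particle's
measured D_eff(1 s); D_o is the Stokes–Einstein diffusivity in water at
25 °C (η = 8.9×10⁻⁴ Pa·s), 0.490 µm²/s for 1 µm spheres — an assumption,
since particles inside gel pores are taken to feel only the viscous drag
of water. The inversion is closed-form; a log-ratio channel is provided
because tight meshes (r_g ≲ 13 nm) drive the ratio below the float64
underflow limit. Ratios ≥ 1 (apparent diffusion at or above water —
measurement noise) are flagged censored, never clamped: they count toward
every "spacing ≥ threshold" fraction and are excluded from means.
Reported "pore size"/mesh spacing is the diameter 2·r_g, the scale on
which probe diameters are quoted. Headline means are computed per sample
first, then averaged across samples (mean ± SEM over samples), matching a
per-donor experimental structure.

## Slab penetration Monte Carlo

Walkers start at x = 0 and take Gaussian steps of variance 2DΔt
(Δt = 1 s); a walker is penetrated from the first sampled instant with
x ≥ L. The entry side is open — walkers may diffuse to negative x and
return. This is the unique simple boundary semantics under which
one-sided first-passage scaling erfc(L/√(4Dt)) holds simultaneously
across slab thicknesses; a reflecting entry wall or a lose-on-exit rule
breaks that internal consistency. Immobile (D = 0) walkers are legal and
never penetrate. Default ensemble size is 30 replicates per measured
diffusivity (~18,000–20,000 walkers for a 2×600-particle study).

Discrete-time crossing detection misses excursions above L between
sampling instants and therefore under-counts continuous-time first
passages by a small, systematic amount (~0.2–0.5 percentage points for
the regimes here). The optional Brownian-bridge correction scores a
between-step crossing with probability exp(−(L−x₁)(L−x₂)/(DΔt)) and
removes this bias; it is off by default (plain stepping is the simpler,
more transparent baseline) and switched on where the Monte Carlo is
compared against the continuous-time analytic value, as in
`scripts/acceptance.py`. The calibration D = L²/(4t·erfc⁻¹(f)²) inverts
the analytic expression in closed form; an independent monotone bisection
agrees to 10⁻⁶ relative and serves as a cross-check.

## Paired statistics and dose arithmetic

The paired comparison uses a one-tailed Wilcoxon signed-rank test with an
exactly enumerated null (generating-polynomial convolution over all 2ⁿ
sign assignments; mid-ranks for tied |differences|; zero differences
dropped) for n ≤ 20 — with ~6 pairs the normal approximation is invalid,
and the smallest attainable one-tailed p is 1/2⁶ = 0.015625. Beyond
n = 20 a tie-corrected, continuity-corrected normal approximation is
used. Zero-difference dropping is the standard convention but matters at
tiny n, so it is explicit in the API documentation.

Exposure dose: deposited mass = airborne concentration × breathing rate ×
duration × deposition fraction; mucus volume = airway surface area ×
layer thickness; the ratio is reported as % w/v (g per 100 mL; density
plays no role). With the default inputs (10 mg/m³, 3.2 m³/hr, 8 hr,
5–10% tracheobronchial deposition, 2741 cm², 30 µm) the bracket is
0.156–0.311% w/v.

## Numerical choices and degenerate inputs

- Trajectories must have ≥ 2 points, strictly increasing times with
  relative spacing jitter < 10⁻⁶; violations raise errors naming the
  particle. Tables are CSV (µm/s units), full float precision, so
  write→read round-trips are exact to well below 10⁻⁹ µm.
- α fits require ≥ 3 lags in range and positive MSD; zero-MSD curves
  raise with a pointer to resolution flooring.
- `tau_ref` outside a profile's lag range is an error, not an
  extrapolation.
- Wilcoxon with all-zero differences warns and returns p = 1.
- Diffusivity calibration rejects target fractions outside (0, 1)
  (f → 1 needs D → ∞ and is out of bracket by construction).

## Problem sizes

Default test and acceptance runs use the study-scale ensemble (1200
tracks of 300 frames), ~20,000-walker Monte Carlo per condition/thickness
for ensemble predictions, and ~100,000 walkers for the calibrated water
reference; these sizes put Monte Carlo standard errors well inside the
tolerances asserted (binomial SE ≈ 0.1–0.3 percentage points).

## Known limitations

- The pipeline starts at centroid coordinates: no spot detection,
  linking, drift correction, gap closing, or 3-D analysis.
- The obstruction model assumes non-interacting probes and a single fiber
  radius; r_f is fixed, not fitted.
- The water reference D_o is an assumption (Stokes–Einstein at 25 °C),
  and the radius-vs-diameter convention for "pore size" is a reporting
  choice, both documented above.
- The penetration model is 1-D and homogeneous: no advection, clearance,
  spatial heterogeneity, or particle–particle interaction.
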