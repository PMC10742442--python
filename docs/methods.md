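# Methods

## Measures

Both measures operate on an `Ensemble` of `K ≥ 2` replicate samples of
one data kind — continuous observations or categorical counts — with a
weighting scheme: `equal` (`w_k = 1/K`, pairwise 1/2) or `proportional`
(`w_k = n_k/N`), the latter appropriate when replicates re-sample one
underlying population.

**Incoherence** is the weighted spread of per-sample entropies around the
entropy of the pooled distribution, `I = sqrt((1/H~) Σ_k w_k (H~ − H_k)²)`.
The un-rooted form `I²` is also reported (`incoherence_unrooted`); the
rooted form is the default because it is an RMS of entropy deviations and
scales like an entropy.  If the pooled entropy is zero (every sample puts
all mass in one category) the ratio is degenerate and `I = 0` is returned
with a warning.  Entropies are in nats unless a log base is requested.
`I` has no upper bound in general.

**Pairwise Jensen–Shannon divergence** between samples a and b is
`d_ab = w_a(H~_ab − H_a) + w_b(H~_ab − H_b)`, the entropy of the weighted
mixture minus the weighted entropies.  JSD is symmetric, non-negative and
bounded by the entropy of the weight vector (ln 2 at equal weights); it is
finite for disjoint supports, which Kullback–Leibler is not — replicates
on opposite sides of a tipping point routinely have disjoint supports.
Values in `[−1e−9, 0)` from floating-point cancellation are clipped to 0;
anything more negative raises an internal-consistency error.

**Cohesion** is `C = (1 − H(G))²` where `H(G)` is the density-variance
entropy of the set of all `K(K−1)/2` normalised divergences.  With the
histogram estimator, divergences are normalised by ln 2 (the theoretical
maximum at equal pairwise weights) rather than by the observed maximum:
this avoids a divide-by-zero for identical ensembles and keeps `C = 1`
attainable exactly.

## The density-variance entropy estimator

For observations `o_i` on (approximately) `[0, 1]`, a profile
`G_j = sqrt((1/N) Σ_i exp(−k·|r_j − o_i|))` is evaluated at reference
points `r_j` and its **population variance** `Var(G)` is mapped to

    H = 1 − (Var(G) − V0) / (V1 − V0),   clipped to [0, 1],

where `V1` is the profile variance of a point mass at 0 (minimal entropy)
and `V0` that of a dense uniform on `[0, 1]` (maximal entropy).  The
square root linearises the concave response of entropy to density; the
clipping handles data that are more concentrated than the point-mass
anchor's grid alignment or more spread than the uniform anchor.

Parameters (`DensityVarianceParams`):

* `k = 100` — kernel decay (dimensionless; length scale 1/k in data
  units).  The canonical value for divergence sets normalised to [0, 1].
* `support = [−0.5, 1.5]` — brackets unit-interval data with half a unit
  of margin so boundary kernels are captured.
* `n_ref = 501` — reference points, i.e. **500 even intervals** with both
  endpoints included (spacing exactly 0.004).  Under this convention the
  point-mass anchor is `V1 = 0.009711690148675985` to machine precision;
  a 500-point endpoint-inclusive grid (spacing 2/499) misses it by 1.5%,
  so the interval-count reading of the grid is the one used throughout.
* `V0` calibration uses a deterministic even grid of `1e5` points over
  `[0, 1]` rather than random draws: it is seed-free and converges to the
  continuum limit (`V0 = 0.0047692` at `1e5`, within 0.02% of the
  `0.0047683913076489465` anchor; the residual reflects the uniform
  representation, hence the calibrated value is recomputed, not hard-coded).

Calibration anchors are exact by construction: after calibration,
`H(point mass at 0) = 0` and `H(dense uniform) = 1` identically.

Relation to binned entropy: on the full support the estimate agrees with
the normalised 50-bin entropy (both ≈ 1 for uniform data).  For a uniform
on `[0, x]` the density-variance reading is ≈ `x` (near-linear in the
support width), which is systematically *below* `log(50x)/log(50)`: the
two scales only coincide at the anchors.  Tests assert the linear
response and the ordering, not a pointwise match.

## Continuous samples: two divergence routes

The entropy estimator inside `d_ab` is a free choice for continuous data,
and the package provides two, behind one `estimator=` switch:

* **`histogram`** (default): all samples of an ensemble are discretised
  on one shared bin scheme (Freedman–Diaconis on the pooled data, capped
  at 512 bins — IQR-driven rules explode on near-degenerate pooled data)
  and the categorical formulas apply.  Right choice when per-sample
  counts are large (hundreds+).
* **`density_variance`**: observations are mapped to `[0, 1]` by the
  ensemble's global range; per-sample and pooled-pair entropies are
  density-variance estimates with a data-side decay `raw_k`, and
  `d_ab = H_pool − (H_a + H_b)/2` (clipped at 0; these divergences are
  already on a normalised entropy scale, so the normaliser is 1).  Right
  choice when per-sample counts are tiny: for `n ≈ 10` observations per
  sample the expected histogram JSD between two draws of the *same*
  distribution is ≈ `(B−1)/4n` nats — pure sampling noise that swamps any
  signal — while a heavily smoothed kernel estimate remains stable.

`raw_k` defaults: the organised-noise analysis uses `raw_k = 1` (kernel
length scale equal to the full data range — the strongest smoothing the
estimator admits, appropriate for 2–18-point bursts; message cohesion
medians vary by < 0.05 for `raw_k` anywhere in `[0.5, 3]`, so the choice
is not delicate).  The Daisyworld temperature ensembles (841 points per
sample) use the canonical `raw_k = 100`.

The incoherence statistic follows the same switch: with
`density_variance`, `H_k` and `H~` are density-variance entropies of the
range-scaled samples and their concatenation.  This matters for
Daisyworld: in the saturated single-species band the replicate
temperature fields are identical to 0.02 °C, yet shared fine bins resolve
the micro-texture and a histogram incoherence reads ≈ 0.25 where the
physical answer is ≈ 0; the kernel estimator at `k = 100` is insensitive
to that texture.

## Organised-noise generator

A letter is two Gaussian components with means uniform on `[0, 20)`,
standard deviations drawn from Normal(1, 0.5) truncated below at 0.05
(the untruncated law admits non-positive draws), and per-component counts
uniform on `{1, …, 9}` — so a burst carries 2–18 points.  Counts and
component parameters are fixed per letter; observations are redrawn at
every timestep from a uniformly picked letter.  Messages default to 20
bursts.  Ground-truth letter labels ride along as sample metadata and are
never used in any computation.

What the generator emulates: repeated noisy transmissions from a finite
symbol set, with burst-to-burst sampling noise.  What it does not: letter
frequencies other than uniform, temporal structure (the measures are
order-blind), drifting letters, or observation noise models beyond
Gaussian.  A passing cohesion-ordering test therefore shows the measure
separates alphabet sizes under ideal mixture noise, not that it decodes
real signals.

## Daisyworld

A direct port of the NetLogo model.  Constants not restated in the
source description are taken from the NetLogo original and exposed in
`DaisyworldConfig`: solar heating `72·ln(absorbed) + 80` (80 when nothing
is absorbed) blended 50/50 with the current patch temperature; `diffuse`
at rate 0.5 (each patch offers half its heat split eight ways); sprouting
probability `0.1457·T − 0.0032·T² − 0.6443` clipped to `[0, 1]`, whose
support realises the `[5, 40]` °C viability band; `max_age = 25`.
Defaults: 29×29 patches, albedos 0.25 (black) / 0.75 (white) / 0.4
(bare), start fractions 30/30/40 assigned independently per patch, ages
initialised uniform below `max_age`, temperatures at 0 °C, 400 ticks.

Design choices where the port was genuinely open:

* **Scheduler**: `interleaved` (default) visits the daisies present at
  the start of the phase in one shuffled pass; each ages, dies at
  `max_age`, or sprouts into a uniformly chosen *currently* empty Moore
  neighbour — NetLogo's agent scheduler in distribution.  A `phased`
  variant (all deaths, then all sprouts) is kept for comparison.
  Survive-before-diffuse ordering was tested and rejected: undiffused
  radiative temperatures put both species outside viability near
  luminosity 1.0 and the coexistence band collapses.
* **Boundary**: bounded world by default — edge patches have truncated
  neighbourhoods and keep the undistributed diffusion share (NetLogo's
  `diffuse` edge semantics).  A toroidal wrap (`wrap=True`) is available.
  The bounded world reproduces the survival threshold's two-attractor
  behaviour at luminosity 0.50 itself (edge retention lets marginal
  colonies bootstrap); on the torus the bistable window sits strictly
  inside (0.50, 0.55).
* **Hard kill** (`hard_kill=True`): daisies whose local temperature
  leaves `[5, 40]` die outright instead of merely failing to reproduce.
  Off by default; it narrows the survival-threshold bistability and
  advances the black die-off by ~0.05 in luminosity.

The sweep harness runs `replicates` independently seeded simulations per
luminosity (seeds spawned from one master via `SeedSequence`, so the
sweep is reproducible end to end) and reports, per luminosity:
temperature-ensemble incoherence and cohesion (density-variance route),
species-count incoherence and cohesion (categorical route), the mean of
replicate mean temperatures, the pooled mean, σ(μ), σ(σ), and mean
species counts.  With equal replicate sizes the mean of means and the
pooled mean agree up to floating point.

**Peak detection**: a tipping region is a maximal run of consecutive
luminosities whose incoherence exceeds a threshold.  The default
threshold is the trace mean + 1 sd.  That statistic has a known failure
mode: a single dominant spike (e.g. the dead-vs-alive bistability at the
survival threshold, I ≈ 0.4 against ≈ 0.1 elsewhere) inflates the mean
and sd enough to mask every secondary region, and the detector returns
one region where the trace visibly carries three.  `robust=True` uses
median + 1.4826·MAD, which is insensitive to the peaks being detected;
the scaled sweep then yields its three regions (survival threshold at
0.50, white-daisy onset near 0.80, black die-off at 1.30–1.35).

## Problem sizes and numerical conventions

* Test and acceptance sweeps use the scaled configuration — luminosity
  0.45–1.45 in steps of 0.05, 10 replicates, 200 ticks (equilibrium is
  reached well before 400 at this grid size) — about one minute of
  compute; the full 30 × 400 configuration is the library default.
* Median cohesion targets use 21 seeds in tests and 101 in the
  acceptance script (the 21-seed median of two-letter message cohesion
  has sampling sd ≈ 0.03; 101 seeds stabilise it).
* `0·log 0 ≡ 0` throughout; probability vectors must sum to 1 within
  1e−6 and be non-negative within 1e−9.
* Kernel-density profiles are computed in observation chunks (~2M matrix
  elements) to bound memory during calibration-sized evaluations.
* Degenerate pooled data (zero range) gets a single unit-width bin;
  out-of-range observations raise an error naming the offending value.

## Limitations

* Categorical and one-dimensional continuous data only; no multivariate
  joint-density divergences.
* The density-variance scale is anchored to `[0, 1]`-supported data; data
  are range-scaled before estimation, so the estimate is invariant to
  affine transformations of the observations — a feature for divergence
  sets, but it means absolute spread information is deliberately
  discarded.
* Kullback–Leibler divergence and limiting-density-of-discrete-points
  entropy are out of scope by design.
* The Daisyworld port matches the NetLogo model in distribution, not
  tick-for-tick; quantitative tipping-point locations shift by up to
  ~0.05 in luminosity across defensible port variants (boundary,
  scheduler, kill rule), and conclusions drawn from it should respect
  that granularity.
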