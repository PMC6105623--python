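# Methods

This note records the models, conventions and numerical choices behind
`lymphtrack`, and what the synthetic-data tests do and do not demonstrate
about real imaging data.

## Data model and units

Tracks are ordered 3D centroid observations in μm with timestamps in
seconds, right-handed axes, z increasing with imaging depth. Each track
declares a nominal frame interval (30 s by default, matching a typical
two-photon acquisition of 60 cycles over 30 min); consecutive timestamps
must be integer multiples of that interval apart. Missing frames are kept
as gaps — no metric ever interpolates a position, and any step-based
quantity (speed, turn, arrest) uses only single-frame steps. Speeds are
reported in μm/min and turn speeds in degrees/min, the units the field
plots, although storage is in seconds.

Photoconversion series use hours, since dwell experiments run over days.

The `imaris_position` CSV dialect ships with a default column mapping
(`Position X/Y/Z`, `Time`, `TrackID`, seconds) that is fully configurable,
because commercial export headers vary by software version.

## Motility metrics

**Instantaneous speeds** are pooled across a population, one value per
single-frame step. **ECDFs** are right-continuous with range [1/n, 1], so
the value 0.5 falls at the (upper) median. The **meandering index** is net
displacement over total path length; it is undefined (signalled) for a
track that never moves. The **arrest coefficient** is the fraction of a
track's steps below 3 μm/min — the conventional arrest threshold for
lymphocytes. **Turn speeds** are the 3D angle between successive
single-frame displacements divided by the frame interval; zero-length
displacements carry no direction and are skipped. Degrees/min was chosen
for readability; no consensus unit exists.

**MSD.** MSD(τ) averages squared displacements over *all* ordered
observation pairs separated by exactly τ within a track (time-averaged,
not anchored at the first frame), pooled across tracks with pair-count
weights. The lag grid stops at 25% of the longest track's duration: longer
lags are dominated by the few slow cells that stay in view, biasing the
curve. The anomalous exponent α is the ordinary least-squares slope of
log₁₀ MSD against log₁₀ τ over lags with positive mass. A log–log fit is
the only reading under which α carries its sub/superdiffusive meaning; a
linear-linear regression cannot produce an exponent.

**KS D** comes from `scipy.stats.ks_2samp` with the asymptotic p-value.
D, not p, is the scientifically meaningful effect size here: with
thousands of pooled steps, trivial differences reach significance. Exact
small-sample p-values are out of scope.

**Surface and contact analytics.** Surfaces are unions of spheres;
distance is to the nearest primitive's surface, floored at zero inside —
so "proximity < 20 μm" means within 20 μm of the *surface*, the reading
used for the close/far speed segmentation as well (a figure caption that
swaps the labels is treated as an erratum). Contacts are centroid-based:
a subject is in contact when its nearest partner is within 10 μm (about
one cell diameter). This approximates an image-intensity colocalisation
criterion that cannot be reproduced from centroids; the threshold is
configurable. Runs of contacting frames with the same nearest partner
form events, single-frame interruptions are bridged, and an event's
duration includes the closing frame interval. Contact rates are
normalised to events per 5 min of subject track. Region assignment uses
the majority of a track's points, ties broken by the first point.

**Residence time.** With exponential dwell at rate λ and a steady supply
of new arrivals, the photoconverted:unconverted ratio decays as e^(−λt);
λ is minus the slope of ln(ratio) against time, fitted by least squares.
Half-life = ln2/λ and mean residence = 1/λ hold identically, so a 48 h
half-life yields 48/ln2 ≈ 69 h. A non-negative slope (no decay) is
signalled rather than estimated.

## The simulator

Agents are non-overlapping 5 μm-radius spheres in boundless space.
Recording is restricted to an imaging volume (default 300 × 300 × 150 μm,
a typical two-photon stack) at 30 s intervals; tracks are split into
fragments exactly where agents leave the volume. Agents start uniformly
in the volume inflated by a placement margin (default a quarter of the
longest axis) so cells can flux into and out of view, as in situ.

Step rules, at Δt = 30 s (3 s for the Lévy walk, to resolve its variable
run durations; recording stays at 30 s):

* *Brownian*: isotropic Gaussian displacement, per-axis sd √(2DΔt).
* *Lévy walk*: piecewise-constant runs; at each run's end a fresh
  isotropic heading, speed and duration are drawn, speeds and durations
  from independent truncated power laws (the standard finite-cost
  Lévy-walk construction; exponents and truncation bounds are free
  parameters).
* *CRW*: per step, the heading rotates by (turn-speed draw)·Δt about an
  axis chosen uniformly among directions perpendicular to the heading
  (isotropic turning — 3D turning geometry is otherwise underdetermined),
  then the agent advances by (speed draw)·Δt. Draws are log-normal around
  the agent's own speed and turn scales with a per-step coefficient of
  variation (default 0.3) separating frame-to-frame from agent-to-agent
  variability.

CRW populations are *homogeneous* (every agent carries the population
median scales) or *heterogeneous* (per-agent scales drawn log-normally
around the medians); *inverse* variants couple the two draws rank-
inversely (turn quantile = 1 − speed quantile), so the fastest agents are
the straightest. Zero turn scale with zero step variability is the exact
ballistic limit (α = 2 to regression precision), used as an analytic
anchor in the tests alongside the Brownian identity MSD(τ) = 6Dτ.

Collisions are resolved by propose–reject: a move bringing two centres
closer than one diameter is re-drawn up to 10 times (the Lévy walk draws
a whole new run — the cell bumps and redirects), after which the agent
holds position for that step. The resolution scheme is a package choice;
only the non-overlap constraint itself is inherent to the model. All
randomness flows from one seed; identical seed and configuration give
bit-identical output.

## Fitting

NSGA-II (implemented in-package: fast non-dominated sort, crowding
distance, binary tournament, SBX crossover η = 15, polynomial mutation
η = 20) searches each family's box-bounded parameters — defaults span
0.1–20 μm/min speed scales and 1–360 deg/min turn scales — minimising
speed KS D, turn KS D and |Δα| jointly. Default budget: population 50,
at most 40 generations, so ≤ 50 × 41 simulations.

Because the objectives are stochastic, every candidate within a
generation is simulated with the same seed (common random numbers), which
stabilises within-generation ranking; parents keep the scores from their
own generation.

**Λ score.** Λ = max(KS_speed, KS_turn, |Δα|/2). The division by 2 maps
the slope difference onto [0, 1] (two units spans the plausible α range
from subdiffusive to ballistic), so Λ is the worst-case alignment across
metrics and is zero only when all three vanish. This formula, and the
overfitting rule below, are this package's own definitions of otherwise
under-specified quantities, and results quoting Λ should cite them as
such.

**Early stopping.** A quarter of the target tracks (configurable) is held
out before fitting. Each generation, every candidate's Λ against the
holdout tracks is computed from the same simulated pool as its training
objectives (no extra simulations), and the median holdout Λ over the
current front is logged. Fitting stops when that median has not improved
for `patience` (default 5) consecutive generations. Holdouts smaller than
5 tracks disable the rule with a logged warning.

Model complexity is controlled only through this fixed computational
budget — information criteria do not apply across a multi-objective,
multi-metric comparison — so a more complex family justifies itself only
by reaching lower Λ within the same budget.

## Synthetic data and what the tests show

The generators reproduce the *acquisition artefacts* of two-photon
imaging: boundary fragmentation (via the simulator's imaging volume),
isotropic Gaussian localisation noise (default sd 0.5 μm, typical of
centroid detection), and per-frame dropout (default 2%) that leaves gaps.
They do not emulate drift, depth-dependent noise, mistracking/identity
swaps, or any biology beyond the walk models (no chemotaxis, adhesion,
division or tissue confinement). Passing tests therefore demonstrate that
the estimators are correct *given* the walk-model world; they cannot rule
out biases that those unmodelled features introduce in real data.

The photoconversion generator models the unconverted arm as a constant
steady-state level of new arrivals (default n0/2 — a nuisance scale that
cancels in the ratio), which makes the ratio exactly exponential and the
log-linear estimator exactly unbiased at zero noise.

## Problem sizes and numerical choices

Analytic simulator checks (Brownian 6Dτ, CRW superdiffusion) use 200
agents × 60 records, where the relative standard error of the MSD at the
longest fitted lag is a few percent. Parameter recovery runs NSGA-II at
population 50 for up to 10 generations (patience 3, one replicate per
evaluation, 80-agent evaluation simulations against a 150-track target),
recovering the Brownian diffusion coefficient to well within 25%; the
generating-vs-mismatched family comparison uses population 16 × 5
generations for both sides. These sizes were fixed once as desk-scale
study conditions.

Timestamp/frame alignment uses a relative tolerance of 1e-6 on the frame
interval; geometry containment is inclusive of boundaries; ECDF and KS
computations are exact (no binning). Degenerate inputs — single-point
tracks, zero path length, frozen populations, non-decaying ratios — are
signalled with `MetricError` rather than returning NaN, and an infeasible
simulation during fitting scores worst on every objective instead of
aborting the search.

## Known limitations

* The contact criterion is centroid-distance-based and will differ
  systematically from intensity-colocalisation counts for touching but
  non-overlapping cells.
* Λ and the early-stopping rule are package-defined stand-ins (see
  above); fitted fronts are comparable within this package, not across
  other implementations.
* The Lévy walk draws run speed and duration independently; coupled
  draws would be a different (also defensible) construction.
* MSD pooling weights tracks by their pair counts, so long tracks
  dominate long lags; the 25% lag cap mitigates but does not remove
  this.
* Agent radius (5 μm) and imaging-volume dimensions must be set by the
  caller to match their data; defaults are typical, not universal.
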