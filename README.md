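# lymphtrack

Motility analysis and random-walk model inference for intravital
two-photon cell tracks, built around the question of how lymphocytes —
in particular memory B cells patrolling the subcapsular niche of the
lymph node — search their tissue for antigen.

Intravital two-photon microscopy yields short, fragmented 3D cell tracks:
centroid positions every 30 s for ~30 min, inside an imaging volume
~150 μm deep, with cells wandering in and out of view. `lymphtrack`
provides the full quantitative chain such a study needs, on top of plain
CSV track tables:

* **Motility metrics** — pooled instantaneous speeds and their empirical
  CDFs, net displacement, meandering index (net displacement / path
  length ∈ [0, 1]), arrest coefficient (fraction of steps < 3 μm/min),
  turn speeds, and the mean squared displacement
  MSD(τ) ∝ τ^α whose log–log slope α classifies motion
  (α = 1 diffusive, α > 1 superdiffusive, α = 2 ballistic). Distributions
  are compared with the two-sample Kolmogorov–Smirnov statistic
  D = sup |F₁ − F₂| ∈ [0, 1].
* **Micro-anatomy analytics** — distance and proximity (< 20 μm) to a
  labelled surface such as the CD169⁺ subcapsular-sinus macrophage layer,
  speeds segmented by surface distance, cell–cell contact detection from
  centroid trajectories with per-5-min contact rates, and assignment of
  tracks to tissue compartments (SPF / FM / GC).
* **Residence-time estimation** — an exponential dwell model fitted to
  photoconversion time courses: the resident/newcomer ratio decays as
  e^(−λt), giving half-life ln2/λ and mean residence time 1/λ
  (a 48 h half-life ⇒ 69 h residence).
* **An agent-based simulator** of six candidate walk models — Brownian
  motion, a Lévy walk (truncated power-law run speeds and durations), and
  four correlated random walks (homogeneous/heterogeneous agents,
  with or without an inverse speed–turn coupling) — as non-overlapping
  spheres in boundless space, recorded only inside an artificial imaging
  volume so simulated data carries the same truncation artefacts as the
  microscope's.
* **Multi-objective model fitting** — NSGA-II calibration minimising
  (1) speed-distribution KS D, (2) turn-speed KS D and (3) |Δα|
  simultaneously, returning a Pareto front scored by
  Λ = max(KS_speed, KS_turn, |Δα|/2); low Λ means all three metrics align
  at once. Fitting holds out a fraction of tracks and stops early when
  holdout Λ stops improving.
* **Synthetic-data generators** that emulate the acquisition protocol
  (localisation noise, frame dropout, boundary fragmentation) with known
  ground truth, so the whole chain is testable without microscope data.

## Worked example

`examples/01_motility_metrics.py` generates a 60-frame synthetic
population from a persistent heterogeneous correlated random walk and
computes the headline metrics:

```
94 tracks recorded inside the 60-frame imaging volume
pooled speeds: n=2289, median=6.03 um/min (ECDF at median = 0.50)
meandering index median 0.83 (1 = straight, 0 = closed)
arrest coefficient median 0.03 (fraction of steps < 3 um/min)
MSD slope alpha = 1.82 (1 = diffusive, > 1 = superdiffusive search, 2 = ballistic)
```

The median speed matches the generator's 6 μm/min scale, almost no steps
fall below the 3 μm/min arrest threshold, and the directional persistence
of the walk shows up as a superdiffusive exponent (α ≈ 1.8) — the motility
signature of an efficient search for rare antigen. The other examples
cover model comparison (`02`), NSGA-II parameter recovery (`03`),
residence-time estimation (`04`) and contacts/regions (`05`).

The same functionality is scriptable from the shell:

```sh
lymphtrack synth tracks --family crw_hetero --seed 7 --out run/
lymphtrack metrics --tracks run/tracks.csv --out run/metrics/
lymphtrack fit --family brownian --target run/tracks.csv --seed 1 --out run/fit/
```

Every command writes a `manifest.json` (config echo, package version,
seed, input checksums) so a run is reproducible from its manifest alone.

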