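# Methods

## Overview

`budsim` simulates an N-component eukaryotic gene network inside individual
budding-yeast cells whose volume, cell-cycle stage and gene dosage change in
real time. Each cell carries (i) a deterministic volume/cell-cycle model with
per-cell parameters, and (ii) an exact stochastic (Gillespie) simulation of
per-gene two-state-promoter chemistry whose propensities are rescaled by the
current cell volume. Cells divide asymmetrically; molecular content is
partitioned binomially; daughters inherit growth parameters partially and are
tracked in a lineage forest. On top of the simulator sit a
fluorescence-histogram likelihood for fitting simulated reporter counts to
flow-cytometry data, and phenotype analyses (ON/OFF fractions, switching
rates).

## Cell growth and division model

The cycle has two growth stages — G1 at rate `r1` and S/G2/M at rate `r2`
(fL/min) — split into three time blocks. T1 runs from cycle start to *start*
(the size-licensed G1 commitment point), reached at volume `Vs = k*r1 + b`;
T2 is a short fixed interval from *start* to S entry; T3 covers S/G2/M. T1 is

    T1 = max(T1min, (Vs - V0) / r1)

`T1min` acts as a lower bound: a cell born above the start size still spends
`T1min` in G1 (the formula can be switched to a literal `min` with the
`t1_combiner` config flag; the bound semantics is the default because it is
the behaviorally meaningful reading of a minimum G1 duration).

At division the daughter receives the bud volume `(r2 - r2m) * T3`, where
`r2m` is the mother compartment's share of S/G2/M growth; the mother keeps
the remainder and both re-enter T1 immediately. Volume is conserved exactly.
Per-cell parameters (`Vi, r1, r2, r2m, T1min, T2, T3`) are drawn from
truncated-normal population distributions (redraw on negative values);
daughters inherit them as `c*parent + (1-c)*fresh` with `c = 0.25` by
default. The mother's generation counter increments at each division; the
daughter starts at generation 0 (standard replicative-age bookkeeping).

### Default calibration

Supplementary parameter tables for the measured strain are not part of the
shipped package; the defaults are instead calibrated to the strain's stated
120-min average doubling time:

| parameter | mean | sd | unit |
|---|---|---|---|
| Vi | 30 | 3 | fL |
| r1 | 0.25 | 0.025 | fL/min |
| r2 | 0.45 | 0.045 | fL/min |
| r2m | 0.15 | 0.015 | fL/min |
| T1min | 30 | 3 | min |
| T2 | 15 | 1.5 | min |
| T3 | 75 | 7.5 | min |

with `k = 40 min`, `b = 20 fL`. At the means, a daughter is born at the bud
volume 22.5 fL and needs exactly `(Vs - V0)/r1 = 30 min = T1min` to reach the
start size, and a mother re-enters G1 above `Vs`, so both nominal cycles are
30 + 15 + 75 = 120 min. Because daughters sit exactly at the margin where the
two arguments of the `max` coincide, parameter noise inflates the *realized*
daughter cycle to ~127 min (`E[max(A,B)] > max(E[A],E[B])`); mothers stay at
120 min. The population consequently multiplies by ~41x rather than the naive
2^5.5 = 45x over 11 h, and the steady exponential age structure carries ~50%
never-divided and ~25% once-divided cells. These are emergent properties of
the size-control rule, not separately tuned targets.

## Gene network model

Each gene `G_x` (a fluorescent reporter G0 plus network genes) has seven
reaction channels: promoter activation (`r_ON,x * PR_OFF`), inactivation
(`r_OFF,x * PR_ON`), basal and full transcription, mRNA decay, translation,
and protein decay. Concentration-type propensities carry a `Vref/V` factor so
rates are expressed at a reference volume (45 fL by default). Promoter
activation is modulated by the network activity `F` in [0,1]:
`r_ON,x = r_x * F`.

Users specify *observed* quantities — the population mRNA synthesis rate
`rm_obs`, the basal fraction `b_obs`, and the fully-induced active fraction
`f = r/(r + r_OFF)` — which the package converts to mechanistic ON-state
rates:

    r_off   = r * (1 - f) / f
    rm_true = rm_obs * (1 - b_obs*(1 - f)) / f
    b_true  = b_obs * rm_obs / rm_true

The transform is exactly invertible (tested to machine precision), and keeps
mean expression comparable across choices of `f` — the duty cycle then
controls burstiness rather than the mean.

A note on volume scaling: because the `Vref/V` factor multiplies synthesis
*and* first-order decay alike, the stationary count distribution of the
chemistry is independent of volume — volume only stretches the kinetic
timescale. Concentrations therefore dilute as cells grow between synthesis
events. A `scale_first_order: conventional` flag removes the factor from the
decay channels for users who prefer volume-independent first-order decay.

### GAL-network activity function

The shipped instantiation is the canonical yeast galactose circuit (reporter
+ GAL1, GAL3, GAL80), with activity

    F = 1 / (1 + (S80*[Gal80p] / (1 + (S3*g*[Gal3p] + S1*g*[Gal1p])^alpha))^beta)

with `alpha = 1` and `S80` pinned at 4500 — only scale ratios matter once the
activator term dominates (joint rescaling invariance is a tested property).
Concentrations are counts normalized to `Vref`. The inducer coupling `g` is
linear in galactose % w/v by default (a saturating `gal/(K+gal)` variant is
available); the fitted scales `S3`, `S1` absorb its units.

Gene-expression defaults (per gene: `r = 0.1/min`, `f = 0.5`,
`rm_obs = 1/min`, `b_obs = 0.01`, `r_p = 0.5/min`, `d_m = 0.05/min`,
`d_p = 0.01/min`; GAL80 weaker and leakier: `rm_obs = 0.2`, `b_obs = 0.5`)
give basal mRNA counts of order 1 and induced reporter counts of order 10^3.
`S3 = 5e4`, `S1 = 5e3`, `beta = 3` were chosen by a mean-field fixed-point
scan so that the deterministic skeleton is bistable across the 0.02–0.07 %
galactose window, OFF-monostable below and ON-monostable at 0.1 % — the
qualitative regime of the real circuit, where intermediate galactose
produces bimodal populations. The scan also showed that a strongly
Gal4-inducible GAL80 (repressor scaling proportionally with the activators)
destroys bistability in this functional form, hence the weakly inducible
repressor default (~2x induction). The reporter and GAL1 share a promoter and
are tied to the same `r` and `f` by the parameter-tying map.

## Stochastic engine

The chemistry is simulated exactly: exponential waiting times on the total
propensity, linear channel selection. Cell volume is itself a stochastic
reaction firing at `growth_rate/dV` and adding a fixed quantum `dV`; the
trajectory converges to the deterministic ramp as `dV -> 0`. The default
`dV = 0.02 fL` keeps the division-volume scatter under 2% RMS of the
deterministic value (`sd = sqrt(growth * dV)`), while leaving the volume
channel subdominant to the chemistry.

Deterministic cycle events are interleaved by the next-event-time method: a
sampled reaction that would land beyond the next scheduled boundary is
rejected and the state advanced to the boundary instead. At S entry (T2→T3)
every promoter copy replicates in place preserving its ON/OFF state; double
replication within a cycle is a guarded error. At division, mRNA and protein
are partitioned per species by `Binomial(n, V_daughter/V_total)`; the `2n`
promoter copies are dealt `n` to each cell with per-copy state preserved
(hypergeometric split of the ON copies). Counts are conserved exactly at
every division.

The inner loop is JIT-compiled (numba) over flat per-cell arrays; a
pure-Python `compute_propensities`/`step` pair expresses the same semantics
one event at a time and anchors the unit tests. Stationary moments of the
engine match telegraph/birth-death closed forms within Monte-Carlo error.

## Population protocols

`init_population` draws per-cell cycle parameters, one multiplicative
extrinsic-noise factor per process category (promoter switching,
transcription, mRNA decay, translation, protein decay; `Normal(1, 0.10)`
truncated positive, shared across genes within a cell), an age
`Exponential(mean cycle length)` mapped modulo the cell's own cycle onto the
deterministic volume trajectory, and molecular counts from the rounded basal
fixed point of the cell's own noise-perturbed rates (promoter states
`Bernoulli(phi)`). Cells embedded past S entry start with replicated
promoters.

The two standard protocols are: 22-h — 1000 cells, inducer from t=0, 11 h,
uniform sample of 2000, 11 h more; and 5-h — 20,000 cells, 5 h basal, sample
of 20,000, inducer on, 5 h more. All sizes and durations are configurable,
and chemistry can be disabled for demographic questions (the growth/division
module alone is orders of magnitude faster). Every division is appended to a
lineage log; optional per-cell (time, volume, reporter) series are recorded
at a configurable snapshot interval. Per-cell random streams are seeded
deterministically from `(master seed, cell_id)`, so runs are bit-reproducible
and cells could be scheduled in any order; daughters draw fresh noise factors
by default (`noise_inheritance` flag).

## Fluorescence likelihood

A simulated cell with `R` reporter molecules maps to fluorescence
`F = c*R + B`, `B ~ Normal(61, 17)` (background measured on uninduced
cells). Samples are compared on a 20-bin histogram of `log10(F)` over
[0, 4), area-normalized to 1; an experimental value scores the floored height
of its bin, `pdf(g) = max(1e-4, H)`. Non-positive totals (possible under the
normal background) are clamped to fluorescence 1 before the log, mimicking
the instrument floor; normalization is over in-range values so the pre-floor
area is exactly 1. The log-likelihood of n cells is bounded between
`n*log(1e-4)` and `n*log(5)`.

The conversion factor `c` is fitted per repeat by maximizing the combined
(summed) log-likelihood across conditions over `log10(c)`: a 33-point grid
scan locates the basin — the histogram makes the objective a staircase, so a
simplex alone can stall on a plateau — followed by Nelder-Mead refinement.
Each restart uses one fixed background draw per condition (a
`fresh_background_per_eval` variant was considered and rejected: it makes the
objective non-deterministic within a single optimization); the score is the
mean over restarts of the per-restart maximum.

## Parameter fitting

The GAL free parameters are `r` and `f` for the three promoter groups
(reporter/GAL1 tied, GAL3, GAL80) plus `S3`, `S1`, `beta` — nine in all.
`evaluate` runs `N_R` independent simulation repeats of every condition and
averages the fluorescence scores; `fit` seeds Nelder-Mead from the best
point of a coarse sweep, preferring sweep points flagged as producing
bimodal reporter distributions (two-component Gaussian-mixture criterion;
the flag never enters the score). Positive scales are optimized in log10
space within generous bounds (`f in (0.01, 1]`, `r in [1e-4, 10]/min`,
`beta in [0.5, 8]`, `S3, S1 in [1e-3, 1e6]`). Stage budgets are expressed in
objective evaluations, not wall-clock, for hardware independence. Fresh
simulation seeds are drawn per repeat (a `common_random_numbers` flag
enables CRN instead).

At desk scale (100-cell populations, N_R = 4, single condition,
500-cell synthetic datasets) the likelihood identifies sharp parameters such
as the Hill exponent `beta` to within ~15–20%; threshold-type scales (`S3`)
carry an intrinsic ~25% identifiability floor at this data size because the
likelihood plateaus on the saturated side of the dose response. Full
9-parameter recovery is stochastic and multimodal and is not claimed.

## Phenotype analysis

Cells are classified ON when the reporter count (or fluorescence) is at or
above a threshold; the default threshold is the midpoint in log space
between the two modes of a two-component Gaussian mixture fitted to the
final distribution. Two switching-rate estimators are provided:

* **Dense-series counting** — transitions between consecutive snapshot
  classifications divided by time spent in the originating state, pooled
  over cells and lineage-aware (exposure ends at division; daughters
  contribute their own series). Unbiased up to O(k*dt) censoring for a
  memoryless process.
* **Two-state endpoint back-calculation** — the closed-form solution
  `f(t) = f_ss + (f0 - f_ss) e^{-(k_on+k_off)t}` solved from the ON
  fractions of two oppositely prepared populations at t=0 and t=T (the
  difference of the two histories isolates `e^{-kT}`; the remainder gives
  `f_ss`). Degenerate fully-relaxed data report the total rate at a 10^3/h
  cap. This is the package's standard-solution stand-in for endpoint-style
  experimental rate extraction; outputs are labeled accordingly.

For a homogeneous memoryless two-state process the endpoint method is
consistent, so the documented tendency of endpoint extraction to
*underestimate* rates relative to dense observation emerges only when the
population relaxes sub-exponentially — e.g., under per-cell rate
heterogeneity, the synthetic condition used in the tests (lognormal rates,
CV 0.5, 22 h, ~10^4 cells per history, the flow-cytometry measurement
scale). At that scale the endpoint estimates sit below the dense ones in
>= 90% of replicates.

## What the synthetic data do and do not show

The fixture generator produces fluorescence CSVs from known ground truth
(simulated counts, linear conversion, normal background) in the exact shape
of exported flow-cytometry data, enabling offline recovery tests. It
emulates count noise, extrinsic per-cell rate variation, cycle/volume
demography and measurement background — but not instrument gating,
autofluorescence spectra, cell-size-correlated scatter, or non-linear
detector response. Passing recovery tests therefore demonstrates the
correctness of the fitting machinery, not that real flow-cytometry data meet
the model's assumptions.

## Numerical choices and degenerate inputs

* Volume quantum `dV = 0.02 fL`; boundary interleaving advances the cycle
  clock by the exact boundary increment to avoid floating-point stalls on
  sub-ulp residuals.
* Basal fixed point: damped-free iteration, relative tolerance 1e-6, error
  after 1e4 iterations; counts rounded to nearest integer at initialization.
* `divide` errors on non-positive daughter volume (r2 = r2m) and on a bud
  larger than the whole cell; partition errors on volume mismatch > 1e-9.
* Two-state back-calculation errors on crossed or non-relaxing endpoint
  fractions (no non-negative solution), returns zeros for static data, and
  caps fully-relaxed data.
* Histogram queries outside [0, 4) in log10 return the floor; all-zero-count
  likelihoods are flat in `c` and return a finite optimum.

## Problem sizes used in the shipped checks

Demographic checks run 1000→~41,000→(sample 2000)→~82,000 cells and a
12,000-cell generation census; engine checks average ~1e5 simulated minutes
of single-gene chemistry; fitting checks use 100-cell populations with
N_R = 4 and 500-cell synthetic datasets; switching-rate checks use 2e4
cell-hours (dense accuracy) and 50 replicates of 10^4 cells per history
(endpoint-vs-dense direction). These sizes were chosen as the smallest that
leave the statistical assertions well inside their Monte-Carlo tolerances.

## Known limitations

* Senescence, replicative-lifespan limits and mother-specific aging are out
  of scope; volume grows without bound in old mothers (consistent with the
  modeled time horizon of ~11 generations).
* No nutrient- or crowding-dependent growth modulation; no cell death.
* The functional form treats Gal4p implicitly (absorbed into F); alternative
  network topologies require a custom activity plug-in.
* Exact per-copy promoter-state tracking at division assumes promoters are
  exchangeable between mother and daughter.
* The deterministic embedding of initial ages ignores the small correlation
  between a cell's age and its molecular state that a long burn-in would
  produce; the 5-h protocol's basal phase exists precisely to wash this out.
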