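# Methods

## Arena geometry

The substrate is a square field carrying a square grid of circular
stimulatory spots. "30 µm apart" is read as center-to-center pitch, not
edge gap: only that reading reproduces 64 spots of 10 µm diameter in a
50,625-µm² (225-µm side) field (an edge-gap reading gives 36). The grid
is anchored with the first spot tangent to the field corner (first
center at one spot radius), giving an 8×8 layout for the reference case;
the anchoring itself is not empirically constrained. Per-spot arrest
capacity defaults to 1 for 10-µm spots and 4 for 20-µm spots, the
nearest integers to the measured means of 1.15 and 4.5 simultaneously
arrested cells per spot. Fields of other sizes are handled by tiling the
reference field; all per-field quantities are normalized to the
50,625-µm² reference unit.

## Synthetic motility and arrest generator

Cells perform a persistent random walk: each cell draws a constant speed
from a lognormal with phenotype mean and CV 0.3, and its heading gains a
wrapped-normal increment (SD 0.6 rad per 0.5-min frame, ~2-min
persistence time) every step. Imaging cadence is dt = 0.5 min (a 90-min
movie is 181 frames); no cadence is empirically fixed, so dt is a
package choice. Boundaries are periodic by default (a window on a larger
channel), reflecting optionally.

Encounters are footprint entries: the first frame inside a spot after at
least one full frame outside (or entry into a different spot's
footprint). On an encounter at a spot with spare capacity the cell
arrests with phenotype probability `arrest_prob`; arrested cells jitter
about their arrest point (SD 0.2 µm — so the downstream speed-threshold
caller is exercised realistically rather than on frozen coordinates) and
release after an exponential dwell with half-life `dwell_half_life`.
Released cells take a fresh heading and cannot re-arrest for a short
refractory period (2 frames); footprint entries during the refractory
period are not scored as encounters. Whether re-arrest occurs with the
same probability after release is not empirically constrained; we assume
it does.

Default phenotypes encode the reported contrasts: naive speed
10 µm/min, memory 16 µm/min (the ~1.6-fold difference); naive
arrest probability 0.1 ("1 in 10"), memory 0.4 (~40%); memory dwell
half-life 3.5-fold shorter than naive. Absolute half-lives are not
reported here, so naive t₁/₂ = 210 min, memory 60 min are
order-of-magnitude defaults; every fold-based result is insensitive to
the absolute scale.

**Open-field (replenished) mode.** The imaging field of the experiment
is an open window: arrested cells accumulate while the free-cell density
is maintained by settling and through-traffic. A closed simulation
conserves total cells and therefore depletes its free pool as arrests
accumulate, which distorts any rate averaged over the movie. With
`replenish=True`, each arrest admits one fresh free cell of the same
phenotype at a uniformly random position (a cell landing on a spot
encounters it on arrival and may itself arrest). Measurement studies use
this mode; the default is the closed field.

On a uniform stimulatory surface there are no discrete spots: free cells
arrest anywhere with per-frame probability 1 − exp(−hazard·dt), without
capacity limits.

The generator emits a ground-truth event log alongside the tracks, so
the pipeline's calls can be scored for sensitivity and precision.

What the generator does *not* emulate: cell–cell collisions and
crowding, chemokine gradients, ligand-density-dependent signaling,
heterogeneous per-cell arrest probabilities, cell division, imaging
noise, or tracking errors (identity swaps, gaps). Passing tests
therefore validate the measurement logic and its statistical behavior,
not robustness to tracker artifacts.

## Measurement pipeline

**Arrest calls.** The criteria are attachment-like confinement plus
deceleration: starting at an encounter, a call requires the trailing
mean speed (5-min span, truncated at the call onset so earlier fast
frames never leak in) to stay below 2 µm/min while the centroid stays
within the footprint plus a 1.5-µm margin (tolerating arrest-point
jitter), for at least 5 min. The end time is the first frame violating
either condition. The numeric thresholds are not published; these
defaults were validated against synthetic ground truth (≥95% sensitivity
on dwells ≥ 5 min and ≥95% precision) and are configurable. Footprint
entries that occur while the same cell is already inside an ongoing call
(e.g. jitter flickering across the footprint edge) are excluded from the
encounter list — they offer no new chance to arrest and must not inflate
the efficiency denominator.

**On-rate.** Least-squares slope through the origin of the attachment
curve (cumulative first arrests per cell, per reference field) over an
initial window: from t = 0 to the earlier of (a) the time cumulative
arrests reach 15% of total site capacity and (b) 30 min, with at least 5
points (widened with a warning otherwise). The window rule avoids
saturation bias while keeping enough points for a stable slope.

**Common-window decomposition.** The identity on_rate =
encounter_rate × efficiency holds instantaneously; once spots fill or
the bound pool turns over, quantities averaged over different epochs
diverge from each other for reasons unrelated to the identity. The
report therefore estimates encounter rate and arrest efficiency inside
the same initial window used for the on-rate slope, and the residual
|predicted − measured| / measured is the self-consistency check.

**Censoring correction.** A caller requiring 5 min of sustained arrest
cannot see shorter dwells, biasing raw efficiency low by the exponential
survival S(5 min) = 2^(−5/t₁/₂). The corrected estimator divides by
S(5) using the dwell half-life fitted from call durations by maximum
likelihood with left truncation at 5 min and right censoring at movie
end. Parameter-recovery estimates also drop encounters within 5 min of
movie end (no full detection window ahead). The decomposition residual
uses raw detection-level quantities on both sides, where detection
losses cancel.

**Folds.** Memory/naive ratios; the on-rate fold carries a percentile
bootstrap interval (1,000 reps, seeded) over cell-level first-arrest
indicators, re-centered on the measured slope ratio. Donor-level scatter
in the original data is replaced by replicate seeds.

## Competition model

Two species bind a pool of S = n_sites × capacity identical sites:
dB_i/dt = kon_i (N_i − B_i)(S − ΣB) − koff_i B_i, koff = ln 2 / t₁/₂.
Three consistent views: the analytic steady-state occupancy ratio
(kon_m/koff_m)/(kon_n/koff_n) for equal non-depleting pools (independent
of site count and of common rescalings); the mass-action ODE (adaptive
stiff-capable integration, rtol 1e-8; fixed point by bracketing
root-finding on the free-site count); and an exact Gillespie simulation
that tracks bound-cell identities uniformly at random, yielding
per-cell bound intervals.

**Loading.** "1×" = 1.66 cells per arrest site (120,000 cells for
63,000 spots at 1.15 cells/spot), applied at a tractable site count
(default 500). Only rate *folds* are reported quantities; the absolute
naive kon (default 1e-5 per cell per site per min) is normalized so the
2-h transient is sub-saturating, and every reported comparison is a
ratio, which the absolute scale cancels out of.

**Activation readout.** A naive cell is scored activated (CD62L-low
surrogate) when any single bound interval lasts ≥ θ = 60 min of
continuous engagement; sub-threshold dwells leave no memory under the
default rule (a cumulative-time alternative is available behind a
switch). θ and the scenario duration (720 min, within the 10–12-h
assay span) are package choices. Intervals still open at the horizon
count with their elapsed time. The three standard scenarios are 1×
naive alone, 2× naive (dilution control), and 1× naive + 1× memory
(competition); under the reported folds the activated-naive fraction
ordering 1× > 2× > 1×+memory is reproduced on every tested seed.

## Study designs and problem sizes

- Decomposition self-consistency: 600 cells per phenotype, 90-min
  movies, 5×5-tiled reference field with capacity 2 per spot, open-field
  mode, seeds 1–5. The capacity is chosen so the 15%-of-capacity rule
  ends the on-rate window (~10 min for memory, 30-min cap for naive)
  before release/re-arrest recycling contaminates the first-arrest
  curve (koff × window ≪ 1).
- Parameter recovery: 400 cells per phenotype per seed, five seeds
  pooled, ample capacity (50/spot) so site competition does not distort
  the arrest Bernoulli; 90-min movies for naive, 240-min for memory (to
  accumulate ≥ 500 releases for the dwell fit).
- Stochastic/deterministic agreement: single species, 50 sites, 1,000
  Gillespie replicates at t = 60 min.
- Dose–response ladders: 150–400 cells per rung, 30–60-min movies,
  fixed seeds.

These sizes put binomial and Monte-Carlo standard errors well inside the
tolerances being tested while keeping the full suite fast on one CPU.

## Known limitations

- Frame-based encounter detection undercounts fast cells' spot
  transits (a 16-µm/min cell can step across a 10-µm footprint between
  frames); generator and pipeline share the convention, so
  self-consistency is unaffected, but absolute encounter rates are
  cadence-dependent.
- The spatial simulation and the well-mixed competition model are
  complementary, not coupled: spatial search sets the encounter rate,
  the site-occupancy model takes rates as given.
- Donor-to-donor variability is represented only by seed-to-seed
  scatter; no attempt is made to reproduce measured human donor values,
  which depend on the original imaging data.
- The activation surrogate maps continuous engagement to a binary
  CD62L-low call with a single threshold; real shedding kinetics are
  graded.
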