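# Methods

## The setting

Long-stay residents are assessed repeatedly on nine activities of daily
living (ADLs), each recorded as completely dependent (1) versus independent
or partially dependent (0).  The nine flags define 2⁹ = 512 *disability
states*; a resident's ADL history is a *trajectory*: an ordered list of
spells `(state, duration-in-days)` in which the state is constant.  The
package turns raw assessment tables into trajectories, collapses identical
trajectories into weighted records, and computes per-trajectory indicators,
transition analytics and descriptive aggregates.

## State coding

Each ADL letter carries a fixed bit weight — F=1, S=2, G=4, D=8, B=16,
W=32, T=64, L=128, U=256 — and a state code is the sum over dependent ADLs,
so code ↔ flag-set is a bijection on [0, 511].  Names list the letters in
the fixed display order F,S,G,T,B,W,D,L,U (code 0 is `O`, 511 is `All`);
severity is the popcount of the code.  The table is a single exported
constant (`bit_weights_json()`), so an alternative coding can be swapped in
one place.  The tests pin the coding through every published code/name pair
the package targets (16=B, 20=GB, 92=GTBD, 124=GTBWD, 476=GTBDLU,
509=FGTBWDLU, ...); of these only codes 116 and 348 distinguish the T/D
weight assignment, and both are covered.

## Trajectory construction

Durations are integer days, 1-based, closed on the left: an assessment's
state holds from its own day until the day before the next assessment, and
the final assessment closes the observation window.  Trajectory length
therefore equals the day span between first and last kept assessment, and
`l = Σ durations` throughout.  Cleaning order: residents with invalid ages
(outside [0, 120]) are dropped, then death records, then duplicate
`(resident, date)` rows (keep-last by default), then residents left with
fewer than two assessments; each step is counted in an exclusion report.
Consecutive assessments with an unchanged state merge into one spell, so
adjacent spells always differ — the *distinct successive states* (DSS)
sequence is just the spell states.

When restricting to the `k` predominant states, states are ranked by
weighted spell occurrences (one spell = one case) rather than by
person-days; day-occupancy ranking is available via `rank_by="days"`.  The
reported coverage is the kept share of the ranking mass.  Out-of-alphabet
material can be handled by dropping whole sequences (default, keeps spell
adjacency exact) or by deleting the offending spells and re-merging; no
claim is made that either matches the original study's unstated choice.

## Indicators

**Entropy.** `H = −Σ pᵢ log pᵢ` (natural log) with day-level occupancy
`pᵢ` = share of the trajectory's days in state `i`; normalized by
`log a` with `a` the alphabet size (25 by default).  Spell-level occupancy
is available behind a flag; day-level is the default because occupancy of
time, not of events, is what the state-distribution analytics show.

**Spell-duration statistics.** Population (divide-by-n) mean and SD.  The
starred versions pad the duration list with `a − n_visited` zeros, one per
never-visited alphabet state; with `a = 25` this reproduces the published
summary minima (mean 0.08 for a single 2-day spell; SD 0.2713 for two
1-day spells), which is how the padding convention was pinned down.

**Distinct subsequences.** `Φ(x)` counts distinct subsequences of the DSS,
the empty one included, by the standard dynamic program
`φ(i) = 2φ(i−1) − φ(prev(xᵢ)−1)` in exact integer arithmetic (counts in
the tens of millions arise on long trajectories); it is property-tested
against brute-force enumeration.

**Turbulence.** `T* = log₂(Φ · (s*²_max+1)/(s*²+1))` with `s*²` the padded
duration variance.  For the variance ceiling we use the exact maximum over
feasible duration allocations — `n` spells of ≥ 1 day summing to `l` plus
`m − n` structural zeros (`m = n + a − n_visited`):

    s*²_max = [ (n−1)(1−d̄*)² + (l−n+1−d̄*)² + (m−n)·d̄*² ] / m ,  d̄* = l/m,

attained by concentrating all slack in one spell.  With no padding this
reduces to the classic bound `(n−1)(1−d̄)²`.  The choice matters: applying
the unpadded closed form directly to the padded list can fall below the
realized variance (e.g. a single 440-day spell with `a = 25`), which would
push `T*` below 1 and break the normalization; with the exact maximum the
single-spell trajectory attains its own bound and lands at `T* = 1`
exactly.  `T*_n = (T*−1)/(T*_max−1)` normalizes against the reference
sequence of the same length whose unit-day spells cycle the alphabet
(⌊l/a⌋ full cycles plus the first `l − a⌊l/a⌋` states); the reference
attains the variance ceiling, so `T*_max = log₂ Φ_ref`, computed by the
same dynamic program (previous occurrence exactly `a` steps back) and
cached per `(l, a)`.  Seeded property tests keep `T*_n` in [0, 1] across
randomized trajectories; the degenerate case `T*_max ≤ 1` (only possible at
day-scale lengths) returns `T*_n = 0`.

**Insecurity.** `I_insec = π(x₁)·I_integr(sp(x₁)) + I_degrad + c` where

- `π(x₁)` is the initial state's severity rescaled to [0, 1]
  (disabilities / 9), so the first term reads the start of the trajectory
  as a fall from full ability; the raw 0–9 degree stays available as
  `severity`;
- `I_integr(sp) = Σ_{t∈sp} t^z / Σ_{t=1..l} t^z` with `z = 1` by default
  (linear position weights, configurable), so late spells integrate more;
- `I_degrad = (worsening − improving)/transitions` with severity ordering
  the states and equal-severity moves counting only in the denominator;
- `c = √( (q/(l−1)) · H_norm )` with `q = n_spells − 1` transitions over
  `l − 1` day steps — the proportion-of-transitions factor uses day-level
  `l` because that convention, and only that one, reproduces the published
  maximum insecurity 1.01 for the two-spell trajectory `(0,14)-(511,426)`
  (first term 0, degradation 1, complexity 0.00999).

The index mostly lands in [0, 1] but is unbounded: strongly improving
trajectories go negative.

**Summary tables.** Weighted Min/Q1/Median/Mean/Q3/Max per indicator;
quantiles use lower cumulative-weight interpolation (the first sorted value
whose cumulative weight reaches `q` of the total), so tables are exactly
reproducible.

## Transitions and aggregates

Spell-level matrices count each adjacent spell pair once per trajectory
weight (empty diagonal by construction); day-level matrices count day
pairs, so a `d`-day spell adds `d − 1` diagonal counts plus one boundary
count.  Rates are row-normalized; rows without outgoing mass are flagged
absorbing, and the display/prediction path re-excludes the diagonal.  A
transition is a recovery/decline when severity falls/rises; a
`single_change_only` filter restricts to one-ADL flips.  Both matrix modes
are produced because published bubble plots can be read either way.

State distributions place, per day, the weights of trajectories still
observed on their current states and renormalize (right truncation);
an alternative carries ended trajectories in an explicit `exited` column.
Mean time per state includes zeros for non-visitors (population mean,
consistent with the starred duration statistics).  Index-plot sampling
sorts trajectories lexicographically by their daily state-name sequence
(compared spell-wise, without daily expansion) and takes the first member
of each of `n` contiguous groups — deterministic, and a subset of the
input.

## Synthetic cohorts

The generator emulates the data's structure, not any particular resident:

- assessments every 84 ± 7 days (uniform), horizons capped at 5331 days,
  follow-up ended by a per-assessment hazard of 0.08 (mean span ≈ 2.5 y);
- initial severity: mass 0.5 on zero disabilities, geometric decay (0.55)
  over 1–9; which ADLs are set follows onset propensities favouring
  bathing, walking and grooming, concentrating mass on a small set of
  predominant states as observed in practice;
- at each epoch the state changes with probability 0.2 (mean spell
  duration ≈ 400 days at quarterly cadence); a change flips exactly one
  ADL (`single_change_only`), so severity moves by ±1 and no transition is
  lateral;
- the recovery-vs-onset probability is severity-dependent,
  `q(s) = min(1, θ·s/9)` with forced `q(0)=0`, `q(9)=1`, and θ is solved
  at configuration time by root-finding on the expected realized recovery
  share of the epoch model (severity distribution propagated across
  epochs, censoring-weighted) — deterministic runtime, no rejection
  sampling.  With the default target 0.45, a 2,000-resident cohort
  realizes the share within ±0.02;
- planted single-assessment residents (3%), invalid-age residents (1%) and
  terminal death records (5%, only for residents with ≥ 3 assessments so
  no further exclusions cascade) exercise the cleaning logic; the planted
  counts are reported as gold values.

What the generator does **not** emulate: demographic effects on
progression, mortality as a competing risk, calendar-time trends,
measurement error in assessments, and the heavy concentration of the real
data on a handful of no-disability short stays.  Passing tests on
synthetic cohorts therefore demonstrate correctness of the computations
and calibration machinery, not epidemiological fidelity of any particular
rate beyond those explicitly targeted.

A second generator simulates spell sequences from a given spell-level
matrix with geometric durations; transition-rate estimation recovers the
generating matrix within 0.05 (max absolute error) from ≥ 10,000 simulated
transitions, which is the oracle used to validate the estimator.

## Numerical choices and degenerate inputs

Exact integer arithmetic for Φ; `log₂ Φ` taken on the integer to avoid
overflow; tie-breaks are always deterministic (lowest state code for modal
next states, shorter-then-lexicographic for frequency ranking);
single-state alphabets define `H_norm = 0`; one-day trajectories define
`c = 0`; trajectories without transitions have degradation 0, while a
recovery *fraction* over a pool without transitions is an error (a share
of nothing).  Empty pools and empty spell strings are errors, not empty
results.  Problem sizes in the test suite (cohorts of ≤ 2,000 residents,
pools of ~10³ trajectories) keep the full suite in the tens of seconds
while leaving every law-of-large-numbers check comfortably inside its
tolerance.

## Known limitations

- The supplementary conventions of the original analysis (exact padding
  formula for the turbulence ceiling, integration-index exponent) are
  reconstructed from the reproducible anchors rather than transcribed;
  deviations are confined to single functions and covered by bound tests.
- No imputation, interval censoring or calendar alignment: assessment
  dates are taken at face value and states persist between assessments.
- Partial dependence is folded into "not completely dependent"; the
  intermediate assessment-scale levels are out of scope.
- Trajectory clustering, dimension reduction and mortality modelling are
  out of scope.
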