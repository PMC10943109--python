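# adltraj

Sequence analytics for trajectories of disability in **activities of daily
living (ADLs)**, aimed at researchers in geriatrics, epidemiology and health
services who study functional decline and recovery in longitudinal
assessment data (e.g. nursing-home Minimum Data Set records).

Nine ADLs — feeding (F), transferring (S), grooming (G), toilet use (T),
bathing (B), walking (W), dressing (D), bowel (L) and urinary (U)
continence — are each dichotomized as completely dependent (1) or not (0),
so a resident's functional status at any time is one of 2⁹ = 512
*disability states*, bit-coded 0–511 (state 16 = *B*, 476 = *GTBDLU*,
511 = *All*).  A resident's *trajectory* is their sequence of states in
spell format, `(state, duration-in-days)` pairs such as
`(476,974)-(92,83)-(16,245)-(476,323)`; identical trajectories are collapsed
into weighted records.

## What it computes

For a trajectory *x* of length *l* days over an alphabet of *a* admitted
states the package provides:

- **Basic indicators** — length, spell count, visited states, recurrence
  degree (spells per visited state).
- **Diversity** — longitudinal normalized entropy
  `H(x) = −Σᵢ pᵢ log pᵢ`, `H_norm = H / log a`, with day-level occupancy
  `pᵢ`; spell-duration mean/SD, optionally zero-padded with one 0-length
  spell per non-visited state.
- **Complexity** — turbulence
  `T*(x) = log₂( Φ(x) · (s*²_{d,max}+1)/(s*²_d+1) )`, where `Φ(x)` is the
  exact number of distinct subsequences of the distinct-successive-states
  sequence (dynamic programming with arbitrary-precision integers) and
  `s*²_d` the padded duration variance; normalized as
  `T*_n = (T*−1)/(T*_max−1)` against the maximally turbulent sequence of the
  same length and alphabet.
- **Unfavorableness** — the insecurity index
  `I_insec(x) = π(x₁)·I_integr(x, sp(x₁)) + I_degrad(x) + c(x)` combining
  the initial state's severity `π` (disabilities/9), the integrative
  potential of the first spell, the degradation index (worsening − improving
  transitions over all transitions) and the complexity index
  `c(x) = √( (transitions/(l−1)) · H_norm )`.
- **Transition analytics** — weighted spell-level or day-level transition
  matrices, recovery/decline classification by severity, recovery share,
  modal next-state prediction and top recovery patterns.
- **Descriptives** — day-by-day state distributions, most frequent
  trajectories, mean time per state, deterministic index-plot sampling.
- **Synthetic cohorts** — a generator emitting realistic assessment tables
  (quarterly cadence, single-ADL changes, calibrated recovery share,
  planted exclusion cases) with gold-standard trajectories, for testing
  every pipeline stage without access to restricted data.

## Worked example

```python
from adltraj import parse_spell_string, indicator_row

traj = parse_spell_string("(476,974)-(92,83)-(16,245)-(476,323)", id="130202")
row = indicator_row(traj, a=25)
print(f"length      {row['length']} days over {row['n_spells']} spells")
print(f"recurrence  {row['recurrence']:.4f}")
print(f"entropy     {row['entropy_norm']:.4f} (normalized)")
print(f"phi         {row['phi']:.0f} distinct subsequences")
print(f"turbulence  {row['turbulence']:.4f} (normalized {row['turbulence_norm']:.4f})")
print(f"insecurity  {row['insecurity']:.4f}")
```

prints

```
length      1625 days over 4 spells
recurrence  1.3333
entropy     0.1917 (normalized)
phi         15 distinct subsequences
turbulence  5.2194 (normalized 0.0026)
insecurity  -0.0749
```

This resident spent most of 4.5 years severely disabled (*GTBDLU*, six
dependencies), recovered to *GTBD* and then to bathing-only, and relapsed.
Recurrence 4/3 reflects the return visit; entropy is low because one state
dominates the person-time; the negative insecurity value reflects that two
of the three transitions were recoveries (degradation −1/3) while the
complexity term is small.

The same functions drive a CLI pipeline:

```bash
adltraj simulate --n 1000 --seed 7 --out cohort     # synthetic assessments
adltraj build --input cohort/assessments.csv --out built
adltraj indicators --input built/trajectories.tsv --alphabet-size 25 --out out
adltraj transitions --input built/trajectories.tsv --out out
adltraj plot bubble --input built/trajectories.tsv --alphabet-size 25 --out plots
```

Every plot is backed by a JSON payload holding exactly the numbers the
analytics modules produced.

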