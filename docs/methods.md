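# Methods

## The concordance procedure

A diary record is one displayed trend arrow: (participant, system, sensor,
time, arrow, visit).  The analysis pairs it with the trend *realized* over
the following 30 minutes:

1. **Interpolation.**  The reference trace (the sensor's own stored
   readings, or the participant's blood-glucose measurements in the BG
   variant) is linearly interpolated at the record time `t` and at
   `t + horizon`.  Interpolation is exact at sample times and refuses to
   bridge a gap wider than `max_gap`; a record whose endpoints are not
   interpolable is excluded with a reason code (`out-of-range`, `gap`) and
   never imputed.
2. **Rate and category.**  The forward rate `(G(t+h) − G(t))/h` in
   mg/(dL·min) is classified with the device's own arrow taxonomy.
3. **Comparison.**  The ordinal difference |recorded − calculated| is
   tabulated as match (0), off-by-one (1) and off-by-two-plus (≥2)
   percentages, pooled and as mean ± SD of per-participant match
   percentages; a full recorded × calculated contingency table is kept so
   every reported count is reconstructable.
4. **Stratification.**  By study-site visit (visit 1 = days 0–2, visit 2 =
   days 5–7, visit 3 = days 12–14, closed spans in minutes-since-start;
   anything else is "home" and outside visit stratification), and by the
   event-window flag: a record at `t` is *inside* when some carbohydrate
   intake or insulin bolus at `e` satisfies `e − 30 < t < e + 120`
   (minutes, strict inequalities).  Parallel-sensor agreement compares the
   two same-system sensors' arrows paired by (participant, time).

## Conventions and their rationale

- **Boundary convention.**  A rate exactly on a cut point (|r| = 1, 2 or 3
  mg/(dL·min)) goes to the less-extreme category for both devices.  The
  two user manuals word the steady band inconsistently ("not changing >1"
  vs "<1"); a single closed-steady convention keeps the systems comparable
  and only affects a measure-zero set of rates.  The report echoes the
  convention in its options block.
- **Horizon.**  30 min by default — the span used by predictive
  low-glucose management in commercial pumps, hence the natural notion of
  "where glucose is heading".  Configurable.
- **max_gap.**  2.5× the storage cadence (12.5 min at 5-min cadence,
  37.5 min at 15-min cadence): tolerates one missed stored reading,
  refuses real dropouts.  The BG reference uses 75 min, which tolerates a
  missed hourly measurement but excludes the overnight gap between the
  2400 and 0300 measurements.  Whether BG values were interpolated the
  same way in the original evaluation is not documented; applying the
  identical procedure with a BG-specific cap is this package's convention.
- **Event windows** are anchored at the record time, not the whole
  [t, t+30] interval; with the 30-min pre-window the two formulations
  coincide for point events.  Events are treated as instantaneous;
  continuous basal insulin does not open windows, discrete boluses do.
- **Display rounding.**  Percentages are rounded half-up to one decimal at
  the summary boundary; internal statistics (participant means/SDs) stay
  unrounded.  The participant SD uses the n−1 denominator; participants
  with zero records are omitted.

## The synthetic study

The generator produces the *study conditions*, not a physiological model:

- **Trajectory** (1-min grid): participant baseline ~N(130, 15²) mg/dL;
  each meal adds a gamma-shaped pulse `A·(τ/τp)^k·e^{k(1−τ/τp)}` with
  amplitude A ~N(70, 15²) mg/dL, peak τp = 45 min, shape k = 2; each bolus
  subtracts the same shape with amplitude 0.9·A and peak 90 min, so
  glucose rises then returns toward baseline.  Meals at 0700/1200/1800
  daily; on dynamic days the breakfast moves to 0800, its amplitude is
  ×1.5 and its bolus is delayed 30 min (the induced-excursion protocol).
  Added noise is an Ornstein–Uhlenbeck process (SD 15 mg/dL, reversion
  time 60 min) rather than white noise so 30-min forward rates are
  realistically autocorrelated — the minimal structure placing emulated
  arrows between the oracle (100% match) and chance.  Values are clamped
  to 40–400 mg/dL.
- **Sensing.**  Readings at the device cadence equal the trajectory
  7 min earlier (interstitial lag) plus N(0, 8²) mg/dL sensor noise; the
  BG reference is the trajectory at the measurement time plus N(0, 3²)
  meter noise.  No published error model exists for either device; these
  magnitudes are plausible-by-literature knobs, not estimates.
- **Arrows.**  The least-squares slope of the stored readings in the
  trailing 15 min (the span both manuals use to phrase their bands),
  classified with the device taxonomy; fewer than two readings means no
  arrow and the diary record is omitted.  `arrow_mode="oracle"` instead
  writes the realized-forward-rate category, making 100% match the unique
  correct pipeline output — the end-to-end self-consistency check.
- **Schedule.**  Diary records at 0300 and hourly 0600–2400 on the nine
  visit days, plus a 15-min grid during 0800–1300 on dynamic days; no
  diary at home, though sensors keep recording.  All randomness descends
  from one master seed via spawned seed sequences, so identical config +
  seed reproduces every file byte-for-byte.

What the generator does *not* emulate: insulin–glucose feedback dynamics,
hypoglycemia rescue carbohydrates, sensor warm-up artifacts (so the
first-visit degradation seen clinically has no synthetic counterpart),
calibration schedules, compression lows, or dropout bursts.  Passing tests
therefore demonstrate the *pipeline's* correctness and the qualitative
event-window mechanism — not device performance on real patients.

## Numerical and degenerate-input choices

- Interpolation at an exact sample time returns the stored value without a
  gap check; traces need ≥2 samples.
- Empty record sets yield `n = 0` summaries with percentage fields absent
  (`None`) rather than NaN arithmetic.
- Non-finite rates, non-positive horizons, negative window bounds, unknown
  arrow tokens and cross-profile category comparisons raise typed errors;
  a diary sensor without a trace is a configuration error rather than an
  exclusion, since it indicates mismatched inputs.
- The vectorized event-window check broadcasts the exact scalar
  comparisons, so both paths agree bit-for-bit at float boundaries.

## Problem sizes

The default study is the full design: 20 participants × 9 visit days ×
(20 hourly + 15 dynamic-extra) diary slots × 4 sensors = 18 000 diary
records per replicate.  The seed-robustness experiment regenerates the
full study under 20 master seeds; the bundled tests use 3-participant
replicates of the same schedule wherever the statistic does not need the
full cohort.

## Known limitations

- The real devices' arrow algorithms are proprietary; the backward-slope
  emulation is a stand-in mechanism, and synthetic concordance levels
  should be read qualitatively, not as device estimates.
- Ordinal agreement is reported descriptively (as in the source
  evaluation); no chance-corrected statistic (e.g. weighted kappa) is
  computed.
- Extended meals are collapsed to instantaneous events when opening
  windows; a long meal's tail is only covered by its 120-min post-window.
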