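# Methods

## Scope and data model

`wearwindow` operates on epoch-level tri-axial counts — the integer movement
summaries a hip-worn actigraph exports per fixed epoch (15 s in the default
protocol) — and never on raw acceleration waveforms. A series is contiguous
by contract: epoch *i* covers `[start + i·L, start + (i+1)·L)` seconds. Gaps
or duplicate timestamps in an input file raise an error rather than being
zero-filled, because silent zero-fill would bias the non-zero-fraction day
filter downward and could flip a day across the 10 % threshold. Timestamps
are timezone-naive local clock time; a "day" is simply the set of recorded
epochs carrying a calendar date (midnight to 11:59 PM), so daylight-saving
shifts are not modeled and partial first/last days are judged on their
recorded epochs, not a nominal 5 760.

"Non-zero epoch" means vector magnitude > 0, which is equivalent to any axis
non-zero. The VM convention matches the non-wear stage, which is explicitly a
vector-magnitude method; a vertical-axis-only variant is exposed
(`nonzero_axis="vertical"`) for protocols that count only the vertical axis.

## Window-selection procedure

Four steps, with every threshold a strict inequality:

1. **Day filter.** Keep days with fraction of non-zero epochs > 
   `nonzero_fraction_threshold` (default 0.10). A day at exactly 10 % is
   excluded.
2. **First-day rule.** If the chosen run's first day has a leading run of
   zero-VM epochs from midnight strictly longer than
   `leading_zero_exclusion_hours` (default 8), drop that day. The rule is
   applied once, never iterated, and by default has no symmetric last-day
   counterpart (a config switch `trailing_day_rule` adds one, off by
   default) — the asymmetry reflects how such protocols start: the device
   goes on partway through day 1 but typically comes off early enough on the
   last day to fail the day filter outright.
3. **Short-circuit.** A surviving run of ≤ `max_window_days` (default 7)
   days is returned as-is; the result is then provably independent of every
   non-wear-stage parameter.
4. **Sub-window search.** For longer runs, the Choi mask is computed over
   the sub-series spanning the run's calendar days, wear minutes are summed
   per date, and every contiguous `max_window_days`-day sub-window is
   scored; the maximum wins, with ties going to the earliest start (favoring
   early protocol compliance).

When several disjoint candidate runs exist — rare under a 24-h protocol,
which produces one cluster of wear days — the longest run is chosen, ties
broken by the higher summed non-zero fraction, then by the earlier start.
This is deterministic and favors the evidently dominant cluster.

`total_wear_hours` of the returned window is always filled from the Choi
mask restricted to the window, including in the short-circuit case, so that
hour-level comparisons between methods are well defined. An empty candidate
set yields an empty window (`n_days = 0`), which is a reportable value:
signals with no apparent wear are the caller's decision, not an exception.

## Non-wear classification

The Choi vector-magnitude rule on one-minute epochs: a minute is non-wear
iff it lies in an interval of ≥ `min_nonwear_minutes` (default 90)
consecutive zero-VM minutes, where interruptions of ≤
`spike_tolerance_minutes` (default 2) consecutive non-zero minutes are
absorbed as artifact provided the `flank_window_minutes` (default 30) on
both sides of the interruption contain no other non-zero minute. The
defaults follow the published vector-magnitude parameterization and are
config-exposed, since different protocols warrant different tuning.

Numerical/edge choices, fixed by design:

* 15-s counts are aggregated to 60-s epochs by per-axis summation and VM is
  taken of the summed axes — the same additive convention device epoch
  exports use. Running the classifier at 15 s instead would shift non-wear
  interval edges by sub-minute amounts; the package standardizes on 60 s.
* A flank window truncated by the series edge is evaluated on the available
  minutes only (no padding).
* An all-zero series shorter than `min_nonwear_minutes` is all-wear — the
  interval rule applied literally; this is not configurable.
* Two tolerable interruptions closer than a flank window disqualify each
  other (each sees the other as "another non-zero minute"), so dense spike
  trains correctly remain wear.

The production implementation is vectorized (run-length encoding plus prefix
sums for O(1) flank checks). A deliberately naive reference — a pure-Python
per-minute scan of the rule as stated — lives in `wearwindow.reference`, and
the acceptance checks require bit-identical masks on hundreds of randomized
series. The same dual-path discipline applies to the window selector, whose
reference enumerates every candidate date range and sub-window exhaustively.

## Logs and annotations

Participant logs are read from a minimal CSV (`participant_id, date_on,
date_off[, worn_1..worn_k]`). This schema is a synthetic stand-in: real
study logs are study-specific paper forms with additional fields (sleep
times, notes) that the comparison logic does not need — only dates matter
for window agreement. Records that fail validation (inverted dates,
malformed dates, flag-count mismatches) are collected with row numbers and
never abort parsing. A log converts to a window by taking the date span
(capped at `max_window_days`) or, when per-day worn flags are present, the
longest run of worn dates, earliest on ties. Log windows carry no wear hours
unless the caller supplies the signal, in which case the same Choi stage
fills them — the assumption behind hour-difference comparisons between log
and algorithm windows, which is otherwise undefined.

## Agreement taxonomy

`compare_windows` maps any pair of valid windows to exactly one of seven
categories: `exact`, `same_length_shift_1`, `same_length_shift_ge2`,
`diff_length_1`, `diff_length_ge2`, `one_empty`, `both_empty`. For
equal-length non-empty windows the shift is |Δ start date| (which equals
|Δ end date|), making "shifted by one day" well defined. The summary reports
per-category counts and percentages, the pooled same-length percentage
(exact plus both shift categories — the "same total number of days if date
shifts are allowed" aggregation), mean signed wear-hour differences within
the shift categories, and which method had more days among different-length
pairs. No kappa or ICC machinery is provided: with a variable number of
candidate start days per signal the rating scale varies per pair, and a
chance-corrected coefficient would also collapse a 1-day shift and a 7-day
shift into the same "disagreement".

## Simulator

The generator reproduces the two signal regimes the detector exploits:

* **Wear**: each scheduled-wear epoch is zero with probability
  `p_zero_during_wear` (default 0.5), otherwise its axis counts are drawn
  from rounded lognormals (vertical axis forced ≥ 1). The default makes a
  full wear day's expected non-zero fraction 0.5 — a "substantial
  proportion" with a wide margin above the 10 % filter, as real worn days
  show. Count magnitudes are irrelevant downstream (only the zero/non-zero
  pattern and zero-run structure matter), so the heavy-tailed shape is a
  plausibility choice, not a calibrated one.
* **Non-wear**: zeros except solitary spikes at `spike_rate_per_hour`
  (default 0.5/h), drawn per-epoch Bernoulli with probability
  `rate · L / 3600`; spikes are single-epoch by default, with a width
  parameter to stress the spike-tolerance rule.

The default schedule is the nine-calendar-day protocol targeting seven wear
days: on at 10:00 of day 1, continuous wear days 2–8, off at 09:00 of day 9.
Optional removal episodes (bathing-style within-day blocks) carve non-wear
out of scheduled wear. `expected_nonzero_fraction` gives the analytic
per-day expectation — exact for single-epoch spikes, first-order in the
spike width otherwise — and the calibration checks require the empirical
fractions to match it within three standard errors at 5 760 epochs/day.

The planted ground-truth window is derived from the *schedule*, not the
realized draw: days pass the filter by expected fraction, the first-day rule
uses scheduled leading zeros, and runs longer than `max_window_days` are
capped at the sub-window with the most scheduled wear (earliest on ties).
Simulated logs reproduce the truth dates shifted by a draw from a
configurable offset distribution and go missing with probability
`p_missing_log` (default 0.057, a realistic mailed-log loss rate).

What the simulator does **not** emulate: circadian intensity profiles, bout
structure, sedentary-vs-non-wear ambiguity at the count-magnitude level,
device clock drift, or recording gaps. Passing tests therefore demonstrate
the selection logic, boundary behavior, and internal consistency of the
pipeline — not field accuracy on any particular cohort, which depends on how
sharply real wear/non-wear days separate around the 10 % threshold.

## Validation problem sizes

The acceptance checks run at sizes chosen to keep the whole suite quick on a
single CPU while exercising every code path: 500 randomized per-minute
series (≤ 2 880 min) for classifier/reference bit-equality, 200 randomized
≤ 14-day protocols at 60-s epochs for selector/brute-force equality, 200
planted-window simulations at 15-s epochs (wear-day expected fraction 0.35,
non-wear 0.04) for exact recovery, with recovery-degradation probes at
margins 0.11/0.09 and 0.103/0.098, and 20 replicates of the default protocol
for calibration. Larger sizes change none of the observed outcomes.

## Known limitations

* The selector assumes contiguous recordings; interrupted recordings must be
  handled upstream.
* Epoch lengths above 60 s cannot feed the non-wear stage (no exact
  down-conversion to minutes); such series are fine for the day filter but
  raise an error if step 4 is reached.
* Day definitions are purely calendar-date based; protocols that define days
  by time-since-first-wear need a different partitioner.
* The >10 % day filter adds movement and artifact counts alike, so a
  non-worn day with unusually dense artifact could in principle pass; the
  simulator's spike model (sparse solitary spikes) reflects the typical,
  not adversarial, case.
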