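# Methods

This note records the models behind `adlwatch`, the defaults that
matter, and the choices made where the design was genuinely open.

## Scope and assumptions

The package consumes *activity-labeled* event streams: an upstream
activity-recognition system has already tagged each sensor reading with
an ADL label and begin/end markers. Recognition itself is out of scope.
One resident per home is assumed; labels are restricted to five
monitored ADLs — sleeping, eating (split into breakfast/lunch/dinner),
taking a shower, going to the toilet, and leaving home. Leaving home is
instrumental: for a housebound person the label is simply absent from
the profile and nothing downstream requires it.

The central modelling assumption is *routine regularity*: the person's
healthy behavior is stable enough that a baseline window (default 30
days) characterizes it, and departures from that personal baseline —
not from population norms — carry the clinical signal. People with
genuinely irregular routines violate this assumption and will generate
spurious deviations.

## Time conventions

All times are seconds; a behavioral day runs midnight to midnight,
except sleeping, which is anchored to the evening it begins (bedtimes
after midnight up to a noon cutoff attach to the previous day, on an
extended 0–172,800 s axis). This keeps a 2 a.m. bedtime comparable
with the usual 10:30 p.m. one instead of wrapping it to the far side of
the clock, and avoids circular-distance arithmetic in clustering.
Generic "eating" instances are assigned to breakfast/lunch/dinner by
nearest learned meal cluster, falling back to fixed windows
(06–11 h / 11–16 h / 16–22 h) when no profile exists yet.

## Routine learning

Instances of each activity are clustered in (start, duration) with
DBSCAN; points flagged as noise are the baseline's point anomalies and
are removed before any statistic is computed. Defaults `min_pts = 4`,
`eps = 2`. DBSCAN's `eps` is unit-dependent and the choice of feature
units is a declared configuration (`ProfilingConfig`), not a constant:
the defaults scale start time to hours and duration to 10-minute
units, so `eps = 2` tolerates roughly two hours of start-time spread —
wide enough to keep a meal's instances in one cluster, narrow enough to
separate the three meals. The three-meals structure is recovered by
pooling all eating instances and letting the clustering find the three
clusters, then naming them by mean start time.

Each cluster yields a pattern: mean start, mean duration (the scalars
used by the scores), min/max start interval, min/max duration range,
and min/max daily occurrence counts over the baseline span (days
without the activity count as zero). Cluster size is kept
(`n_instances`): when density splits an activity into several
clusters, the largest one is the routine. K-means-style alternatives
were rejected deliberately — the cluster count is not known in advance
and the noise notion is exactly what removes baseline anomalies.

Toileting is profiled by frequency, not time-of-day: counts per 2-hour
slot (configurable, must divide 24), daily totals, and the longest
visit per day, each as an inclusive [min, max] range over baseline
days. Days containing a visit whose duration exceeds a robust
median + 3·MAD cutoff are excluded from the max-duration range so one
anomalous baseline day cannot stretch it.

## Scores and anomaly rules

The similarity score is the temporal intersection of the observed and
usual activity intervals as a percentage of the usual duration,
clamped to [0, 100]: the raw formula goes negative for disjoint
intervals, and a negative "percentage of intersection" has no meaning,
so 0 is the floor. The duration score is the observed duration as a
percentage of the usual one and is deliberately unbounded above —
taking ever longer for the same activity is a decline signal.

Aggregation to a day: similarity averages over *expected* pattern
occurrences, with a missing activity contributing 0 (skipping lunch
must hurt the day's score); duration averages instance scores within
an activity, then activity values across activities present. Surplus
occurrences beyond the expected count affect frequency flags, not
similarity: each is scored against its nearest-in-time pattern and
only the best overlap per pattern counts.

Range comparisons are inclusive everywhere: a value equal to the
learned min or max is Normal. Percentages are reported to 2 decimals,
round-half-up (note: a worked 21/17 ratio therefore prints 123.53
where a truncating convention prints 123.52).

Deviation periods are maximal runs of at least `min_run = 2`
consecutive days with similarity below `threshold = 80 %` or duration
outside the symmetric 80–120 % band. The thresholds are explicit,
configurable parameters: trend reading "by eye" is not reproducible,
and no changepoint model (CUSUM etc.) is attempted — the fixed rule is
the simplest auditable formalization.

## Fuzzy decision support

Each ADL-Disease variable (activity × {duration, frequency}, daily
totals) carries three trapezoids. Where a configuration does not give
corners explicitly they are derived from the normal range [m, M]:

* durations — transition half-width `w = α(M−m)`, default `α = 0.25`:
  `Abnormal− = (−∞, −∞, m−w, m+w)`, `Normal = (m−w, m+w, M−w, M+w)`,
  `Abnormal+ = (M−w, M+w, ∞, ∞)`;
* frequencies — integer counts, one-count ramps:
  `Abnormal− = (−∞, −∞, m−1, m)`, `Normal = (m−1, m, M, M+1)`,
  `Abnormal+ = (M, M+1, ∞, ∞)`, so a count at the range bound is
  fully Normal (a frequency of 2 against a max of 2 is not suspicious).

The shipped gastrointestinal reference config overrides the
leaving-home and sleeping duration corners to honor two published
worked fuzzification pairs (4600 s → 0.3 Abnormal− / 0.1 Normal;
30,000 s of sleep → 0.2 Abnormal− / 0.6 Normal — note those ramps are
intentionally non-complementary). With the default output sets
(Low = (0, 0, 0.2, 0.4), High = (0.2, 0.4, 0.6, 0.8), Very high =
(0.6, 0.8, 1, 1)) this calibration reproduces the published worked
day's level 0.19 without further tuning. The published sleeping
example reads "3000 s", which contradicts its own 31,200–40,800 s
normal range; it is adopted as 30,000 s (a dropped zero).

Inference is Mamdani max-min: MIN over AND-joined clause degrees (MAX
over OR), consequent sets clipped at the activation, pointwise-MAX
aggregation, centroid defuzzification on a uniform grid (default 1001
samples; the discrete centroid agrees with adaptive quadrature to
better than 10⁻³). Rules support OR-groups inside an AND rule (and
vice versa) so mixed expert rules are expressible. An all-zero
aggregate (no rule fires) raises instead of inventing a level.

Besides the expert rules, a complete rule base is generated from the
abnormal-state-count guidance (< 2 ⇒ Low, 2–3 ⇒ High, ≥ 4 ⇒ Very
high) by enumerating which subset of variables is abnormal, with an
`Abnormal` clause matching either tail. This is equivalent to
enumerating all per-tail combinations (MIN is monotone and rules
aggregate by MAX) at 2ⁿ instead of 3ⁿ rules. Expert rules can
deliberately override the count guidance: in the reference config a
verbatim High rule fires fully on some heavily abnormal days and pulls
their level below the pure count-based value — that is treated as
intended expert behavior, not a defect.

Category cutpoints are thirds: level < 1/3 ⇒ Low, < 2/3 ⇒ High, else
Very high; alerts map Low → Minor, High → Important, Very high →
Major. These cutpoints are the only thirds-style rule consistent with
every published (level, label) pair in the reference episode.

## Synthetic worlds

The generator draws per-activity start times and durations from
truncated Gaussians (floor 60 s, rounded to whole seconds — sensor
resolution) and toileting counts per 2-hour slot from Poissons;
scenario edits (drop, scale duration, shift start, set toilet count,
housebound) are applied to ground-truth instances and re-emitted as a
CASAS-style log, so parsing and pairing are exercised end to end. The
default routine mirrors the reference config's normal ranges (36,000 s
sleep; three meals totalling 3,960 s; one 11,700 s outing; 11 toilet
visits across the slots), so the DSS fixture and the synthetic resident
describe one world. A mean-schedule overlap check rejects infeasible
specs.

Two regimes are used deliberately:

* **noisy** (realistic SDs: 15–30 min on starts, 2–5 min on most
  durations, 30 min on sleep) — used for parameter recovery: profiling
  30-day baselines recovers generator means within 3 standard errors
  in ≥ 90 % of seeded runs.
* **noiseless** (zero jitter, deterministic toilet counts) — used for
  end-to-end detection scoring. This is a property of min/max-range
  flags, not a convenience: with ranges learned as the min/max of `n`
  baseline days, a *continuously* jittered normal day falls outside
  the learned range with probability ≈ 2/(n+1) per variable regardless
  of how small the jitter is, so day-level accuracy bounds are only
  exact in the noiseless regime. Passing end-to-end tests therefore
  demonstrate correct plumbing and detection logic, not robustness of
  min/max ranges to real behavioral noise — on real data, some
  false-positive anomaly days are expected and the deviation-period
  rule (persistence over ≥ 2 days) is the noise guard.

The end-to-end episode (six days: short then also late sleep, skipped
lunches, housebound days, toileting elevated to 13–16 visits) escalates
to ≥ 4 abnormal states and recovers, producing a level sequence that
rises from Low through High to Very high and back — the qualitative
shape expected of an acute episode.

Default problem sizes (63-day logs, 30-day baselines, 10 detection
seeds, 20 recovery seeds) keep the full suite and the acceptance script
in the low seconds on one CPU while leaving the statistics stable.

## Known limitations

* No per-weekday behavior patterns yet (the `day_of_week` hook exists;
  profiles are currently learned across all days).
* The chronological-order criterion of a day's activity sequence is
  not scored; ordering influences scores only through start-time
  overlap.
* Min/max normal ranges are sample extremes, not tolerance intervals;
  see the noiseless/noisy discussion above.
* Frequency flags for scheduled activities assume integer daily
  counts; fractional "frequencies" are not meaningful.
* The reference disease config is a calibrated illustration for one
  disease; real deployments must configure variables, ranges and rules
  with clinicians.
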