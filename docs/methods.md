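# Methods

This note documents the models, conventions and design choices behind
`dmoval`, in the order the pipeline runs.

## Data model and time conventions

Times are decimal seconds from session start. The two systems sample at
100 Hz and are synchronized to within ±10 ms, so times are stored at
millisecond precision and compared with a 1 ms tolerance (`TIME_TOL_S`).
Both stride tables are assumed to share a clock origin beyond that alignment.

A stride spans two consecutive initial contacts (ICs) of the same foot;
stride intervals are closed at both ends, so per-foot adjacency (one stride's
end equals the next one's start) is legal and marks a continuous chain.
Same-foot strides may touch but not overlap; opposite feet overlap freely.
Stride length may be absent: such records survive I/O and filtering, but any
bout containing one yields no spatial DMOs (walking speed, stride length,
distance) — the bout is flagged, not dropped.

## Stride filtering and bout assembly

Validity criteria: stride duration within **[0.2, 3.0] s inclusive** and
length **≥ 0.15 m** (skipped for length-less strides). Inclusive bounds are a
deliberate reading of "0.2 to 3 seconds"; they are applied with a 1e-9 s
float slack so that durations constructed from decimal times land on the
intended side.

Bout assembly works on the merged two-foot timeline, time-sorted. The gap at
each stride is its start minus the latest end seen so far (overlapping or
touching intervals have gap 0). A break splits the sequence only when the gap
is **strictly greater than 3 s**, so pauses of up to 3 s stay inside a bout
and are included in its duration (last stride end − first stride start).
Runs must contain **at least 2 strides of each foot**; the alternative
reading "≥2 strides total across feet" is a one-line change via
`WBCriteria.min_strides_per_foot`. Strides rejected by filtering are
invisible to assembly and can therefore create breaks.

## Per-bout DMOs

All six DMOs average **per stride**, not totals over duration:
stride duration = mean(dᵢ); cadence = mean(120/dᵢ); stride length =
mean(ℓᵢ); walking speed = mean(ℓᵢ/dᵢ); distance = walking speed × bout
duration. Because bout duration includes pauses while the speed average does
not, distance can exceed the summed stride lengths for pausing walkers — a
property of the definition that the tests assert explicitly rather than
"fix".

Steps are counted as distinct IC events: a contiguous per-foot chain of k
strides contributes k + 1 ICs, so an ordinary bout has (total strides + 2)
steps and a valid bout at least 6. A chain broken by a mid-bout detection
hole contributes an extra IC per fragment; this is the standard IC-counting
convention confined to one function.

Duration bins: < 10 s, 10–30 s, > 30 s. The boundaries 10 s and 30 s are
ambiguous in the usual "<10 / 10–30 / >30" notation; both are assigned to the
**10–30 s** bin, and every report manifest states this. The ">10 s" stratum
is the union of the upper two bins.

## True-positive matching

A device/reference bout pair is eligible when their temporal overlap
**strictly exceeds** 80% of bout duration. "Duration" is read as **both**
durations (the symmetric, strictest convention): this prevents a long bout on
one side from absorbing fragments on the other. The denominator is a config
enum (`both` | `reference_only` | `device_only`) because the literature also
uses one-sided conventions. Pairing is one-to-one, greedy in descending
overlap with deterministic tie-breaks (earlier reference start, then earlier
device start); an exhaustive matcher maximizing (pair count, total overlap)
sits behind the same interface and the test suite proves the greedy result
equal to it on 1000 random instances. Unmatched device bouts are false
positives, unmatched reference bouts false negatives.

## Agreement statistics

ME/MRE/MAE/MARE follow the printed formulas exactly, relative errors in
percent of the reference value (which per-bout DMO construction guarantees
positive). Limits of agreement use mean ± 1.96 × SD with the n−1 SD — the
conventional Bland–Altman form, chosen because the source convention is
unstated. ICC(2,1) is computed from the two-way ANOVA mean squares; its 95%
CI uses the F-distribution bounds with Satterthwaite degrees of freedom
(McGraw–Wong). Identical columns short-circuit to ICC exactly 1.0 — the
ANOVA route would only blur the perfect-agreement limit with float
cancellation. Zero between-subject variance returns a ≤ 0 ICC with a warning
rather than failing, as does n < 5. Qualitative bands: poor < 0.5, moderate
[0.5, 0.75), good [0.75, 0.9], excellent > 0.9; membership of the exact
boundary values is stated in the manifest.

Quantiles (5%/95% summaries, medians, IQRs) use linear interpolation between
order statistics — the convention that reproduces the example cohort's
gait-speed IQR (0.69–0.97) — selectable via `PipelineConfig.quantile_method`.
For odd n the median is the exact middle order statistic; published
characteristic tables of this kind are occasionally internally inconsistent
at the half-step level (the bundled cohort's printed height/weight medians
differ from the middle order statistic by 0.5), so medians are trusted and
the IQR convention is documented rather than reverse-engineered.

## Stratified reporting

Duration strata are keyed on the **reference** bout's duration (the
reference system is ground truth throughout); device-keyed stratification is
available for sensitivity analysis. Participants without an SPPB score stay
in duration strata, drop out of SPPB strata, and are listed in the manifest.
Days-since-surgery and walking-aid effects are reported descriptively
(sorted per-participant median/IQR tables), not tested — with ~11
participants formal inference is not meaningful. Report bundles are written
with fixed column orders and float formatting so identical inputs give
byte-identical files.

## Synthetic cohort generator

The generator's defaults are the study conditions the pipeline is meant for:

* **Cohort** — the bundled 11-participant example cohort (SPPB 3–12, 32–390
  days after surgery); alternatively n synthesized participants, each drawn
  from an index-keyed random stream.
* **Session** — 2.5 h; Poisson(15) bouts per session; inter-bout gaps
  uniform in (4, 40) s, strictly above the 3 s break threshold.
* **Bout durations** — a three-component mixture with shares
  (39.6%, 36.6%, 23.8%): uniform(5.5, 10) s, uniform(10, 30) s, and
  30 s + Exp(40 s) capped at 420 s. The component families are a free
  modelling choice; the shares are the constraint. Because stride counts are
  quantized to the stride-duration grid, the per-foot stride count is
  clamped so each bout's nominal duration stays inside its sampled stratum
  (0.35 s safety margin); without this, bouts near 10 s would migrate
  between strata and systematically distort the mixture.
* **Speeds** — per SPPB group, mean 0.59 (SD 0.17) m/s below the 8-point
  threshold and 0.70 (SD 0.20) m/s at or above it, truncated to
  (0.2, 1.35) m/s. The group SD is split 0.6/0.8 between a per-participant
  baseline and within-participant variation (0.6² + 0.8² = 1), giving
  realistic between-subject structure for the ICC.
* **Cadence** — 65 + 38 × speed steps/min plus N(0, 4²), clamped to
  (55, 130): a modelling choice anchored so 0.65 m/s walks at ≈ 90
  steps/min. Stride duration follows as 120/cadence; stride length as
  speed × stride duration, so every truth stride walks at the bout speed.
* **Gait** — feet alternate strictly (asymmetric gait is a config hook left
  off: no magnitudes to calibrate against); step times vary with CV 3%;
  with probability 0.25 a bout contains one pause uniform in (0.5, 2.8) s.

Error models apply per stride in the fixed order **miss → timing jitter →
length perturbation → spurious insertion → fragmentation**. Jitter perturbs
IC events (not stride endpoints independently) so per-foot chain adjacency —
and hence step counting — survives. Fragmentation assembles the current
stream with default criteria and deletes a 3.5 s stride window inside a bout
with the configured probability, reproducing the split-bout failure mode of
intermittent gait. The default device model (+10% length bias, 15% length
noise CV, 10 ms jitter, 4% miss, 0.0003 Hz spurious, 12% fragmentation) is
chosen to produce error magnitudes typical of lower-back wearables in slow
cohorts; the reference model defaults to error-free.

Determinism: one master seed feeds a `SeedSequence` tree with
per-participant, per-stream children keyed by index, so adding participants
never perturbs existing ones, and identical seed + config give byte-identical
cohorts.

### What the simulator does and does not show

The simulator reproduces the *statistical shape* the pipeline assumes
(bout-duration mixture, group-dependent speeds, pauses, fragmentation), so
passing tests demonstrate correct bookkeeping, error propagation and
statistics. It does **not** model real signal-level failure modes —
speed-dependent detection bias, turning, asymmetric or shuffling gait,
context-dependent errors — and per-stride noise largely averages out within
long bouts, so simulated bout-level ICCs are optimistic relative to real
device performance. Published bout-level reliabilities from real cohorts are
not reproducible from synthetic data and are not targets of the test suite.

## Numerical choices and degenerate inputs

* Boundary comparisons on times use 1e-9 s slack; stride/bout equality uses
  the 1 ms tolerance.
* `error_metrics` on an empty stratum returns absent (None), never zeros;
  the same applies to participant median rows with no pairs.
* A constant paired table yields ICC 0 with a "degenerate" warning.
* Problem sizes: the default simulation uses 11 participants × ~15 bouts
  (~170 matched pairs); the bias-recovery run uses 20 × 30 (~580 pairs); the
  ICC calibration uses 2000 pairs; oracle suites run 1000 random instances
  of ≤ 25 strides / ≤ 8 bouts per side. These sizes give Monte-Carlo
  tolerances comfortably inside the asserted bounds.

## Known limitations

* Greedy matching is provably equal to the optimal assignment only on the
  non-pathological instances tested; adversarial overlap structures could
  differ (the optimal matcher is available behind the same interface).
* The ICC CI uses the standard 95% F-based construction; published tables
  in this field sometimes print uncertainty columns of unstated
  construction, which are not reverse-engineered.
* Walking-aid flags in the bundled cohort are a synthetic assumption (two
  users are known to exist, their identities are not).
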