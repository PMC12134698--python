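# dmoval — validating real-world digital mobility outcomes

`dmoval` is a Python package for validating **digital mobility outcomes
(DMOs)** — gait parameters estimated from wearable sensors during daily life —
against a concurrent reference system. It targets the setting of slow,
intermittent walkers such as older adults recovering from hip fracture, where
walking happens in many short bouts and algorithm accuracy degrades.

Given stride-level detections (initial-contact times and stride lengths) from
two systems worn simultaneously — a single lower-back **device** and a
multisensor **reference** — the package:

1. **filters strides** by validity criteria (duration in [0.2, 3.0] s,
   length ≥ 0.15 m);
2. **assembles walking bouts** (WBs): maximal stride runs with merged-timeline
   gaps ≤ 3 s and at least 2 strides of each foot; intra-bout pauses of up to
   3 s stay inside a bout;
3. **computes six per-bout DMOs** as averages over member strides: walking
   speed (m/s), cadence (steps/min, 120 / stride duration per stride), stride
   length (m), stride duration (s), number of steps, and distance
   (= mean speed × bout duration);
4. **matches bouts across systems** as true positives when temporal overlap
   strictly exceeds 80% of both bouts' durations (one-to-one, greedy by
   overlap, with an exact optimal matcher available for cross-checking);
5. **summarizes agreement** per DMO and stratum.

## Agreement statistics

With device value $d_i$ and reference value $r_i$ over $n$ matched bouts:

$$\mathrm{ME} = \tfrac1n\sum_i (d_i - r_i), \qquad
  \mathrm{MRE} = \tfrac{100}{n}\sum_i \frac{d_i - r_i}{r_i}$$

$$\mathrm{MAE} = \tfrac1n\sum_i |d_i - r_i|, \qquad
  \mathrm{MARE} = \tfrac{100}{n}\sum_i \frac{|d_i - r_i|}{r_i}$$

with Bland–Altman 95% limits of agreement ($\bar e \pm 1.96\,s_e$) around ME
and MRE. Reliability is ICC(2,1) — two-way random effects, absolute
agreement, single measures:

$$\mathrm{ICC}(2,1) = \frac{MS_R - MS_E}{MS_R + (k-1)MS_E + \tfrac{k}{n}(MS_C - MS_E)}$$

with an F-based 95% CI and qualitative bands: poor < 0.5 ≤ moderate < 0.75 ≤
good ≤ 0.9 < excellent.

Results are stratified by bout duration (all, >10 s, 10–30 s, >30 s, keyed on
the reference bout) and by physical function (SPPB < 8 vs ≥ 8), with
per-participant median (IQR) summaries sorted by days since surgery.

Because raw paired-sensor recordings of this kind are rarely shareable, the
package includes a **synthetic gait simulator** that generates truth, device
and reference stride streams for 2.5 h free-living sessions with known ground
truth — many short bouts, SPPB-dependent speeds, speed-coupled cadence,
intra-bout pauses — and configurable device error (length bias/noise, timing
jitter, missed/spurious strides, bout fragmentation), enabling
parameter-recovery testing of the whole pipeline.

## Worked example

```python
from dmoval import CohortConfig, simulate_cohort, run_validation

cohort = simulate_cohort(CohortConfig(), seed=1)   # bundled 11-person cohort
report = run_validation(cohort.device_sessions, cohort.reference_sessions,
                        cohort.metas, seed=1)
print("matched pairs:", report.manifest["n_matched_pairs"])
t = report.agreement_duration
print(t[t.stratum == "all"][["dmo", "n", "mre_pct", "mare_pct", "icc"]].round(2))
```

prints (default device error model: +10% stride-length bias, 15% length
noise, 10 ms timing jitter, 4% missed strides, 12% bout fragmentation):

```
matched pairs: 173
stratum               dmo   n  mre_pct  mare_pct  icc icc_level
    all walking_speed_mps 173    10.12     10.21 0.94 excellent
    all       cadence_spm 173     0.04      0.12 1.00 excellent
    all   stride_length_m 173    10.07     10.16 0.91 excellent
    all           n_steps 173    -1.21      1.21 1.00 excellent
    all stride_duration_s 173    -0.03      0.12 1.00 excellent
    all        distance_m 173     9.26      9.72 0.99 excellent
```

The injected +10% stride-length bias resurfaces as ≈10% mean relative error
in stride length and walking speed (length errors propagate one-to-one into
speed), ≈9.3% in distance, and ≈0% in the purely temporal DMOs — exactly the
error-propagation pattern the pipeline is designed to expose. `report.write(
outdir)` saves the full bundle (bout counts, agreement tables, participant
summaries, JSON manifest) deterministically.

The same workflow is available from the shell:

```bash
dmoval simulate --out sim --seed 5
dmoval validate --device sim/device_strides.csv \
                --reference sim/reference_strides.csv \
                --participants sim/participants.csv --out report
```

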