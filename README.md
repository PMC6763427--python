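# eicapvt

Event-related group ICA (eICA) of psychomotor vigilance task (PVT) fMRI:
a tested, reusable implementation of the full analysis chain — finite
impulse response (FIR) deconvolution split by reaction-time class, group
spatial ICA with GICA back-reconstruction, and windowed polynomial
time-course inference with a two-level residual bootstrap — exercised
end to end on synthetic 4D image data with known ground truth.

## The problem

The PVT is the workhorse test of sustained attention: a millisecond
counter appears at random inter-stimulus intervals (ISIs of 3–11 s, each
of the eight values once per set of eight trials, 14 sets = 112 stimuli
per ~13-minute run) and the subject presses a button as fast as
possible.  Responses slower than 500 ms are *lapses* — attention
failures that become more frequent when sleep is restricted.  The
question this pipeline addresses: which brain networks respond to each
stimulus, how does the response differ between lapses and normal
responses (200–450 ms), and does time in bed (short sleep vs healthy
sleep, SS vs HS) modulate either?

Because lapses are sparse and irregular, the analysis avoids assuming a
response shape.  Instead it:

1. **Deconvolves** each session voxel-wise with an FIR model: 24 free
   parameters per RT class at one per TR (2 s), spanning 16 s *before*
   each stimulus to 32 s after — 48 event parameters per session, plus
   nuisance regressors (spurious < 200 ms and ambiguous 450–500 ms
   responses as their own FIR blocks, six motion parameters, one-hot
   flags for artifact volumes, intercept and linear drift).
2. **Stacks** the 48 parameter maps of every dataset (two per subject:
   SS and HS) as a pseudo time series, reduces them with two PCA stages,
   and unmixes with **Infomax ICA** into spatially independent group
   components.  GICA back-reconstruction yields a per-dataset spatial
   map and a 48-point component time course (24 points per RT class).
3. **Quantifies** each component time course in windows: a line over the
   pre-stimulus period (slope, intercept at t = 0), a cubic over the
   early post-stimulus period (0–16 s) from which the **first peak's
   height and latency** are extracted (trough for task-negative,
   default-mode-like components).  Parameter uncertainty comes from a
   1000-rep residual bootstrap; per subject, a 2 × 2 (RT class × sleep)
   effect-coded ANOVA is bootstrapped over the cell distributions; the
   per-subject mean coefficients are tested across subjects with a
   one-sided Wilcoxon signed-rank test (significant p < 0.005, trending
   0.005–0.05).

A behavioral module implements the RT classification and the adherence
filters (> 75 lapses → task non-adherence; < 0.5 h mean sleep-period
difference between conditions → sleep non-adherence), performance
summaries, a mixed sleep × setting ANOVA with partial η², and the
1/RT-vs-ISI regression.  A synthetic-data module generates complete
cohorts — schedules, RT streams with condition-dependent lapse
probability, and 4D NIfTI sessions containing spatially fixed networks
with class/condition-dependent amplitude, latency and pre-stimulus
drift, plus noise, motion and injectable artifact volumes — so every
stage can be validated against an injected truth.

## Worked example

Run the full synthetic demo (8 subjects × 2 conditions, 4 embedded
networks on a 16 × 16 × 12 grid, 200 bootstrap reps) from Python:

```python
import numpy as np
from eicapvt import RunConfig, run_pipeline
from eicapvt.ica import match_components
from eicapvt.timecourse import format_results_table

cfg = RunConfig(n_subjects=8, n_boot=200, seed=1)
manifest, art = run_pipeline(cfg, outdir="demo")

truth = np.stack([n.spatial_map.reshape(-1)[art.model.mask_]
                  for n in art.networks])
assign, corrs = match_components(art.model.group_maps_, truth)
for net, comp, r in zip(art.networks, assign, corrs):
    print(f"{net.name:15s} -> component {comp}  spatial r = {r:.3f}")
print(format_results_table(art.results).to_string())
```

prints (about 10 s on one CPU):

```
frontoparietal  -> component 7  spatial r = 0.896
default_mode    -> component 3  spatial r = 0.907
sensorimotor    -> component 2  spatial r = 0.967
visual          -> component 0  spatial r = 0.953

                        rt_class      sleep interaction
component parameter
0         peak_height   0.00391*   0.00391*    0.00391*
          peak_latency  0.00391*         ns          ns
2         peak_height   0.00391*         ns   (0.00781)
          peak_latency  (0.0391)         ns          ns
3         peak_height   0.00391*   0.00391*    0.00391*
          peak_latency  0.00391*         ns          ns
7         peak_height   0.00391*   0.00391*    0.00391*
          peak_latency  0.00391*         ns          ns
```

Reading this: component selection retained exactly the four embedded
networks (each matched to its ground-truth map with spatial r ≈ 0.9 or
better).  The generator injects a larger, delayed response to lapses in
every network, and the `rt_class` column recovers it as a significant
peak-height (and mostly peak-latency) effect in every retained
component; 0.00391 = 2⁻⁸ is the smallest one-sided signed-rank p
attainable with eight subjects.  Starred entries are significant at the
p < 0.005 threshold, parenthesized entries are trending (0.005–0.05),
`ns` is neither.

The same run is available from a shell:

```bash
eicapvt all --out demo --seed 1
```

which writes events tables, a QA report, per-dataset component time
courses, the p-value tables and one mean-time-course figure (with
standard-error bars, split by condition and RT class) per retained
component.

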