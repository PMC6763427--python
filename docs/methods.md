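# Methods

This note documents the models, conventions and numerical choices the
package makes, what the synthetic generator does and does not emulate,
and the known limitations.

## Task model and reaction-time classes

A PVT session presents 112 stimuli: 14 consecutive sets, each a random
permutation of the eight ISIs {3, 4, 5, 6, 8, 9, 10, 11} s (784 s of
ISI time in total, ~13 min).  Response feedback is shown for 500 ms.
The generator spaces onsets as ISI + previous RT + feedback by default;
whether the feedback interval counts inside or outside the ISI differs
between task implementations, so `isi_includes_feedback` switches the
convention.  Responses above 2.4 s trigger the alarm and are truncated
there.

Reaction times partition into four classes: spurious (< 200 ms), normal
(200–450 ms, both ends inclusive), ambiguous (450–500 ms, 500
inclusive) and lapse (> 500 ms).  The published bounds are ambiguous at
the boundary points; the conventions here were chosen so the classes
partition the RT axis exactly, and timeout trials count as lapses.
Task non-adherence is a strict > 75 lapses per session; sleep
non-adherence is a strict < 0.5 h mean nightly sleep-period difference
between conditions.

## Synthetic data: what it emulates

The generator's defaults are the study conditions:

* **RT model** — a shifted-lognormal mixture per condition.  The fast
  component has median 376.8 ms (SS) / 371.6 ms (HS) with `spread_ms`
  = 50 (≈ sd of the fast component); the explicit lapse component sits
  entirely above 500 ms with weight 0.13 (SS) / 0.10 (HS), matching
  ~15 and ~11 lapses per 112 trials.  The distribution family is a
  package choice (none is published); the mixture makes the lapse
  probability an explicit dial, and `effective_lapse_prob` gives the
  closed-form P(RT > 500 ms) including the fast component's tail.  An
  optional `isi_speed_slope` adds a linear preparation benefit of long
  ISIs in the speed (1/RT) domain.
* **Images** — default 16 × 16 × 12 voxel grid, TR 2 s, baseline 100,
  white Gaussian noise sd 0.5 (0.5% of baseline; AR(1) optional),
  random-walk motion parameters, and injectable artifact volumes that
  receive both a sustained 4-mm motion jump and a global intensity
  spike.  The grid is small so the full pipeline runs in seconds to
  minutes on one CPU; dimensions are configurable.
* **Networks** — four multi-nodal Gaussian-blob networks: three
  task-positive (fronto-parietal-, sensorimotor- and visual-like) and
  one task-negative (default-mode-like, negative amplitude).  Responses
  are double-gamma curves (unit peak, so amplitudes read as peak signal
  change) and the networks deliberately differ in peak delay (4–7.5 s),
  dispersion, undershoot depth and pre-stimulus trend.  This temporal
  diversity is not cosmetic: spatial sources whose time courses are
  collinear at the noise level are unidentifiable by *any*
  decomposition (their data reduce to a single term), and real networks
  do differ temporally.  The injected effects are the phenomenology the
  method targets: lapses evoke 1.5–1.8 × the normal amplitude with a
  delayed peak, and the normal-response amplitude is attenuated by 0.85
  under short sleep.
* A `support_s` option truncates the response to a finite window; with
  support inside the FIR span the noiseless evoked signal is exactly
  representable by the FIR basis, which the exact-recovery tests use.
  The default keeps the full tail (order 1e-4 of peak beyond +32 s).

Not emulated: scanner physics, susceptibility and slice-timing effects,
anatomy, physiological noise, spatial noise correlation, and
inter-subject spatial variability (maps are identical across subjects).
Passing tests therefore demonstrate the correctness and calibration of
the *pipeline*, not its robustness to registration error or
between-subject map variability.

Seeding: one master seed fans out via `numpy.random.SeedSequence` into
named substreams (schedule, rt, noise, motion) per session, so any
component can be reproduced in isolation.

## Quality assurance

A volume is an outlier if volume-to-volume composite motion exceeds
3 mm or the global-intensity change has |z| > 3 relative to the series
of adjacent-volume differences.  Composite motion is computed as the
maximum displacement of the six axis points on a 65-mm-radius reference
sphere under the change in rigid-body transform — the convention of the
standard automated artifact-detection toolbox, whose exact formula is
not published; it is a convention here, not a specification.  Motion
files carry translations in mm and rotations in radians.  Flagged
volumes become one-hot nuisance regressors (scrubbing by regression).
Whole-session rejection, done visually in practice, is operationalized
as a threshold on the flagged fraction (default 20%).

## FIR deconvolution

24 half-open 2-s bins per RT class with left edges −16, −14, …, +30 s.
The stated span (−16 to +32 s with 24 points) has a one-bin ambiguity
(25 edges); left-edge half-open binning is asserted everywhere, so each
scan time in a window belongs to exactly one bin and the window end
(+32 s) is excluded.  Events are assigned to bins by scan-time
membership without interpolating onsets to the TR grid; overlapping
windows superpose additively, which is what lets OLS average over
events.  Intercept and linear drift columns are included per session
(the source protocol is silent; this is standard practice), and no
autocorrelation modeling is applied.  All-zero columns (an absent
class) are dropped from the solve and returned as zero maps with a
warning.  Rank deficiency raises an error naming the collinear columns;
an optional ridge fallback (λ = 1e-6 × mean Gram diagonal) can be
enabled explicitly.  The design condition number is recorded.

## Group eICA

Each session's 48 maps form a pseudo time series.  Stage-1 reduction
removes the mean image and projects onto the top `dataset_dims`
(default 30) temporal principal directions *without whitening* —
whitening at this stage would raise every retained noise direction to
the variance of the signal directions and, for a group of one, make the
group stage uninformative.  Stage 2 reduces and whitens the
concatenated datasets to `n_components` (default 20, the study-scale
setting) dimensions for the ICA.

Infomax is implemented natively (it is the named algorithm, and
determinism under a seed is required): natural-gradient ascent with the
logistic nonlinearity in shuffled mini-batches, learning-rate annealing
when the update direction turns by more than 60°, a restart at half the
rate on divergence, and convergence when the per-pass weight change
falls below 1e-7.  The logistic nonlinearity matches the
super-Gaussian (sparse) statistics of spatial brain maps.

Back-reconstruction follows the GICA projection: the per-dataset time
course is `basis_i @ pinv(G)_i @ A` (48 × components) and the
per-dataset map is the ICA unmixing applied to the dataset's
group-reduced, voxel-centered data.  Components are sign-fixed so the
voxel of maximum |weight| in the group map is positive, with the
mixing column, per-dataset maps and time courses flipped jointly
(products invariant).  Dual-regression back-reconstruction is not the
default and is not implemented; the GICA projection is the approach the
pipeline standardizes on.

Mean back-reconstructed maps are z-scored over the mask and thresholded
at z > 1.5.  Component selection replaces visual judgment with two
quantitative rules: rejection when the thresholded support overlaps the
periphery/ventricle (rim) mask by more than 25%, or when the temporal
consistency score — the mean over post-stimulus bins of |mean| / SEM
across datasets — falls below 1.0.  Manual overrides are honored and
logged.  In tests, estimated components are matched to ground-truth
maps by Hungarian assignment on |spatial correlation|.

## Time-course statistics

Each 24-bin class curve splits into pre-stimulus (t < 0; 8 bins), early
post-stimulus (0 ≤ t ≤ 16 s; 9 bins, the t = 0 bin is post) and late
post-stimulus (t > 16 s; 7 bins).  The late window is segmented and
exportable but not analyzed — its content is dominated by carryover
from subsequent events.  The pre window gets a least-squares line with
the intercept evaluated at t = 0 (stimulus-time extrapolation; the
alternative, t = −16, is a pure reparameterization).  The early window
gets a cubic; a dual-gamma fit was considered and rejected because the
back-reconstructed curves are sometimes bi-phasic.

The first peak is the earliest interior stationary point of the cubic
in (0, 16) whose curvature matches the component's dominant response
sign — a maximum for task-positive components, a minimum for
task-negative ones.  The dominant sign is taken from the group-mean
early curve as the direction of its largest excursion from the
stimulus-time value, computed on the raw binned curve (a cubic smooths
narrow peaks down while exaggerating edge undershoots, which inverts
the decision for fast sensorimotor-like responses).  When no interior
extremum of the right curvature exists, the window-end value is
returned and flagged; excluding such cells instead is available by
configuration.

Uncertainty propagates in two bootstrap levels (1000 reps each by
default, configurable; the end-to-end demo uses 200):

1. **Residual bootstrap per fit** — replicates refit `fitted +
   resample(residuals)`.  Residuals are rescaled by √(n/(n−p)) so the
   bootstrap parameter sd is unbiased for the analytic OLS sd; at these
   window sizes (8–9 points) the raw-residual bootstrap would
   underestimate it by ~13%.
2. **Per-subject 2 × 2 bootstrap ANOVA** — each replicate draws one
   value per (RT class × sleep) cell and computes effect-coded
   coefficients (lapse and SS on the positive poles; main effects are
   differences of marginal means over 2, the interaction the difference
   of differences over 4).  One index stream is shared across the four
   independent cells, which preserves the marginals and makes label
   swaps permute draws with the data.

The per-subject coefficient entered into the group test is the mean of
its bootstrap distribution (point-fit coefficients are also available).
Group inference is a one-sided Wilcoxon signed-rank test against zero
with fixed thresholds: p < 0.005 significant (adjusted for assessment
across multiple components), 0.005–0.05 trending; no FDR.  The test
direction is configurable: `auto` uses the sign of the group mean,
which is convenient for exploration but roughly doubles the effective
one-sided type-I error (the tail is chosen from the data); calibration
checks and confirmatory use should fix the direction a priori.  With
eight subjects the smallest attainable one-sided p is 2⁻⁸ ≈ 0.0039,
just under the significance threshold — effects must be consistent in
every subject to clear it at demo scale.

## Behavioral statistics

The mixed sleep (within) × setting (between) ANOVA is computed directly
from sums of squares — the between stratum tested against subjects
within groups, the within stratum against the sleep × subject
interaction — with partial η² = SS_effect / (SS_effect + SS_error) per
stratum; it is cross-checked against an independent mixed-ANOVA
implementation in the tests.  Both median and mean RT are computed
(summaries report both; the factorial model takes whichever column is
passed).  The ISI regression fits 1/RT (1/s) on ISI (s) by OLS.  The
short-ISI sensitivity variant (trials with 3–4-s ISIs relegated to a
nuisance FIR block) is a configuration flag that reuses the covariate
mechanism; it is supported but not separately validated.

## Problem sizes and determinism

The packaged demo and the acceptance script use a cohort of 8 subjects
× 2 conditions with 4 networks on a 16 × 16 × 12 grid, 8 ICA components
and 200 bootstrap reps — sizes chosen so a full run takes ~10 s while
every stage retains its study-scale structure (the 20-component /
66-dataset configuration remains the estimator default and is exercised
as structural arithmetic).  Statistical calibration uses 100 null
cohorts at 200 reps; power checks use 50 cohorts of 32 subjects.  All
randomness flows from explicit seeds; identical configurations
reproduce identical stage checksums in the run manifest.

## Known limitations

* Subject spatial maps are identical in the generator, so
  back-reconstruction variability across subjects reflects noise only.
* FIR bins assume the TR grid samples each event window densely; very
  short sessions with few events per class produce noisy lapse maps
  (the lapse class has ~10× fewer events than the normal class, as in
  real data).
* The composite-motion formula and the GIFT-internal scaling choices
  are conventions, not published definitions; absolute component
  amplitudes are therefore arbitrary units, and only comparisons across
  cells/conditions are meaningful.
* The `auto` sign-rank direction is exploratory (see above).
* No autocorrelation modeling in the FIR stage; with TR 2 s and
  parameter averaging over ~100 events the impact on point estimates is
  nil and on bootstrap variances small, but single-session inferences
  should not be read from this pipeline.
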