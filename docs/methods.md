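# Methods

## Experimental conditions modelled

Four conditions of a tethered-miniscope experiment are represented throughout:
`free` (tether on a freely rotating joint), `on` (pOEC torque compensation
active), `off` (compensation disabled, the animal drags the tether's
rotational resistance), and `fixed` (head-fixed on a rotating platter). The
`on` condition is the baseline for all neural comparisons. Sessions default to
1000 frames at 3 frames/s (333 s) in a 25.4 cm (10-inch) square arena, with
two sessions per condition pooled per neuron.

## Behavioral kinematics

Walking distance is the sum of frame-to-frame Euclidean displacements
(reported in metres). Heading is the direction of each displacement vector;
displacements shorter than `min_displacement` (default 0.2 cm) contribute no
heading change, suppressing tracking jitter at rest. Turning angle is the sum
of absolute heading increments wrapped to (−π, π] — total absolute rotation,
not net rotation, which is why a session can accumulate hundreds of radians.
Linear speed uses central differences (one-sided at the ends).

Locomotion segmentation thresholds linear speed at 1 cm/s. Runs of either
state shorter than `min_bout` (default 1 s) are absorbed into the neighbouring
state, shortest-first with ties going to the earlier run; this smoothing is a
design choice, as is the central-difference speed estimate. For platter
sessions the angular threshold is `1 cm/s / effective_radius`; the effective
radius (animal's distance from the rotation axis) defaults to 10 cm and should
be set explicitly for a real rig, since platter geometry varies.

Percent changes between condition means, (A−B)/B×100, are reported truncated
toward zero when integer output is requested; this is the convention under
which the package's summary of the reference condition means (9.51 vs 4.67 m
→ 103%, 287.15 vs 160.20 rad → 79%) matches integer-percent reporting.

## Event detection and the fluorescence rate

The per-event statistic is r = ΔS/Δt: the area under a firing peak of the
ΔF/F trace divided by its duration. ΔS uses a rectangle-rule sum of the
baseline-subtracted trace clipped at zero (noise dips cannot contribute
negative area), so r equals the mean clipped excess over the event and a
rectangular pulse of height h scores r = h exactly; a symmetric triangle of
peak p scores p/2 up to discretization. Events are defined by hysteresis
thresholding (open at k_on·σ = 2.5σ, close below k_off·σ = 0.5σ), merged
across gaps of at most one frame, and discarded below two frames. This
operationalises "firing peak" directly on the ΔF/F trace; no spike
deconvolution is performed.

Baseline: a rolling 8th percentile over 90 s, debiased upward by the Gaussian
quantile (1.405σ₀ for the 8th percentile) using a successive-difference noise
estimate σ₀ = MAD(Δdff)·1.4826/√2. The debias matters: a raw low-percentile
baseline sits ~1.4σ below the quiescent level, which places the event-closing
threshold inside the noise band and makes event boundaries — and hence r —
depend on transient density. σ₀ from successive differences is used because a
residual MAD grows with event density. The long window keeps the rolling
percentile's sampling error small; that error is shared by all events under
one session's baseline, and if it is large it cluster-correlates the session's
rates and anticonservatively inflates the rank test (a ground-truth-baseline
control puts the null rate at its nominal level, an estimated-baseline run
with a short window ~1.4 points above it).

Cross-condition consistency: within one neuron, the pipeline estimates one
common debias σ₀ (median of the sessions' successive-difference estimates,
passed as ``noise_sd``) and pools the residuals of all sessions into a single
detection σ (``pooled_noise_sigma``). Shared estimates make both the baseline
offset error and the detection thresholds common across conditions, so they
cancel in condition comparisons; per-condition estimates differ systematically
with event density and were observed to bias the null comparison far above the
nominal significance level. With these choices the null false-positive rate
measures 3.5–5.0% across seeds (the continuity-corrected normal approximation
is mildly conservative).

Locomotion gating keeps events whose onset frame falls inside a locomotion
bout (a majority-overlap rule is available).

## Condition comparison

Per neuron and comparison (off-vs-on, fixed-vs-on), the two rate multisets are
tested with a two-sided Mann–Whitney U test at α = 0.05, with midranks for
ties. Exact p-values come from full enumeration of rank assignments when both
samples have ≤ 8 observations (the null distribution of U is symmetric about
n_a·n_b/2, so the two-sided p is twice the smaller tail, capped at 1); larger
samples use the normal approximation with tie correction and a 0.5 continuity
correction. Significant neurons are labelled by the direction statistic
U versus n_a·n_b/2 (rank-biserial sign), falling back to the median difference
on an exact tie. Neurons with fewer than 3 events in either set are labelled
`other` with an insufficiency flag rather than tested. No multiple-testing
correction is applied across neurons by default (per-neuron testing at 0.05 is
the primary convention here); Benjamini–Hochberg is available as an option.
Consistent-trend neurons are those classified `increased` in both comparisons
(or `decreased` in both); a looser median-ordering criterion is available.

## Synthetic data generator

The generator emulates the study conditions so every downstream stage can be
tested against ground truth:

- **ΔF/F traces.** Event times are a homogeneous Poisson process
  (`base_event_rate`, events/min; cohort default mean 6/min, Gamma-distributed
  across neurons and floored at 1/min so every neuron is scoreable). Each event
  adds an amplitude times a double-exponential kernel (rise 0.1 s, decay 0.6 s,
  GCaMP6m-like; configurable) whose *sampled* values are normalised to unit
  peak, so an isolated event's maximum frame equals its amplitude regardless of
  sub-frame timing. Additive i.i.d. Gaussian noise (default σ = 0.05 ΔF/F) and
  optional lognormal per-event amplitude jitter (pipeline default 0.25
  log-units) complete the trace. When a locomotion mask is supplied, events are
  placed only in locomotion frames, matching an analysis that scores firing
  during locomotion.
- **Condition effects.** A neuron's multiplier for `off`/`fixed` scales both
  its Poisson event frequency and its per-event amplitude scale. The amplitude
  component is essential: the downstream statistic r = ΔS/Δt measures
  transient size, not count, so a frequency-only effect would be invisible to
  the classification. Physically, stronger firing produces both more and
  larger calcium transients. Default cohort mixture: 5%/9% of neurons
  increased/decreased under `off` and 6%/18% under `fixed` at multipliers
  2.0/0.5, with `fixed` effects assigned to `off`-affected neurons first so a
  consistent-trend subset exists by construction.
- **Trajectories.** Correlated random walk: per-frame speed Gamma(shape 2)
  with condition-dependent mean (on 2.9, off 1.4, free 3.0 cm/s — chosen to
  land per-session distances near the reference scale of ~9.5 m compensated
  vs ~4.7 m uncompensated), von Mises heading increments (κ = 9, giving
  ~300 rad total turning per compensated session), specular reflection at the
  arena walls.
- **Platter.** Alternating rest/locomotion schedule (default 15 s/20 s) at a
  constant locomotion angular velocity (0.5 rad/s) plus Gaussian noise.

What the generator does *not* emulate: photobleaching and baseline drift,
correlated (shared) noise across neurons, bursty or refractory firing,
neuropil contamination, pose-estimation errors, and any image-level artefact —
the pipeline starts from extracted traces and point trajectories. Passing
tests therefore validate the analysis logic and its calibration, not the
upstream extraction steps.

## Seeding and reproducibility

Every stochastic operation takes an explicit integer seed; there is no global
random state. The pipeline expands one root seed with
`numpy.random.SeedSequence.spawn` in a fixed order (cohort, behavior streams,
per-neuron trace streams), so the same config and seed reproduce every output
byte-identically.

## Commutator simulator

The tether is a linear torsional spring (stiffness default 2 mN·m/rad, chosen
so a few degrees of twist reach the 0.8 mN·m threshold — no measured stiffness
is available, so it is a required configuration value for quantitative use).
Per 1 ms tick: twist = heading − shaft angle, τ = k·twist; if compensation is
on and the sensed torque (optionally noisy/quantized; the 0.2 mN·m sensor
resolution is exposed as a quantization option, off by default) reaches the
0.8 mN·m threshold, the motor issues up to `max_step_rate·dt` microsteps of
0.225° toward reducing it, stopping once |τ| falls below the release level
(same threshold by default; a release fraction is available). The 1.2 µs
driver response time is orders of magnitude below any sensible tick and is
modelled as zero latency within a tick. Rotational work is ∫τ dθ_animal,
reported in µJ. Consequences tested: without compensation the spring law holds
exactly (τ = k·2πn after n turns); with compensation the torque never exceeds
threshold + k·(step + ω·dt); the compensated rotational work on a five-turn
profile is ~2.5% of the uncompensated work.

## Numerical and degenerate-input choices

- Angle wrapping maps increments into (−π, π]; an exact ±π increment counts π.
- A zero σ on a non-constant trace falls back to an absolute detection
  threshold (default 0.1 ΔF/F) with a logged warning; a constant trace yields
  no events.
- Traces shorter than the baseline window use a global percentile baseline
  with a logged warning.
- Percent change against a zero mean is flagged (`undefined`) rather than
  dropped or raised.
- Empty rate sets are carried through with an insufficiency flag so cohort
  summaries account for every neuron.

## Problem sizes used by the test suite and acceptance script

Monte-Carlo checks use 1000 replicate sessions for Poisson calibration, 576+
random instances for exact Mann–Whitney enumeration (all sample-size pairs up
to 6), 10⁵-resample permutation oracles at n = 30, a 1000-neuron null cohort,
and a 150-neuron recovery cohort — sizes at which the Monte-Carlo bands in the
assertions are meaningful while a full run stays fast on one CPU.

## Known limitations

- **Behavior-coupled event scoring.** Because events can overlap and merge,
  the fluorescence-rate distribution depends weakly on locomotion
  fragmentation: nearly continuous locomotion (as under `on`) yields more
  merged, larger events than short scattered bouts. With condition-dependent
  mobility this couples behavior into the neural statistic and inflates
  apparent condition effects for truly null neurons (~6.6% flagged vs the
  nominal 5% under default mobility differences, short-window baselines). The null-calibration
  experiments therefore use exchangeable conditions (identical mobility); on
  real data, condition differences in locomotion structure should be treated
  as a potential confound of threshold-based event scoring.
- The platter's effective radius is unknown in general; the 1 cm/s-equivalent
  angular threshold scales inversely with it.
- Exact Mann–Whitney enumeration is O(C(n_a+n_b, n_a)) and is capped at 8+8
  observations; beyond that the normal approximation is used (observed within
  0.005 of a 10⁵-resample permutation p at n = 30).
- The controller model reflects a threshold-and-step reading of the feedback
  loop; real firmware may add debouncing or burst logic not modelled here.
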