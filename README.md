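# poeclab

Analysis toolkit for studying how the rotational resistance of a head-mounted
two-photon fiberscope tether affects behavior and motor-cortex calcium activity
in mice, together with a closed-loop simulator of a proactive
optoelectrical commutator (pOEC) — a rotary joint that senses torque building in
the tether and rotates the fiberscope to cancel it before the animal feels
resistance.

It is aimed at researchers running tethered-miniscope experiments who want to
quantify, on their own recordings or on fully synthetic ground-truth data, what
a tether does to an animal's movement and to its neurons' activity.

## What it computes

**Behavior.** Open-field sessions (2-D point trajectories in a square arena)
are summarised by walking distance, total absolute turning angle
(Σ|Δheading|, headings from displacement vectors, increments wrapped to
(−π, π]), and per-frame linear/angular speed. Locomotion and rest are
segmented by a 1 cm/s linear-speed threshold; for head-fixed sessions on a
rotating platter the threshold is applied to the platter's angular velocity as
ω ≥ v_th / r_eff.

**Calcium activity.** For each neuron's ΔF/F trace, firing events are detected
by hysteresis thresholding of the baseline-subtracted trace, and each event is
scored by the *fluorescence rate*

    r = ΔS / Δt

— the area under the firing peak divided by its duration (so a rectangular
pulse of height *h* scores exactly *r = h*). Events are gated to locomotion
periods, and each neuron's rates under one condition form a multiset
R (R_on, R_off, R_fixed).

**Condition comparison.** Per neuron, rate sets are compared with a two-sided
Mann–Whitney U test (midranks for ties; exact by full enumeration for small
samples, tie/continuity-corrected normal approximation otherwise) at α = 0.05.
Significant neurons are labelled *increased* or *decreased* by the direction of
the shift relative to the torque-compensated baseline; neurons shifted the same
way in both off-vs-on and fixed-vs-on are *consistent-trend* neurons.

**Commutator simulation.** The tether is a linear torsional spring between the
animal's heading and the commutator shaft. Each tick, if the sensed torque
reaches the threshold (0.8 mN·m default), the stepper motor issues 0.225°
microsteps until the torque drops back below threshold. With compensation off
the shaft is frozen and the spring law τ = k·Δθ applies.

**Synthetic data.** A first-class generator produces all three input kinds with
known ground truth: GCaMP6m-like ΔF/F traces (double-exponential kernel,
Poisson event times, condition-effect multipliers), correlated-random-walk
arena trajectories with reflecting walls, and platter angular-velocity traces.

## Worked example

Run the full synthetic pipeline (150 neurons, two 1000-frame sessions at
3 fps per condition):

```python
from poeclab.pipeline import RunConfig, run_pipeline

summary = run_pipeline(RunConfig(seed=7, out_dir="demo_run",
                                 synthetic=dict(n_neurons=150)))
```

This writes session/event/classification CSVs, figures, and `summary.json`.
With seed 7 it prints condition means of 9.61 m (on) vs 4.47 m (off) walking
distance — a +115% change when compensation is enabled, the same direction and
scale as the ~+103% reported for real tethered mice — and per-neuron
proportions such as:

```
off_vs_on:   5.3% increased, 12.7% decreased, 82.0% other
fixed_vs_on: 7.3% increased, 18.7% decreased, 74.0% other
```

i.e. more neurons change their firing when the animal is head-fixed than when
it merely drags an uncompensated tether, with decreases dominating — the
pattern the generator's defaults encode. Of 150 neurons, 8 were consistent-up
and 13 consistent-down across both comparisons.

The commutator simulator, from the command line:

```
poeclab poec-sim --out-dir poec_demo --turns 5 --turn-rate 0.5
{"total_steps": 7899, ..., "max_abs_torque_mNm": 0.806, "rotational_work_uJ": 25057.0, ...}
{"total_steps": 0,    ..., "max_abs_torque_mNm": 62.83, "rotational_work_uJ": 987059.1, ...}
```

After five full turns the uncompensated tether has wound up to
τ = k·10π ≈ 62.8 mN·m, while the compensated run never exceeds one microstep
above the 0.8 mN·m trigger threshold and costs the animal ~2.5% of the
rotational work.

Other subcommands: `simulate-data`, `behavior`, `detect-events`, `compare`,
`report` (see `poeclab --help`).

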