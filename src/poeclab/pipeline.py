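"""End-to-end pipeline: synthetic cohort -> behavior -> events -> comparison.

All stage parameters live in a validated :class:`RunConfig` (unknown keys are
rejected).  One root seed drives every stage: it is expanded with
``numpy.random.SeedSequence(seed).spawn(...)`` in a fixed documented order
(cohort, trajectories, platter, traces), so a run is bit-reproducible from its
config alone.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import behavior as bhv
from . import compare as cmp
from . import events as evt
from . import plots
from . import synthetic as syn

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "load_config", "save_config"]


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SyntheticStage(_StrictModel):
    n_neurons: int = 150
    n_sessions_per_condition: int = 2
    n_frames: int = 1000
    frame_rate: float = 3.0
    arena_side_cm: float = 25.4
    base_event_rate_per_min: float = 6.0
    amplitude: float = 1.0
    amplitude_jitter_sd: float = 0.25
    noise_sigma: float = 0.05
    kernel_rise_s: float = 0.1
    kernel_decay_s: float = 0.6
    frac_increased_off: float = 0.05
    frac_decreased_off: float = 0.09
    frac_increased_fixed: float = 0.06
    frac_decreased_fixed: float = 0.18
    multiplier_up: float = 2.0
    multiplier_down: float = 0.5
    step_speed_mean_cm_s: dict[str, float] = Field(
        default_factory=lambda: {"free": 3.0, "on": 2.9, "off": 1.4}
    )
    turn_concentration: float = 9.0
    platter_omega_rad_s: float = 0.5
    platter_bout_s: float = 20.0
    platter_rest_s: float = 15.0
    platter_noise_sd: float = 0.01


class BehaviorStage(_StrictModel):
    speed_threshold_cm_s: float = 1.0
    min_bout_s: float = 1.0
    min_displacement_cm: float = 0.2
    effective_radius_cm: float = 10.0


class EventsStage(_StrictModel):
    baseline_window_s: float = 90.0
    baseline_percentile: float = 8.0
    k_on: float = 2.5
    k_off: float = 0.5
    min_duration_frames: int = 2
    merge_gap_frames: int = 1
    gate_rule: str = "onset"


class CompareStage(_StrictModel):
    alpha: float = 0.05
    min_events: int = 3
    mode: str = "auto"
    adjust: str = "none"


class RunConfig(_StrictModel):
    seed: int = 0
    out_dir: str = "poeclab_run"
    make_figures: bool = True
    synthetic: SyntheticStage = Field(default_factory=SyntheticStage)
    behavior: BehaviorStage = Field(default_factory=BehaviorStage)
    events: EventsStage = Field(default_factory=EventsStage)
    compare: CompareStage = Field(default_factory=CompareStage)


def load_config(path: str | Path) -> RunConfig:
    return RunConfig.model_validate_json(Path(path).read_text())


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(config.model_dump_json(indent=2))


def _spawn_seeds(seed: int, n: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(seed).spawn(n)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage on synthetic data and write the report bundle.

    Emits, under ``config.out_dir``: trajectory/locomotion/kinematics CSVs,
    events CSV, rate-set JSON, classification CSV, a summary JSON, and (when
    ``make_figures``) box-whisker / stacked-bar / median-trend figures.
    Returns the summary dictionary.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    s = config.synthetic
    # fixed spawn order: cohort, behavior streams, trace streams
    ss_cohort, ss_behavior, ss_traces = _spawn_seeds(config.seed, 3)
    logger.info("pipeline seed=%d n_neurons=%d", config.seed, s.n_neurons)

    cohort = syn.generate_cohort(
        n_neurons=s.n_neurons,
        base_event_rate=s.base_event_rate_per_min,
        frac_increased_off=s.frac_increased_off,
        frac_decreased_off=s.frac_decreased_off,
        frac_increased_fixed=s.frac_increased_fixed,
        frac_decreased_fixed=s.frac_decreased_fixed,
        multiplier_up=s.multiplier_up,
        multiplier_down=s.multiplier_down,
        amplitude=s.amplitude,
        seed=int(ss_cohort.generate_state(1)[0] % (2**31)),
    )
    syn.write_ground_truth_json(cohort, out / "ground_truth.json")

    # --- behavior stage: trajectories (free/on/off) and platter (fixed) -------
    behavior_rngs = ss_behavior.spawn(4 * s.n_sessions_per_condition)
    session_rows = []
    masks: dict[tuple[str, int], bhv.LocomotionMask] = {}
    rng_idx = 0
    for condition in ("free", "on", "off", "fixed"):
        for sess in range(s.n_sessions_per_condition):
            seed_i = int(behavior_rngs[rng_idx].generate_state(1)[0] % (2**31))
            rng_idx += 1
            spec = syn.SessionSpec(
                condition=condition,
                n_frames=s.n_frames,
                frame_rate=s.frame_rate,
                arena_side=s.arena_side_cm,
                seed=seed_i,
            )
            if condition == "fixed":
                schedule = _alternating_schedule(spec.duration, s.platter_bout_s, s.platter_rest_s)
                plat = syn.generate_platter(
                    spec, schedule, omega_locomotion=s.platter_omega_rad_s, noise_sd=s.platter_noise_sd
                )
                mask = bhv.platter_locomotion(
                    plat.platter,
                    linear_threshold=config.behavior.speed_threshold_cm_s,
                    effective_radius=config.behavior.effective_radius_cm,
                    min_bout=config.behavior.min_bout_s,
                )
                session_rows.append(
                    {
                        "condition": condition,
                        "session": sess,
                        "walking_distance": np.nan,
                        "turning_angle": np.nan,
                        "locomotion_fraction": mask.locomotion_fraction,
                    }
                )
            else:
                traj = syn.generate_trajectory(
                    spec,
                    step_speed_mean=s.step_speed_mean_cm_s.get(condition, 3.0),
                    turn_concentration=s.turn_concentration,
                )
                kin = bhv.compute_kinematics(traj, min_displacement=config.behavior.min_displacement_cm)
                mask = bhv.segment_locomotion(
                    kin.linear_speed_series,
                    frame_rate=s.frame_rate,
                    threshold=config.behavior.speed_threshold_cm_s,
                    min_bout=config.behavior.min_bout_s,
                )
                session_rows.append(
                    {
                        "condition": condition,
                        "session": sess,
                        "walking_distance": kin.walking_distance,
                        "turning_angle": kin.turning_angle,
                        "locomotion_fraction": mask.locomotion_fraction,
                    }
                )
                if condition == "free" and sess == 0:
                    syn.write_trajectory_csv(traj, out / "trajectory_free_s0.csv")
            masks[(condition, sess)] = mask
    sessions_df = pd.DataFrame(session_rows)
    sessions_df.to_csv(out / "sessions.csv", index=False)
    means, changes = bhv.session_summary_table(
        sessions_df.dropna(subset=["walking_distance"]),
        metrics=("walking_distance", "turning_angle"),
    )
    changes.to_csv(out / "kinematics_percent_change.csv", index=False)

    # --- events stage ---------------------------------------------------------
    trace_rngs = ss_traces.spawn(len(cohort))
    event_frames = []
    for gt, ss in zip(cohort, trace_rngs):
        per_neuron = ss.spawn(3 * s.n_sessions_per_condition)
        j = 0
        # first pass: generate all of this neuron's sessions; estimate one common
        # debias noise sd and one pooled detection sigma so that baseline offsets
        # and thresholds are identical across conditions
        generated = []
        for condition in ("on", "off", "fixed"):
            for sess in range(s.n_sessions_per_condition):
                seed_i = int(per_neuron[j].generate_state(1)[0] % (2**31))
                j += 1
                spec = syn.SessionSpec(
                    condition=condition,
                    n_frames=s.n_frames,
                    frame_rate=s.frame_rate,
                    arena_side=s.arena_side_cm,
                    seed=seed_i,
                )
                mask = masks[(condition, sess)]
                sdff = syn.generate_dff(
                    gt,
                    spec,
                    noise_sigma=s.noise_sigma,
                    kernel_rise=s.kernel_rise_s,
                    kernel_decay=s.kernel_decay_s,
                    amplitude_jitter_sd=s.amplitude_jitter_sd,
                    locomotion_mask=mask.mask,
                    session_id=f"s{sess}",
                )
                generated.append((condition, sess, sdff.trace, mask))
        noise_sd = float(np.median([evt.diff_noise_sd(tr.dff) for _, _, tr, _ in generated]))
        sessions = []
        for condition, sess, trace, mask in generated:
            baseline, _ = evt.estimate_baseline_noise(
                trace,
                window=config.events.baseline_window_s,
                percentile=config.events.baseline_percentile,
                noise_sd=noise_sd,
            )
            sessions.append((condition, sess, trace, baseline, mask))
        sigma = evt.pooled_noise_sigma([tr.dff - b for _, _, tr, b, _ in sessions])
        for condition, sess, trace, baseline, mask in sessions:
            detected = evt.detect_events(
                trace,
                baseline,
                sigma,
                k_on=config.events.k_on,
                k_off=config.events.k_off,
                min_duration=config.events.min_duration_frames,
                merge_gap=config.events.merge_gap_frames,
            )
            gated = evt.gate_by_locomotion(detected, mask, rule=config.events.gate_rule)
            event_frames.append(
                evt.events_to_frame(gated, gt.neuron_id, condition, s.frame_rate, f"s{sess}")
            )
    events_df = pd.concat(event_frames, ignore_index=True)
    events_df.to_csv(out / "events.csv", index=False)
    rate_sets = evt.build_rate_sets(events_df)
    evt.write_rate_sets_json(rate_sets, out / "rate_sets.json")

    # --- comparison stage -----------------------------------------------------
    classifications = cmp.classify_cohort(
        rate_sets,
        alpha=config.compare.alpha,
        min_events=config.compare.min_events,
        mode=config.compare.mode,
        adjust=config.compare.adjust,
    )
    classifications.to_csv(out / "classifications.csv", index=False)
    proportions = cmp.proportion_summary(classifications)

    by_key = {(rs.neuron_id, rs.condition): rs for rs in rate_sets}
    cls_by = {(c.neuron_id, c.comparison): c for c in classifications.itertuples()}
    trend_rows = []
    for gt in cohort:
        c_off = cls_by.get((gt.neuron_id, "off_vs_on"))
        c_fix = cls_by.get((gt.neuron_id, "fixed_vs_on"))
        if c_off is None or c_fix is None:
            continue
        medians = {
            cond: by_key[(gt.neuron_id, cond)].median
            for cond in ("on", "off", "fixed")
            if (gt.neuron_id, cond) in by_key
        }
        tr = cmp.trend_analysis(_as_cls(c_off), _as_cls(c_fix), medians)
        trend_rows.append(vars(tr))
    trends = pd.DataFrame(trend_rows)
    trends.to_csv(out / "trends.csv", index=False)

    if config.make_figures:
        plots.box_whisker_by_condition(
            sessions_df.dropna(subset=["walking_distance"]),
            "walking_distance",
            out / "walking_distance_box.png",
            ylabel="walking distance (m)",
        )
        plots.box_whisker_by_condition(
            sessions_df.dropna(subset=["turning_angle"]),
            "turning_angle",
            out / "turning_angle_box.png",
            ylabel="turning angle (rad)",
        )
        plots.stacked_proportions(proportions, out / "proportions_stacked.png")
        if not trends.empty:
            plots.median_trend(trends, out / "median_trend.png")

    summary = {
        "seed": config.seed,
        "n_neurons": s.n_neurons,
        "condition_means": {
            metric: {cond: float(means.loc[cond, metric]) for cond in means.index}
            for metric in means.columns
        },
        "percent_changes": changes.to_dict(orient="records"),
        "proportions": proportions.to_dict(orient="records"),
        "n_consistent_up": int((trends["trend"] == "consistent_up").sum()) if not trends.empty else 0,
        "n_consistent_down": int((trends["trend"] == "consistent_down").sum()) if not trends.empty else 0,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary


def _alternating_schedule(duration: float, bout_s: float, rest_s: float) -> list[tuple[float, float]]:
    schedule = []
    t = rest_s
    while t < duration:
        schedule.append((t, min(t + bout_s, duration)))
        t += bout_s + rest_s
    return schedule


def _as_cls(row) -> cmp.NeuronClassification:
    return cmp.NeuronClassification(
        neuron_id=row.neuron_id,
        comparison=row.comparison,
        label=row.label,
        p_value=row.p_value,
        median_a=row.median_a,
        median_b=row.median_b,
        n_a=row.n_a,
        n_b=row.n_b,
        reason=row.reason,
    )
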