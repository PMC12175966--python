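"""Synthetic sessions with known ground truth: ΔF/F traces, arena walks, platter spins.

Every downstream stage (kinematics, locomotion segmentation, event detection,
condition comparison) is testable against the ground truth retained by these
generators, with no recorded data required.  The defaults emulate the study
conditions this package targets: 1000-frame sessions at 3 frames/s (333 s) in a
10-inch (25.4 cm) square arena, GCaMP6m-like transients, and four experimental
conditions — ``free`` (untethered-equivalent), ``on`` (tether with torque
compensation active), ``off`` (compensation disabled), and ``fixed``
(head-fixed on a rotating platter).

Condition effects on a neuron are encoded as multipliers relative to the
baseline ``on`` condition.  A multiplier scales both the Poisson event
frequency and the per-event transient amplitude: stronger firing produces both
more and larger calcium transients, and the latter is what the downstream
fluorescence-rate statistic r = ΔS/Δt detects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .behavior import PlatterTrace, Trajectory
from .errors import ConfigurationError
from .events import CONDITIONS, DffTrace

__all__ = [
    "SessionSpec",
    "NeuronGroundTruth",
    "SyntheticDff",
    "SyntheticPlatter",
    "render_events",
    "generate_dff",
    "generate_trajectory",
    "generate_platter",
    "generate_cohort",
    "write_traces_csv",
    "read_traces_csv",
    "write_trajectory_csv",
    "write_ground_truth_json",
]


@dataclass(frozen=True)
class SessionSpec:
    """One imaging/behavior session: condition, length, frame rate, arena size."""

    condition: str
    n_frames: int = 1000
    frame_rate: float = 3.0
    arena_side: float = 25.4  # cm (10-inch square arena)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ConfigurationError(f"condition must be one of {CONDITIONS}")
        if self.n_frames <= 0:
            raise ConfigurationError("n_frames must be positive")
        if self.frame_rate <= 0:
            raise ConfigurationError("frame_rate must be positive")
        if self.arena_side <= 0:
            raise ConfigurationError("arena_side must be positive")

    @property
    def duration(self) -> float:
        """Session length in seconds (n_frames / frame_rate)."""
        return self.n_frames / self.frame_rate


_LABELS = ("increased", "decreased", "other")


def _label_from_multiplier(m: float) -> str:
    if m > 1:
        return "increased"
    if m < 1:
        return "decreased"
    return "other"


@dataclass(frozen=True)
class NeuronGroundTruth:
    """Generative parameters of one synthetic neuron.

    ``base_event_rate`` is the firing-event rate (events/min) under the baseline
    ``on`` condition; the multipliers give the relative firing intensity under
    ``off`` and ``fixed``.  True condition-comparison labels follow the
    multipliers by construction.
    """

    neuron_id: int
    base_event_rate: float
    rate_multiplier_off: float = 1.0
    rate_multiplier_fixed: float = 1.0
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.base_event_rate < 0:
            raise ConfigurationError("base_event_rate must be >= 0")
        if self.rate_multiplier_off <= 0 or self.rate_multiplier_fixed <= 0:
            raise ConfigurationError("rate multipliers must be positive")
        if self.amplitude <= 0:
            raise ConfigurationError("amplitude must be positive")

    @property
    def true_label_off_vs_on(self) -> str:
        return _label_from_multiplier(self.rate_multiplier_off)

    @property
    def true_label_fixed_vs_on(self) -> str:
        return _label_from_multiplier(self.rate_multiplier_fixed)

    def multiplier(self, condition: str) -> float:
        if condition == "off":
            return self.rate_multiplier_off
        if condition == "fixed":
            return self.rate_multiplier_fixed
        return 1.0  # "on" and "free" are baseline


@dataclass(frozen=True)
class SyntheticDff:
    """A generated trace together with its ground-truth event times/amplitudes."""

    trace: DffTrace
    event_times_s: np.ndarray
    event_amplitudes: np.ndarray


@dataclass(frozen=True)
class SyntheticPlatter:
    """A generated platter trace with ground-truth locomotion bout boundaries."""

    platter: PlatterTrace
    bouts_frames: list[tuple[int, int]]
    omega_locomotion: float


def _kernel(dt_s: np.ndarray, rise: float, decay: float) -> np.ndarray:
    """Unnormalised double-exponential calcium kernel, zero for dt < 0."""
    out = np.where(dt_s >= 0, np.exp(-np.maximum(dt_s, 0) / decay) - np.exp(-np.maximum(dt_s, 0) / rise), 0.0)
    return out


def render_events(
    event_times_s: np.ndarray,
    amplitudes: np.ndarray,
    n_frames: int,
    frame_rate: float,
    kernel_rise: float = 0.1,
    kernel_decay: float = 0.6,
) -> np.ndarray:
    """Render a noiseless ΔF/F trace from event times and amplitudes.

    Each event contributes its amplitude times a double-exponential kernel whose
    *sampled* values are normalised to unit peak, so an isolated event's maximum
    frame value equals its amplitude exactly regardless of where the event time
    falls between frames.
    """
    if kernel_rise >= kernel_decay:
        raise ConfigurationError("kernel_rise must be smaller than kernel_decay")
    t = np.arange(n_frames) / frame_rate
    dff = np.zeros(n_frames)
    support = int(np.ceil(8 * kernel_decay * frame_rate)) + 1
    for t0, amp in zip(np.asarray(event_times_s, float), np.asarray(amplitudes, float)):
        i0 = max(0, int(np.floor(t0 * frame_rate)))
        i1 = min(n_frames, i0 + support)
        if i0 >= n_frames:
            continue
        k = _kernel(t[i0:i1] - t0, kernel_rise, kernel_decay)
        peak = k.max()
        if peak > 0:
            dff[i0:i1] += amp * k / peak
    return dff


def generate_dff(
    gt: NeuronGroundTruth,
    spec: SessionSpec,
    noise_sigma: float = 0.05,
    kernel_rise: float = 0.1,
    kernel_decay: float = 0.6,
    amplitude_jitter_sd: float = 0.0,
    locomotion_mask: np.ndarray | None = None,
    seed: int | None = None,
    session_id: str = "s0",
) -> SyntheticDff:
    """Generate one neuron-session ΔF/F trace with known event ground truth.

    Event times are a homogeneous Poisson process at ``base_event_rate`` times
    the condition multiplier.  When ``locomotion_mask`` (per-frame boolean) is
    supplied, events are placed only during locomotion frames, matching an
    analysis that scores firing during locomotion periods; otherwise events are
    uniform over the session.  Per-event amplitudes are the neuron amplitude
    times the condition multiplier, with optional lognormal jitter
    (``amplitude_jitter_sd`` is the log-scale sd).  Additive i.i.d. Gaussian
    noise is applied last.
    """
    if noise_sigma < 0:
        raise ConfigurationError("noise_sigma must be >= 0")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    mult = gt.multiplier(spec.condition)
    rate_hz = gt.base_event_rate / 60.0 * mult

    if locomotion_mask is not None:
        mask = np.asarray(locomotion_mask, dtype=bool)
        if mask.size != spec.n_frames:
            raise ConfigurationError("locomotion_mask length must equal n_frames")
        loco_frames = np.flatnonzero(mask)
        total_time = loco_frames.size / spec.frame_rate
        n_events = rng.poisson(rate_hz * total_time)
        if loco_frames.size == 0:
            n_events = 0
            times = np.empty(0)
        else:
            # uniform over locomotion time, mapped back onto locomotion frames
            u = np.sort(rng.uniform(0, loco_frames.size, size=n_events))
            times = (loco_frames[np.floor(u).astype(int)] + (u % 1.0)) / spec.frame_rate
    else:
        n_events = rng.poisson(rate_hz * spec.duration)
        times = np.sort(rng.uniform(0, spec.duration, size=n_events))

    amp_scale = gt.amplitude * mult
    if amplitude_jitter_sd > 0:
        amps = amp_scale * rng.lognormal(mean=0.0, sigma=amplitude_jitter_sd, size=n_events)
    else:
        amps = np.full(n_events, amp_scale)

    dff = render_events(times, amps, spec.n_frames, spec.frame_rate, kernel_rise, kernel_decay)
    if noise_sigma > 0:
        dff = dff + rng.normal(0.0, noise_sigma, size=spec.n_frames)
    trace = DffTrace(
        neuron_id=gt.neuron_id,
        frame_rate=spec.frame_rate,
        dff=dff,
        condition=spec.condition,
        session_id=session_id,
    )
    return SyntheticDff(trace=trace, event_times_s=times, event_amplitudes=amps)


def generate_trajectory(
    spec: SessionSpec,
    step_speed_mean: float = 3.0,
    turn_concentration: float = 9.0,
    seed: int | None = None,
) -> Trajectory:
    """Correlated random walk in the square arena with reflecting walls.

    Per-frame speed is Gamma(shape=2) with mean ``step_speed_mean`` (cm/s);
    heading increments are von Mises with concentration ``turn_concentration``.
    Positions outside [0, arena_side] are folded back (specular reflection), so
    the walk never leaves the arena.
    """
    if step_speed_mean < 0:
        raise ConfigurationError("step_speed_mean must be >= 0")
    if turn_concentration <= 0:
        raise ConfigurationError("turn_concentration must be positive")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n_frames
    dt = 1.0 / spec.frame_rate
    L = spec.arena_side

    pos = np.empty((n, 2))
    pos[0] = rng.uniform(0.2 * L, 0.8 * L, size=2)
    heading = rng.uniform(-np.pi, np.pi)
    if step_speed_mean == 0:
        pos[1:] = pos[0]
    else:
        speeds = rng.gamma(shape=2.0, scale=step_speed_mean / 2.0, size=n - 1)
        turns = rng.vonmises(0.0, turn_concentration, size=n - 1)
        for i in range(1, n):
            heading = heading + turns[i - 1]
            step = speeds[i - 1] * dt
            x = pos[i - 1, 0] + step * np.cos(heading)
            y = pos[i - 1, 1] + step * np.sin(heading)
            x, flip_x = _reflect(x, L)
            y, flip_y = _reflect(y, L)
            if flip_x:
                heading = np.pi - heading
            if flip_y:
                heading = -heading
            pos[i] = (x, y)
    time_s = np.arange(n) * dt
    return Trajectory(time_s=time_s, x_cm=pos[:, 0], y_cm=pos[:, 1])


def _reflect(coord: float, side: float) -> tuple[float, bool]:
    """Fold a coordinate back into [0, side]; report whether a reflection happened."""
    flipped = False
    while coord < 0 or coord > side:
        if coord < 0:
            coord = -coord
        else:
            coord = 2 * side - coord
        flipped = not flipped
    return coord, flipped


def generate_platter(
    spec: SessionSpec,
    bout_schedule: list[tuple[float, float]],
    omega_locomotion: float = 0.5,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> SyntheticPlatter:
    """Platter angular-velocity trace for a head-fixed session.

    ``bout_schedule`` lists locomotion bouts as (start_s, end_s); during bouts
    the angular velocity is ``omega_locomotion`` (rad/s), otherwise zero, with
    additive Gaussian noise of sd ``noise_sd`` throughout.  Ground-truth bout
    boundaries (frames, half-open) are retained.
    """
    if spec.condition != "fixed":
        raise ConfigurationError("platter traces exist only for the 'fixed' condition")
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be >= 0")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    omega = np.zeros(spec.n_frames)
    bouts_frames: list[tuple[int, int]] = []
    for start_s, end_s in bout_schedule:
        if not 0 <= start_s < end_s:
            raise ConfigurationError("bout schedule entries must satisfy 0 <= start < end")
        s = int(round(start_s * spec.frame_rate))
        e = min(int(round(end_s * spec.frame_rate)), spec.n_frames)
        if s >= e:
            continue
        omega[s:e] = omega_locomotion
        bouts_frames.append((s, e))
    if noise_sd > 0:
        omega = omega + rng.normal(0.0, noise_sd, size=spec.n_frames)
    platter = PlatterTrace(time_s=np.arange(spec.n_frames) / spec.frame_rate, omega=omega)
    return SyntheticPlatter(platter=platter, bouts_frames=bouts_frames, omega_locomotion=omega_locomotion)


def generate_cohort(
    n_neurons: int = 150,
    base_event_rate: float = 6.0,
    frac_increased_off: float = 0.05,
    frac_decreased_off: float = 0.09,
    frac_increased_fixed: float = 0.06,
    frac_decreased_fixed: float = 0.18,
    multiplier_up: float = 2.0,
    multiplier_down: float = 0.5,
    amplitude: float = 1.0,
    seed: int = 0,
) -> list[NeuronGroundTruth]:
    """A cohort of neurons with a condition-effect mixture.

    The affected fractions default to the scale reported for tether-resistance
    experiments (roughly 13-23% of neurons affected off-vs-on, more under head
    fixation, with decreases outnumbering increases).  Affected index ranges
    overlap deliberately so a consistent-trend subset (same direction in both
    comparisons) exists: neurons affected under ``fixed`` are drawn first from
    those already affected under ``off``.
    """
    if n_neurons <= 0:
        raise ConfigurationError("n_neurons must be positive")
    if frac_increased_off + frac_decreased_off > 1 or frac_increased_fixed + frac_decreased_fixed > 1:
        raise ConfigurationError("affected fractions must sum to at most 1 per comparison")
    rng = np.random.default_rng(seed)
    n_up_off = int(round(frac_increased_off * n_neurons))
    n_down_off = int(round(frac_decreased_off * n_neurons))
    n_up_fixed = int(round(frac_increased_fixed * n_neurons))
    n_down_fixed = int(round(frac_decreased_fixed * n_neurons))

    mult_off = np.ones(n_neurons)
    mult_fixed = np.ones(n_neurons)
    mult_off[:n_up_off] = multiplier_up
    mult_off[n_up_off : n_up_off + n_down_off] = multiplier_down
    # fixed-condition effects reuse off-affected indices first (-> consistent-trend
    # neurons), then spill into the unaffected tail of the cohort
    tail = n_up_off + n_down_off
    k = min(n_up_fixed, n_up_off)
    mult_fixed[:k] = multiplier_up
    spill_up = n_up_fixed - k
    mult_fixed[tail : tail + spill_up] = multiplier_up
    k2 = min(n_down_fixed, n_down_off)
    mult_fixed[n_up_off : n_up_off + k2] = multiplier_down
    spill_down = n_down_fixed - k2
    mult_fixed[tail + spill_up : tail + spill_up + spill_down] = multiplier_down

    rates = rng.gamma(shape=4.0, scale=base_event_rate / 4.0, size=n_neurons)
    rates = np.maximum(rates, 1.0)  # keep every neuron scoreable
    return [
        NeuronGroundTruth(
            neuron_id=i,
            base_event_rate=float(rates[i]),
            rate_multiplier_off=float(mult_off[i]),
            rate_multiplier_fixed=float(mult_fixed[i]),
            amplitude=amplitude,
        )
        for i in range(n_neurons)
    ]


# ---------------------------------------------------------------------------
# CSV / JSON round-trips


def write_traces_csv(traces: list[DffTrace], path: str | Path) -> None:
    """Long-format trace table: neuron_id, frame, time_s, dff, condition, session_id."""
    frames = []
    for tr in traces:
        frames.append(
            pd.DataFrame(
                {
                    "neuron_id": tr.neuron_id,
                    "frame": np.arange(tr.n_frames),
                    "time_s": tr.time_s,
                    "dff": tr.dff,
                    "condition": tr.condition,
                    "session_id": tr.session_id,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_traces_csv(path: str | Path) -> list[DffTrace]:
    df = pd.read_csv(path)
    traces = []
    for (nid, cond, sid), grp in df.groupby(["neuron_id", "condition", "session_id"], sort=False):
        grp = grp.sort_values("frame")
        t = grp["time_s"].to_numpy()
        frame_rate = 1.0 / float(np.mean(np.diff(t))) if t.size > 1 else 1.0
        traces.append(
            DffTrace(
                neuron_id=int(nid),
                frame_rate=frame_rate,
                dff=grp["dff"].to_numpy(),
                condition=str(cond),
                session_id=str(sid),
            )
        )
    return traces


def write_trajectory_csv(traj: Trajectory, path: str | Path) -> None:
    traj.to_frame().to_csv(path, index=False)


def write_ground_truth_json(cohort: list[NeuronGroundTruth], path: str | Path) -> None:
    payload = [
        {
            "neuron_id": gt.neuron_id,
            "base_event_rate": gt.base_event_rate,
            "rate_multiplier_off": gt.rate_multiplier_off,
            "rate_multiplier_fixed": gt.rate_multiplier_fixed,
            "amplitude": gt.amplitude,
            "true_label_off_vs_on": gt.true_label_off_vs_on,
            "true_label_fixed_vs_on": gt.true_label_fixed_vs_on,
        }
        for gt in cohort
    ]
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
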