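import numpy as np
import pytest

from poeclab import DffTrace


@pytest.fixture
def make_trace():
    """Factory for ΔF/F traces from raw arrays."""

    def _make(dff, frame_rate=3.0, condition="on", neuron_id=0, session_id="s0"):
        return DffTrace(
            neuron_id=neuron_id,
            frame_rate=frame_rate,
            dff=np.asarray(dff, dtype=float),
            condition=condition,
            session_id=session_id,
        )

    return _make


@pytest.fixture(scope="session")
def poisson_event_counts():
    """Ground-truth event counts from 1000 replicate generated sessions at 6 events/min."""
    from poeclab import NeuronGroundTruth, SessionSpec, generate_dff

    gt = NeuronGroundTruth(neuron_id=0, base_event_rate=6.0)
    counts = []
    for seed in range(1000):
        spec = SessionSpec(condition="on", seed=seed)
        counts.append(generate_dff(gt, spec, noise_sigma=0.0).event_times_s.size)
    return np.asarray(counts)
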