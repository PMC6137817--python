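import numpy as np
import pytest

import corridor_neuro as cn


@pytest.fixture(scope="session")
def geometry():
    return cn.TaskGeometry()


@pytest.fixture(scope="session")
def small_bundle():
    """Cued-only session with a few planted neurons; shared read-only."""
    specs = [
        cn.NeuronSpec(category="reward_zone", anchor_pos=88.0, peak_rate=8.0),
        cn.NeuronSpec(category="untuned"),
        cn.NeuronSpec(category="corridor", peak_rate=6.0),
    ]
    return cn.simulate_session(
        lick_policy=cn.LickPolicy(mode="uniform", rate=0.05),
        neuron_specs=specs,
        n_trials=8,
        seed=11,
    )


@pytest.fixture(scope="session")
def phase2_bundle():
    """Alternating cued/uncued trials with reward-zone vs grating-offset neurons."""
    geom = cn.TaskGeometry(uncued_period=2)
    specs = [
        cn.NeuronSpec(category="reward_zone", anchor_pos=88.0, peak_rate=10.0),
        cn.NeuronSpec(category="grating_offset", peak_rate=10.0),
        cn.NeuronSpec(category="untuned"),
    ]
    return cn.simulate_session(
        geometry=geom,
        lick_policy=cn.LickPolicy(mode="expert", rate=0.03, target_center=88.0),
        neuron_specs=specs,
        n_trials=30,
        seed=21,
    )


@pytest.fixture(scope="session")
def gain_bundle():
    """All-uncued session, every other trial at gain 0.75, anchored neurons."""
    geom = cn.TaskGeometry(uncued_period=1, gain_period=2)
    specs = [
        cn.NeuronSpec(
            category="gain_anchored_treadmill", anchor_pos=85.0,
            anchor_frame="treadmill", peak_rate=10.0, width_cm=6.0,
        ),
        cn.NeuronSpec(
            category="gain_anchored_virtual", anchor_pos=80.0,
            anchor_frame="virtual", peak_rate=10.0, width_cm=6.0,
        ),
    ]
    return cn.simulate_session(
        geometry=geom,
        lick_policy=cn.LickPolicy(mode="expert", target_center=85.0, anchor="treadmill"),
        neuron_specs=specs,
        n_trials=30,
        seed=31,
    )


@pytest.fixture(scope="session")
def small_dff(small_bundle):
    return cn.compute_dff(small_bundle.fluorescence, small_bundle.calcium.frame_rate)


def make_spatial(matrix, bin_width=2.0, frame="virtual"):
    """SpatialResponse from a raw trials x bins matrix (bins start at 0 cm)."""
    matrix = np.asarray(matrix, dtype=float)
    edges = bin_width * np.arange(matrix.shape[1] + 1)
    return cn.SpatialResponse(matrix=matrix, bin_edges=edges, frame_of_reference=frame)
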