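import numpy as np
import pytest

from betareach import designs, simulate as sim, tfr as tf


@pytest.fixture(scope="session")
def layout64():
    return tf.make_standard_layout(64)


@pytest.fixture(scope="session")
def layout32():
    return tf.make_standard_layout(32)


@pytest.fixture(scope="session")
def mov_design():
    return designs.build_mov_design(7)


@pytest.fixture(scope="session")
def clean_subject():
    """Noise-free trajectories: isolates estimator accuracy from sensor noise."""
    return sim.SubjectParams(rng_seed=42, kin_noise_cm=0.0)


@pytest.fixture(scope="session")
def noisy_subject():
    return sim.SubjectParams(rng_seed=42)


@pytest.fixture(scope="session")
def mov_trajectories(mov_design, clean_subject):
    return sim.simulate_block_kinematics(mov_design, clean_subject)


@pytest.fixture(scope="session")
def small_epochs(layout32):
    """One simulated 40-trial mov block at 32 channels, movement-aligned."""
    from betareach import kinematics as kin

    subj = sim.SubjectParams(rng_seed=5, eeg=sim.default_eeg_params("mov"))
    design = designs.build_mov_design(5)
    design.targets = design.targets[:40]
    design.movements_per_set = 40
    trajs = sim.simulate_block_kinematics(design, subj)
    records = [kin.compute_kinematics(t) for t in trajs]
    epochs, truth = sim.simulate_epochs(design, trajs, subj, layout=layout32)
    onsets = np.array([r.onset_s for r in records])
    keep = kin.exclude_outliers(records)
    realigned = tf.realign_to_movement_onset(epochs, onsets, keep_mask=keep)
    return realigned, truth, subj
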