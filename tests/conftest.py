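"""Shared fixtures.

The expensive fixtures (trained decoders) are session-scoped and sized for
a single CPU: a high-SNR synthetic subject (8 trials/class) trained for 6
epochs is enough for the decoder to pull far ahead of chance, and is
reused by the learning, anchoring, interpretability and export tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import mignet as mg
from mignet.training import TrainConfig, train


@pytest.fixture(scope="session")
def layout():
    return mg.load_builtin_montage(64)


@pytest.fixture(scope="session")
def prior(layout):
    return mg.build_prior_adjacency(layout)


@pytest.fixture(scope="session")
def tiny_layout():
    rng = np.random.default_rng(11)
    return mg.MontageLayout(
        names=("A", "B", "C", "D", "E"), coords=rng.standard_normal((5, 3))
    )


def desk_scale_dataset(layout, snr_db: float, seed: int, trials_per_class: int = 8):
    cfg = mg.SyntheticConfig(trials_per_class=trials_per_class, snr_db=snr_db, seed=seed)
    return mg.generate_dataset(cfg, layout)


def desk_scale_training(layout, snr_db: float, seed: int, epochs: int = 6,
                        update_period: int = 2, trials_per_class: int = 8):
    """Train one decoder on a small synthetic subject; returns everything."""
    trials = desk_scale_dataset(layout, snr_db, seed, trials_per_class)
    train_trials, test_trials = mg.split_trials(trials, ratio=0.8, seed=seed)
    train_segs = mg.window_trials(train_trials)
    test_segs = mg.window_trials(test_trials)
    model = mg.MotorImageryDecoder(layout, seed=seed, dtype=np.float32)
    cfg = TrainConfig(epochs=epochs, update_period=update_period, seed=seed)
    history = train(model, train_segs, cfg)
    return {
        "model": model, "history": history, "cfg": cfg,
        "train_segs": train_segs, "test_segs": test_segs,
        "train_trials": train_trials, "test_trials": test_trials,
    }


@pytest.fixture(scope="session")
def trained_high_snr(layout):
    """Decoder trained on easily separable (+10 dB) synthetic data."""
    return desk_scale_training(layout, snr_db=10.0, seed=7)


@pytest.fixture(scope="session")
def trained_no_signal(layout):
    """Decoder trained on pure-noise (-100 dB) synthetic data."""
    return desk_scale_training(layout, snr_db=-100.0, seed=7, epochs=4)
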