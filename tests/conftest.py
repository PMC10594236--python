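"""Shared, session-scoped fixtures: built once, reused read-only."""

import numpy as np
import pandas as pd
import pytest

from fingerbmi import SimSession, TaskConfig, label_segments, make_fixtures


@pytest.fixture(scope="session")
def eg_fix():
    """Error-gain scenario: the main detection fixture (distance coding plus
    a direct error drive)."""
    return make_fixtures("error-gain", rng_seed=1, n_trials_train=120, n_trials_brain=200)


@pytest.fixture(scope="session")
def eg_segments(eg_fix):
    return label_segments(eg_fix["brain"], n_window=4, channels=eg_fix["kf"].channels_)


@pytest.fixture(scope="session")
def dist_fix():
    """Distance-coding scenario (no direct error drive), manual session used
    for encoding analyses."""
    return make_fixtures("distance-coding", rng_seed=2, n_trials_train=150, n_trials_brain=60)


def make_session(pos, vel, target, bin_width_ms=50.0, half_width=0.1, trials=None,
                 sbp=None, mode="brain"):
    """Hand-built session for labeling/metric tests (arrays given per bin)."""
    pos = np.atleast_2d(np.asarray(pos, dtype=float))
    if pos.shape[0] == 1:
        pos = pos.T
    vel = np.asarray(vel, dtype=float).reshape(pos.shape)
    target = np.asarray(target, dtype=float).reshape(pos.shape)
    n, g = pos.shape
    cfg = TaskConfig(
        n_finger_groups=g,
        bin_width_ms=bin_width_ms,
        hold_time_ms=10 * bin_width_ms,
        target_half_width=half_width,
        n_trials=1,
    )
    if trials is None:
        rec = {"trial": 0, "start_bin": 0, "end_bin": n - 1, "success": True}
        rec.update({f"target_{i}": target[0, i] for i in range(g)})
        trials = pd.DataFrame([rec])
    return SimSession(
        mode=mode, config=cfg, pos=pos, vel=vel, target=target, trials=trials, sbp=sbp
    )
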