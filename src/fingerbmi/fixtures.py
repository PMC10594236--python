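"""Documented, seeded end-to-end fixtures used by tests and examples.

Each scenario builds the standard experiment: a manual-control training run
(phase I) that fits the Kalman filter, then an initial brain-control run
(phase II) from which detectors can be trained.  Scenario defaults mirror
the study conditions (50 ms bins, two finger groups, 500-trial training
phases, 500 ms hold); the simulated-subject parameters (controller gain
3 /s, AR(1) motor noise of 0.4 arc/s with coefficient 0.85) were chosen once
so that manual control succeeds essentially always, closed-loop brain
control succeeds in most trials, and away-from-target movements occur at a
workable rate for balanced detector training.

Scenarios
---------
``distance-coding``
    Channels encode velocity, position and distance to target; no direct
    error drive.  Detection relies on distance coding alone.
``error-gain``
    As above plus a direct additive error drive when a finger group moves
    away from its target: the main detection fixture.
``null-coding``
    All kinematic weights and the error drive are zero, so channels are
    bias + noise only and carry no movement information: detectors must be
    at chance.  (Velocity coding alone is *not* a valid null here: the
    feedback controller ties velocity to distance, so any kinematic coding
    leaks label information.)
``single-finger``
    One finger group (all fingers as one), error-gain tuning; two detectors
    instead of four.
"""

from __future__ import annotations

import zlib
from pathlib import Path

import numpy as np

from .config import TaskConfig, TuningModel
from .errors import ConfigurationError
from .kalman import KalmanVelocityDecoder
from .session import SimSession
from .simulator import simulate_session

SCENARIOS = ("null-coding", "distance-coding", "error-gain", "single-finger")

#: study-condition defaults shared by every scenario
DEFAULT_GAIN = 3.0
DEFAULT_MOTOR_NOISE = 0.4
DEFAULT_MOTOR_NOISE_AR = 0.85
DEFAULT_N_CHANNELS = 16
DEFAULT_ERROR_GAIN = 0.1


def scenario_params(scenario: str) -> dict:
    if scenario not in SCENARIOS:
        raise ConfigurationError(
            f"unknown scenario {scenario!r}; valid scenarios: {', '.join(SCENARIOS)}"
        )
    tuning = {
        "n_channels": DEFAULT_N_CHANNELS,
        "n_groups": 2,
        "w_p_scale": 0.2,
        "w_v_scale": 0.5,
        "w_d_scale": 1.5,
        "noise_sd": 0.4,
        "error_gain_scale": 0.0,
    }
    if scenario == "error-gain":
        tuning["error_gain_scale"] = DEFAULT_ERROR_GAIN
    elif scenario == "null-coding":
        tuning.update(w_p_scale=0.0, w_v_scale=0.0, w_d_scale=0.0)
    elif scenario == "single-finger":
        tuning.update(n_groups=1, error_gain_scale=DEFAULT_ERROR_GAIN)
    return {
        "n_groups": tuning["n_groups"],
        "tuning": tuning,
        "gain": DEFAULT_GAIN,
        "motor_noise_sd": DEFAULT_MOTOR_NOISE,
        "motor_noise_ar": DEFAULT_MOTOR_NOISE_AR,
    }


def make_fixtures(
    scenario: str,
    rng_seed: int = 0,
    n_trials_train: int = 500,
    n_trials_brain: int = 500,
    out_dir: str | Path | None = None,
) -> dict:
    """Deterministic fixture set: config, tuning, manual session, fitted
    Kalman filter, and a phase-II brain-control session.

    The same scenario and seed always produce bit-identical sessions.
    """
    from .closed_loop import run_closed_loop  # local import: avoid cycle

    params = scenario_params(scenario)
    scen_key = zlib.crc32(scenario.encode()) % (2**31)  # stable across processes
    ss = np.random.SeedSequence([scen_key, rng_seed])
    s_tun, s_man, s_brain = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)]

    cfg = TaskConfig(
        n_finger_groups=params["n_groups"],
        hold_time_ms=750.0,
        n_trials=n_trials_train,
    )
    tuning = TuningModel.random(rng_seed=s_tun, **params["tuning"])
    manual = simulate_session(
        cfg,
        tuning,
        gain=params["gain"],
        motor_noise_sd=params["motor_noise_sd"],
        motor_noise_ar=params["motor_noise_ar"],
        rng_seed=s_man,
    )
    kf = KalmanVelocityDecoder(position_range=cfg.position_range).fit_session(manual)
    online_cfg = TaskConfig(
        n_finger_groups=params["n_groups"],
        hold_time_ms=500.0,
        n_trials=n_trials_brain,
    )
    brain, log = run_closed_loop(
        kf,
        online_cfg,
        tuning,
        bank=None,
        gain=params["gain"],
        motor_noise_sd=params["motor_noise_sd"],
        motor_noise_ar=params["motor_noise_ar"],
        rng_seed=s_brain,
        phase="II",
    )
    out = {
        "scenario": scenario,
        "config": online_cfg,
        "tuning": tuning,
        "manual": manual,
        "kf": kf,
        "brain": brain,
        "log": log,
        "gain": params["gain"],
        "motor_noise_sd": params["motor_noise_sd"],
        "motor_noise_ar": params["motor_noise_ar"],
        "seeds": {"root": rng_seed, "tuning": s_tun, "manual": s_man, "brain": s_brain},
    }
    if out_dir is not None:
        from .io import save_kf, write_session

        out_dir = Path(out_dir)
        write_session(manual, out_dir / "manual")
        write_session(brain, out_dir / "brain")
        save_kf(kf, out_dir / "kf.json")
    return out
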