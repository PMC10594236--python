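"""Synthetic virtual-finger task and lagged linear neural generator.

The simulated subject is a proportional feedback controller: in every 50 ms
bin it commands a velocity proportional to the signed distance of each finger
group to its target center, plus Gaussian motor noise.  The noise is what
produces movements away from the target ("execution errors") at a
controllable rate.  Neural channels are generated from the kinematics with
the lagged linear tuning in :class:`~fingerbmi.config.TuningModel`.
"""

from __future__ import annotations

import numpy as np

from .config import TaskConfig, TuningModel
from .errors import ConfigurationError
from .session import SimSession, make_trial_table

__all__ = [
    "generate_targets",
    "simulate_intent",
    "generate_sbp",
    "simulate_session",
    "away_indicator",
]


def generate_targets(cfg: TaskConfig, rng_seed: int) -> np.ndarray:
    """Per-trial target centers, shape (n_trials, n_groups).

    Centers are drawn uniformly from the sub-interval in which the full
    target extent fits inside ``position_range``; consecutive trials are
    guaranteed to differ in at least one finger group.
    """
    lo, hi = cfg.position_range
    c_lo, c_hi = lo + cfg.target_half_width, hi - cfg.target_half_width
    if c_hi < c_lo:
        raise ConfigurationError("target_half_width too large for position_range")
    if cfg.n_trials == 0:
        return np.empty((0, cfg.n_finger_groups))
    if c_hi == c_lo and cfg.n_trials > 1:
        raise ConfigurationError(
            "target_half_width so large that only one target center fits; "
            "consecutive trials cannot differ"
        )
    rng = np.random.default_rng(rng_seed)
    centers = rng.uniform(c_lo, c_hi, size=(cfg.n_trials, cfg.n_finger_groups))
    for t in range(1, cfg.n_trials):
        while np.all(centers[t] == centers[t - 1]):  # measure-zero guard
            centers[t] = rng.uniform(c_lo, c_hi, size=cfg.n_finger_groups)
    return centers


def simulate_intent(
    cfg: TaskConfig,
    targets: np.ndarray,
    gain: float = 3.0,
    motor_noise_sd: float = 0.4,
    motor_noise_ar: float = 0.85,
    rng_seed: int = 0,
) -> SimSession:
    """Manual-control kinematics: velocity = gain * D + motor noise.

    ``gain`` is in 1/s (fraction of the remaining distance closed per
    second), ``motor_noise_sd`` in arc units/s.  The motor noise is AR(1)
    over bins with coefficient ``motor_noise_ar`` and stationary standard
    deviation ``motor_noise_sd``: command errors are smooth and persist for
    a few hundred ms, producing sustained movements away from the target
    rather than bin-to-bin jitter (``motor_noise_ar=0`` recovers white
    noise).  Positions are integrated at bin width and clipped to
    ``position_range``.  A trial ends at success (every finger group inside
    its target for ``hold_time_ms``) or timeout.
    """
    if gain <= 0:
        raise ConfigurationError("controller gain must be positive")
    if not 0 <= motor_noise_ar < 1:
        raise ConfigurationError("motor_noise_ar must be in [0, 1)")
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    n_trials, n_groups = targets.shape
    if n_groups != cfg.n_finger_groups:
        raise ConfigurationError("target schedule does not match n_finger_groups")
    rng = np.random.default_rng(rng_seed)
    dt = cfg.dt_s
    lo, hi = cfg.position_range
    hw = cfg.target_half_width
    hold_bins, timeout_bins = cfg.hold_bins, cfg.timeout_bins

    p = np.full(n_groups, 0.5 * (lo + hi))
    eta = np.zeros(n_groups)  # AR(1) motor-noise state
    innov_sd = motor_noise_sd * np.sqrt(1.0 - motor_noise_ar**2)
    pos_l, vel_l, tgt_l, records = [], [], [], []
    k = 0
    for trial in range(n_trials):
        t = targets[trial]
        start = k
        hold = 0
        success = False
        for _ in range(timeout_bins):
            d = t - p
            if np.all(np.abs(d) <= hw):
                hold += 1
            else:
                hold = 0
            if motor_noise_sd:
                eta = motor_noise_ar * eta + rng.normal(0.0, innov_sd, n_groups)
            v = gain * d + eta
            pos_l.append(p.copy())
            vel_l.append(v)
            tgt_l.append(t.copy())
            p = np.clip(p + dt * v, lo, hi)
            k += 1
            if hold >= hold_bins:
                success = True
                break
        rec = {"trial": trial, "start_bin": start, "end_bin": k - 1, "success": success}
        rec.update({f"target_{g}": t[g] for g in range(n_groups)})
        records.append(rec)

    return SimSession(
        mode="manual",
        config=cfg,
        pos=np.array(pos_l).reshape(k, n_groups),
        vel=np.array(vel_l).reshape(k, n_groups),
        target=np.array(tgt_l).reshape(k, n_groups),
        trials=make_trial_table(records, n_groups),
        seeds={"intent": int(rng_seed)},
    )


def _lagged(arr: np.ndarray, lag: int) -> np.ndarray:
    """arr evaluated at bin k + lag, replicate-padded at the session edges."""
    n = arr.shape[0]
    if abs(lag) >= n:
        raise ValueError(f"lag {lag} exceeds session length {n}")
    idx = np.clip(np.arange(n) + lag, 0, n - 1)
    return arr[idx]


def away_indicator(vel: np.ndarray, dist: np.ndarray) -> np.ndarray:
    """Per-bin, per-group boolean: movement strictly away from the target
    center (velocity increases |D|, i.e. V * D < 0)."""
    return vel * dist < 0


def generate_sbp(session: SimSession, tuning: TuningModel, rng_seed: int = 0) -> np.ndarray:
    """Binned spiking-band-power matrix (n_bins, n_channels) generated from
    the session kinematics under the lagged linear tuning model."""
    if tuning.n_groups != session.n_groups:
        raise ConfigurationError("tuning model group count does not match session")
    n = session.n_bins
    for lag in (tuning.position_lag, tuning.velocity_lag, tuning.distance_lag, tuning.error_lag):
        if abs(lag) >= n:
            raise ValueError(f"lag {lag} exceeds session length {n}")
    rng = np.random.default_rng(rng_seed)
    p = _lagged(session.pos, tuning.position_lag)
    v = _lagged(session.vel, tuning.velocity_lag)
    d = _lagged(session.dist, tuning.distance_lag)
    away = _lagged(away_indicator(session.vel, session.dist).astype(float), tuning.error_lag)
    sbp = (
        tuning.w0[None, :]
        + p @ tuning.w_p.T
        + v @ tuning.w_v.T
        + d @ tuning.w_d.T
        + away @ tuning.error_gain.T
    )
    if np.any(tuning.noise_sd > 0):
        sbp = sbp + rng.normal(0.0, 1.0, sbp.shape) * tuning.noise_sd[None, :]
    if not np.all(np.isfinite(sbp)):
        raise FloatingPointError("generated SBP contains non-finite values")
    return sbp


def simulate_session(
    cfg: TaskConfig,
    tuning: TuningModel,
    gain: float = 3.0,
    motor_noise_sd: float = 0.4,
    motor_noise_ar: float = 0.85,
    rng_seed: int = 0,
) -> SimSession:
    """Full manual-control session: targets, intent kinematics and SBP.

    Sub-seeds for the three stages are derived deterministically from
    ``rng_seed``.
    """
    ss = np.random.SeedSequence(rng_seed)
    s_tgt, s_int, s_sbp = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)]
    targets = generate_targets(cfg, s_tgt)
    session = simulate_intent(
        cfg,
        targets,
        gain=gain,
        motor_noise_sd=motor_noise_sd,
        motor_noise_ar=motor_noise_ar,
        rng_seed=s_int,
    )
    sbp = generate_sbp(session, tuning, rng_seed=s_sbp)
    out = session.with_sbp(sbp, tuning)
    out.seeds.update({"root": int(rng_seed), "targets": s_tgt, "intent": s_int, "sbp": s_sbp})
    return out
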