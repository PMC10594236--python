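"""Task and neural-tuning configuration.

All times are milliseconds, arc positions are dimensionless fractions in
``position_range`` (default [0, 1]), velocities are arc fractions per second.
Flexion is movement toward increasing arc position, extension toward
decreasing position.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import ConfigurationError

#: default lag placement, in bins, of each kinematic term in the neural
#: generator: SBP in bin k reflects the kinematic value at bin k + lag, so a
#: negative lag means the kinematics precede the neural activity.  Motor
#: cortex activity tracks velocity with no appreciable lag, lags the distance
#: to target by ~200 ms (4 bins of 50 ms), and lags the position by ~300 ms.
DEFAULT_VELOCITY_LAG = 0
DEFAULT_DISTANCE_LAG = -4
DEFAULT_POSITION_LAG = -6
#: the direct error drive reflects visual feedback of the previous bin's
#: rendered movement (one-bin feedback latency).
DEFAULT_ERROR_LAG = -1

MIN_CHANNELS = 8


@dataclass
class TaskConfig:
    """Geometry and timing of the virtual-finger target-acquisition task.

    Parameters
    ----------
    n_finger_groups : 1 for the single-finger task (all fingers move as one
        group), 2 for the two-group task (index + middle-ring-small).
    bin_width_ms : neural/kinematic binning interval.
    hold_time_ms : continuous in-target dwell required of every finger group
        for trial success (500 ms online; 750 ms is conventional for
        manual-control training sessions).
    trial_timeout_ms : trial fails if the hold is not completed in time.
    target_half_width : half extent of each target along its arc.
    position_range : closed interval of reachable arc positions.
    n_trials : default number of trials per run.
    """

    n_finger_groups: int = 2
    bin_width_ms: float = 50.0
    hold_time_ms: float = 500.0
    trial_timeout_ms: float = 10_000.0
    target_half_width: float = 0.1
    position_range: tuple[float, float] = (0.0, 1.0)
    n_trials: int = 100

    def __post_init__(self) -> None:
        if self.n_finger_groups not in (1, 2):
            raise ConfigurationError("n_finger_groups must be 1 or 2")
        if self.bin_width_ms <= 0:
            raise ConfigurationError("bin_width_ms must be positive")
        ratio = self.hold_time_ms / self.bin_width_ms
        if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
            raise ConfigurationError(
                "hold_time_ms must be a positive integer multiple of bin_width_ms"
            )
        if self.trial_timeout_ms <= 0:
            raise ConfigurationError("trial_timeout_ms must be positive")
        if self.target_half_width <= 0:
            raise ConfigurationError("target_half_width must be positive")
        lo, hi = self.position_range
        if not hi > lo:
            raise ConfigurationError("position_range must be a nonempty interval")
        if hi - lo < 2 * self.target_half_width:
            raise ConfigurationError(
                "target_half_width too large: no target fits inside position_range"
            )
        if self.n_trials < 0:
            raise ConfigurationError("n_trials must be non-negative")

    @property
    def dt_s(self) -> float:
        return self.bin_width_ms / 1000.0

    @property
    def hold_bins(self) -> int:
        return int(round(self.hold_time_ms / self.bin_width_ms))

    @property
    def timeout_bins(self) -> int:
        return max(1, int(np.ceil(self.trial_timeout_ms / self.bin_width_ms)))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["position_range"] = list(self.position_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TaskConfig":
        d = dict(d)
        if "position_range" in d:
            d["position_range"] = tuple(d["position_range"])
        return cls(**d)


@dataclass
class TuningModel:
    """Lagged linear encoding model of one synthetic motor-cortex population.

    Channel ``c`` produces, in bin ``k``::

        SBP(k, c) = w0[c]
                    + sum_g w_p[c, g] * P_g(k + position_lag)
                    + sum_g w_v[c, g] * V_g(k + velocity_lag)
                    + sum_g w_d[c, g] * D_g(k + distance_lag)
                    + sum_g error_gain[c, g] * 1[group g moving away](k + error_lag)
                    + noise_sd[c] * N(0, 1)

    where D = T - P is the signed distance to the target center.  The
    ``error_gain`` term is an optional direct error drive, modelling error
    processing in motor cortex over and above distance coding.
    """

    w_p: np.ndarray  # (n_channels, n_groups)
    w_v: np.ndarray
    w_d: np.ndarray
    w0: np.ndarray  # (n_channels,)
    noise_sd: np.ndarray  # (n_channels,)
    error_gain: np.ndarray  # (n_channels, n_groups), >= 0
    velocity_lag: int = DEFAULT_VELOCITY_LAG
    distance_lag: int = DEFAULT_DISTANCE_LAG
    position_lag: int = DEFAULT_POSITION_LAG
    error_lag: int = DEFAULT_ERROR_LAG

    def __post_init__(self) -> None:
        for name in ("w_p", "w_v", "w_d", "w0", "noise_sd", "error_gain"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        c, g = self.w_p.shape
        if c < MIN_CHANNELS:
            raise ConfigurationError(f"at least {MIN_CHANNELS} channels required, got {c}")
        for name in ("w_v", "w_d", "error_gain"):
            if getattr(self, name).shape != (c, g):
                raise ConfigurationError(f"{name} must have shape {(c, g)}")
        if self.w0.shape != (c,) or self.noise_sd.shape != (c,):
            raise ConfigurationError("w0 and noise_sd must be per-channel vectors")
        if np.any(self.noise_sd < 0):
            raise ConfigurationError("noise_sd must be non-negative")
        if np.any(self.error_gain < 0):
            raise ConfigurationError("error_gain must be non-negative")

    @property
    def n_channels(self) -> int:
        return self.w_p.shape[0]

    @property
    def n_groups(self) -> int:
        return self.w_p.shape[1]

    @classmethod
    def random(
        cls,
        n_channels: int = 16,
        n_groups: int = 2,
        rng_seed: int = 0,
        w_p_scale: float = 0.2,
        w_v_scale: float = 0.5,
        w_d_scale: float = 1.5,
        bias: float = 1.0,
        noise_sd: float = 0.4,
        error_gain_scale: float = 0.0,
        velocity_lag: int = DEFAULT_VELOCITY_LAG,
        distance_lag: int = DEFAULT_DISTANCE_LAG,
        position_lag: int = DEFAULT_POSITION_LAG,
        error_lag: int = DEFAULT_ERROR_LAG,
    ) -> "TuningModel":
        """Draw a random population: Gaussian kinematic weights, half-normal
        error gains (non-negative by construction)."""
        rng = np.random.default_rng(rng_seed)
        shape = (n_channels, n_groups)
        return cls(
            w_p=rng.normal(0.0, w_p_scale, shape) if w_p_scale else np.zeros(shape),
            w_v=rng.normal(0.0, w_v_scale, shape) if w_v_scale else np.zeros(shape),
            w_d=rng.normal(0.0, w_d_scale, shape) if w_d_scale else np.zeros(shape),
            w0=rng.normal(bias, 0.2, n_channels),
            noise_sd=np.full(n_channels, float(noise_sd)),
            error_gain=(
                np.abs(rng.normal(0.0, error_gain_scale, shape))
                if error_gain_scale
                else np.zeros(shape)
            ),
            velocity_lag=velocity_lag,
            distance_lag=distance_lag,
            position_lag=position_lag,
            error_lag=error_lag,
        )

    def to_dict(self) -> dict:
        return {
            "w_p": self.w_p.tolist(),
            "w_v": self.w_v.tolist(),
            "w_d": self.w_d.tolist(),
            "w0": self.w0.tolist(),
            "noise_sd": self.noise_sd.tolist(),
            "error_gain": self.error_gain.tolist(),
            "velocity_lag": self.velocity_lag,
            "distance_lag": self.distance_lag,
            "position_lag": self.position_lag,
            "error_lag": self.error_lag,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TuningModel":
        return cls(**d)


@dataclass
class CorrectionPolicy:
    """Two-step stopping strategy applied to detected erroneous movements:
    zero the offending group's velocity for ``stop_bins`` bins, then suspend
    further corrections of that group for ``pause_bins`` bins (avoiding
    oscillation and deadlock)."""

    stop_bins: int = 4
    pause_bins: int = 8
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.stop_bins < 1:
            raise ConfigurationError("stop_bins must be >= 1")
        if self.pause_bins < 0:
            raise ConfigurationError("pause_bins must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CorrectionPolicy":
        return cls(**d)
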