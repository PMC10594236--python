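"""In-memory container for one simulated run (manual or brain control)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import TaskConfig, TuningModel

#: trial-table columns; target columns are appended per finger group.
TRIAL_COLUMNS = ["trial", "start_bin", "end_bin", "success"]


@dataclass
class SimSession:
    """Binned kinematics, targets, neural features and trial bookkeeping.

    ``pos[k]`` is the rendered arc position of each finger group during bin
    ``k``; ``vel[k]`` the commanded velocity during that bin, so that
    ``pos[k+1] = clip(pos[k] + dt * vel[k])`` except at range boundaries.
    ``target[k]`` holds the active target centers, and the signed distance to
    the target center is always ``dist = target - pos``.
    """

    mode: str  # "manual" | "brain"
    config: TaskConfig
    pos: np.ndarray  # (n_bins, n_groups)
    vel: np.ndarray
    target: np.ndarray
    trials: pd.DataFrame
    sbp: np.ndarray | None = None  # (n_bins, n_channels)
    tuning: TuningModel | None = None
    seeds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float)
        self.vel = np.asarray(self.vel, dtype=float)
        self.target = np.asarray(self.target, dtype=float)
        if self.pos.shape != self.vel.shape or self.pos.shape != self.target.shape:
            raise ValueError("pos, vel and target must share shape (n_bins, n_groups)")
        if self.sbp is not None:
            self.sbp = np.asarray(self.sbp, dtype=float)
            if self.sbp.shape[0] != self.pos.shape[0]:
                raise ValueError("sbp must have one row per bin")

    @property
    def n_bins(self) -> int:
        return self.pos.shape[0]

    @property
    def n_groups(self) -> int:
        return self.pos.shape[1]

    @property
    def n_channels(self) -> int:
        return 0 if self.sbp is None else self.sbp.shape[1]

    @property
    def dist(self) -> np.ndarray:
        """Signed distance to the target center, D = T - P (exact by construction)."""
        return self.target - self.pos

    @property
    def trial_id(self) -> np.ndarray:
        """Per-bin trial index (-1 for bins outside any trial)."""
        tid = np.full(self.n_bins, -1, dtype=int)
        for row in self.trials.itertuples():
            tid[int(row.start_bin) : int(row.end_bin) + 1] = int(row.trial)
        return tid

    def in_target(self, half_width: float | None = None) -> np.ndarray:
        """Boolean (n_bins, n_groups): finger group inside its target extent."""
        hw = self.config.target_half_width if half_width is None else half_width
        return np.abs(self.dist) <= hw

    def with_sbp(self, sbp: np.ndarray, tuning: TuningModel | None = None) -> "SimSession":
        return SimSession(
            mode=self.mode,
            config=self.config,
            pos=self.pos,
            vel=self.vel,
            target=self.target,
            trials=self.trials,
            sbp=sbp,
            tuning=tuning if tuning is not None else self.tuning,
            seeds=dict(self.seeds),
        )


def make_trial_table(records: list[dict], n_groups: int) -> pd.DataFrame:
    cols = TRIAL_COLUMNS + [f"target_{g}" for g in range(n_groups)]
    if not records:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame.from_records(records, columns=cols)
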