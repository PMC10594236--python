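"""Velocity Kalman filter decoder mapping binned SBP to finger kinematics.

The conventional BMI formulation: state x(k) = [positions, velocities, 1],
observation y(k) = SBP(k).  Position rows of the transition matrix are fixed
to exact integration of velocity (identity + bin-width coupling, never
regressed); velocity rows and the observation matrix are least-squares
estimates from a manual-control training session, with residual covariances
as process/observation noise.  Decoding is velocity-based: the rendered
position is re-derived by integrating the decoded velocity with clipping at
the arc boundaries, and fed back into the state so the filter tracks what is
actually displayed.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .errors import SingularFitError
from .session import SimSession

__all__ = ["KalmanVelocityDecoder", "kf_step"]

_RCOND = 1e-10


def kf_step(
    A: np.ndarray,
    W: np.ndarray,
    H: np.ndarray,
    Q: np.ndarray,
    x: np.ndarray,
    P: np.ndarray,
    y: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """One predict-then-update cycle; returns posterior (x, P).

    ``A``/``W`` are the state transition and process noise, ``H``/``Q`` the
    observation matrix and observation noise.  The posterior covariance is
    symmetrized to keep it PSD under roundoff.
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite observation passed to kf_step")
    x_pred = A @ x
    P_pred = A @ P @ A.T + W
    S = H @ P_pred @ H.T + Q
    K = np.linalg.solve(S.T, (P_pred @ H.T).T).T  # P_pred H' S^-1
    x_post = x_pred + K @ (y - H @ x_pred)
    P_post = (np.eye(len(x)) - K @ H) @ P_pred
    P_post = 0.5 * (P_post + P_post.T)
    return x_post, P_post


class KalmanVelocityDecoder(BaseEstimator):
    """Sklearn-style estimator: ``fit`` on a manual session, ``predict``
    decoded kinematics from an SBP stream.

    Parameters
    ----------
    activity_floor : channels whose mean activity is at or below this floor
        are excluded from decoding (emulating the convention of keeping only
        channels with appreciable firing).  ``None`` keeps every channel.
    position_range : decoded positions are clipped to this interval.
    """

    def __init__(
        self,
        activity_floor: float | None = None,
        position_range: tuple[float, float] = (0.0, 1.0),
    ):
        self.activity_floor = activity_floor
        self.position_range = position_range

    # ------------------------------------------------------------------ fit
    def fit(self, sbp: np.ndarray, pos: np.ndarray, vel: np.ndarray, bin_width_ms: float = 50.0):
        sbp = np.asarray(sbp, dtype=float)
        pos = np.atleast_2d(np.asarray(pos, dtype=float))
        vel = np.atleast_2d(np.asarray(vel, dtype=float))
        if pos.shape[0] == 1 and pos.shape[1] > 2:  # row vector passed for 1-D task
            pos, vel = pos.T, vel.T
        n, n_groups = pos.shape
        if sbp.shape[0] != n:
            raise ValueError("sbp and kinematics must have one row per bin")
        if sbp.shape[1] < 2:
            raise ValueError("at least 2 channels required")
        if n < 1000:
            raise ValueError("training session must have at least 1000 bins")

        channels = np.arange(sbp.shape[1])
        if self.activity_floor is not None:
            channels = channels[sbp.mean(axis=0) > self.activity_floor]
            if len(channels) < 2:
                raise ValueError("fewer than 2 channels above activity_floor")
        Z = sbp[:, channels]

        dt = bin_width_ms / 1000.0
        dim = 2 * n_groups + 1
        X = np.column_stack([pos, vel, np.ones(n)])  # state at bin k

        # velocity rows: V(k+1) ~ full state at k
        coef_v, *_ = np.linalg.lstsq(X[:-1], vel[1:], rcond=None)
        resid_v = vel[1:] - X[:-1] @ coef_v
        A = np.zeros((dim, dim))
        A[:n_groups, :n_groups] = np.eye(n_groups)
        A[:n_groups, n_groups : 2 * n_groups] = dt * np.eye(n_groups)
        A[n_groups : 2 * n_groups, :] = coef_v.T
        A[-1, -1] = 1.0
        W = np.zeros((dim, dim))
        denom = max(1, len(resid_v) - 1)
        W[n_groups : 2 * n_groups, n_groups : 2 * n_groups] = resid_v.T @ resid_v / denom

        # observation: SBP(k) ~ state at k
        coef_h, *_ = np.linalg.lstsq(X, Z, rcond=None)
        resid_h = Z - X @ coef_h
        H = coef_h.T
        Q = resid_h.T @ resid_h / max(1, n - 1)
        Q = 0.5 * (Q + Q.T)
        self._check_observability(Q, resid_h, channels)

        # C-contiguous copies: keeps decode output bit-identical across a
        # JSON serialization round trip (summation order in BLAS)
        self.A_, self.W_, self.H_, self.Q_ = (
            np.ascontiguousarray(m) for m in (A, W, H, Q)
        )
        self.channels_ = channels
        self.n_groups_ = n_groups
        self.dt_ = dt
        self.n_features_in_ = sbp.shape[1]
        self.train_meta_ = {"n_bins": int(n), "n_channels": int(len(channels))}
        return self

    @staticmethod
    def _check_observability(Q: np.ndarray, resid: np.ndarray, channels: np.ndarray) -> None:
        eig = np.linalg.eigvalsh(Q)
        if eig[0] > _RCOND * max(eig[-1], _RCOND):
            return
        # name offending channels: zero-variance residuals or perfectly
        # correlated residual pairs
        sd = np.sqrt(np.diag(Q))
        offenders: list[str] = [f"channel {channels[i]}" for i in np.where(sd <= _RCOND)[0]]
        ok = sd > _RCOND
        if ok.sum() >= 2:
            corr = np.corrcoef(resid[:, ok].T)
            ii, jj = np.where(np.triu(np.abs(corr) > 1 - 1e-8, k=1))
            idx = channels[ok]
            offenders += [f"channels {idx[i]} and {idx[j]}" for i, j in zip(ii, jj)]
        raise SingularFitError(
            "observation noise covariance is singular (collinear channels): "
            + ("; ".join(offenders) if offenders else "unidentified channel set")
        )

    # -------------------------------------------------------------- predict
    def initial_state(self, pos0: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        lo, hi = self.position_range
        x = np.zeros(2 * self.n_groups_ + 1)
        x[: self.n_groups_] = 0.5 * (lo + hi) if pos0 is None else np.asarray(pos0, dtype=float)
        x[-1] = 1.0
        P = self.W_ + 1e-4 * np.eye(len(x))
        return x, P

    def predict(self, sbp: np.ndarray, pos0: np.ndarray | None = None):
        """Open-loop decode of an SBP stream.

        Returns ``(pos_dec, vel_dec)``; the decoded position integrates the
        decoded velocity (clipped to the arc range) and is written back into
        the filter state after every update, mirroring the online loop where
        the rendered kinematics feed the next filter update.
        """
        sbp = np.asarray(sbp, dtype=float)
        if sbp.shape[1] != self.n_features_in_:
            raise ValueError(
                f"sbp has {sbp.shape[1]} channels, model trained on {self.n_features_in_}"
            )
        Z = sbp[:, self.channels_]
        g = self.n_groups_
        lo, hi = self.position_range
        x, P = self.initial_state(pos0)
        p_disp = x[:g].copy()
        pos_out = np.empty((len(Z), g))
        vel_out = np.empty((len(Z), g))
        for k in range(len(Z)):
            x, P = kf_step(self.A_, self.W_, self.H_, self.Q_, x, P, Z[k])
            v = x[g : 2 * g]
            pos_out[k] = p_disp
            vel_out[k] = v
            p_disp = np.clip(p_disp + self.dt_ * v, lo, hi)
            x[:g] = p_disp
        return pos_out, vel_out

    def fit_session(self, session: SimSession):
        """Convenience: fit from a manual-control :class:`SimSession`."""
        if session.sbp is None:
            raise ValueError("session has no SBP")
        return self.fit(
            session.sbp, session.pos, session.vel, bin_width_ms=session.config.bin_width_ms
        )
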