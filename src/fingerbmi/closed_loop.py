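"""Closed-loop brain-control simulation with online error correction.

Every 50 ms bin: the simulated subject forms an intended velocity toward the
targets from the currently rendered finger positions; the tuning model turns
the (lagged) kinematic history into one bin of SBP; the Kalman filter
updates; the correction policy (if a stop is active) zeroes the offending
group's velocity; the corrected velocity is integrated into the rendered
position, which is written back into the filter state for the next update.
At the end of the bin each finger group's last N corrected velocity bins are
checked for a consistent movement, and if so the matching detector scores
the N-bin SBP block; a flag triggers the two-step stopping policy (stop for
``stop_bins``, suppress further corrections for ``pause_bins``).

Performance is summarized per trial by time to first acquire (TFA), orbiting
time (OT) and total time to target (TTT), and phases are compared with a
one-sided Wilcoxon rank-sum test in an ABA design (monitoring, correction,
monitoring).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import CorrectionPolicy, TaskConfig, TuningModel
from .detection import DEFAULT_N_BINS, DetectorBank, label_segments
from .errors import ConfigurationError
from .kalman import KalmanVelocityDecoder, kf_step
from .session import SimSession, make_trial_table
from .simulator import generate_targets

__all__ = [
    "run_closed_loop",
    "tag_detections",
    "compute_trial_metrics",
    "distance_histograms",
    "DistanceDistributions",
    "rank_sum_less",
    "compare_aba",
]

# per-group correction states logged per bin
STATE_IDLE, STATE_STOPPING, STATE_PAUSED = 0, 1, 2


def run_closed_loop(
    kf: KalmanVelocityDecoder,
    cfg: TaskConfig,
    tuning: TuningModel,
    bank: DetectorBank | None = None,
    policy: CorrectionPolicy | None = None,
    gain: float = 3.0,
    motor_noise_sd: float = 0.4,
    motor_noise_ar: float = 0.85,
    rng_seed: int = 0,
    n_trials: int | None = None,
    oracle: bool = False,
    n_window: int = DEFAULT_N_BINS,
    phase: str = "",
) -> tuple[SimSession, pd.DataFrame]:
    """Run one brain-control phase; returns the session and a per-bin log.

    ``bank=None`` with ``oracle=False`` is pure monitoring-free brain
    control (phase II); ``oracle=True`` substitutes the ground-truth
    away-segment flag for the classifier.  Correction is applied only when
    ``policy.enabled``; with a disabled policy detections are logged but the
    kinematics pass through unchanged (phase III monitoring).
    """
    if tuning.n_groups != cfg.n_finger_groups:
        raise ConfigurationError("tuning model group count does not match task config")
    if bank is not None and not np.array_equal(
        np.sort(bank.channels), np.sort(kf.channels_)
    ):
        raise ValueError("detector bank and Kalman filter use different channel sets")
    if bank is not None:
        n_window = bank.n_window
    policy = policy if policy is not None else CorrectionPolicy()
    g_count = cfg.n_finger_groups
    dt = cfg.dt_s
    lo, hi = cfg.position_range
    hw = cfg.target_half_width

    ss = np.random.SeedSequence(rng_seed)
    s_tgt, s_noise, s_mnoise = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)]
    run_cfg = cfg if n_trials is None else TaskConfig.from_dict({**cfg.to_dict(), "n_trials": n_trials})
    targets = generate_targets(run_cfg, s_tgt)
    rng_sbp = np.random.default_rng(s_noise)
    rng_motor = np.random.default_rng(s_mnoise)

    if not 0 <= motor_noise_ar < 1:
        raise ConfigurationError("motor_noise_ar must be in [0, 1)")
    eta = np.zeros(g_count)  # AR(1) motor-noise state
    innov_sd = motor_noise_sd * np.sqrt(1.0 - motor_noise_ar**2)

    x, P = kf.initial_state()
    p_disp = x[:g_count].copy()

    pos_l: list[np.ndarray] = []
    vel_corr_l: list[np.ndarray] = []
    vel_dec_l: list[np.ndarray] = []
    tgt_l: list[np.ndarray] = []
    sbp_l: list[np.ndarray] = []
    log_rows: list[dict] = []
    records: list[dict] = []

    stop_rem = np.zeros(g_count, dtype=int)
    pause_rem = np.zeros(g_count, dtype=int)

    def hist(lst: list[np.ndarray], k: int, lag: int, current: np.ndarray) -> np.ndarray:
        """Value at bin k + lag from the rendered history (replicate-padded);
        lag 0 returns the current bin's value."""
        if lag == 0:
            return current
        j = max(0, k + lag)
        if j >= len(lst):
            return current
        return lst[j]

    k = 0
    for trial in range(run_cfg.n_trials):
        t = targets[trial]
        start = k
        hold = 0
        success = False
        for _ in range(cfg.timeout_bins):
            d_disp = t - p_disp
            if np.all(np.abs(d_disp) <= hw):
                hold += 1
            else:
                hold = 0
            if motor_noise_sd:
                eta = motor_noise_ar * eta + rng_motor.normal(0.0, innov_sd, g_count)
            v_int = gain * d_disp + eta

            # ---- neural generation from lagged rendered kinematics
            p_lag = hist(pos_l, k, tuning.position_lag, p_disp)
            d_lag = (hist(tgt_l, k, tuning.distance_lag, t)
                     - hist(pos_l, k, tuning.distance_lag, p_disp))
            if k == 0:
                away_prev = np.zeros(g_count)
            else:
                # online, only committed bins exist: error_lag 0 degrades to
                # the previous bin (one-bin feedback latency)
                j = min(max(0, k + min(tuning.error_lag, -1)), len(vel_corr_l) - 1)
                away_prev = (
                    vel_corr_l[j] * (tgt_l[j] - pos_l[j]) < 0
                ).astype(float)
            sbp_k = (
                tuning.w0
                + tuning.w_p @ p_lag
                + tuning.w_v @ v_int
                + tuning.w_d @ d_lag
                + tuning.error_gain @ away_prev
            )
            if np.any(tuning.noise_sd > 0):
                sbp_k = sbp_k + rng_sbp.normal(0.0, 1.0, tuning.n_channels) * tuning.noise_sd

            # ---- decode
            x, P = kf_step(kf.A_, kf.W_, kf.H_, kf.Q_, x, P, sbp_k[kf.channels_])
            v_dec = x[g_count : 2 * g_count].copy()

            # ---- correction state for this bin
            state_k = np.full(g_count, STATE_IDLE, dtype=int)
            for g in range(g_count):
                if stop_rem[g] > 0:
                    state_k[g] = STATE_STOPPING
                    stop_rem[g] -= 1
                elif pause_rem[g] > 0:
                    state_k[g] = STATE_PAUSED
                    pause_rem[g] -= 1
            v_corr = v_dec.copy()
            stopped = state_k == STATE_STOPPING
            v_corr[stopped] = 0.0
            x[g_count : 2 * g_count][stopped] = 0.0  # corrected velocity feeds the KF

            pos_l.append(p_disp.copy())
            vel_dec_l.append(v_dec)
            vel_corr_l.append(v_corr)
            tgt_l.append(t.copy())
            sbp_l.append(sbp_k)

            # ---- detection on the segment ending at this bin
            raw_flag = np.zeros(g_count, dtype=bool)
            eff_flag = np.zeros(g_count, dtype=bool)
            score_k = np.full(g_count, np.nan)
            if (bank is not None or oracle) and k - start + 1 >= n_window:
                w = slice(k - n_window + 1, k + 1)
                vw = np.array(vel_corr_l[w.start : w.stop])
                dw = np.array(tgt_l[w.start : w.stop]) - np.array(pos_l[w.start : w.stop])
                for g in range(g_count):
                    if oracle:
                        raw_flag[g] = bool(np.all(vw[:, g] * dw[:, g] < 0))
                    else:
                        if np.all(vw[:, g] > 0):
                            mt = "flexion"
                        elif np.all(vw[:, g] < 0):
                            mt = "extension"
                        else:
                            continue
                        if (g, mt) not in bank:
                            continue
                        det = bank.get(g, mt)
                        feats = np.array(sbp_l[w.start : w.stop])[:, bank.channels].ravel()
                        score_k[g] = float(det.score(feats)[0])
                        raw_flag[g] = score_k[g] >= det.threshold
                    if raw_flag[g] and state_k[g] == STATE_IDLE:
                        eff_flag[g] = True
                        if policy.enabled:
                            stop_rem[g] = policy.stop_bins
                            pause_rem[g] = policy.pause_bins

            log_rows.append(
                {
                    "bin": k,
                    "trial": trial,
                    "phase": phase,
                    **{f"v_dec_{g}": v_dec[g] for g in range(g_count)},
                    **{f"v_corr_{g}": v_corr[g] for g in range(g_count)},
                    **{f"state_{g}": state_k[g] for g in range(g_count)},
                    **{f"score_{g}": score_k[g] for g in range(g_count)},
                    **{f"raw_flag_{g}": raw_flag[g] for g in range(g_count)},
                    **{f"flag_{g}": eff_flag[g] for g in range(g_count)},
                }
            )

            # ---- render: corrected velocity moves the virtual fingers
            p_disp = np.clip(p_disp + dt * v_corr, lo, hi)
            x[:g_count] = p_disp  # rendered position feeds the next KF update
            k += 1
            if hold >= cfg.hold_bins:
                success = True
                break
        rec = {"trial": trial, "start_bin": start, "end_bin": k - 1, "success": success}
        rec.update({f"target_{g}": t[g] for g in range(g_count)})
        records.append(rec)

    session = SimSession(
        mode="brain",
        config=run_cfg,
        pos=np.array(pos_l).reshape(k, g_count),
        vel=np.array(vel_corr_l).reshape(k, g_count),
        target=np.array(tgt_l).reshape(k, g_count),
        trials=make_trial_table(records, g_count),
        sbp=np.array(sbp_l).reshape(k, tuning.n_channels),
        tuning=tuning,
        seeds={"root": int(rng_seed), "targets": s_tgt, "sbp_noise": s_noise, "motor": s_mnoise},
    )
    log = pd.DataFrame(log_rows)
    log.attrs["phase"] = phase
    log.attrs["n_window"] = n_window
    return session, log


def tag_detections(session: SimSession, log: pd.DataFrame, n_window: int | None = None) -> pd.DataFrame:
    """Tag every effective detector flag as TP/FP against the offline labeler
    applied to the logged (corrected) trajectory.

    A flag at bin k for group g is a TP when the N-bin segment ending at k is
    labeled 'away', an FP when labeled 'toward', and untagged otherwise.
    """
    n_window = n_window if n_window is not None else int(log.attrs.get("n_window", DEFAULT_N_BINS))
    segs = label_segments(session, n_window=n_window)
    dir_map = {
        (int(r.end_bin), int(r.group)): r.direction for r in segs.meta.itertuples()
    }
    rows = []
    for g in range(session.n_groups):
        flagged = log.loc[log[f"flag_{g}"], "bin"]
        for k in flagged:
            d = dir_map.get((int(k), g))
            tag = {"away": "TP", "toward": "FP"}.get(d)
            rows.append({"bin": int(k), "group": g, "direction": d, "tag": tag})
    return pd.DataFrame(rows, columns=["bin", "group", "direction", "tag"])


# --------------------------------------------------------------------------
# trial metrics
# --------------------------------------------------------------------------
def compute_trial_metrics(session: SimSession) -> pd.DataFrame:
    """Per-trial TFA and OT per finger group, trial-level TTT and success.

    Conventions (bin k spans [k, k+1) bin widths from trial start): TFA is
    the time elapsed before the first in-target bin; OT is the time between
    first acquisition and the final (re)entry after which the group stays in
    target to the trial's end -- zero when it never leaves once entered; TTT
    = trial duration - hold time, reported for successful trials only.
    """
    if len(session.trials) == 0:
        raise ValueError("session has an empty trial table")
    bw = session.config.bin_width_ms
    hold = session.config.hold_time_ms
    inside = session.in_target()
    rows = []
    for r in session.trials.itertuples():
        s, e = int(r.start_bin), int(r.end_bin)
        duration = (e - s + 1) * bw
        row: dict = {
            "trial": int(r.trial),
            "success": bool(r.success),
            "duration_ms": duration,
            "ttt_ms": duration - hold if r.success else np.nan,
        }
        for g in range(session.n_groups):
            win = inside[s : e + 1, g]
            if not win.any():
                row[f"tfa_ms_{g}"] = np.nan  # never acquired
                row[f"ot_ms_{g}"] = np.nan
            else:
                f = int(np.argmax(win))
                row[f"tfa_ms_{g}"] = f * bw
                out_after = np.where(~win[f:])[0]
                if len(out_after) == 0:
                    row[f"ot_ms_{g}"] = 0.0
                else:
                    last_out = f + int(out_after[-1])
                    if last_out == len(win) - 1:
                        row[f"ot_ms_{g}"] = np.nan  # outside target at trial end
                    else:
                        row[f"ot_ms_{g}"] = (last_out + 1 - f) * bw
        rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# distance distributions
# --------------------------------------------------------------------------
@dataclass
class DistanceDistributions:
    """Normalized histograms (mass sums to 1) of one finger group's distance
    to target under four conditions: every bin (total), bins ending an
    away-labeled segment (errors), and bins with TP / FP detections."""

    edges: np.ndarray
    mass: dict[str, np.ndarray]
    stats: pd.DataFrame  # mean, sd, n, frac_inside per condition


def distance_histograms(
    session: SimSession,
    log: pd.DataFrame | None = None,
    group: int | None = None,
    n_window: int = DEFAULT_N_BINS,
    edges: np.ndarray | None = None,
) -> DistanceDistributions:
    """Distance-to-target distributions motivating the stopping strategy.

    ``group`` defaults to the last finger group (MRS in the two-group task).
    """
    g = session.n_groups - 1 if group is None else group
    if edges is None:
        edges = np.linspace(-1.0, 1.0, 41)
    d = session.dist[:, g]
    segs = label_segments(session, n_window=n_window)
    m = segs.meta
    err_bins = m.loc[(m["group"] == g) & (m["direction"] == "away"), "end_bin"].to_numpy()
    samples = {"total": d, "errors": d[err_bins]}
    if log is not None and f"flag_{g}" in log.columns:
        tags = tag_detections(session, log, n_window=n_window)
        tg = tags[tags["group"] == g]
        samples["tps"] = d[tg.loc[tg["tag"] == "TP", "bin"].to_numpy()]
        samples["fps"] = d[tg.loc[tg["tag"] == "FP", "bin"].to_numpy()]
    hw = session.config.target_half_width
    mass, rows = {}, []
    for name, x in samples.items():
        if len(x) == 0:
            warnings.warn(f"no samples for condition {name!r}", RuntimeWarning, stacklevel=2)
            mass[name] = np.zeros(len(edges) - 1)
            rows.append({"condition": name, "mean": np.nan, "sd": np.nan, "n": 0,
                         "frac_inside": np.nan})
            continue
        xc = np.clip(x, edges[0], edges[-1])
        h, _ = np.histogram(xc, bins=edges)
        mass[name] = h / h.sum()
        rows.append(
            {
                "condition": name,
                "mean": float(np.mean(x)),
                "sd": float(np.std(x, ddof=1)) if len(x) > 1 else 0.0,
                "n": int(len(x)),
                "frac_inside": float(np.mean(np.abs(x) <= hw)),
            }
        )
    return DistanceDistributions(edges=edges, mass=mass, stats=pd.DataFrame(rows).set_index("condition"))


# --------------------------------------------------------------------------
# ABA comparison
# --------------------------------------------------------------------------
def rank_sum_less(b: np.ndarray, a: np.ndarray) -> float:
    """One-sided Wilcoxon rank-sum p-value for the alternative that ``b``
    is stochastically smaller than ``a`` (exact distribution for small
    untied samples, normal approximation with tie correction otherwise)."""
    b = np.asarray(b, dtype=float)
    a = np.asarray(a, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("rank-sum comparison requires non-empty samples")
    return float(stats.mannwhitneyu(b, a, alternative="less", method="auto").pvalue)


def compare_aba(
    metrics_a1: pd.DataFrame,
    metrics_b: pd.DataFrame,
    metrics_a2: pd.DataFrame,
    min_trials: int = 20,
) -> pd.DataFrame:
    """Compare the correction phase B against the pooled monitoring phases
    A1 + A2: one-sided rank-sum (alternative: B smaller) and mean deltas for
    TTT and per-group OT, over successful trials with defined metrics."""
    for name, m in (("A1", metrics_a1), ("B", metrics_b), ("A2", metrics_a2)):
        if len(m) == 0:
            raise ValueError(f"phase {name} has no trials")
        if len(m) < min_trials:
            warnings.warn(
                f"phase {name} has only {len(m)} trials (< {min_trials})",
                RuntimeWarning,
                stacklevel=2,
            )
    pooled_a = pd.concat([metrics_a1, metrics_a2], ignore_index=True)
    cols = ["ttt_ms"] + sorted(c for c in metrics_b.columns if c.startswith("ot_ms_"))
    rows = []
    for col in cols:
        a = pooled_a.loc[pooled_a["success"], col].dropna().to_numpy()
        b = metrics_b.loc[metrics_b["success"], col].dropna().to_numpy()
        rows.append(
            {
                "metric": col,
                "p_value": rank_sum_less(b, a),
                "mean_a": float(np.mean(a)),
                "mean_b": float(np.mean(b)),
                "mean_delta": float(np.mean(b) - np.mean(a)),
                "n_a": len(a),
                "n_b": len(b),
            }
        )
    return pd.DataFrame(rows).set_index("metric")
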