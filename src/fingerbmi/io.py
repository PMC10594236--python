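"""Session and model readers/writers plus run-configuration loading.

A session on disk is a directory with a delimited per-bin table
(``bins.csv``: bin index, trial id, per-group P/V/T/D, one column per SBP
channel), a trial table (``trials.csv``) and a JSON sidecar
(``session.json``) holding the task config, tuning model, seeds and schema
version.  Floats survive the round trip bit-exactly (shortest-repr
formatting).  Models are JSON files with matrices as nested lists.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import CorrectionPolicy, TaskConfig, TuningModel
from .detection import Detector, DetectorBank, SWLDAClassifier
from .errors import SchemaError
from .kalman import KalmanVelocityDecoder
from .session import SimSession

SCHEMA_VERSION = 1

__all__ = [
    "write_session",
    "read_session",
    "save_kf",
    "load_kf",
    "save_bank",
    "load_bank",
    "load_run_config",
    "SCHEMA_VERSION",
]


# --------------------------------------------------------------------------
# sessions
# --------------------------------------------------------------------------
def write_session(session: SimSession, path: str | Path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    g = session.n_groups
    cols = {"bin": np.arange(session.n_bins), "trial": session.trial_id}
    for i in range(g):
        cols[f"P_{i}"] = session.pos[:, i]
        cols[f"V_{i}"] = session.vel[:, i]
        cols[f"T_{i}"] = session.target[:, i]
        cols[f"D_{i}"] = session.dist[:, i]
    if session.sbp is not None:
        for c in range(session.n_channels):
            cols[f"sbp_{c:03d}"] = session.sbp[:, c]
    pd.DataFrame(cols).to_csv(path / "bins.csv", index=False, float_format="%.17g")
    session.trials.to_csv(path / "trials.csv", index=False, float_format="%.17g")
    sidecar = {
        "schema_version": SCHEMA_VERSION,
        "mode": session.mode,
        "n_bins": int(session.n_bins),
        "n_groups": g,
        "n_channels": int(session.n_channels),
        "config": session.config.to_dict(),
        "tuning": session.tuning.to_dict() if session.tuning is not None else None,
        "seeds": {k: int(v) for k, v in session.seeds.items()},
    }
    (path / "session.json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_session(path: str | Path) -> SimSession:
    path = Path(path)
    side = json.loads((path / "session.json").read_text())
    if side.get("schema_version") != SCHEMA_VERSION:
        raise SchemaError(
            f"session schema version {side.get('schema_version')} != {SCHEMA_VERSION}"
        )
    try:
        bins = pd.read_csv(path / "bins.csv", float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise SchemaError(f"malformed bins.csv: {exc}") from exc
    if len(bins) != side["n_bins"]:
        raise SchemaError(
            f"bins.csv truncated: {len(bins)} rows at line {len(bins) + 1}, "
            f"sidecar promises {side['n_bins']}"
        )
    g = side["n_groups"]
    trials = pd.read_csv(path / "trials.csv", float_precision="round_trip")
    sbp_cols = [c for c in bins.columns if c.startswith("sbp_")]
    return SimSession(
        mode=side["mode"],
        config=TaskConfig.from_dict(side["config"]),
        pos=bins[[f"P_{i}" for i in range(g)]].to_numpy(),
        vel=bins[[f"V_{i}" for i in range(g)]].to_numpy(),
        target=bins[[f"T_{i}" for i in range(g)]].to_numpy(),
        trials=trials,
        sbp=bins[sbp_cols].to_numpy() if sbp_cols else None,
        tuning=TuningModel.from_dict(side["tuning"]) if side.get("tuning") else None,
        seeds=side.get("seeds", {}),
    )


# --------------------------------------------------------------------------
# Kalman filter model
# --------------------------------------------------------------------------
def save_kf(kf: KalmanVelocityDecoder, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "schema_version": SCHEMA_VERSION,
        "kind": "kalman_velocity_decoder",
        "params": {
            "activity_floor": kf.activity_floor,
            "position_range": list(kf.position_range),
        },
        "A": kf.A_.tolist(),
        "W": kf.W_.tolist(),
        "H": kf.H_.tolist(),
        "Q": kf.Q_.tolist(),
        "channels": kf.channels_.tolist(),
        "n_groups": kf.n_groups_,
        "dt": kf.dt_,
        "n_features_in": kf.n_features_in_,
        "train_meta": kf.train_meta_,
    }
    path.write_text(json.dumps(payload))
    return path


def load_kf(path: str | Path) -> KalmanVelocityDecoder:
    d = json.loads(Path(path).read_text())
    if d.get("schema_version") != SCHEMA_VERSION or d.get("kind") != "kalman_velocity_decoder":
        raise SchemaError("not a compatible Kalman decoder file")
    kf = KalmanVelocityDecoder(
        activity_floor=d["params"]["activity_floor"],
        position_range=tuple(d["params"]["position_range"]),
    )
    kf.A_ = np.array(d["A"])
    kf.W_ = np.array(d["W"])
    kf.H_ = np.array(d["H"])
    kf.Q_ = np.array(d["Q"])
    kf.channels_ = np.array(d["channels"], dtype=int)
    kf.n_groups_ = int(d["n_groups"])
    kf.dt_ = float(d["dt"])
    kf.n_features_in_ = int(d["n_features_in"])
    kf.train_meta_ = d["train_meta"]
    return kf


# --------------------------------------------------------------------------
# detector bank (SWLDA only: the operational classifier)
# --------------------------------------------------------------------------
def _swlda_to_dict(clf: SWLDAClassifier) -> dict:
    return {
        "p_enter": clf.p_enter,
        "p_remove": clf.p_remove,
        "max_features": clf.max_features,
        "classes": clf.classes_.tolist(),
        "mean": clf.mean_.tolist(),
        "scale": clf.scale_.tolist(),
        "selected": clf.selected_.tolist(),
        "lda_coef": clf.lda_.coef_.tolist() if clf.lda_ is not None else None,
        "lda_intercept": clf.lda_.intercept_.tolist() if clf.lda_ is not None else None,
        "n_features_in": clf.n_features_in_,
    }


class _FrozenLDA:
    """Minimal stand-in for a fitted LDA: linear decision function only."""

    def __init__(self, coef: np.ndarray, intercept: np.ndarray):
        self.coef_ = coef
        self.intercept_ = intercept

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return (X @ self.coef_.T + self.intercept_).ravel()


def _swlda_from_dict(d: dict) -> SWLDAClassifier:
    clf = SWLDAClassifier(
        p_enter=d["p_enter"], p_remove=d["p_remove"], max_features=d["max_features"]
    )
    clf.classes_ = np.array(d["classes"])
    clf.mean_ = np.array(d["mean"])
    clf.scale_ = np.array(d["scale"])
    clf.selected_ = np.array(d["selected"], dtype=int)
    clf.n_features_in_ = int(d["n_features_in"])
    if d["lda_coef"] is None:
        clf.lda_ = None
    else:
        clf.lda_ = _FrozenLDA(np.array(d["lda_coef"]), np.array(d["lda_intercept"]))
    return clf


def save_bank(bank: DetectorBank, path: str | Path) -> Path:
    path = Path(path)
    dets = {}
    for (g, mt), det in bank.detectors.items():
        if not isinstance(det.clf, SWLDAClassifier):
            raise NotImplementedError(
                "only SWLDA detector banks are serializable; retrain with kind='swlda'"
            )
        dets[f"{g}:{mt}"] = {
            "clf": _swlda_to_dict(det.clf),
            "threshold": det.threshold,
            "kind": det.kind,
            "val_fpr": det.val_fpr,
            "val_tpr": det.val_tpr,
            "val_auc": det.val_auc,
            "n_train": det.n_train,
        }
    payload = {
        "schema_version": SCHEMA_VERSION,
        "kind": "detector_bank",
        "n_window": bank.n_window,
        "channels": bank.channels.tolist(),
        "fpr_limit": bank.fpr_limit,
        "meta": bank.meta,
        "detectors": dets,
    }
    path.write_text(json.dumps(payload))
    return path


def load_bank(path: str | Path) -> DetectorBank:
    d = json.loads(Path(path).read_text())
    if d.get("schema_version") != SCHEMA_VERSION or d.get("kind") != "detector_bank":
        raise SchemaError("not a compatible detector bank file")
    detectors = {}
    for key, dd in d["detectors"].items():
        g, mt = key.split(":")
        detectors[(int(g), mt)] = Detector(
            clf=_swlda_from_dict(dd["clf"]),
            threshold=float(dd["threshold"]),
            kind=dd["kind"],
            val_fpr=float(dd["val_fpr"]),
            val_tpr=float(dd["val_tpr"]),
            val_auc=float(dd["val_auc"]),
            n_train=int(dd["n_train"]),
        )
    return DetectorBank(
        detectors=detectors,
        n_window=int(d["n_window"]),
        channels=np.array(d["channels"], dtype=int),
        fpr_limit=float(d["fpr_limit"]),
        meta=d.get("meta", {}),
    )


# --------------------------------------------------------------------------
# run configuration
# --------------------------------------------------------------------------
_RUN_SECTIONS = {"task", "tuning", "policy", "simulation", "classifier", "seeds", "schema_version"}
_SIM_KEYS = {"gain", "motor_noise_sd", "motor_noise_ar"}
_CLF_KEYS = {"kind", "n_window", "fpr_limit", "train_frac", "p_enter", "p_remove", "max_features"}


def load_run_config(path: str | Path) -> dict:
    """Load a YAML/JSON run configuration; unknown keys are rejected and all
    seeds are materialized (defaults filled in)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - _RUN_SECTIONS
    if unknown:
        raise SchemaError(f"unknown config sections: {sorted(unknown)}")
    if raw.get("schema_version", SCHEMA_VERSION) != SCHEMA_VERSION:
        raise SchemaError("config schema_version mismatch")
    out: dict = {}
    task_d = raw.get("task", {})
    known_task = set(TaskConfig.__dataclass_fields__)
    if set(task_d) - known_task:
        raise SchemaError(f"unknown task keys: {sorted(set(task_d) - known_task)}")
    out["task"] = TaskConfig.from_dict(task_d)
    tun = raw.get("tuning", {})
    if "w_p" in tun:  # explicit weight matrices
        out["tuning"] = TuningModel.from_dict(tun)
    else:
        known = {
            "n_channels", "n_groups", "rng_seed", "w_p_scale", "w_v_scale", "w_d_scale",
            "bias", "noise_sd", "error_gain_scale", "velocity_lag", "distance_lag",
            "position_lag", "error_lag",
        }
        if set(tun) - known:
            raise SchemaError(f"unknown tuning keys: {sorted(set(tun) - known)}")
        tun.setdefault("n_groups", out["task"].n_finger_groups)
        out["tuning_params"] = tun
    pol = raw.get("policy", {})
    known_pol = set(CorrectionPolicy.__dataclass_fields__)
    if set(pol) - known_pol:
        raise SchemaError(f"unknown policy keys: {sorted(set(pol) - known_pol)}")
    out["policy"] = CorrectionPolicy.from_dict(pol)
    sim = raw.get("simulation", {})
    if set(sim) - _SIM_KEYS:
        raise SchemaError(f"unknown simulation keys: {sorted(set(sim) - _SIM_KEYS)}")
    out["simulation"] = {"gain": 3.0, "motor_noise_sd": 0.4, "motor_noise_ar": 0.85, **sim}
    clf = raw.get("classifier", {})
    if set(clf) - _CLF_KEYS:
        raise SchemaError(f"unknown classifier keys: {sorted(set(clf) - _CLF_KEYS)}")
    out["classifier"] = {"kind": "swlda", "n_window": 4, "fpr_limit": 0.05, **clf}
    seeds = raw.get("seeds", {})
    known_seeds = {"simulate", "detectors", "loop"}
    if set(seeds) - known_seeds:
        raise SchemaError(f"unknown seed keys: {sorted(set(seeds) - known_seeds)}")
    out["seeds"] = {k: int(seeds.get(k, 0)) for k in known_seeds}
    return out
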