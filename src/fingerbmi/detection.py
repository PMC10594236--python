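"""Detection of erroneous (away-from-target) movement segments from SBP.

A moving window of N bins (default 4, i.e. 200 ms at 50 ms bins) over the
decoded movement of each finger group yields overlapping candidate segments.
A segment is labeled 'toward' ('away') when the decoded velocity in every
one of its N bins decreases (increases) the absolute distance to the target
center, and is unlabeled otherwise; segments whose window spans a target
change are unlabeled because their direction is ill-defined.  Segments are
additionally typed by movement consistency (all-flexion, all-extension, else
inconsistent) and one detector is trained per (finger group x movement
type) on the flattened N x C block of SBP from the channels used by the
Kalman filter.  Thresholds are chosen from a validation ROC to keep the
false positive rate below 5% (or at the minimum positive FPR when 5% is
unattainable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC
from sklearn.utils.validation import check_X_y, check_array

from .errors import InsufficientSegmentsError
from .session import SimSession

__all__ = [
    "SegmentSet",
    "label_segments",
    "build_balanced_sets",
    "SWLDAClassifier",
    "train_swlda",
    "train_qda",
    "train_svm",
    "make_classifier",
    "RocCurve",
    "compute_roc",
    "select_threshold",
    "operating_point",
    "cross_validate",
    "stratify_by_location",
    "location_grid",
    "Detector",
    "DetectorBank",
    "train_detector_bank",
]

DEFAULT_N_BINS = 4
DEFAULT_FPR_LIMIT = 0.05
MOVEMENT_TYPES = ("flexion", "extension")


# --------------------------------------------------------------------------
# segment labeling
# --------------------------------------------------------------------------
@dataclass
class SegmentSet:
    """All candidate N-bin segments of one session (every end bin, every
    finger group), with features flattened bin-major (bin 0 channels, bin 1
    channels, ...)."""

    meta: pd.DataFrame  # end_bin, group, move_type, direction, location, trial
    features: np.ndarray  # (n_segments, N * n_channels)
    n_window: int
    channels: np.ndarray

    def __len__(self) -> int:
        return len(self.meta)

    def stratum(self, group: int, move_type: str, labeled: bool = True) -> np.ndarray:
        """Row indices of one (finger group x movement type) stratum."""
        m = (self.meta["group"] == group) & (self.meta["move_type"] == move_type)
        if labeled:
            m &= self.meta["direction"].isin(["toward", "away"])
        return np.where(m.to_numpy())[0]

    def labels(self, idx: np.ndarray) -> np.ndarray:
        """Binary labels for labeled segments: away = 1, toward = 0."""
        d = self.meta["direction"].to_numpy()[idx]
        if not np.all(np.isin(d, ["toward", "away"])):
            raise ValueError("labels requested for unlabeled segments")
        return (d == "away").astype(int)


def _window_all(flags: np.ndarray, n: int) -> np.ndarray:
    """For boolean flags (n_bins,), windows[k] = all(flags[k-n+1 .. k])."""
    c = np.concatenate([[0], np.cumsum(flags.astype(int))])
    return (c[n:] - c[:-n]) == n


def label_segments(
    session: SimSession,
    n_window: int = DEFAULT_N_BINS,
    channels: np.ndarray | None = None,
) -> SegmentSet:
    """Slide an N-bin window over each finger group's decoded movement and
    label every candidate segment.

    Zero decoded velocity in any bin makes the movement type inconsistent
    and the segment unlabeled.  The segment location (inside/outside target)
    is judged by the position at the segment's end bin.
    """
    if n_window < 2:
        raise ValueError("segment window must span at least 2 bins")
    if session.sbp is None:
        raise ValueError("session has no SBP")
    if len(session.trials):
        lengths = session.trials["end_bin"] - session.trials["start_bin"] + 1
        if n_window > lengths.max():
            raise ValueError(
                f"window of {n_window} bins is longer than every trial "
                f"(max {int(lengths.max())} bins)"
            )
    if session.n_bins < n_window:
        raise ValueError("session shorter than the segment window")

    chan = np.arange(session.n_channels) if channels is None else np.asarray(channels)
    sbp = session.sbp[:, chan]
    n = session.n_bins
    ends = np.arange(n_window - 1, n)
    # bin-major flatten of the (N, C) block ending at each bin
    swv = np.lib.stride_tricks.sliding_window_view(sbp, n_window, axis=0)  # (n-N+1, C, N)
    feats_one = swv.transpose(0, 2, 1).reshape(len(ends), -1)

    trial_id = session.trial_id
    frames, feat_blocks = [], []
    for g in range(session.n_groups):
        v = session.vel[:, g]
        d = session.dist[:, g]
        t = session.target[:, g]
        pos_sign = v > 0
        neg_sign = v < 0
        toward = v * d > 0
        away = v * d < 0
        same_t = np.concatenate([[False], t[1:] == t[:-1]])  # equal to previous bin
        all_flex = _window_all(pos_sign, n_window)
        all_ext = _window_all(neg_sign, n_window)
        all_toward = _window_all(toward, n_window)
        all_away = _window_all(away, n_window)
        # window spans no target change: every bin after the window start must
        # equal its predecessor's target value
        c = np.concatenate([[0], np.cumsum(same_t.astype(int))])
        starts = ends - n_window + 1
        no_switch = (c[ends + 1] - c[starts + 1]) == (n_window - 1)

        move_type = np.full(len(ends), "inconsistent", dtype=object)
        move_type[all_flex] = "flexion"
        move_type[all_ext] = "extension"
        direction = np.full(len(ends), None, dtype=object)
        direction[all_toward & no_switch] = "toward"
        direction[all_away & no_switch] = "away"
        location = np.where(
            np.abs(d[ends]) <= session.config.target_half_width, "inside", "outside"
        )
        frames.append(
            pd.DataFrame(
                {
                    "end_bin": ends,
                    "group": g,
                    "move_type": move_type,
                    "direction": direction,
                    "location": location,
                    "trial": trial_id[ends],
                }
            )
        )
        feat_blocks.append(feats_one)
    meta = pd.concat(frames, ignore_index=True)
    features = np.vstack(feat_blocks)
    return SegmentSet(meta=meta, features=features, n_window=n_window, channels=chan)


# --------------------------------------------------------------------------
# balanced sets
# --------------------------------------------------------------------------
def build_balanced_sets(
    segments: SegmentSet,
    group: int,
    move_type: str,
    train_frac: float = 0.7,
    rng_seed: int = 0,
    min_per_class: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Balanced, segment-disjoint train/validation index sets for a stratum.

    The majority direction class is subsampled without replacement to the
    minority count, then each class is split by ``train_frac`` so both sets
    stay balanced.
    """
    idx = segments.stratum(group, move_type)
    y = segments.labels(idx)
    rng = np.random.default_rng(rng_seed)
    parts = {"away": idx[y == 1], "toward": idx[y == 0]}
    m = min(len(parts["away"]), len(parts["toward"]))
    if m < min_per_class:
        raise InsufficientSegmentsError(
            f"stratum (group={group}, {move_type}): only "
            f"{len(parts['away'])} away / {len(parts['toward'])} toward labeled "
            f"segments; need at least {min_per_class} of each"
        )
    n_tr = int(round(train_frac * m))
    if n_tr < 1 or n_tr >= m:
        raise ValueError("train_frac leaves an empty train or validation set")
    train, val = [], []
    for lab in ("toward", "away"):
        sub = rng.choice(parts[lab], size=m, replace=False)
        sub = rng.permutation(sub)
        train.append(sub[:n_tr])
        val.append(sub[n_tr:])
    return np.concatenate(train), np.concatenate(val)


# --------------------------------------------------------------------------
# classifiers
# --------------------------------------------------------------------------
class SWLDAClassifier(BaseEstimator, ClassifierMixin):
    """Stepwise linear discriminant analysis.

    Forward-backward stepwise regression of the +/-1 class label on the
    (per-feature z-scored) features selects a feature subset: a candidate
    enters while its partial-F p-value is below ``p_enter``, an included
    feature is dropped when its p-value rises above ``p_remove``, and the
    retained count is capped at ``max_features``.  A pooled-covariance
    linear discriminant on the retained features provides the continuous
    detection score.  With unrestricted entry (``p_enter=1``) this reduces
    exactly to ordinary LDA on all features.
    """

    def __init__(self, p_enter: float = 0.10, p_remove: float = 0.15, max_features: int = 60):
        self.p_enter = p_enter
        self.p_remove = p_remove
        self.max_features = max_features

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("SWLDA is a two-class classifier")
        t = np.where(y == self.classes_[1], 1.0, -1.0)
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        self.scale_ = np.where(sd > 0, sd, 1.0)
        Z = (X - self.mean_) / self.scale_
        self.selected_ = self._stepwise(Z, t)
        if len(self.selected_) == 0:
            warnings.warn(
                "SWLDA: no feature met the entry criterion; classifier is "
                "degenerate and scores a constant 0",
                RuntimeWarning,
                stacklevel=2,
            )
            self.lda_ = None
        else:
            self.lda_ = LinearDiscriminantAnalysis().fit(Z[:, self.selected_], y)
        self.n_features_in_ = X.shape[1]
        return self

    def _stepwise(self, Z: np.ndarray, t: np.ndarray) -> np.ndarray:
        n, p = Z.shape
        norms = np.linalg.norm(Z, axis=0)
        usable = norms > 1e-12  # zero-variance features can never enter
        included: list[int] = []
        # orthonormal basis of [intercept, included features]
        Q = np.ones((n, 1)) / np.sqrt(n)
        r = t - Q @ (Q.T @ t)

        def refit() -> tuple[np.ndarray, np.ndarray]:
            """Rebuild Q and the label residual from the included set."""
            B = np.column_stack([np.ones(n)] + [Z[:, j] for j in included])
            q, _ = np.linalg.qr(B)
            return q, t - q @ (q.T @ t)

        for _ in range(2 * self.max_features + 10):
            changed = False
            # ---- entry step
            if len(included) < self.max_features:
                cand = np.array([j for j in range(p) if usable[j] and j not in included])
                if len(cand):
                    R = Z[:, cand] - Q @ (Q.T @ Z[:, cand])
                    rn = np.linalg.norm(R, axis=0)
                    ok = rn > 1e-8 * norms[cand]
                    if ok.any():
                        rnorm = np.linalg.norm(r)
                        dof = n - len(included) - 2
                        if rnorm > 1e-12 and dof > 0:
                            corr = (R[:, ok].T @ r) / (rn[ok] * rnorm)
                            corr = np.clip(corr, -1 + 1e-15, 1 - 1e-15)
                            F = corr**2 * dof / (1 - corr**2)
                            pvals = stats.f.sf(F, 1, dof)
                            best = int(np.argmin(pvals))
                            if pvals[best] < self.p_enter:
                                j = int(cand[ok][best])
                                included.append(j)
                                qn = R[:, ok][:, best] / rn[ok][best]
                                Q = np.column_stack([Q, qn])
                                r = r - qn * (qn @ r)
                                changed = True
            # ---- removal step(s)
            while len(included) > 1:
                B = np.column_stack([np.ones(n)] + [Z[:, j] for j in included])
                dof = n - B.shape[1]
                if dof <= 0:
                    break
                beta, *_ = np.linalg.lstsq(B, t, rcond=None)
                resid = t - B @ beta
                sigma2 = resid @ resid / dof
                XtX_inv = np.linalg.pinv(B.T @ B)
                se = np.sqrt(np.maximum(sigma2 * np.diag(XtX_inv), 1e-300))
                tstat = beta / se
                pv = 2 * stats.t.sf(np.abs(tstat[1:]), dof)  # skip intercept
                worst = int(np.argmax(pv))
                if pv[worst] > self.p_remove:
                    included.pop(worst)
                    Q, r = refit()
                    changed = True
                else:
                    break
            if not changed:
                break
        return np.array(sorted(included), dtype=int)

    def decision_function(self, X) -> np.ndarray:
        X = check_array(X)
        if self.lda_ is None:
            return np.zeros(len(X))
        Z = (X - self.mean_) / self.scale_
        return self.lda_.decision_function(Z[:, self.selected_])

    def predict(self, X) -> np.ndarray:
        return self.classes_[(self.decision_function(X) > 0).astype(int)]


def _check_balanced(y: np.ndarray) -> None:
    vals, counts = np.unique(y, return_counts=True)
    if len(vals) != 2:
        raise ValueError("training set must contain exactly two classes")


def train_swlda(X, y, **params) -> SWLDAClassifier:
    _check_balanced(np.asarray(y))
    return SWLDAClassifier(**params).fit(X, y)


def train_qda(X, y, reg_param: float = 1e-6) -> Pipeline:
    """Per-class Gaussian classifier; the score is the log posterior-odds.

    ``reg_param`` shrinks each class covariance toward the identity; with
    ``reg_param=0`` a singular class covariance raises an error instructing
    regularization.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    _check_balanced(y)
    if reg_param == 0:
        for cls in np.unique(y):
            cov = np.cov(X[y == cls].T)
            if np.linalg.eigvalsh(np.atleast_2d(cov))[0] <= 1e-12:
                raise ValueError(
                    f"class {cls!r} covariance is singular; set reg_param > 0 "
                    "to regularize"
                )
    clf = Pipeline(
        [("scale", StandardScaler()), ("qda", QuadraticDiscriminantAnalysis(reg_param=reg_param))]
    )
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Variables are collinear")
        clf.fit(X, y)
    return clf


def train_svm(X, y, C: float = 1.0) -> Pipeline:
    """Linear soft-margin SVM; the score is the signed margin."""
    _check_balanced(np.asarray(y))
    clf = Pipeline([("scale", StandardScaler()), ("svm", LinearSVC(C=C, dual="auto"))])
    clf.fit(X, y)
    return clf


_TRAINERS = {"swlda": train_swlda, "qda": train_qda, "svm": train_svm}


def make_classifier(kind: str, X, y, **params):
    """Train a detector of the given kind ('swlda' | 'qda' | 'svm')."""
    try:
        trainer = _TRAINERS[kind]
    except KeyError:
        raise ValueError(f"unknown classifier kind {kind!r}; choose from {sorted(_TRAINERS)}")
    return trainer(X, y, **params)


# --------------------------------------------------------------------------
# ROC and threshold rule
# --------------------------------------------------------------------------
@dataclass
class RocCurve:
    """Empirical ROC from sweeping the score threshold (a segment is flagged
    when score >= threshold); AUC by the trapezoid rule."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def compute_roc(scores: np.ndarray, labels: np.ndarray) -> RocCurve:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) != 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, thr = _sk_roc_curve(labels, scores, drop_intermediate=False)
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thr, auc=float(_sk_auc(fpr, tpr)))


def select_threshold(roc: RocCurve, fpr_limit: float = DEFAULT_FPR_LIMIT) -> float:
    """Threshold rule: among operating points with FPR strictly below the
    limit, take the one maximizing TPR (ties: lower FPR, then larger
    threshold).  If no point below the limit detects anything, fall back to
    the minimum strictly-positive FPR point."""
    if len(roc.thresholds) == 0:
        raise ValueError("empty ROC")
    ok = (roc.fpr < fpr_limit) & (roc.tpr > 0)
    if ok.any():
        cand = np.where(ok)[0]
        order = sorted(
            cand, key=lambda i: (-roc.tpr[i], roc.fpr[i], -roc.thresholds[i])
        )
        return float(roc.thresholds[order[0]])
    pos = np.where(roc.fpr > 0)[0]
    if len(pos) == 0:
        return float(roc.thresholds[-1])
    fmin = roc.fpr[pos].min()
    cand = pos[roc.fpr[pos] == fmin]
    order = sorted(cand, key=lambda i: (-roc.tpr[i], -roc.thresholds[i]))
    return float(roc.thresholds[order[0]])


def operating_point(scores: np.ndarray, labels: np.ndarray, threshold: float) -> tuple[float, float]:
    """(FPR, TPR) of flagging score >= threshold, by direct counting."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    flag = scores >= threshold
    fpr = flag[~labels].mean() if (~labels).any() else np.nan
    tpr = flag[labels].mean() if labels.any() else np.nan
    return float(fpr), float(tpr)


# --------------------------------------------------------------------------
# cross-validation
# --------------------------------------------------------------------------
def cross_validate(
    segments: SegmentSet,
    group: int,
    move_type: str,
    kind: str = "swlda",
    k_folds: int = 5,
    rng_seed: int = 0,
    fpr_limit: float = DEFAULT_FPR_LIMIT,
    **clf_params,
) -> pd.DataFrame:
    """K-fold evaluation of one stratum's detector.

    A balanced pool is drawn first (majority class subsampled, seeded); per
    fold the classifier trains on the other folds and both the ROC and the
    threshold come from the held-out fold, whose recounted (FPR, TPR) at
    that threshold is reported.
    """
    idx = segments.stratum(group, move_type)
    y_all = segments.labels(idx)
    rng = np.random.default_rng(rng_seed)
    m = min((y_all == 1).sum(), (y_all == 0).sum())
    if m < k_folds:
        raise InsufficientSegmentsError(
            f"stratum (group={group}, {move_type}) has too few labeled segments "
            f"({m} per class) for {k_folds} folds"
        )
    pool = np.concatenate(
        [rng.choice(idx[y_all == c], size=m, replace=False) for c in (0, 1)]
    )
    X = segments.features[pool]
    y = segments.labels(pool)
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=int(rng_seed) % (2**32))
    rows = []
    for fold, (tr, va) in enumerate(skf.split(X, y)):
        if len(np.unique(y[va])) < 2 or len(np.unique(y[tr])) < 2:
            raise ValueError(f"fold {fold} contains a single class")
        clf = make_classifier(kind, X[tr], y[tr], **clf_params)
        s = clf.decision_function(X[va])
        roc = compute_roc(s, y[va])
        thr = select_threshold(roc, fpr_limit)
        fpr, tpr = operating_point(s, y[va], thr)
        rows.append({"fold": fold, "fpr": fpr, "tpr": tpr, "auc": roc.auc, "threshold": thr})
    out = pd.DataFrame(rows)
    out.attrs["mean_fpr"] = float(out["fpr"].mean())
    out.attrs["mean_tpr"] = float(out["tpr"].mean())
    out.attrs["mean_auc"] = float(out["auc"].mean())
    return out


# --------------------------------------------------------------------------
# inside/outside-target stratification
# --------------------------------------------------------------------------
LOCATION_STRATA = ("all", "outside", "inside")


def _location_pool(segments: SegmentSet, idx: np.ndarray, loc: str) -> np.ndarray:
    if loc == "all":
        return idx
    return idx[segments.meta["location"].to_numpy()[idx] == loc]


def stratify_by_location(
    segments: SegmentSet,
    group: int,
    move_type: str,
    rng_seed: int = 0,
    min_per_class: int = 10,
) -> dict[str, np.ndarray]:
    """Balanced training pools of equal size for the three location strata.

    The common per-class size is the limiting stratum's balanced count, so
    classifier comparisons across strata are not confounded by training-set
    size.
    """
    idx = segments.stratum(group, move_type)
    rng = np.random.default_rng(rng_seed)
    sizes = {}
    for loc in LOCATION_STRATA:
        sub = _location_pool(segments, idx, loc)
        y = segments.labels(sub)
        sizes[loc] = min((y == 1).sum(), (y == 0).sum())
        if sizes[loc] == 0:
            raise InsufficientSegmentsError(
                f"location stratum {loc!r} for (group={group}, {move_type}) is empty"
            )
    m = min(sizes.values())
    if m < min_per_class:
        raise InsufficientSegmentsError(
            f"limiting location stratum has only {m} per-class segments "
            f"(need {min_per_class})"
        )
    pools = {}
    for loc in LOCATION_STRATA:
        sub = _location_pool(segments, idx, loc)
        y = segments.labels(sub)
        pools[loc] = np.concatenate(
            [rng.choice(sub[y == c], size=m, replace=False) for c in (0, 1)]
        )
    return pools


def location_grid(
    segments: SegmentSet,
    group: int,
    move_type: str,
    kind: str = "swlda",
    k_folds: int = 5,
    rng_seed: int = 0,
    fpr_limit: float = DEFAULT_FPR_LIMIT,
    **clf_params,
) -> pd.DataFrame:
    """3 x 3 train-location x validation-location evaluation.

    Labeled segments are split into k folds; per fold, training candidates
    come from the out-of-fold segments of the training stratum (balanced,
    size-matched across strata) and validation scores accumulate over the
    in-fold segments of the validation stratum.  Returns a DataFrame indexed
    by training stratum with per-validation-stratum TPR (at the selected
    threshold) and AUC columns.
    """
    idx = segments.stratum(group, move_type)
    y_all = segments.labels(idx)
    rng = np.random.default_rng(rng_seed)
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=int(rng_seed) % (2**32))
    folds = list(skf.split(idx, y_all))

    scores: dict[tuple[str, str], list] = {
        (a, b): [] for a in LOCATION_STRATA for b in LOCATION_STRATA
    }
    labels: dict[tuple[str, str], list] = {k: [] for k in scores}
    train_sizes = []
    for tr, va in folds:
        tr_idx, va_idx = idx[tr], idx[va]
        # size-matched balanced training pools from out-of-fold segments
        per_class = []
        for loc in LOCATION_STRATA:
            sub = _location_pool(segments, tr_idx, loc)
            y = segments.labels(sub)
            per_class.append(min((y == 1).sum(), (y == 0).sum()))
        m = min(per_class)
        if m < 2:
            raise InsufficientSegmentsError(
                "a location stratum is (nearly) empty in a cross-validation fold"
            )
        train_sizes.append(m)
        for a in LOCATION_STRATA:
            sub = _location_pool(segments, tr_idx, a)
            y = segments.labels(sub)
            pool = np.concatenate(
                [rng.choice(sub[y == c], size=m, replace=False) for c in (0, 1)]
            )
            clf = make_classifier(kind, segments.features[pool], segments.labels(pool), **clf_params)
            for b in LOCATION_STRATA:
                vb = _location_pool(segments, va_idx, b)
                if len(vb) == 0:
                    continue
                scores[(a, b)].append(clf.decision_function(segments.features[vb]))
                labels[(a, b)].append(segments.labels(vb))

    rows = []
    for a in LOCATION_STRATA:
        row: dict = {"train": a}
        for b in LOCATION_STRATA:
            s = np.concatenate(scores[(a, b)])
            y = np.concatenate(labels[(a, b)])
            roc = compute_roc(s, y)
            thr = select_threshold(roc, fpr_limit)
            _, tpr = operating_point(s, y, thr)
            row[f"tpr_{b}"] = tpr
            row[f"auc_{b}"] = roc.auc
        rows.append(row)
    out = pd.DataFrame(rows).set_index("train")
    out.attrs["train_size_per_class"] = [int(m) for m in train_sizes]
    return out


# --------------------------------------------------------------------------
# detector bank
# --------------------------------------------------------------------------
@dataclass
class Detector:
    """One trained classifier plus its FPR-constrained threshold."""

    clf: object
    threshold: float
    kind: str
    val_fpr: float
    val_tpr: float
    val_auc: float
    n_train: int

    def score(self, features: np.ndarray) -> np.ndarray:
        return self.clf.decision_function(np.atleast_2d(features))

    def flag(self, features: np.ndarray) -> np.ndarray:
        return self.score(features) >= self.threshold


@dataclass
class DetectorBank:
    """One detector per (finger group x movement type)."""

    detectors: dict[tuple[int, str], Detector]
    n_window: int
    channels: np.ndarray
    fpr_limit: float
    meta: dict = field(default_factory=dict)

    def get(self, group: int, move_type: str) -> Detector:
        return self.detectors[(group, move_type)]

    def __contains__(self, key: tuple[int, str]) -> bool:
        return key in self.detectors


def train_detector_bank(
    segments: SegmentSet,
    kind: str = "swlda",
    train_frac: float = 0.7,
    fpr_limit: float = DEFAULT_FPR_LIMIT,
    rng_seed: int = 0,
    groups: list[int] | None = None,
    **clf_params,
) -> DetectorBank:
    """Train the operational detectors: per stratum, a balanced 70/30 split;
    the classifier fits the training part and the threshold comes from the
    validation ROC under the FPR rule."""
    if groups is None:
        groups = sorted(segments.meta["group"].unique())
    detectors = {}
    ss = np.random.SeedSequence(rng_seed)
    seeds = iter(int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2 * len(groups)))
    for g in groups:
        for mt in MOVEMENT_TYPES:
            s = next(seeds)
            tr, va = build_balanced_sets(segments, g, mt, train_frac=train_frac, rng_seed=s)
            clf = make_classifier(kind, segments.features[tr], segments.labels(tr), **clf_params)
            sv = clf.decision_function(segments.features[va])
            roc = compute_roc(sv, segments.labels(va))
            thr = select_threshold(roc, fpr_limit)
            fpr, tpr = operating_point(sv, segments.labels(va), thr)
            detectors[(g, mt)] = Detector(
                clf=clf,
                threshold=thr,
                kind=kind,
                val_fpr=fpr,
                val_tpr=tpr,
                val_auc=roc.auc,
                n_train=len(tr),
            )
    return DetectorBank(
        detectors=detectors,
        n_window=segments.n_window,
        channels=segments.channels,
        fpr_limit=fpr_limit,
        meta={"rng_seed": int(rng_seed), "kind": kind},
    )
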