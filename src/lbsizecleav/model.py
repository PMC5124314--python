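"""SVM training, cross-validated evaluation, and whole-precursor scanning.

The classifier is a soft-margin SVM with an RBF (or linear) kernel on the
binary window features.  Evaluation follows the standard protocol for this
problem: fivefold cross-validation split BY PRECURSOR (a hairpin's positive
and negative windows overlap heavily in sequence, so letting them straddle
train/test would leak), reporting sensitivity, specificity, accuracy and
Matthews correlation coefficient per fold with their mean and sample
variance, separately for the 5p and 3p arms, plus a pooled ROC curve.

The scanner slides a window across every inter-nucleotide site of a
precursor, scores each with the fitted decision function, and calls the
predicted cleavage site on each arm as the argmax of the score profile on
that side of the apex (ties broken toward the 5'-most site).  Prediction
quality of called sites is summarised by the End Absolute Error (EAE):
|predicted - true| in nucleotides.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import joblib
import numpy as np
from sklearn import metrics as _skm
from sklearn.svm import SVC

from .dataset import LabeledWindow, Precursor, tokenize_positions
from .encoding import EncodingScheme, encode_windows
from .structure import (
    StructureError,
    annotate_loops,
    complementary_segment,
    find_apex,
)

__all__ = [
    "ConfusionCounts",
    "compute_metrics",
    "EvalResult",
    "TrainedModel",
    "fit",
    "assign_folds",
    "cross_validate",
    "roc_curve",
    "ScanResult",
    "scan_precursor",
    "end_absolute_error",
    "eae_profile",
    "save_model",
    "load_model",
]

METRIC_NAMES = ("Sn", "Sp", "Ac", "MCC")

MODEL_FORMAT = "lbsizecleav-model-v1"


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionCounts":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        return cls(
            TP=int(np.sum((y_true == 1) & (y_pred == 1))),
            TN=int(np.sum((y_true == -1) & (y_pred == -1))),
            FP=int(np.sum((y_true == -1) & (y_pred == 1))),
            FN=int(np.sum((y_true == 1) & (y_pred == -1))),
        )


def compute_metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Sensitivity, specificity, accuracy and MCC from confusion counts.

    Sn = TP/(TP+FN), Sp = TN/(TN+FP), Ac = (TP+TN)/total,
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
    Any zero factor in the MCC denominator yields MCC = 0; an undefined
    Sn or Sp (empty class) yields NaN for that metric.
    """
    tp, tn, fp, fn = counts.TP, counts.TN, counts.FP, counts.FN
    total = counts.total
    if total == 0:
        raise ValueError("compute_metrics: no evaluated examples")
    sn = tp / (tp + fn) if (tp + fn) > 0 else math.nan
    sp = tn / (tn + fp) if (tn + fp) > 0 else math.nan
    ac = (tp + tn) / total
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / math.sqrt(denom)
    return {"Sn": sn, "Sp": sp, "Ac": ac, "MCC": mcc}


@dataclass
class TrainedModel:
    """A fitted SVM together with the encoding it was trained under.

    The scheme's M is frozen at fit time; test data must be encoded with
    the training M so feature dimensions line up.
    """

    scheme: EncodingScheme
    kernel: str
    gamma: float
    cost: float
    svc: SVC = field(repr=False)

    def decision_scores(self, X) -> np.ndarray:
        """Real-valued decision scores; positive sign = cleavage site."""
        return self.svc.decision_function(X)

    def predict(self, X) -> np.ndarray:
        return np.where(self.decision_scores(X) >= 0, 1, -1)


def default_gamma(scheme: EncodingScheme) -> float:
    """Default RBF width: 1 / feature dimension."""
    return 1.0 / scheme.n_features


def fit(
    X,
    y,
    scheme: EncodingScheme,
    gamma: float | None = None,
    cost: float = 1.0,
    kernel: str = "rbf",
) -> TrainedModel:
    """Fit an SVM on encoded windows.  Deterministic for fixed inputs."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("fit: need at least one example of each class")
    if gamma is None:
        gamma = default_gamma(scheme)
    svc = SVC(C=cost, kernel=kernel, gamma=gamma)
    svc.fit(X, y)
    return TrainedModel(scheme=scheme, kernel=kernel, gamma=gamma, cost=cost, svc=svc)


def fit_windows(
    windows,
    scheme: EncodingScheme,
    gamma: float | None = None,
    cost: float = 1.0,
    kernel: str = "rbf",
) -> TrainedModel:
    """Encode labeled windows under ``scheme`` and fit."""
    X, y = encode_windows(windows, scheme)
    return fit(X, y, scheme, gamma=gamma, cost=cost, kernel=kernel)


@dataclass
class EvalResult:
    """Cross-validation outcome for one arm."""

    arm: str
    per_fold: list[dict[str, float]]
    mean: dict[str, float]
    variance: dict[str, float]
    folds: list[list[str]]  # precursor ids per fold (test sets)
    roc: tuple[np.ndarray, np.ndarray]  # (FPR, TPR), pooled over folds
    auc: float
    counts: ConfusionCounts  # pooled


def assign_folds(precursor_ids, folds: int, seed: int) -> dict[str, int]:
    """Shuffle precursor ids with ``seed`` and deal them round-robin.

    Splitting by precursor guarantees that one hairpin's positive and
    negative windows never straddle train and test.
    """
    ids = sorted(set(precursor_ids))
    if len(ids) < folds:
        raise ValueError(
            f"need at least {folds} precursors for {folds}-fold CV, got {len(ids)}"
        )
    rng = np.random.default_rng(seed)
    rng.shuffle(ids)
    return {pid: i % folds for i, pid in enumerate(ids)}


def cross_validate(
    windows,
    scheme: EncodingScheme,
    folds: int = 5,
    gamma: float | None = None,
    cost: float = 1.0,
    seed: int = 0,
    kernel: str = "rbf",
) -> dict[str, EvalResult]:
    """Fivefold (by default) cross-validation, evaluated per arm.

    Returns ``{"5p": EvalResult, "3p": EvalResult}`` (arms with no
    windows are omitted).  Folds are shared across arms so a precursor is
    held out as a unit.  Variance is the sample variance over folds
    (n-1 denominator).
    """
    windows = list(windows)
    results: dict[str, EvalResult] = {}
    for arm in ("5p", "3p"):
        arm_windows = [w for w in windows if w.arm == arm]
        if not arm_windows:
            continue
        fold_of = assign_folds([w.precursor_id for w in arm_windows], folds, seed)
        X, y = encode_windows(arm_windows, scheme)
        win_fold = np.array([fold_of[w.precursor_id] for w in arm_windows])
        per_fold = []
        all_scores = np.zeros(len(arm_windows))
        all_pred = np.zeros(len(arm_windows), dtype=np.int64)
        for f in range(folds):
            test = win_fold == f
            train = ~test
            train_ids = {w.precursor_id for w, t in zip(arm_windows, train) if t}
            test_ids = {w.precursor_id for w, t in zip(arm_windows, test) if t}
            assert not (train_ids & test_ids), "precursor leaked across folds"
            model = fit(
                X[train], y[train], scheme, gamma=gamma, cost=cost, kernel=kernel
            )
            scores = model.decision_scores(X[test])
            pred = np.where(scores >= 0, 1, -1)
            all_scores[test] = scores
            all_pred[test] = pred
            per_fold.append(
                compute_metrics(ConfusionCounts.from_predictions(y[test], pred))
            )
        mean = {m: float(np.mean([pf[m] for pf in per_fold])) for m in METRIC_NAMES}
        variance = {
            m: float(np.var([pf[m] for pf in per_fold], ddof=1))
            for m in METRIC_NAMES
        }
        fold_ids: list[list[str]] = [[] for _ in range(folds)]
        for pid, f in fold_of.items():
            fold_ids[f].append(pid)
        (fpr, tpr), auc = roc_curve(all_scores, y)
        results[arm] = EvalResult(
            arm=arm,
            per_fold=per_fold,
            mean=mean,
            variance=variance,
            folds=[sorted(f) for f in fold_ids],
            roc=(fpr, tpr),
            auc=auc,
            counts=ConfusionCounts.from_predictions(y, all_pred),
        )
    return results


def roc_curve(scores, labels):
    """ROC points and trapezoidal AUC from decision scores and ±1 labels.

    Thresholds sweep the unique scores (ties grouped); the curve runs from
    (0,0) to (1,1) with both coordinates non-decreasing.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=np.float64)
    if np.unique(labels).size < 2:
        raise ValueError("roc_curve: both classes must be present")
    fpr, tpr, _ = _skm.roc_curve(labels, scores, pos_label=1)
    auc = float(np.trapezoid(tpr, fpr))
    return (fpr, tpr), auc


@dataclass
class ScanResult:
    """Score profile over every full-window site of one precursor."""

    precursor_id: str
    sites: np.ndarray  # inter-nucleotide indices, length L - w + 1
    scores: np.ndarray
    apex: tuple[int, int]
    predicted_cd5p: int | None
    predicted_cd3p: int | None


def _argmax_5prime(sites: np.ndarray, scores: np.ndarray) -> int | None:
    """Site with the maximal score; ties resolved toward the 5'-most site."""
    if sites.size == 0:
        return None
    return int(sites[int(np.argmax(scores))])  # argmax returns first maximum


def _arm_models(model) -> dict[str, TrainedModel]:
    if isinstance(model, TrainedModel):
        return {"5p": model, "3p": model}
    models = dict(model)
    if set(models) - {"5p", "3p"} or not models:
        raise ValueError("expected models keyed by arm ('5p', '3p')")
    if "5p" not in models:
        models["5p"] = models["3p"]
    if "3p" not in models:
        models["3p"] = models["5p"]
    if models["5p"].scheme != models["3p"].scheme:
        raise ValueError("arm models must share one encoding scheme")
    return models


def scan_precursor(model, precursor: Precursor) -> ScanResult:
    """Score every candidate cleavage site of a hairpin with a shift window.

    ``model`` is a single :class:`TrainedModel` (used on both arms) or a
    dict keyed by arm, matching the per-arm training protocol.  A window
    of size w is slid along the precursor; each inter-nucleotide site
    admitting a full window gets the SVM decision score of its window
    under its own arm's model (windows with no paired position take an
    all-gap complementary segment; sites inside the apex loop are scored
    by the 5p model up to the apex midpoint, then the 3p model).  The
    predicted CD-5p (CD-3p) is the argmax of the profile over sites on
    the 5p (3p) side of the apex.
    """
    models = _arm_models(model)
    scheme = models["5p"].scheme
    w = scheme.w
    L = len(precursor)
    if L < w:
        raise ValueError(f"{precursor.id}: precursor shorter than window (w={w})")
    pairmap = precursor.pairmap()
    annotation = annotate_loops(pairmap)
    arms = find_apex(pairmap)
    sites = np.arange(w // 2, L - w // 2 + 1)
    windows = []
    for site in sites:
        start = int(site) - w // 2
        arm_tokens = tokenize_positions(
            range(start, start + w), precursor.sequence, annotation
        )
        try:
            comp_positions = complementary_segment(start, w, pairmap, annotation)
        except StructureError:
            comp_positions = [None] * w
        comp_tokens = tokenize_positions(
            comp_positions, precursor.sequence, annotation
        )
        side = arms.arm_of_site(int(site))
        windows.append(
            LabeledWindow(
                precursor_id=precursor.id,
                arm=side if side in ("5p", "3p") else "5p",
                label=1,  # placeholder; scanning ignores labels
                center=int(site),
                arm_tokens=arm_tokens,
                comp_tokens=comp_tokens,
            )
        )
    X, _ = encode_windows(windows, scheme)
    apex_start, apex_stop = arms.apex
    apex_mid = (apex_start + apex_stop) / 2.0
    scores = models["5p"].decision_scores(X)
    if models["3p"] is not models["5p"]:
        scores3 = models["3p"].decision_scores(X)
        scores = np.where(sites < apex_mid, scores, scores3)
    on5p = sites <= apex_start
    on3p = sites >= apex_stop
    return ScanResult(
        precursor_id=precursor.id,
        sites=sites,
        scores=scores,
        apex=arms.apex,
        predicted_cd5p=_argmax_5prime(sites[on5p], scores[on5p]),
        predicted_cd3p=_argmax_5prime(sites[on3p], scores[on3p]),
    )


def end_absolute_error(predicted: int, true: int) -> int:
    """EAE: |predicted - true| in nucleotides."""
    return abs(int(predicted) - int(true))


def eae_profile(errors) -> np.ndarray:
    """Cumulative fraction of predictions with EAE <= t, for t = 0,1,...

    The profile is non-decreasing and reaches 1.0 at t = max(errors).
    """
    errors = np.asarray(list(errors), dtype=np.int64)
    if errors.size == 0:
        raise ValueError("eae_profile: no errors given")
    tmax = int(errors.max())
    return np.array(
        [np.mean(errors <= t) for t in range(tmax + 1)], dtype=np.float64
    )


def save_model(model, path) -> None:
    """Serialize trained model(s) into one versioned archive.

    ``model`` is a single :class:`TrainedModel` or a dict keyed by arm;
    the archive holds the shared encoding scheme plus kernel parameters
    and fitted coefficients per arm.
    """
    from dataclasses import asdict

    models = _arm_models(model)
    joblib.dump(
        {
            "format": MODEL_FORMAT,
            "scheme": asdict(models["5p"].scheme),
            "arms": {
                arm: {
                    "kernel": m.kernel,
                    "gamma": m.gamma,
                    "cost": m.cost,
                    "svc": m.svc,
                }
                for arm, m in models.items()
            },
        },
        path,
    )


def load_model(path) -> dict[str, TrainedModel]:
    """Load a model archive back into per-arm :class:`TrainedModel`s."""
    payload = joblib.load(path)
    if payload.get("format") != MODEL_FORMAT:
        raise ValueError(
            f"unrecognized model archive format: {payload.get('format')!r}"
        )
    scheme = EncodingScheme(**payload["scheme"])
    return {
        arm: TrainedModel(scheme=scheme, svc=entry["svc"], kernel=entry["kernel"],
                          gamma=entry["gamma"], cost=entry["cost"])
        for arm, entry in payload["arms"].items()
    }
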