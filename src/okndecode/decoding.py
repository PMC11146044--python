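"""Linear-SVM percept decoding with block-role permutation model selection.

A linear soft-margin SVM is trained on the lagged OKN features of one
unimodal visual block, its cost parameter is chosen on a second block (the
11-value grid below), and performance is evaluated on the third.  Because no
block has a privileged role, all 3! = 6 ordered (train, optimize, evaluate)
assignments are run, yielding six decoders per participant whose outputs are
treated as exchangeable and averaged downstream.

All accuracies are class-adjusted (balanced): per-percept accuracies are
computed first and then averaged with equal weight, so chance level is 50%
regardless of how asymmetric the reported percepts are.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.svm import LinearSVC

from .features import EXCLUDED, FeatureMatrix, StandardizationStats, standardize
from .simulate import INTEGRATED, NONE, SEGREGATED, ReportTrace

__all__ = [
    "DEFAULT_COST_GRID",
    "RoleAssignment",
    "DecoderModel",
    "DecodingResult",
    "PerceptDecoder",
    "train_svm",
    "balanced_accuracy",
    "select_model",
    "run_role_permutations",
    "score_hit_rate",
    "decode_timecourse",
]

# The 11 soft-margin cost settings explored during model selection.
DEFAULT_COST_GRID: tuple[float, ...] = (
    0.0001, 0.0005, 0.001, 0.005, 0.01, 0.1, 1, 2, 5, 10, 100,
)


@dataclass(frozen=True)
class RoleAssignment:
    """Which block trains, which selects the cost, which evaluates."""

    train_block: int
    opt_block: int
    eval_block: int

    def __post_init__(self) -> None:
        if len({self.train_block, self.opt_block, self.eval_block}) != 3:
            raise ValueError("train/opt/eval blocks must be pairwise distinct")


@dataclass
class DecodingResult:
    """Class-adjusted accuracy with its per-percept components."""

    acc_seg: float
    acc_int: float
    n_seg: int
    n_int: int

    @property
    def balanced(self) -> float:
        return 0.5 * (self.acc_seg + self.acc_int)


class PerceptDecoder:
    """Linear-SVM classifier for integrated-vs-segregated percepts.

    sklearn-style estimator around :class:`sklearn.svm.LinearSVC` with a
    linear kernel, soft-margin cost ``cost``, and class weights inversely
    proportional to training-class frequency so that training matches the
    class-adjusted evaluation objective.

    Parameters
    ----------
    cost : float
        Soft-margin cost parameter C.
    stride : int
        Optional training-row decimation (keep every ``stride``-th labeled
        row); 100-Hz rows are strongly autocorrelated so moderate decimation
        barely changes the fit. Default 1 (use all rows).

    Attributes
    ----------
    coef_ : np.ndarray
        Linear weight vector, shape (n_features,).
    intercept_ : float
        Bias term.
    classes_ : np.ndarray
        ``[INTEGRATED, SEGREGATED]``.
    """

    def __init__(self, cost: float = 1.0, stride: int = 1) -> None:
        self.cost = cost
        self.stride = stride

    def get_params(self, deep: bool = True) -> dict:
        return {"cost": self.cost, "stride": self.stride}

    def set_params(self, **params) -> "PerceptDecoder":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: np.ndarray, y: np.ndarray) -> "PerceptDecoder":
        """Fit on labeled rows only (labels EXCLUDED are dropped)."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        keep = y != EXCLUDED
        X, y = X[keep], y[keep]
        if self.stride > 1:
            X, y = X[:: self.stride], y[:: self.stride]
        present = np.unique(y)
        for cls, name in ((INTEGRATED, "integrated"), (SEGREGATED, "segregated")):
            if cls not in present:
                raise ValueError(f"training labels contain no {name} timepoints")
        svc = LinearSVC(
            C=self.cost,
            class_weight="balanced",
            dual=False,
            tol=1e-4,
            max_iter=20000,
        )
        svc.fit(X, y)
        self._svc = svc
        self.classes_ = svc.classes_
        self.coef_ = svc.coef_.ravel().copy()
        self.intercept_ = float(svc.intercept_[0])
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"feature dimension {X.shape[1]} does not match the fitted "
                f"model ({self.n_features_in_})"
            )
        return X @ self.coef_ + self.intercept_

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Sign of the decision function mapped to the two percepts."""
        d = self.decision_function(X)
        pos = self.classes_[1]
        neg = self.classes_[0]
        return np.where(d > 0, pos, neg).astype(np.int8)

    def score(self, X: np.ndarray, y: np.ndarray) -> float:
        """Class-adjusted accuracy on labeled rows."""
        keep = y != EXCLUDED
        return balanced_accuracy(self.predict(X[keep]), y[keep]).balanced


@dataclass
class DecoderModel:
    """A selected decoder: weights, cost, block roles, training stats."""

    decoder: PerceptDecoder
    cost: float
    roles: RoleAssignment
    stats: StandardizationStats | None
    opt_accuracy: float
    eval_accuracy: float | None = None

    @property
    def weights(self) -> np.ndarray:
        return self.decoder.coef_

    @property
    def bias(self) -> float:
        return self.decoder.intercept_

    def to_json(self) -> dict:
        return {
            "weights": self.weights.tolist(),
            "bias": self.bias,
            "cost": self.cost,
            "roles": {
                "train": self.roles.train_block,
                "opt": self.roles.opt_block,
                "eval": self.roles.eval_block,
            },
            "standardization": None
            if self.stats is None
            else {"mean": self.stats.mean.tolist(), "sd": self.stats.sd.tolist()},
            "opt_accuracy": self.opt_accuracy,
            "eval_accuracy": self.eval_accuracy,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json()))


# --------------------------------------------------------------------------
# Functional wrappers
# --------------------------------------------------------------------------

def train_svm(
    X: np.ndarray, y: np.ndarray, cost: float, stride: int = 1
) -> PerceptDecoder:
    """Train a linear percept SVM with the given soft-margin cost."""
    return PerceptDecoder(cost=cost, stride=stride).fit(X, y)


def balanced_accuracy(predicted: np.ndarray, labels: np.ndarray) -> DecodingResult:
    """Class-adjusted accuracy of predictions against percept labels.

    ``acc_seg`` is the fraction of segregated-labeled timepoints predicted
    segregated; ``acc_int`` likewise for integrated; excluded timepoints are
    ignored.  The balanced accuracy is their unweighted mean, which keeps
    chance at 50% under any label asymmetry.

    Raises
    ------
    ValueError
        If either percept is absent from the labels (its per-class ratio
        has a zero denominator).
    """
    predicted = np.asarray(predicted)
    labels = np.asarray(labels)
    keep = labels != EXCLUDED
    predicted, labels = predicted[keep], labels[keep]
    n_seg = int((labels == SEGREGATED).sum())
    n_int = int((labels == INTEGRATED).sum())
    if n_seg == 0 or n_int == 0:
        missing = "segregated" if n_seg == 0 else "integrated"
        raise ValueError(f"labels contain no {missing} timepoints")
    acc_seg = float(
        ((predicted == SEGREGATED) & (labels == SEGREGATED)).sum() / n_seg
    )
    acc_int = float(
        ((predicted == INTEGRATED) & (labels == INTEGRATED)).sum() / n_int
    )
    return DecodingResult(acc_seg=acc_seg, acc_int=acc_int, n_seg=n_seg, n_int=n_int)


def select_model(
    candidates: list[tuple[float, PerceptDecoder]],
    opt_X: np.ndarray,
    opt_y: np.ndarray,
) -> tuple[PerceptDecoder, float, float]:
    """Pick the candidate with the highest balanced accuracy on the
    optimization block; ties break toward the smallest cost (stronger
    regularization).  Returns (decoder, cost, opt_accuracy)."""
    if not candidates:
        raise ValueError("no candidate models")
    best = None
    for cost, dec in sorted(candidates, key=lambda c: c[0]):
        acc = dec.score(opt_X, opt_y)
        if best is None or acc > best[2] + 1e-15:
            best = (dec, cost, acc)
    return best


def run_role_permutations(
    blocks: list[tuple[FeatureMatrix, np.ndarray]],
    cost_grid: tuple[float, ...] = DEFAULT_COST_GRID,
    stride: int = 1,
    standardize_features: bool = True,
) -> list[DecoderModel]:
    """Train/select/evaluate decoders under all 6 block-role permutations.

    Parameters
    ----------
    blocks : list of (FeatureMatrix, labels)
        Exactly three unimodal visual blocks with raw (unstandardized)
        features and aligned labels.
    cost_grid : tuple
        Soft-margin costs to explore per training block.
    stride : int
        Training-row decimation passed to :class:`PerceptDecoder`.
    standardize_features : bool
        Standardize each block by the training block's statistics.

    Returns
    -------
    list of DecoderModel
        Six models, each carrying its evaluation-block balanced accuracy.
    """
    if len(blocks) != 3:
        raise ValueError(f"expected exactly 3 unimodal visual blocks, got {len(blocks)}")

    # cache per training block: standardization stats + 11 fitted models
    trained: dict[int, tuple[StandardizationStats | None, list]] = {}
    for i, (fm, y) in enumerate(blocks):
        if standardize_features:
            fm_std, stats = standardize(fm)
        else:
            fm_std, stats = fm, None
        keep = (y != EXCLUDED) & fm.complete
        fits = [
            (cost, train_svm(fm_std.X[keep], y[keep], cost, stride=stride))
            for cost in cost_grid
        ]
        trained[i] = (stats, fits)

    models: list[DecoderModel] = []
    for tr, op, ev in itertools.permutations(range(3)):
        stats, fits = trained[tr]
        fm_op, y_op = blocks[op]
        fm_op_std = standardize(fm_op, stats)[0] if stats is not None else fm_op
        keep_op = (y_op != EXCLUDED) & fm_op.complete
        dec, cost, opt_acc = select_model(
            fits, fm_op_std.X[keep_op], y_op[keep_op]
        )
        fm_ev, y_ev = blocks[ev]
        fm_ev_std = standardize(fm_ev, stats)[0] if stats is not None else fm_ev
        keep_ev = (y_ev != EXCLUDED) & fm_ev.complete
        eval_acc = dec.score(fm_ev_std.X[keep_ev], y_ev[keep_ev])
        models.append(
            DecoderModel(
                decoder=dec,
                cost=cost,
                roles=RoleAssignment(tr, op, ev),
                stats=stats,
                opt_accuracy=opt_acc,
                eval_accuracy=eval_acc,
            )
        )
    return models


def score_hit_rate(
    report: ReportTrace,
    schedule: list[tuple[int, float]] | tuple,
    start_s: float = 0.0,
) -> float:
    """Catch-trial hit rate over a disambiguated tail, as percent.

    The hit rate is the time the exclusive report matches the suggested
    percept divided by the total time of exclusive report, in percent;
    no-report time does not enter the denominator.

    Raises
    ------
    ValueError
        If the report never shows an exclusive percept during the schedule.
    """
    rate = report.rate
    truth = []
    for state, dur in schedule:
        truth.append(np.full(int(round(dur * rate)), state, dtype=np.int8))
    truth = np.concatenate(truth)
    a = int(round(start_s * rate))
    seg = report.states[a:a + len(truth)]
    if len(seg) < len(truth):
        raise ValueError("schedule extends beyond the report")
    exclusive = seg != NONE
    n_exc = int(exclusive.sum())
    if n_exc == 0:
        raise ValueError("no exclusive report during the disambiguated part")
    hits = int((seg[exclusive] == truth[exclusive]).sum())
    return 100.0 * hits / n_exc


def decode_timecourse(
    model: DecoderModel, features: FeatureMatrix
) -> np.ndarray:
    """Predict the percept at every complete timepoint of a block.

    Features are standardized with the model's training statistics; the
    returned int8 series holds INTEGRATED/SEGREGATED at complete rows and
    EXCLUDED where the row is incomplete.
    """
    fm = standardize(features, model.stats)[0] if model.stats is not None else features
    out = np.full(len(fm.t), EXCLUDED, dtype=np.int8)
    rows = fm.complete
    if rows.any():
        out[rows] = model.decoder.predict(fm.X[rows])
    return out
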