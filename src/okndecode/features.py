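"""Lagged feature matrices and report-derived labels for percept decoding.

Each decoding timepoint (100 Hz) is described by the three smoothed OKN
variables sampled at 21 lags from -2.0 s to 0 s in 100-ms steps, giving a
63-dimensional feature vector.  Only causal lags are used, so a feature row
at time t depends exclusively on gaze samples at or before t.

Labels come from the button report: integrated or segregated where exactly
one percept was reported, excluded where no (or both) buttons were pressed
or where the feature row is incomplete (lag window before block start, or
missing data in any lagged sample).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocessing import OknVariables
from .simulate import NONE, ReportTrace

__all__ = [
    "EXCLUDED",
    "FeatureMatrix",
    "LagFeatureExtractor",
    "assemble_features",
    "align_labels",
    "standardize",
    "StandardizationStats",
]

EXCLUDED = -1  # label code; INTEGRATED/SEGREGATED come from simulate


@dataclass
class FeatureMatrix:
    """Timepoints x lagged-feature matrix with completeness flags.

    Attributes
    ----------
    t : np.ndarray
        Timepoint timestamps in seconds (feature rate, default 100 Hz).
    X : np.ndarray
        (n_timepoints, n_features) array; rows flagged incomplete may hold
        NaN.
    complete : np.ndarray
        Boolean per row; False where the lag window extends before the
        block start or into missing data.
    lags : np.ndarray
        The lag grid in seconds (non-positive, ending at 0).
    variable_names : tuple
        Names of the source variables, one block of ``len(lags)`` columns
        each.
    """

    t: np.ndarray
    X: np.ndarray
    complete: np.ndarray
    lags: np.ndarray
    variable_names: tuple[str, ...] = ("v_smooth", "fp_len_smooth", "fp_dist_smooth")

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


@dataclass(frozen=True)
class StandardizationStats:
    """Per-column mean/SD from a training block; SD 0 marks pass-through."""

    mean: np.ndarray
    sd: np.ndarray


def assemble_features(
    okn: OknVariables,
    rate: float = 100.0,
    lag_min: float = -2.0,
    lag_step: float = 0.1,
) -> FeatureMatrix:
    """Build the lagged feature matrix from the smoothed OKN variables.

    Parameters
    ----------
    okn : OknVariables
        The three smoothed signals on their native (1000 Hz) grid.
    rate : float
        Output timepoint rate in Hz (timepoints every ``1/rate`` s).
    lag_min : float
        Most negative lag in seconds (inclusive); must be <= 0.
    lag_step : float
        Lag spacing in seconds.

    Returns
    -------
    FeatureMatrix
        ``round((0 - lag_min)/lag_step) + 1`` lags per variable; with the
        defaults, 21 lags x 3 variables = 63 columns.
    """
    if lag_min > 0 or lag_step <= 0:
        raise ValueError("require lag_min <= 0 and lag_step > 0")
    src_rate = okn.rate
    n_lags = int(round((0.0 - lag_min) / lag_step)) + 1
    lags = lag_min + lag_step * np.arange(n_lags)
    lag_samples = lags * src_rate
    if not np.allclose(lag_samples, np.round(lag_samples), atol=1e-6):
        raise ValueError("lag grid is not commensurate with the source rate")
    lag_samples = np.round(lag_samples).astype(np.int64)

    step = src_rate / rate
    if abs(step - round(step)) > 1e-9:
        raise ValueError("feature rate must divide the source rate")
    step = int(round(step))

    n_src = len(okn.t)
    rows = np.arange(0, n_src, step)
    t_out = okn.t[rows]
    mat = okn.as_matrix()  # (n_src, 3)

    n_rows = len(rows)
    X = np.full((n_rows, 3 * n_lags), np.nan)
    for j, lag in enumerate(lag_samples):
        src = rows + lag
        ok = src >= 0
        for v in range(3):
            X[ok, v * n_lags + j] = mat[src[ok], v]
    complete = np.isfinite(X).all(axis=1)
    return FeatureMatrix(t=t_out, X=X, complete=complete, lags=lags)


def align_labels(features: FeatureMatrix, report: ReportTrace) -> np.ndarray:
    """Label each feature timepoint from the report trace.

    Returns an int8 vector over feature rows with values INTEGRATED,
    SEGREGATED or EXCLUDED; a row is excluded when the report shows no
    exclusive percept at that time or the row is incomplete.
    """
    if len(report.states) == 0:
        raise ValueError("empty report")
    idx = np.round(features.t * report.rate).astype(np.int64)
    if idx[-1] > len(report.states):
        raise ValueError("report does not cover the feature time range")
    idx = np.minimum(idx, len(report.states) - 1)
    labels = report.states[idx].astype(np.int8)
    labels[labels == NONE] = EXCLUDED
    labels[~features.complete] = EXCLUDED
    return labels


def standardize(
    features: FeatureMatrix,
    stats: StandardizationStats | None = None,
) -> tuple[FeatureMatrix, StandardizationStats]:
    """Center/scale feature columns by training-block statistics.

    When ``stats`` is None they are computed from the complete rows of
    ``features`` (i.e. this is the training block).  Zero-variance columns
    pass through unchanged.  Returns the standardized matrix and the stats
    used, so evaluation blocks can reuse the training statistics.
    """
    if stats is None:
        rows = features.X[features.complete]
        mean = rows.mean(axis=0)
        sd = rows.std(axis=0, ddof=0)
        stats = StandardizationStats(mean=mean, sd=sd)
    scale = np.where(stats.sd > 0, stats.sd, 1.0)
    shift = np.where(stats.sd > 0, stats.mean, 0.0)
    X = (features.X - shift) / scale
    out = FeatureMatrix(
        t=features.t,
        X=X,
        complete=features.complete,
        lags=features.lags,
        variable_names=features.variable_names,
    )
    return out, stats


class LagFeatureExtractor:
    """Transformer: OknVariables -> standardized lagged FeatureMatrix.

    ``fit`` learns the per-column standardization statistics from the
    complete rows of the training block (disabled with
    ``standardize=False``); ``transform`` assembles the lag matrix for any
    block and applies the training statistics.
    """

    def __init__(
        self,
        rate: float = 100.0,
        lag_min: float = -2.0,
        lag_step: float = 0.1,
        standardize: bool = True,
    ) -> None:
        self.rate = rate
        self.lag_min = lag_min
        self.lag_step = lag_step
        self.standardize = standardize

    def get_params(self, deep: bool = True) -> dict:
        return {
            k: getattr(self, k)
            for k in ("rate", "lag_min", "lag_step", "standardize")
        }

    def set_params(self, **params) -> "LagFeatureExtractor":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, okn: OknVariables, y=None) -> "LagFeatureExtractor":
        fm = assemble_features(okn, self.rate, self.lag_min, self.lag_step)
        if self.standardize:
            _, self.stats_ = standardize(fm)
        else:
            self.stats_ = None
        self.n_features_ = fm.n_features
        return self

    def transform(self, okn: OknVariables) -> FeatureMatrix:
        fm = assemble_features(okn, self.rate, self.lag_min, self.lag_step)
        if getattr(self, "stats_", None) is not None:
            fm, _ = standardize(fm, self.stats_)
        return fm

    def fit_transform(self, okn: OknVariables, y=None) -> FeatureMatrix:
        return self.fit(okn).transform(okn)
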