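"""OKN preprocessing: blinks, fast/slow-phase segmentation, sliding variables.

Turns a raw 1000-Hz horizontal gaze trace into the three smoothed
eye-movement signals that carry the percept information:

1. smoothed slow-phase velocity (deg/s) — steeper during the integrated
   (plaid) percept, whose horizontal motion component is larger;
2. smoothed fast-phase-direction run length (samples) — for each sample, the
   length of the maximal run of consecutive samples whose displacement points
   in the OKN fast-phase direction;
3. smoothed fast-phase-direction run extent (deg) — the distance covered by
   that run.

All sliding averages are trailing (causal): the value at time t uses only
samples at or before t, so downstream features with lags -2.0...0 s never
peek into the future.  Missing samples (blinks, padded) are excluded from
the averages and break displacement runs.

Constants below are segmentation defaults: a 22 deg/s velocity threshold on
a 10-ms local-regression (Savitzky-Golay) smoothed derivative separates
saccadic fast phases from ~2 deg/s slow-phase drift by an order of
magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.signal import savgol_filter

from .simulate import GazeTrace

__all__ = [
    "SLOW",
    "FAST",
    "MISSING",
    "PhaseLabels",
    "OknVariables",
    "OknPreprocessor",
    "detect_blinks",
    "detect_fast_phases",
    "compute_slow_velocity",
    "compute_fastphase_runs",
]

SLOW, FAST, MISSING = 0, 1, 2

DEFAULT_VEL_THRESH = 22.0   # deg/s
DEFAULT_MIN_DUR_MS = 4.0
DEFAULT_MERGE_GAP_MS = 20.0
DEFAULT_SMOOTH_MS = 10.0    # saccade-detector derivative smoothing
DEFAULT_PAD_MS = 50.0       # blink padding per side


@dataclass
class PhaseLabels:
    """Per-sample segmentation: slow / fast / missing."""

    labels: np.ndarray  # int8 in {SLOW, FAST, MISSING}

    def __post_init__(self) -> None:
        if not np.isin(self.labels, [SLOW, FAST, MISSING]).all():
            raise ValueError("labels must be in {SLOW, FAST, MISSING}")

    def counts(self) -> dict[str, int]:
        return {
            "slow": int((self.labels == SLOW).sum()),
            "fast": int((self.labels == FAST).sum()),
            "missing": int((self.labels == MISSING).sum()),
        }


@dataclass
class OknVariables:
    """The three smoothed OKN signals on the original 1000-Hz grid.

    NaN marks samples where a signal is undefined (no defined source sample
    in the trailing window yet, or missing data).
    """

    t: np.ndarray
    rate: float
    v_smooth: np.ndarray
    fp_len_smooth: np.ndarray
    fp_dist_smooth: np.ndarray

    def as_matrix(self) -> np.ndarray:
        """(n, 3) array in the order velocity, run length, run extent."""
        return np.column_stack([self.v_smooth, self.fp_len_smooth, self.fp_dist_smooth])


# --------------------------------------------------------------------------
# Stage functions
# --------------------------------------------------------------------------

def detect_blinks(trace: GazeTrace, pad_ms: float = DEFAULT_PAD_MS) -> np.ndarray:
    """Extend every run of invalid samples by ``pad_ms`` on each side.

    Eye trackers lose the pupil slightly before and regain it slightly after
    a blink, so samples adjacent to missing runs are unreliable.  Returns the
    padded validity mask (True = usable).
    """
    if pad_ms < 0:
        raise ValueError("pad_ms must be non-negative")
    valid = trace.valid.copy()
    invalid = ~valid
    if not invalid.any() or pad_ms == 0:
        return valid
    pad = int(round(pad_ms * trace.rate / 1000.0))
    if pad > 0:
        # dilate the invalid mask by `pad` samples on each side
        kernel = np.ones(2 * pad + 1, dtype=bool)
        invalid = np.convolve(invalid, kernel, mode="same") > 0
    return ~invalid


def _smoothed_abs_velocity(x: np.ndarray, rate: float, smooth_ms: float) -> np.ndarray:
    """|dx/dt| from a Savitzky-Golay local-regression derivative."""
    window = max(5, int(round(smooth_ms * rate / 1000.0)) | 1)  # odd, >= 5
    if len(x) <= window:
        raise ValueError(
            f"trace of {len(x)} samples is shorter than the {window}-sample "
            "smoothing kernel"
        )
    v = savgol_filter(x, window_length=window, polyorder=2, deriv=1, delta=1.0 / rate)
    return np.abs(v)


def detect_fast_phases(
    trace: GazeTrace,
    vel_thresh: float = DEFAULT_VEL_THRESH,
    min_dur_ms: float = DEFAULT_MIN_DUR_MS,
    merge_gap_ms: float = DEFAULT_MERGE_GAP_MS,
    smooth_ms: float = DEFAULT_SMOOTH_MS,
    valid: np.ndarray | None = None,
) -> PhaseLabels:
    """Velocity-threshold saccade detection on blink-masked data.

    Samples whose local-regression-smoothed absolute velocity exceeds
    ``vel_thresh`` for at least ``min_dur_ms`` are labeled fast; fast events
    separated by less than ``merge_gap_ms`` are merged; remaining usable
    samples are slow; masked samples are missing.  Valid segments shorter
    than the smoothing kernel cannot support saccade detection and are
    labeled slow.
    """
    if vel_thresh <= 0 or min_dur_ms <= 0 or merge_gap_ms < 0:
        raise ValueError("thresholds must be positive")
    if valid is None:
        valid = detect_blinks(trace)
    rate = trace.rate
    n = len(trace.x)
    window = max(5, int(round(smooth_ms * rate / 1000.0)) | 1)
    if n <= window:
        raise ValueError("trace shorter than smoothing kernel")

    labels = np.full(n, MISSING, dtype=np.int8)
    labels[valid] = SLOW

    fast = np.zeros(n, dtype=bool)
    # segment-wise so blinks never leak through the derivative filter
    for start, stop in _runs(valid):
        seg = trace.x[start:stop]
        if len(seg) <= window:
            continue
        speed = _smoothed_abs_velocity(seg, rate, smooth_ms)
        fast[start:stop] = speed > vel_thresh

    min_len = max(1, int(round(min_dur_ms * rate / 1000.0)))
    gap_len = int(round(merge_gap_ms * rate / 1000.0))

    events = [(a, b) for a, b in _runs(fast) if b - a >= min_len]
    # merge events separated by short gaps (within the same valid segment)
    merged: list[tuple[int, int]] = []
    for a, b in events:
        if merged and a - merged[-1][1] < gap_len and valid[merged[-1][1]:a].all():
            merged[-1] = (merged[-1][0], b)
        else:
            merged.append((a, b))
    for a, b in merged:
        sel = slice(a, b)
        labels[sel] = np.where(valid[sel], FAST, MISSING)
    return PhaseLabels(labels=labels)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """(start, stop) pairs of True runs in a boolean mask."""
    if len(mask) == 0:
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(len(mask))
    return list(zip(starts, stops))


def _trailing_mean(values: np.ndarray, window: int) -> np.ndarray:
    """Causal sliding mean over the last ``window`` samples, ignoring NaN.

    Output is NaN where the trailing window contains no defined sample.
    """
    defined = np.isfinite(values)
    filled = np.where(defined, values, 0.0)
    csum = np.concatenate(([0.0], np.cumsum(filled)))
    ccnt = np.concatenate(([0], np.cumsum(defined)))
    n = len(values)
    idx = np.arange(n) + 1
    lo = np.maximum(0, idx - window)
    s = csum[idx] - csum[lo]
    c = ccnt[idx] - ccnt[lo]
    out = np.full(n, np.nan)
    nz = c > 0
    out[nz] = s[nz] / c[nz]
    return out


def compute_slow_velocity(
    trace: GazeTrace,
    labels: PhaseLabels,
    window_s: float = 1.0,
    valid: np.ndarray | None = None,
) -> np.ndarray:
    """Smoothed slow-phase velocity in deg/s.

    Raw velocity at sample i is ``(x[i] - x[i-1]) * rate`` and is defined
    only where both samples are slow-phase and usable — velocities are never
    computed across fast phases or blinks, so excising a fast phase cannot
    create a spike.  The raw series is then averaged with a trailing
    ``window_s`` window over defined samples.
    """
    if valid is None:
        valid = labels.labels != MISSING
    rate = trace.rate
    lab = labels.labels
    n = len(trace.x)
    raw = np.full(n, np.nan)
    ok = np.zeros(n, dtype=bool)
    ok[1:] = (lab[1:] == SLOW) & (lab[:-1] == SLOW) & valid[1:] & valid[:-1]
    raw[ok] = (trace.x[np.flatnonzero(ok)] - trace.x[np.flatnonzero(ok) - 1]) * rate
    return _trailing_mean(raw, int(round(window_s * rate)))


def compute_fastphase_runs(
    trace: GazeTrace,
    labels: PhaseLabels,
    fast_dir: int,
    window_s: float = 1.0,
    sign_smooth_ms: float = 20.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Run-length and run-extent series of displacement in ``fast_dir``.

    For each sample, find the maximal run of consecutive samples whose
    local displacement sign equals ``fast_dir`` and that contains the
    sample; the series hold the run's length in samples and absolute extent
    in degrees (0 when the local displacement points the other way).  Runs
    are defined from displacement sign — not from the fast/slow labels —
    and are broken by missing samples.  Both series are smoothed with the
    trailing ``window_s`` mean.

    With ``sign_smooth_ms > 0`` the per-sample displacement is taken from a
    local-regression (Savitzky-Golay) velocity estimate over that window;
    at 1000 Hz the raw sample-to-sample drift (~0.002 deg) is far below
    tracker noise, so unsmoothed signs are near coin flips during slow
    phases and would shred the runs.  ``sign_smooth_ms=0`` uses raw
    sample differences.
    """
    if fast_dir not in (-1, 1):
        raise ValueError("fast_dir must be -1 or +1")
    rate = trace.rate
    n = len(trace.x)
    usable = labels.labels != MISSING

    disp = np.full(n, np.nan)
    if sign_smooth_ms > 0:
        window = max(5, int(round(sign_smooth_ms * rate / 1000.0)) | 1)
        for a, b in _runs(usable):
            if b - a <= window:
                continue
            v = savgol_filter(
                trace.x[a:b], window_length=window, polyorder=2, deriv=1,
                delta=1.0 / rate,
            )
            disp[a:b] = v / rate
        disp[~usable] = np.nan
        # first sample of each segment has no preceding displacement
        for a, _ in _runs(usable):
            disp[a] = np.nan
    else:
        disp[1:] = trace.x[1:] - trace.x[:-1]
        disp[~usable] = np.nan
        disp[1:][~usable[:-1]] = np.nan  # displacement needs both endpoints

    in_dir = np.zeros(n, dtype=bool)
    with np.errstate(invalid="ignore"):
        in_dir[1:] = (np.sign(disp[1:]) == fast_dir)

    run_len = np.zeros(n)
    run_ext = np.zeros(n)
    for a, b in _runs(in_dir):
        length = b - a
        extent = float(np.nansum(np.abs(disp[a:b])))
        run_len[a:b] = length
        run_ext[a:b] = extent
    run_len[~usable] = np.nan
    run_ext[~usable] = np.nan

    window = int(round(window_s * rate))
    return _trailing_mean(run_len, window), _trailing_mean(run_ext, window)


# --------------------------------------------------------------------------
# Estimator
# --------------------------------------------------------------------------

class OknPreprocessor:
    """Transformer: raw gaze trace -> three smoothed OKN variables.

    Stateless in the sklearn sense (``fit`` is a no-op); parameters follow
    the estimator convention so the preprocessor composes with pipelines and
    ``get_params``/``set_params`` based tooling.

    Parameters
    ----------
    pad_ms : float
        Blink padding per side in ms.
    vel_thresh : float
        Saccade-detection velocity threshold in deg/s.
    min_dur_ms, merge_gap_ms, smooth_ms : float
        Saccade-detector minimum duration, merge gap, and derivative
        smoothing window (ms).
    window_s : float
        Trailing sliding-average window in seconds.
    fast_dir : int
        Sign of the OKN fast-phase direction (-1 or +1).
    smoothing : {"trailing"}
        Sliding-average alignment; only the causal option is implemented,
        the parameter exists so the choice is explicit and serialized.
    """

    def __init__(
        self,
        pad_ms: float = DEFAULT_PAD_MS,
        vel_thresh: float = DEFAULT_VEL_THRESH,
        min_dur_ms: float = DEFAULT_MIN_DUR_MS,
        merge_gap_ms: float = DEFAULT_MERGE_GAP_MS,
        smooth_ms: float = DEFAULT_SMOOTH_MS,
        window_s: float = 1.0,
        fast_dir: int = -1,
        sign_smooth_ms: float = 20.0,
        smoothing: Literal["trailing"] = "trailing",
    ) -> None:
        self.pad_ms = pad_ms
        self.vel_thresh = vel_thresh
        self.min_dur_ms = min_dur_ms
        self.merge_gap_ms = merge_gap_ms
        self.smooth_ms = smooth_ms
        self.window_s = window_s
        self.fast_dir = fast_dir
        self.sign_smooth_ms = sign_smooth_ms
        self.smoothing = smoothing

    # sklearn plumbing ----------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {
            k: getattr(self, k)
            for k in (
                "pad_ms", "vel_thresh", "min_dur_ms", "merge_gap_ms",
                "smooth_ms", "window_s", "fast_dir", "sign_smooth_ms", "smoothing",
            )
        }

    def set_params(self, **params) -> "OknPreprocessor":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: GazeTrace | None = None, y=None) -> "OknPreprocessor":
        if self.smoothing != "trailing":
            raise ValueError("only trailing (causal) smoothing is implemented")
        self.n_features_out_ = 3
        return self

    # the work ------------------------------------------------------------
    def segment(self, trace: GazeTrace) -> tuple[np.ndarray, PhaseLabels]:
        valid = detect_blinks(trace, self.pad_ms)
        labels = detect_fast_phases(
            trace, self.vel_thresh, self.min_dur_ms, self.merge_gap_ms,
            self.smooth_ms, valid=valid,
        )
        return valid, labels

    def transform(self, trace: GazeTrace) -> OknVariables:
        self.fit()
        valid, labels = self.segment(trace)
        v = compute_slow_velocity(trace, labels, self.window_s, valid=valid)
        fp_len, fp_dist = compute_fastphase_runs(
            trace, labels, self.fast_dir, self.window_s, self.sign_smooth_ms
        )
        return OknVariables(
            t=trace.t,
            rate=trace.rate,
            v_smooth=v,
            fp_len_smooth=fp_len,
            fp_dist_smooth=fp_dist,
        )

    def fit_transform(self, trace: GazeTrace, y=None) -> OknVariables:
        return self.fit(trace).transform(trace)
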