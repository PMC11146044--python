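"""Audio-visual consistency, percept statistics, and consistency bounds.

Consistency is the class-adjusted accuracy of the decoded *visual* percept
scored against the simultaneously reported *auditory* percept: if visual and
auditory perception flip together, a decoder trained on visual reports will
"decode" the auditory report above chance.  With six decoders and eight
bimodal blocks this gives a 6 x 8 matrix per participant whose mean is the
participant's consistency.

Because consistency is class-adjusted, chance is 50% for any percept
asymmetry — but its attainable extremes are not 100%/0%:

* *theoretical* bounds depend only on the segregated-percept proportions in
  the two modalities (a = auditory, v = visual).  Writing the per-class
  match proportions of the most (or least) consistent joint distribution
  with those marginals,

      theo_max = 1/2 * [ min(a, v)/a + min(1-a, 1-v)/(1-a) ]
      theo_min = 1/2 * [ max(0, a+v-1)/a + max(0, 1-a-v)/(1-a) ]

  which follow from maximizing/minimizing the balanced overlap over all
  joint occupancy tables with marginals (a, v);

* *expected* bounds additionally account for imperfect visual decoding
  accuracy d and auditory reporting accuracy r.  Under error independence a
  true percept match survives into an observed match with probability
  q = d*r + (1-d)(1-r), and each per-class true-match proportion m maps to
  m*q + (1-m)(1-q) before averaging.

Group-level statistics (one-sample and paired t-tests, Pearson
correlations) are two-tailed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from .decoding import DecoderModel, balanced_accuracy, decode_timecourse
from .features import EXCLUDED, FeatureMatrix
from .simulate import INTEGRATED, NONE, SEGREGATED, ReportTrace

__all__ = [
    "ConsistencyResult",
    "BoundsResult",
    "GroupStats",
    "compute_consistency",
    "theoretical_bounds",
    "expected_bounds",
    "percept_proportions",
    "median_phase_duration",
    "group_tests",
    "paired_test",
    "correlation",
    "plot_consistency_bounds",
]


@dataclass
class ConsistencyResult:
    """Model-by-block consistency matrix and its participant mean."""

    matrix: np.ndarray           # (n_models, n_blocks); NaN = undefined cell
    per_class: np.ndarray        # (n_models, n_blocks, 2): acc_int, acc_seg

    @property
    def mean(self) -> float:
        return float(np.nanmean(self.matrix))

    @property
    def n_cells(self) -> int:
        return self.matrix.size

    @property
    def n_defined(self) -> int:
        return int(np.isfinite(self.matrix).sum())


@dataclass(frozen=True)
class BoundsResult:
    """Theoretical and expected consistency bounds for one participant.

    a, v : segregated-percept proportions (auditory report, visual report);
    d : visual decoding accuracy; r : auditory reporting accuracy;
    q : probability that a true percept match survives decoding+reporting.
    """

    a: float
    v: float
    d: float
    r: float
    q: float
    theo_max: float
    theo_min: float
    exp_max: float
    exp_min: float


@dataclass(frozen=True)
class GroupStats:
    """One statistical test outcome."""

    test: str
    statistic: float
    df: int
    p_value: float
    n: int


# --------------------------------------------------------------------------
# Consistency
# --------------------------------------------------------------------------

def compute_consistency(
    models: list[DecoderModel],
    bimodal_features: list[FeatureMatrix],
    auditory_labels: list[np.ndarray],
) -> ConsistencyResult:
    """Score every decoder on every bimodal block against auditory reports.

    ``auditory_labels[b]`` are per-timepoint percept labels derived from the
    auditory report of block b (EXCLUDED where no exclusive report).  A cell
    whose auditory labels lack one of the two percepts is undefined (NaN)
    and excluded from the participant mean.
    """
    if len(bimodal_features) != len(auditory_labels):
        raise ValueError("features and labels block counts differ")
    n_m, n_b = len(models), len(bimodal_features)
    matrix = np.full((n_m, n_b), np.nan)
    per_class = np.full((n_m, n_b, 2), np.nan)
    for j, (fm, y) in enumerate(zip(bimodal_features, auditory_labels)):
        for i, model in enumerate(models):
            pred = decode_timecourse(model, fm)
            keep = (y != EXCLUDED) & (pred != EXCLUDED)
            try:
                res = balanced_accuracy(pred[keep], y[keep])
            except ValueError as err:
                import logging

                logging.getLogger(__name__).warning(
                    "consistency cell (model %d, block %d) undefined: %s", i, j, err
                )
                continue
            matrix[i, j] = res.balanced
            per_class[i, j] = (res.acc_int, res.acc_seg)
    return ConsistencyResult(matrix=matrix, per_class=per_class)


# --------------------------------------------------------------------------
# Bounds
# --------------------------------------------------------------------------

def _check_proportion(name: str, value: float) -> None:
    if not 0.0 < value < 1.0:
        raise ValueError(f"{name} must lie strictly in (0, 1), got {value}")


def _extreme_class_matches(a: float, v: float) -> tuple[tuple[float, float], tuple[float, float]]:
    """Per-class true-match proportions (m_seg, m_int) at the two extremes.

    The joint occupancy table with marginals (a, v) that maximizes the
    balanced overlap puts mass min(a, v) on (seg, seg); the one that
    minimizes it puts mass max(0, a+v-1) there.
    """
    p_ss_max = min(a, v)
    m_seg_max = p_ss_max / a
    m_int_max = (1.0 - a - v + p_ss_max) / (1.0 - a)
    p_ss_min = max(0.0, a + v - 1.0)
    m_seg_min = p_ss_min / a
    m_int_min = (1.0 - a - v + p_ss_min) / (1.0 - a)
    return (m_seg_max, m_int_max), (m_seg_min, m_int_min)


def theoretical_bounds(a: float, v: float) -> tuple[float, float]:
    """Extreme consistencies permitted by percept asymmetry alone.

    Parameters
    ----------
    a, v : float
        Segregated-percept proportions of the auditory and visual modality,
        strictly inside (0, 1).

    Returns
    -------
    (theo_max, theo_min)
    """
    _check_proportion("a", a)
    _check_proportion("v", v)
    (m_seg_max, m_int_max), (m_seg_min, m_int_min) = _extreme_class_matches(a, v)
    return 0.5 * (m_seg_max + m_int_max), 0.5 * (m_seg_min + m_int_min)


def expected_bounds(
    a: float, v: float, d: float, r: float
) -> tuple[float, float, float]:
    """Bounds attenuated by decoding and reporting accuracy.

    Under the independence assumption, a moment where the true percepts
    match is observed as a match when decoder and report are both correct
    or both wrong: q = d*r + (1-d)(1-r).  Each per-class true-match
    proportion m at a theoretical extreme becomes m*q + (1-m)(1-q); the
    per-class values are then averaged.

    Returns
    -------
    (exp_max, exp_min, q)
    """
    _check_proportion("a", a)
    _check_proportion("v", v)
    for name, val in (("d", d), ("r", r)):
        if not 0.0 <= val <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {val}")
    q = d * r + (1.0 - d) * (1.0 - r)

    def attenuate(m: float) -> float:
        return m * q + (1.0 - m) * (1.0 - q)

    (m_seg_max, m_int_max), (m_seg_min, m_int_min) = _extreme_class_matches(a, v)
    exp_max = 0.5 * (attenuate(m_seg_max) + attenuate(m_int_max))
    exp_min = 0.5 * (attenuate(m_seg_min) + attenuate(m_int_min))
    return exp_max, exp_min, q


def bounds_result(a: float, v: float, d: float, r: float) -> BoundsResult:
    """Bundle theoretical and expected bounds for one participant."""
    theo_max, theo_min = theoretical_bounds(a, v)
    exp_max, exp_min, q = expected_bounds(a, v, d, r)
    return BoundsResult(
        a=a, v=v, d=d, r=r, q=q,
        theo_max=theo_max, theo_min=theo_min,
        exp_max=exp_max, exp_min=exp_min,
    )


# --------------------------------------------------------------------------
# Report statistics
# --------------------------------------------------------------------------

def percept_proportions(report: ReportTrace) -> tuple[float, float, float]:
    """(prop_seg, prop_int, exclusive_fraction) of a report trace.

    Percept proportions are taken relative to the summed time of exclusive
    reporting, so they add to 1; ``exclusive_fraction`` is exclusive time
    over total time.
    """
    states = report.states
    if len(states) == 0:
        raise ValueError("empty report")
    n_seg = int((states == SEGREGATED).sum())
    n_int = int((states == INTEGRATED).sum())
    n_exc = n_seg + n_int
    if n_exc == 0:
        raise ValueError("report contains no exclusive percept time")
    return n_seg / n_exc, n_int / n_exc, n_exc / len(states)


def median_phase_duration(report: ReportTrace) -> float:
    """Median duration (s) of maximal constant exclusive-percept phases.

    A phase ends at any percept switch or at the start of a no-report gap.
    """
    states = report.states
    durations = []
    start = None
    for i in range(len(states)):
        if states[i] == NONE:
            if start is not None:
                durations.append(i - start)
                start = None
        elif start is None:
            start = i
        elif states[i] != states[start]:
            durations.append(i - start)
            start = i
    if start is not None:
        durations.append(len(states) - start)
    if not durations:
        raise ValueError("report contains no exclusive percept phases")
    return float(np.median(durations)) / report.rate


# --------------------------------------------------------------------------
# Group statistics
# --------------------------------------------------------------------------

def group_tests(values: np.ndarray, reference: float) -> GroupStats:
    """Two-tailed one-sample t-test of a participant-level mean vs a
    reference (e.g. consistency vs the 50% chance level)."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 2:
        raise ValueError("need at least two values")
    if np.std(values, ddof=1) == 0:
        if np.allclose(values, reference):
            return GroupStats("one-sample t", 0.0, n - 1, 1.0, n)
        raise ValueError("zero variance away from the reference: t undefined")
    t, p = sstats.ttest_1samp(values, reference)
    return GroupStats("one-sample t", float(t), n - 1, float(p), n)


def paired_test(x: np.ndarray, y: np.ndarray) -> GroupStats:
    """Two-tailed paired t-test between two conditions."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("need two equal-length vectors with n >= 2")
    d = x - y
    if np.std(d, ddof=1) == 0:
        if np.allclose(d, 0):
            return GroupStats("paired t", 0.0, len(x) - 1, 1.0, len(x))
        raise ValueError("zero-variance nonzero difference: t undefined")
    t, p = sstats.ttest_rel(x, y)
    return GroupStats("paired t", float(t), len(x) - 1, float(p), len(x))


def correlation(x: np.ndarray, y: np.ndarray) -> GroupStats:
    """Pearson correlation across participants."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    r, p = sstats.pearsonr(x, y)
    return GroupStats("pearson r", float(r), len(x) - 2, float(p), len(x))


# --------------------------------------------------------------------------
# Plot
# --------------------------------------------------------------------------

def plot_consistency_bounds(
    consistencies: np.ndarray,
    bounds: list[BoundsResult],
    path: str | None = None,
):
    """Per-participant consistency bars with their four bounds overlaid.

    Participants are sorted by theoretical maximum.  Returns the matplotlib
    figure; saves to ``path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    consistencies = np.asarray(consistencies, dtype=float)
    order = np.argsort([-b.theo_max for b in bounds])
    xs = np.arange(len(order))
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.bar(xs, consistencies[order] * 100, color="0.6", label="consistency")
    for attr, color, label in (
        ("theo_max", "black", "theoretical max"),
        ("exp_max", "tab:blue", "expected max"),
        ("exp_min", "tab:cyan", "expected min"),
        ("theo_min", "tab:red", "theoretical min"),
    ):
        ax.plot(xs, [getattr(bounds[i], attr) * 100 for i in order],
                color=color, label=label)
    ax.axhline(50, color="0.3", linestyle=":", linewidth=1)
    ax.set_xlabel("participant (sorted by theoretical max)")
    ax.set_ylabel("consistency (%)")
    ax.legend(fontsize=8, ncol=2)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
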