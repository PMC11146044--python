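"""Synthetic bistable-perception sessions with known ground truth.

Generates everything a "day-2" recording session would contain, so every
downstream stage (OKN preprocessing, feature extraction, SVM decoding,
consistency analysis) can be tested without real recordings:

* coupled latent percept traces for the visual and auditory modality,
  built as an alternating-renewal process with gamma-distributed dominance
  durations plus per-modality "disagreement" processes that control the
  cross-modal coupling ``kappa``;
* noisy piecewise-constant button reports (report latency, phase-level
  report errors, no-report gaps around switches);
* sawtooth optokinetic-nystagmus gaze traces whose slow-phase velocity and
  fast-phase duration/extent depend on the current percept, with blinks as
  runs of missing samples;
* the block structure of a session (unimodal visual / unimodal auditory /
  bimodal blocks, each a 180-s multistable part followed by a 30-s
  disambiguated tail with a known 4-segment schedule).

Coupling model
--------------
A single common percept process is shared by both modalities.  Each modality
carries an independent alternating agree/disagree renewal process with
stationary disagree probability ``delta = (1 - kappa) / 2``; while in
"disagree" the modality's percept is the common percept flipped.  The two
modalities therefore match whenever their disagreement indicators agree:
``P(match) = (1 - delta)**2 + delta**2 = (1 + kappa**2) / 2``, which is 1 at
kappa = 1 and 1/2 (independence) at kappa = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "INTEGRATED",
    "SEGREGATED",
    "NONE",
    "PerceptProcessParams",
    "OknParams",
    "BlockDesign",
    "SessionDesign",
    "LatentPerceptTrace",
    "ReportTrace",
    "GazeTrace",
    "SyntheticBlock",
    "SyntheticSession",
    "simulate_coupled_percepts",
    "simulate_report",
    "simulate_okn",
    "build_session",
    "write_gaze_csv",
    "read_gaze_csv",
    "write_report_events",
    "read_report_events",
]

# Percept state codes used throughout the package.
INTEGRATED = 0
SEGREGATED = 1
NONE = -1  # report only: no (or both) buttons pressed

STATE_NAMES = {INTEGRATED: "integrated", SEGREGATED: "segregated", NONE: "none"}


# --------------------------------------------------------------------------
# Parameter containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PerceptProcessParams:
    """Per-modality parameters of the latent percept / report process.

    Attributes
    ----------
    mean_dom : float
        Mean dominance-phase duration in seconds (> 0).  With the default
        gamma shape of 3 the distribution median is ~0.89 * mean, so a mean
        of 9 s gives the ~8-s median phase durations typical of auditory
        streaming and pattern-component rivalry.
    shape : float
        Shape parameter of the gamma dominance-duration distribution.
    pi_seg : float
        Stationary proportion of the segregated percept, in [0, 1].
    kappa : float
        Cross-modal coupling in [0, 1]; shared by both modalities.
    eps_report : float
        Probability that a whole perceptual phase is reported with the
        wrong button.
    lag_report : float
        Report latency in seconds.
    gamma_gap : float
        Fraction of time with no exclusive report (button gaps).
    """

    mean_dom: float = 9.0
    shape: float = 3.0
    pi_seg: float = 0.5
    kappa: float = 0.6
    eps_report: float = 0.1
    lag_report: float = 0.4
    gamma_gap: float = 0.03

    def __post_init__(self) -> None:
        if self.mean_dom <= 0:
            raise ValueError("mean_dom must be positive")
        if self.shape <= 0:
            raise ValueError("shape must be positive")
        for name in ("pi_seg", "kappa", "eps_report", "gamma_gap"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {val}")
        if self.lag_report < 0:
            raise ValueError("lag_report must be non-negative")


@dataclass(frozen=True)
class OknParams:
    """Parameters of the sawtooth OKN gaze-trace generator.

    ``v_int``/``v_seg`` are the slow-phase horizontal velocities (deg/s) during
    integrated/segregated percepts; the integrated (plaid) percept has the
    larger horizontal motion component and hence the steeper slow phase.
    Fast phases reset gaze in direction ``fast_dir`` once eccentricity
    ``reset_ecc`` is reached, with state-dependent mean duration (and hence
    extent, via the fixed fast-phase speed ``v_fast``).
    """

    v_int: float = 1.9
    v_seg: float = 0.5
    fast_dir: int = -1
    reset_ecc: float = 2.0
    fastphase_dur_int: float = 60.0   # ms
    fastphase_dur_seg: float = 35.0   # ms
    v_fast: float = 80.0              # deg/s during fast phases
    noise_sd: float = 0.01            # deg, per-sample position noise
    blink_rate: float = 3.0           # blinks per minute
    blink_dur: float = 150.0          # ms, mean blink duration

    def __post_init__(self) -> None:
        if not (self.v_int > self.v_seg >= 0):
            raise ValueError("require v_int > v_seg >= 0")
        if self.fast_dir not in (-1, 1):
            raise ValueError("fast_dir must be -1 or +1")
        for name in ("reset_ecc", "fastphase_dur_int", "fastphase_dur_seg", "v_fast"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("noise_sd", "blink_rate", "blink_dur"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class BlockDesign:
    """One block: condition plus multistable / disambiguated timing."""

    condition: str  # unimodal_visual | unimodal_auditory | bimodal
    multistable_dur: float = 180.0
    disambig_dur: float = 30.0
    disambig_modality: str = "visual"
    # 4 segments alternating integrated/segregated; durations in seconds
    disambig_schedule: tuple[tuple[int, float], ...] = (
        (INTEGRATED, 7.5),
        (SEGREGATED, 7.5),
        (INTEGRATED, 7.5),
        (SEGREGATED, 7.5),
    )

    def __post_init__(self) -> None:
        if self.condition not in ("unimodal_visual", "unimodal_auditory", "bimodal"):
            raise ValueError(f"unknown condition {self.condition!r}")
        states = [s for s, _ in self.disambig_schedule]
        if len(states) != 4 or states.count(INTEGRATED) != 2 or states.count(SEGREGATED) != 2:
            raise ValueError("disambig schedule must contain each percept exactly twice")
        if any(states[i] == states[i + 1] for i in range(3)):
            raise ValueError("disambig schedule must alternate percepts")

    @property
    def duration(self) -> float:
        return self.multistable_dur + self.disambig_dur


def _default_blocks() -> tuple[BlockDesign, ...]:
    """Default 13-block day-2 design: 3 unimodal visual, 2 unimodal auditory,
    8 bimodal (half of the bimodal tails disambiguate the auditory stimulus,
    half the visual one), interleaved."""
    blocks: list[BlockDesign] = []
    bimodal_disambig = ["auditory", "visual"] * 4
    order = [
        "unimodal_visual", "bimodal", "bimodal", "unimodal_auditory",
        "bimodal", "bimodal", "unimodal_visual", "bimodal", "bimodal",
        "unimodal_auditory", "bimodal", "bimodal", "unimodal_visual",
    ]
    k = 0
    for cond in order:
        if cond == "bimodal":
            dis = bimodal_disambig[k]
            k += 1
        elif cond == "unimodal_visual":
            dis = "visual"
        else:
            dis = "auditory"
        blocks.append(BlockDesign(condition=cond, disambig_modality=dis))
    return tuple(blocks)


@dataclass(frozen=True)
class SessionDesign:
    """Ordered block list of one session."""

    blocks: tuple[BlockDesign, ...] = field(default_factory=_default_blocks)

    def count(self, condition: str) -> int:
        return sum(1 for b in self.blocks if b.condition == condition)


# --------------------------------------------------------------------------
# Trace containers
# --------------------------------------------------------------------------

@dataclass
class LatentPerceptTrace:
    """Piecewise-constant ground-truth percept, sampled on a uniform grid."""

    rate: float
    states: np.ndarray  # int8, INTEGRATED/SEGREGATED per sample

    @property
    def duration(self) -> float:
        return len(self.states) / self.rate

    @property
    def t(self) -> np.ndarray:
        return np.arange(len(self.states)) / self.rate


@dataclass
class ReportTrace:
    """Button-report trace: integrated / segregated / none per sample."""

    rate: float
    states: np.ndarray  # int8 in {INTEGRATED, SEGREGATED, NONE}

    @property
    def duration(self) -> float:
        return len(self.states) / self.rate

    @property
    def t(self) -> np.ndarray:
        return np.arange(len(self.states)) / self.rate


@dataclass
class GazeTrace:
    """Horizontal gaze position on a uniform 1000-Hz grid.

    ``x`` is in degrees; samples with ``valid == False`` are missing (blinks).
    ``phase_truth`` keeps the generator's ground-truth sample labels
    (0 = slow, 1 = fast, 2 = missing) for segmentation tests; real recordings
    do not carry it.
    """

    t: np.ndarray
    x: np.ndarray
    valid: np.ndarray
    phase_truth: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (len(self.t) == len(self.x) == len(self.valid)):
            raise ValueError("t, x and valid must have equal length")
        if len(self.t) > 1:
            dt = np.diff(self.t)
            if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6):
                raise ValueError("t must be strictly increasing and uniform")
        if np.any(~np.isfinite(self.x[self.valid])):
            raise ValueError("x must be finite wherever valid")

    @property
    def rate(self) -> float:
        return 1.0 / (self.t[1] - self.t[0])


# --------------------------------------------------------------------------
# Percept dynamics
# --------------------------------------------------------------------------

def _renewal_states(
    rng: np.random.Generator,
    n: int,
    rate: float,
    mean_a: float,
    mean_b: float,
    shape: float,
    start_b_prob: float,
) -> np.ndarray:
    """Alternating-renewal 0/1 state sequence with gamma phase durations.

    State 0 phases have mean duration ``mean_a``, state 1 phases ``mean_b``.
    Returns int8 array of length ``n``.
    """
    out = np.empty(n, dtype=np.int8)
    pos = 0
    state = 1 if rng.random() < start_b_prob else 0
    # First phase is entered mid-stream; length-biased sampling is ignored
    # (negligible for traces much longer than a phase).
    while pos < n:
        mean = mean_b if state else mean_a
        dur = rng.gamma(shape, mean / shape)
        k = max(1, int(round(dur * rate)))
        end = min(n, pos + k)
        out[pos:end] = state
        pos = end
        state = 1 - state
    return out


def simulate_coupled_percepts(
    params_visual: PerceptProcessParams,
    params_auditory: PerceptProcessParams,
    duration: float,
    seed: int | np.random.SeedSequence,
    rate: float = 1000.0,
) -> tuple[LatentPerceptTrace, LatentPerceptTrace]:
    """Simulate coupled visual and auditory latent percept traces.

    Both modalities share one common alternating-renewal percept process;
    each modality flips the common state during its own "disagreement"
    phases, which occur with stationary probability ``(1 - kappa) / 2``.
    The stationary probability that the two modalities show the same percept
    is ``(1 + kappa**2) / 2``.

    Per-modality segregated occupancy targets ``pi_seg`` are met by solving
    the flip map ``pi = (1 - delta) * pi_c + delta * (1 - pi_c)`` for the
    common-process occupancy ``pi_c`` (using the mean of the two modality
    targets); occupancy is exact when both targets agree and approaches 0.5
    as kappa approaches 0, where the flip erases any asymmetry.

    Parameters
    ----------
    params_visual, params_auditory : PerceptProcessParams
        Modality parameters; ``kappa`` is taken from the visual entry and
        must match the auditory one.
    duration : float
        Trace duration in seconds (> 0).
    seed : int or numpy SeedSequence
        Source of randomness.
    rate : float
        Sampling rate of the output traces in Hz.

    Returns
    -------
    (LatentPerceptTrace, LatentPerceptTrace)
        Visual and auditory traces.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    kappa = params_visual.kappa
    if abs(kappa - params_auditory.kappa) > 1e-12:
        raise ValueError("kappa must agree between modalities")
    if not 0.0 <= kappa <= 1.0:
        raise ValueError("kappa must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    n = int(round(duration * rate))
    delta = (1.0 - kappa) / 2.0

    pi_target = 0.5 * (params_visual.pi_seg + params_auditory.pi_seg)
    if delta < 0.5:
        pi_c = (pi_target - delta) / (1.0 - 2.0 * delta)
    else:  # kappa == 0: flip forces occupancy to 1/2 regardless
        pi_c = pi_target
    pi_c = float(np.clip(pi_c, 0.0, 1.0))

    mean_dom = 0.5 * (params_visual.mean_dom + params_auditory.mean_dom)
    shape = params_visual.shape
    # Both the common switches and the disagreement transitions flip each
    # modality's state, so the common process is slowed to mean_dom / kappa
    # and disagreement phases get mean mean_dom: the per-modality switch
    # rate stays ~1/mean_dom at every kappa (1/mean_c + 2*delta/mean_dom =
    # 1/mean_dom), while the match probability depends on delta alone.
    if kappa > 1e-9:
        mean_c = mean_dom / kappa
        # state-dependent means so common-process seg occupancy = pi_c
        mean_seg = max(2.0 * mean_c * pi_c, 1e-3)
        mean_int = max(2.0 * mean_c * (1.0 - pi_c), 1e-3)
        common = _renewal_states(rng, n, rate, mean_int, mean_seg, shape, pi_c)
    else:
        # kappa = 0: all switching lives in the disagreement processes
        common = np.full(n, 1 if rng.random() < pi_c else 0, dtype=np.int8)

    traces = []
    for params in (params_visual, params_auditory):
        if delta == 0.0:
            states = common.copy()
        else:
            mean_dis = max(params.mean_dom, 1e-3)
            mean_agr = max(params.mean_dom * (1.0 - delta) / delta, 1e-3)
            disagree = _renewal_states(rng, n, rate, mean_agr, mean_dis, shape, delta)
            states = np.where(disagree == 1, 1 - common, common).astype(np.int8)
        traces.append(LatentPerceptTrace(rate=rate, states=states))
    return traces[0], traces[1]


# --------------------------------------------------------------------------
# Reports
# --------------------------------------------------------------------------

def _phase_bounds(states: np.ndarray) -> list[tuple[int, int]]:
    """(start, stop) index pairs of maximal constant runs."""
    if len(states) == 0:
        return []
    change = np.flatnonzero(np.diff(states)) + 1
    starts = np.concatenate(([0], change))
    stops = np.concatenate((change, [len(states)]))
    return list(zip(starts, stops))


def simulate_report(
    latent: LatentPerceptTrace,
    eps_report: float,
    lag_report: float,
    gamma_gap: float,
    seed: int | np.random.SeedSequence,
) -> ReportTrace:
    """Turn a latent percept trace into a noisy button-report trace.

    The latent trace is delayed by ``lag_report`` (the initial ``lag_report``
    seconds are reported as none, emulating the first key press); each
    perceptual phase is independently reported with the wrong button with
    probability ``eps_report``; and no-report gaps with mean total fraction
    ``gamma_gap`` are inserted around percept switches, where button
    releases actually happen.
    """
    for name, val in (("eps_report", eps_report), ("gamma_gap", gamma_gap)):
        if not 0.0 <= val <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    if lag_report < 0:
        raise ValueError("lag_report must be non-negative")

    rng = np.random.default_rng(seed)
    rate = latent.rate
    n = len(latent.states)
    lag = int(round(lag_report * rate))
    out = np.empty(n, dtype=np.int8)
    out[:min(lag, n)] = NONE
    if lag < n:
        out[lag:] = latent.states[: n - lag]

    # phase-level report errors (on the delayed trace, none excluded)
    for start, stop in _phase_bounds(out):
        if out[start] == NONE:
            continue
        if eps_report > 0 and rng.random() < eps_report:
            out[start:stop] = 1 - out[start:stop]

    # no-report gaps around switches
    if gamma_gap > 0:
        switches = np.flatnonzero(np.diff(out) != 0) + 1
        switches = switches[out[switches] != NONE]
        total_gap = gamma_gap * n
        if len(switches) > 0:
            mean_gap = total_gap / len(switches)
            for s in switches:
                g = rng.exponential(mean_gap)
                half = int(round(g / 2))
                lo, hi = max(0, s - half), min(n, s + half)
                out[lo:hi] = NONE
        else:
            # constant trace: place gaps uniformly at random
            n_gaps = max(1, int(round(gamma_gap * latent.duration / 2.0)))
            mean_gap = total_gap / n_gaps
            for _ in range(n_gaps):
                g = int(round(rng.exponential(mean_gap)))
                s = rng.integers(0, max(1, n - g))
                out[s:s + g] = NONE
    return ReportTrace(rate=rate, states=out)


# --------------------------------------------------------------------------
# OKN gaze traces
# --------------------------------------------------------------------------

def simulate_okn(
    latent: LatentPerceptTrace,
    okn: OknParams | None = None,
    rate: float = 1000.0,
    seed: int | np.random.SeedSequence = 0,
) -> GazeTrace:
    """Generate a sawtooth OKN gaze trace driven by the latent percept.

    Slow phases drift opposite to ``fast_dir`` at ``v_int`` or ``v_seg``
    (plus white position noise) depending on the current percept; once the
    position passes ``reset_ecc`` a fast phase moves gaze in ``fast_dir`` at
    ``v_fast`` for a state-dependent duration.  Blinks arrive as a Poisson
    process at ``blink_rate`` per minute and blank ``blink_dur``-long runs
    of samples.

    The returned trace keeps ground-truth per-sample phase labels
    (slow/fast/missing) for testing the segmentation stage.
    """
    okn = okn or OknParams()
    rng = np.random.default_rng(seed)

    # latent trace may be sampled at a different rate
    n = int(round(latent.duration * rate))
    idx = np.minimum((np.arange(n) * latent.rate / rate).astype(np.int64),
                     len(latent.states) - 1)
    states = latent.states[idx]

    slow_dir = -okn.fast_dir
    dt = 1.0 / rate
    x = np.empty(n)
    phase = np.zeros(n, dtype=np.int8)  # 0 slow, 1 fast, 2 missing
    pos = rng.uniform(-okn.reset_ecc, okn.reset_ecc)
    fast_left = 0  # samples remaining in current fast phase
    for i in range(n):
        if fast_left > 0:
            pos += okn.fast_dir * okn.v_fast * dt
            phase[i] = 1
            fast_left -= 1
        else:
            v = okn.v_int if states[i] == INTEGRATED else okn.v_seg
            pos += slow_dir * v * dt
            if pos * slow_dir >= okn.reset_ecc:
                mean_ms = (okn.fastphase_dur_int if states[i] == INTEGRATED
                           else okn.fastphase_dur_seg)
                dur_ms = max(4.0, rng.normal(mean_ms, 0.15 * mean_ms))
                fast_left = int(round(dur_ms * rate / 1000.0))
        x[i] = pos
    if okn.noise_sd > 0:
        x += rng.normal(0.0, okn.noise_sd, size=n)

    valid = np.ones(n, dtype=bool)
    if okn.blink_rate > 0:
        n_blinks = rng.poisson(okn.blink_rate * (n / rate) / 60.0)
        for _ in range(n_blinks):
            d = max(1, int(round(rng.exponential(okn.blink_dur) * rate / 1000.0)))
            s = rng.integers(0, n)
            valid[s:s + d] = False
    x = x.copy()
    x[~valid] = np.nan
    phase[~valid] = 2

    t = np.arange(n) * dt
    return GazeTrace(t=t, x=x, valid=valid, phase_truth=phase)


# --------------------------------------------------------------------------
# Sessions
# --------------------------------------------------------------------------

@dataclass
class SyntheticBlock:
    """All traces of one simulated block, with ground truth."""

    design: BlockDesign
    latent_visual: LatentPerceptTrace
    latent_auditory: LatentPerceptTrace
    report: ReportTrace | None        # the report actually collected
    report_modality: str | None       # which modality the report refers to
    gaze: GazeTrace
    schedule: tuple[tuple[int, float], ...]  # disambiguation ground truth
    seed_key: tuple[int, ...]


@dataclass
class SyntheticSession:
    """One simulated participant-session."""

    design: SessionDesign
    params_visual: PerceptProcessParams
    params_auditory: PerceptProcessParams
    okn: OknParams
    blocks: list[SyntheticBlock]
    master_seed: int

    @property
    def bimodal_blocks(self) -> list[SyntheticBlock]:
        return [b for b in self.blocks if b.design.condition == "bimodal"]

    @property
    def unimodal_visual_blocks(self) -> list[SyntheticBlock]:
        return [b for b in self.blocks if b.design.condition == "unimodal_visual"]

    def manifest(self) -> dict:
        """JSON-serializable session description (block order, schedules, seeds)."""
        return {
            "master_seed": self.master_seed,
            "n_blocks": len(self.blocks),
            "blocks": [
                {
                    "index": i,
                    "condition": b.design.condition,
                    "multistable_dur": b.design.multistable_dur,
                    "disambig_dur": b.design.disambig_dur,
                    "disambig_modality": b.design.disambig_modality,
                    "schedule": [[STATE_NAMES[s], d] for s, d in b.schedule],
                    "report_modality": b.report_modality,
                    "seed_key": list(b.seed_key),
                }
                for i, b in enumerate(self.blocks)
            ],
            "params_visual": vars(self.params_visual).copy(),
            "params_auditory": vars(self.params_auditory).copy(),
            "okn": vars(self.okn).copy(),
        }


def _apply_disambiguation(
    latent: LatentPerceptTrace,
    start_s: float,
    schedule: Sequence[tuple[int, float]],
    transition_lag_s: float = 0.3,
) -> None:
    """Force the latent state to the suggested percept during the tail.

    The forced state takes over ``transition_lag_s`` after each segment onset,
    so hit-rate scoring has a well-defined ground truth while keeping a
    physiologically plausible transition.
    """
    rate = latent.rate
    pos = start_s
    lag = transition_lag_s
    for state, dur in schedule:
        a = int(round((pos + lag) * rate))
        b = int(round((pos + dur) * rate))
        latent.states[a:b] = state
        pos += dur


def build_session(
    design: SessionDesign | None = None,
    params_visual: PerceptProcessParams | None = None,
    params_auditory: PerceptProcessParams | None = None,
    okn: OknParams | None = None,
    seed: int | np.random.SeedSequence = 0,
    gaze_rate: float = 1000.0,
    latent_rate: float = 100.0,
) -> SyntheticSession:
    """Simulate a complete session: latent percepts, reports, gaze per block.

    Visual reports are collected only in unimodal visual blocks; auditory
    reports in unimodal auditory and bimodal blocks.  Disambiguated tails
    force the latent state of the disambiguated modality to the schedule.
    Each block draws its randomness from a child of ``seed`` keyed by the
    block index, so any block can be regenerated in isolation.
    """
    design = design or SessionDesign()
    params_visual = params_visual or PerceptProcessParams()
    params_auditory = params_auditory or PerceptProcessParams()
    okn = okn or OknParams()
    if isinstance(seed, np.random.SeedSequence):
        root = seed
        master = int(root.entropy if isinstance(root.entropy, int) else 0)
    else:
        master = int(seed)
        root = np.random.SeedSequence(master)

    def child(*key: int) -> np.random.SeedSequence:
        # counter scheme: block index x stream appended to the root spawn key,
        # so any block is regenerable in isolation
        return np.random.SeedSequence(
            entropy=root.entropy, spawn_key=tuple(root.spawn_key) + key
        )

    blocks: list[SyntheticBlock] = []
    for i, bd in enumerate(design.blocks):
        ss_percept = child(i, 0)
        ss_report = child(i, 1)
        ss_gaze = child(i, 2)

        lat_v, lat_a = simulate_coupled_percepts(
            params_visual, params_auditory, bd.duration, ss_percept, rate=latent_rate
        )
        if bd.disambig_modality == "visual":
            _apply_disambiguation(lat_v, bd.multistable_dur, bd.disambig_schedule)
        else:
            _apply_disambiguation(lat_a, bd.multistable_dur, bd.disambig_schedule)

        if bd.condition == "unimodal_visual":
            src, mod = lat_v, "visual"
            p = params_visual
        else:
            src, mod = lat_a, "auditory"
            p = params_auditory
        report = simulate_report(src, p.eps_report, p.lag_report, p.gamma_gap, ss_report)

        gaze = simulate_okn(lat_v, okn, rate=gaze_rate, seed=ss_gaze)

        blocks.append(
            SyntheticBlock(
                design=bd,
                latent_visual=lat_v,
                latent_auditory=lat_a,
                report=report,
                report_modality=mod,
                gaze=gaze,
                schedule=bd.disambig_schedule,
                seed_key=(i,),
            )
        )
    return SyntheticSession(
        design=design,
        params_visual=params_visual,
        params_auditory=params_auditory,
        okn=okn,
        blocks=blocks,
        master_seed=master,
    )


# --------------------------------------------------------------------------
# Text I/O (delimited gaze traces, report event tables, manifests)
# --------------------------------------------------------------------------

def write_gaze_csv(trace: GazeTrace, path: str | Path) -> None:
    """Write a gaze trace as delimited text: time_s, x_deg, valid."""
    df = pd.DataFrame(
        {"time_s": trace.t, "x_deg": trace.x, "valid": trace.valid.astype(int)}
    )
    df.to_csv(path, index=False, float_format="%.6f")


def read_gaze_csv(path: str | Path) -> GazeTrace:
    df = pd.read_csv(path)
    valid = df["valid"].to_numpy().astype(bool)
    return GazeTrace(
        t=df["time_s"].to_numpy(float),
        x=df["x_deg"].to_numpy(float),
        valid=valid,
    )


def write_report_events(report: ReportTrace, path: str | Path) -> None:
    """Write a report trace as an event table: onset_s, offset_s, state."""
    rows = []
    for start, stop in _phase_bounds(report.states):
        state = int(report.states[start])
        if state == NONE:
            continue
        rows.append(
            {
                "onset_s": start / report.rate,
                "offset_s": stop / report.rate,
                "state": STATE_NAMES[state],
            }
        )
    pd.DataFrame(rows, columns=["onset_s", "offset_s", "state"]).to_csv(
        path, index=False, float_format="%.6f"
    )


def read_report_events(path: str | Path, rate: float, duration: float) -> ReportTrace:
    df = pd.read_csv(path)
    n = int(round(duration * rate))
    states = np.full(n, NONE, dtype=np.int8)
    name_to_code = {v: k for k, v in STATE_NAMES.items()}
    for _, row in df.iterrows():
        a = int(round(row["onset_s"] * rate))
        b = int(round(row["offset_s"] * rate))
        states[a:b] = name_to_code[row["state"]]
    return ReportTrace(rate=rate, states=states)
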