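"""End-to-end orchestration: simulate -> preprocess -> decode -> couple.

`run_pipeline` simulates N synthetic participants, runs the full analysis
chain for each (OKN preprocessing, lagged features, 6-fold block-role SVM
decoding, bimodal consistency with theoretical/expected bounds), applies the
participant-inclusion criteria, and writes per-participant summaries plus
group statistics to a run directory.  A single master seed is expanded into
per-participant and per-block sub-seeds by a counter scheme, so re-running
with the same config reproduces every number exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coupling as cp
from .decoding import (
    DEFAULT_COST_GRID,
    DecoderModel,
    balanced_accuracy,
    decode_timecourse,
    run_role_permutations,
    score_hit_rate,
)
from .features import EXCLUDED, align_labels, assemble_features
from .preprocessing import OknPreprocessor
from .simulate import (
    OknParams,
    PerceptProcessParams,
    ReportTrace,
    SessionDesign,
    SyntheticSession,
    build_session,
)

__all__ = [
    "RunConfig",
    "ParticipantSummary",
    "run_pipeline",
    "analyze_session",
    "apply_inclusion_criteria",
]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All knobs of a pipeline run; defaults reproduce the reference design
    (1000-Hz gaze, 100-Hz features with lags -2.0...0 s, 11-value cost grid,
    3 unimodal-visual / 2 unimodal-auditory / 8 bimodal blocks)."""

    n_participants: int = 1
    seed: int = 0
    # percept process (per modality)
    mean_dom: float = 9.0
    shape: float = 3.0
    pi_seg_visual: float = 0.5
    pi_seg_auditory: float = 0.5
    kappa: float = 0.6
    eps_report: float = 0.1
    lag_report: float = 0.4
    gamma_gap: float = 0.03
    # OKN generator
    okn: dict = field(default_factory=lambda: dataclasses.asdict(OknParams()))
    # preprocessing
    pad_ms: float = 50.0
    vel_thresh: float = 22.0
    min_dur_ms: float = 4.0
    merge_gap_ms: float = 20.0
    smooth_ms: float = 10.0
    window_s: float = 1.0
    # features
    feature_rate: float = 100.0
    lag_min: float = -2.0
    lag_step: float = 0.1
    standardize: bool = True
    # SVM
    cost_grid: tuple = DEFAULT_COST_GRID
    stride: int = 1
    # paths
    out_dir: str = "runs/default"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cost_grid"] = list(self.cost_grid)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "cost_grid" in d:
            d["cost_grid"] = tuple(d["cost_grid"])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=False)
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(d)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    def percept_params(self, modality: str) -> PerceptProcessParams:
        pi = self.pi_seg_visual if modality == "visual" else self.pi_seg_auditory
        return PerceptProcessParams(
            mean_dom=self.mean_dom,
            shape=self.shape,
            pi_seg=pi,
            kappa=self.kappa,
            eps_report=self.eps_report,
            lag_report=self.lag_report,
            gamma_gap=self.gamma_gap,
        )

    def okn_params(self) -> OknParams:
        return OknParams(**self.okn)

    def preprocessor(self) -> OknPreprocessor:
        return OknPreprocessor(
            pad_ms=self.pad_ms,
            vel_thresh=self.vel_thresh,
            min_dur_ms=self.min_dur_ms,
            merge_gap_ms=self.merge_gap_ms,
            smooth_ms=self.smooth_ms,
            window_s=self.window_s,
            fast_dir=self.okn_params().fast_dir,
        )


@dataclass
class ParticipantSummary:
    """Per-participant outcome of the full analysis chain."""

    participant: int
    decoding_accuracy: float          # mean over the 6 model evaluations
    visual_hit_rate: float            # %, unimodal visual catch trials
    auditory_hit_rate: float          # %, unimodal auditory catch trials
    bimodal_auditory_hit_rate: float  # %, auditory catch trials in bimodal blocks
    prop_seg_visual: float
    prop_seg_auditory: float
    exclusive_fraction_visual: float
    exclusive_fraction_auditory: float
    median_phase_duration_s: float
    consistency: float
    theo_max: float
    theo_min: float
    exp_max: float
    exp_min: float
    n_consistency_cells: int
    # ground-truth latent occupancies over the bimodal multistable parts;
    # NaN when the analysis ran from files without simulator ground truth
    latent_prop_seg_visual: float = float("nan")
    latent_prop_seg_auditory: float = float("nan")
    realized_decoding_accuracy: float = float("nan")
    realized_reporting_accuracy: float = float("nan")
    included: bool = True
    exclusion_flags: tuple = ()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["exclusion_flags"] = list(self.exclusion_flags)
        return d


def _multistable_slice(report: ReportTrace, multistable_dur: float) -> ReportTrace:
    n = int(round(multistable_dur * report.rate))
    return ReportTrace(rate=report.rate, states=report.states[:n].copy())


def _mask_tail(labels: np.ndarray, t: np.ndarray, multistable_dur: float) -> np.ndarray:
    out = labels.copy()
    out[t >= multistable_dur] = EXCLUDED
    return out


def analyze_session(
    session: SyntheticSession, config: RunConfig, participant: int = 0
) -> tuple[ParticipantSummary, list[DecoderModel], cp.ConsistencyResult]:
    """Run the analysis chain for one session.

    All decoding and consistency scoring is restricted to the 180-s
    multistable part of each block; disambiguated tails are used only for
    catch-trial hit rates.
    """
    pre = config.preprocessor()

    # --- unimodal visual blocks: features, labels, 6 models ----------------
    uv_blocks = []
    for block in session.unimodal_visual_blocks:
        okn = pre.transform(block.gaze)
        fm = assemble_features(okn, config.feature_rate, config.lag_min, config.lag_step)
        y = align_labels(fm, block.report)
        y = _mask_tail(y, fm.t, block.design.multistable_dur)
        uv_blocks.append((fm, y))
    models = run_role_permutations(
        uv_blocks,
        cost_grid=tuple(config.cost_grid),
        stride=config.stride,
        standardize_features=config.standardize,
    )
    d = float(np.mean([m.eval_accuracy for m in models]))
    log.info("participant %d: mean evaluation accuracy %.3f", participant, d)

    # --- catch-trial hit rates --------------------------------------------
    def hit_rates(condition: str, disambig: str | None = None) -> float:
        vals = []
        for b in session.blocks:
            if b.design.condition != condition:
                continue
            if disambig is not None and b.design.disambig_modality != disambig:
                continue
            if b.report_modality != b.design.disambig_modality:
                continue
            vals.append(
                score_hit_rate(b.report, b.schedule, start_s=b.design.multistable_dur)
            )
        return float(np.mean(vals))

    hit_v = hit_rates("unimodal_visual")
    hit_a = hit_rates("unimodal_auditory")
    hit_ba = hit_rates("bimodal", disambig="auditory")

    # --- percept proportions (multistable parts) ---------------------------
    uv_reports = [
        _multistable_slice(b.report, b.design.multistable_dur)
        for b in session.unimodal_visual_blocks
    ]
    bi_reports = [
        _multistable_slice(b.report, b.design.multistable_dur)
        for b in session.bimodal_blocks
    ]
    v_props = [cp.percept_proportions(r) for r in uv_reports]
    a_props = [cp.percept_proportions(r) for r in bi_reports]
    v = float(np.mean([p[0] for p in v_props]))
    a = float(np.mean([p[0] for p in a_props]))
    excl_v = float(np.mean([p[2] for p in v_props]))
    excl_a = float(np.mean([p[2] for p in a_props]))
    med_dur = float(np.mean([cp.median_phase_duration(r) for r in bi_reports]))

    # ground-truth latent occupancies over the bimodal multistable parts
    def latent_occ(attr: str) -> float:
        vals = []
        for b in session.bimodal_blocks:
            lat = getattr(b, attr)
            n = int(round(b.design.multistable_dur * lat.rate))
            vals.append(float(lat.states[:n].mean()))
        return float(np.mean(vals))

    lat_v = latent_occ("latent_visual")
    lat_a = latent_occ("latent_auditory")

    # --- bimodal consistency ----------------------------------------------
    bi_features = []
    bi_labels = []
    for block in session.bimodal_blocks:
        okn = pre.transform(block.gaze)
        fm = assemble_features(okn, config.feature_rate, config.lag_min, config.lag_step)
        y = align_labels(fm, block.report)  # auditory report in bimodal blocks
        y = _mask_tail(y, fm.t, block.design.multistable_dur)
        bi_features.append(fm)
        bi_labels.append(y)
    consistency = cp.compute_consistency(models, bi_features, bi_labels)

    # Realized channel accuracies against the latent ground truth, in the
    # report time convention (latents shifted by the report latency): the
    # decoder learns report timing, so these — not the lag-penalized catch
    # trials — are the fidelities the consistency comparison composes.
    lag = config.lag_report
    d_vals, r_vals = [], []
    for block, fm, y in zip(session.bimodal_blocks, bi_features, bi_labels):
        lat_rate = block.latent_visual.rate
        src = np.round((fm.t - lag) * lat_rate).astype(np.int64)
        ok = (src >= 0) & (src < len(block.latent_visual.states))
        lv_shift = np.full(len(fm.t), -1, dtype=np.int8)
        la_shift = np.full(len(fm.t), -1, dtype=np.int8)
        lv_shift[ok] = block.latent_visual.states[src[ok]]
        la_shift[ok] = block.latent_auditory.states[src[ok]]
        keep = (y != EXCLUDED) & ok & fm.complete
        for model in models:
            pred = decode_timecourse(model, fm)
            k = keep & (pred != EXCLUDED)
            try:
                d_vals.append(balanced_accuracy(pred[k], lv_shift[k]).balanced)
            except ValueError:
                pass
        rep_idx = np.round(fm.t * block.report.rate).astype(np.int64)
        rep_idx = np.minimum(rep_idx, len(block.report.states) - 1)
        rep = block.report.states[rep_idx]
        try:
            r_vals.append(balanced_accuracy(rep[keep], la_shift[keep]).balanced)
        except ValueError:
            pass
    d_real = float(np.mean(d_vals)) if d_vals else float("nan")
    r_real = float(np.mean(r_vals)) if r_vals else float("nan")

    bounds = cp.bounds_result(a=a, v=v, d=d, r=hit_ba / 100.0)

    summary = ParticipantSummary(
        participant=participant,
        decoding_accuracy=d,
        visual_hit_rate=hit_v,
        auditory_hit_rate=hit_a,
        bimodal_auditory_hit_rate=hit_ba,
        prop_seg_visual=v,
        prop_seg_auditory=a,
        latent_prop_seg_visual=lat_v,
        latent_prop_seg_auditory=lat_a,
        realized_decoding_accuracy=d_real,
        realized_reporting_accuracy=r_real,
        exclusive_fraction_visual=excl_v,
        exclusive_fraction_auditory=excl_a,
        median_phase_duration_s=med_dur,
        consistency=consistency.mean,
        theo_max=bounds.theo_max,
        theo_min=bounds.theo_min,
        exp_max=bounds.exp_max,
        exp_min=bounds.exp_min,
        n_consistency_cells=consistency.n_cells,
    )
    return summary, models, consistency


def apply_inclusion_criteria(
    summaries: list[ParticipantSummary],
    hit_rate_threshold: float = 70.0,
    accuracy_threshold: float = 0.70,
) -> list[ParticipantSummary]:
    """Flag participants failing the a-priori inclusion criteria.

    A participant is included iff the visual and auditory unimodal
    catch-trial hit rates are both >= 70% and the mean unimodal decoding
    accuracy is >= 70%; each failed criterion is flagged separately.
    """
    out = []
    for s in summaries:
        flags = []
        if s.visual_hit_rate < hit_rate_threshold:
            flags.append("visual_hit_rate")
        if s.auditory_hit_rate < hit_rate_threshold:
            flags.append("auditory_hit_rate")
        if s.decoding_accuracy < accuracy_threshold:
            flags.append("decoding_accuracy")
        out.append(
            dataclasses.replace(s, included=not flags, exclusion_flags=tuple(flags))
        )
    return out


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> Path:
    """Simulate and analyze ``config.n_participants`` synthetic participants.

    Writes to the run directory:

    * ``config.yaml`` — the exact configuration;
    * ``manifest.json`` — config hash, per-participant seeds, block layout;
    * ``participants.csv`` — one summary row per participant;
    * ``consistency_p<k>.csv`` — the 6 x 8 consistency matrix per participant;
    * ``group_stats.json`` — one-sample tests of decoding accuracy and
      consistency against the 50% chance level (when n >= 2).

    Returns the run directory path.
    """
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.save(out / "config.yaml")

    params_v = config.percept_params("visual")
    params_a = config.percept_params("auditory")
    okn = config.okn_params()

    summaries: list[ParticipantSummary] = []
    manifest: dict = {
        "config_hash": config.config_hash(),
        "master_seed": config.seed,
        "participants": [],
    }
    for p in range(config.n_participants):
        root = np.random.SeedSequence(entropy=config.seed, spawn_key=(p,))
        session = build_session(
            SessionDesign(), params_v, params_a, okn, seed=root
        )
        summary, models, consistency = analyze_session(session, config, participant=p)
        summaries.append(summary)
        np.savetxt(
            out / f"consistency_p{p}.csv", consistency.matrix, delimiter=",",
            fmt="%.6f",
        )
        manifest["participants"].append(
            {
                "participant": p,
                "seed_key": [p],
                "n_blocks": len(session.blocks),
                "n_bimodal": len(session.bimodal_blocks),
                "n_models": len(models),
                "session": session.manifest(),
            }
        )

    summaries = apply_inclusion_criteria(summaries)
    df = pd.DataFrame([s.to_dict() for s in summaries])
    df.to_csv(out / "participants.csv", index=False, float_format="%.6f")

    group: dict = {"n": len(summaries)}
    if len(summaries) >= 2:
        acc = np.array([s.decoding_accuracy for s in summaries])
        con = np.array([s.consistency for s in summaries])
        for name, vals in (("decoding_accuracy", acc), ("consistency", con)):
            try:
                gs = cp.group_tests(vals, 0.5)
                group[name] = {
                    "mean": float(vals.mean()),
                    "t": gs.statistic,
                    "df": gs.df,
                    "p": gs.p_value,
                }
            except ValueError as err:
                group[name] = {"mean": float(vals.mean()), "error": str(err)}
    (out / "group_stats.json").write_text(json.dumps(group, indent=2))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
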