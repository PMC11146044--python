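"""File-based pipeline stages for stage-wise (re)execution.

Each stage reads only files written by earlier stages plus the run
configuration, and writes delimited-text intermediates into the run
directory, so deleting any intermediate and re-running its stage
regenerates it identically:

    simulate    gaze traces, report event tables, session manifests
    preprocess  smoothed OKN variables per block (feature-rate grid)
    features    lagged feature matrix + aligned labels per block
    train       six selected decoder models per participant (JSON)
    decode      decoded percept series for the bimodal blocks
    couple      consistency matrices, bounds, per-participant summaries
    report      participant table and group statistics

The in-memory equivalent (:func:`okndecode.pipeline.run_pipeline`) shares
every computational step with these stages; the file layer exists for
auditable, resumable runs from a shell.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import coupling as cp
from .decoding import (
    DecoderModel,
    PerceptDecoder,
    RoleAssignment,
    run_role_permutations,
    score_hit_rate,
)
from .features import EXCLUDED, FeatureMatrix, StandardizationStats, align_labels, assemble_features
from .pipeline import (
    ParticipantSummary,
    RunConfig,
    apply_inclusion_criteria,
    _mask_tail,
    _multistable_slice,
)
from .preprocessing import OknVariables
from .simulate import (
    INTEGRATED,
    SEGREGATED,
    ReportTrace,
    SessionDesign,
    build_session,
    read_gaze_csv,
    read_report_events,
    write_gaze_csv,
    write_report_events,
)

__all__ = [
    "stage_simulate",
    "stage_preprocess",
    "stage_features",
    "stage_train",
    "stage_decode",
    "stage_couple",
    "stage_report",
    "run_stages",
]

_STATE_CODE = {"integrated": INTEGRATED, "segregated": SEGREGATED}


def _participants(run_dir: Path) -> list[Path]:
    return sorted(run_dir.glob("participant_*"))


def _blocks_of(pdir: Path, pattern: str) -> list[Path]:
    return sorted(pdir.glob(pattern))


def _manifest(pdir: Path) -> dict:
    return json.loads((pdir / "manifest.json").read_text())


# --------------------------------------------------------------------------

def stage_simulate(cfg: RunConfig, run_dir: Path) -> None:
    run_dir.mkdir(parents=True, exist_ok=True)
    cfg.save(run_dir / "config.yaml")
    for p in range(cfg.n_participants):
        root = np.random.SeedSequence(entropy=cfg.seed, spawn_key=(p,))
        session = build_session(
            SessionDesign(),
            cfg.percept_params("visual"),
            cfg.percept_params("auditory"),
            cfg.okn_params(),
            seed=root,
        )
        pdir = run_dir / f"participant_{p}"
        pdir.mkdir(exist_ok=True)
        for i, block in enumerate(session.blocks):
            write_gaze_csv(block.gaze, pdir / f"block{i:02d}_gaze.csv")
            write_report_events(block.report, pdir / f"block{i:02d}_report.csv")
        (pdir / "manifest.json").write_text(json.dumps(session.manifest(), indent=2))


def stage_preprocess(cfg: RunConfig, run_dir: Path) -> None:
    """Gaze -> smoothed OKN variables, decimated to the feature-rate grid.

    Feature lags are multiples of the feature-rate step, so the lag matrix
    only ever samples the variables on that subgrid; storing the decimated
    grid loses nothing downstream.
    """
    pre = cfg.preprocessor()
    for pdir in _participants(run_dir):
        for gaze_path in _blocks_of(pdir, "block*_gaze.csv"):
            trace = read_gaze_csv(gaze_path)
            okn = pre.transform(trace)
            step = int(round(okn.rate / cfg.feature_rate))
            sl = slice(0, None, step)
            pd.DataFrame(
                {
                    "time_s": okn.t[sl],
                    "v_smooth": okn.v_smooth[sl],
                    "fp_len": okn.fp_len_smooth[sl],
                    "fp_dist": okn.fp_dist_smooth[sl],
                }
            ).to_csv(
                gaze_path.with_name(gaze_path.name.replace("_gaze", "_okn")),
                index=False,
                float_format="%.8f",
            )


def _read_okn(path: Path, rate: float) -> OknVariables:
    df = pd.read_csv(path)
    return OknVariables(
        t=df["time_s"].to_numpy(float),
        rate=rate,
        v_smooth=df["v_smooth"].to_numpy(float),
        fp_len_smooth=df["fp_len"].to_numpy(float),
        fp_dist_smooth=df["fp_dist"].to_numpy(float),
    )


def stage_features(cfg: RunConfig, run_dir: Path) -> None:
    """OKN variables + reports -> lagged feature matrices with labels."""
    for pdir in _participants(run_dir):
        man = _manifest(pdir)
        for okn_path in _blocks_of(pdir, "block*_okn.csv"):
            i = int(okn_path.name[5:7])
            binfo = man["blocks"][i]
            duration = binfo["multistable_dur"] + binfo["disambig_dur"]
            okn = _read_okn(okn_path, cfg.feature_rate)
            fm = assemble_features(okn, cfg.feature_rate, cfg.lag_min, cfg.lag_step)
            report = read_report_events(
                okn_path.with_name(okn_path.name.replace("_okn", "_report")),
                rate=cfg.feature_rate,
                duration=duration,
            )
            y = align_labels(fm, report)
            y = _mask_tail(y, fm.t, binfo["multistable_dur"])
            n_lags = len(fm.lags)
            cols = {
                "time_s": fm.t,
                "complete": fm.complete.astype(int),
                "label": y,
            }
            for k in range(fm.X.shape[1]):
                cols[f"f{k:02d}"] = fm.X[:, k]
            pd.DataFrame(cols).to_csv(
                okn_path.with_name(okn_path.name.replace("_okn", "_features")),
                index=False,
                float_format="%.8f",
            )
            sidecar = {
                "lags_s": fm.lags.tolist(),
                "variables": list(fm.variable_names),
                "n_features": int(fm.X.shape[1]),
                "n_lags": int(n_lags),
            }
            okn_path.with_name(okn_path.name.replace("_okn.csv", "_features.json")).write_text(
                json.dumps(sidecar)
            )


def _read_features(path: Path) -> tuple[FeatureMatrix, np.ndarray]:
    df = pd.read_csv(path)
    fcols = [c for c in df.columns if c.startswith("f") and c[1:].isdigit()]
    sidecar = json.loads(path.with_suffix(".json").read_text())
    fm = FeatureMatrix(
        t=df["time_s"].to_numpy(float),
        X=df[fcols].to_numpy(float),
        complete=df["complete"].to_numpy().astype(bool),
        lags=np.asarray(sidecar["lags_s"], float),
        variable_names=tuple(sidecar["variables"]),
    )
    return fm, df["label"].to_numpy().astype(np.int8)


def stage_train(cfg: RunConfig, run_dir: Path) -> None:
    """Unimodal visual feature blocks -> six selected decoders (JSON)."""
    for pdir in _participants(run_dir):
        man = _manifest(pdir)
        uv_idx = [b["index"] for b in man["blocks"] if b["condition"] == "unimodal_visual"]
        blocks = [
            _read_features(pdir / f"block{i:02d}_features.csv") for i in uv_idx
        ]
        models = run_role_permutations(
            blocks,
            cost_grid=tuple(cfg.cost_grid),
            stride=cfg.stride,
            standardize_features=cfg.standardize,
        )
        payload = {
            "uv_block_indices": uv_idx,
            "models": [m.to_json() for m in models],
        }
        (pdir / "models.json").write_text(json.dumps(payload))


def _load_models(pdir: Path) -> list[DecoderModel]:
    payload = json.loads((pdir / "models.json").read_text())
    out = []
    for m in payload["models"]:
        dec = PerceptDecoder(cost=m["cost"])
        dec.coef_ = np.asarray(m["weights"], float)
        dec.intercept_ = float(m["bias"])
        dec.classes_ = np.array([INTEGRATED, SEGREGATED], dtype=np.int8)
        dec.n_features_in_ = len(dec.coef_)
        stats = None
        if m["standardization"] is not None:
            stats = StandardizationStats(
                mean=np.asarray(m["standardization"]["mean"], float),
                sd=np.asarray(m["standardization"]["sd"], float),
            )
        out.append(
            DecoderModel(
                decoder=dec,
                cost=m["cost"],
                roles=RoleAssignment(
                    m["roles"]["train"], m["roles"]["opt"], m["roles"]["eval"]
                ),
                stats=stats,
                opt_accuracy=m["opt_accuracy"],
                eval_accuracy=m["eval_accuracy"],
            )
        )
    return out


def stage_decode(cfg: RunConfig, run_dir: Path) -> None:
    """Apply the six decoders to every bimodal block's features."""
    from .decoding import decode_timecourse

    for pdir in _participants(run_dir):
        man = _manifest(pdir)
        models = _load_models(pdir)
        bi_idx = [b["index"] for b in man["blocks"] if b["condition"] == "bimodal"]
        for i in bi_idx:
            fm, _ = _read_features(pdir / f"block{i:02d}_features.csv")
            cols = {"time_s": fm.t}
            for k, model in enumerate(models):
                cols[f"model{k}"] = decode_timecourse(model, fm)
            pd.DataFrame(cols).to_csv(
                pdir / f"block{i:02d}_decoded.csv", index=False, float_format="%.3f"
            )


def stage_couple(cfg: RunConfig, run_dir: Path) -> None:
    """Decoded series + auditory labels -> consistency, bounds, summary."""
    for pdir in _participants(run_dir):
        man = _manifest(pdir)
        models = _load_models(pdir)
        blocks = man["blocks"]
        bi_idx = [b["index"] for b in blocks if b["condition"] == "bimodal"]
        uv_idx = [b["index"] for b in blocks if b["condition"] == "unimodal_visual"]
        ua_idx = [b["index"] for b in blocks if b["condition"] == "unimodal_auditory"]

        n_m = len(models)
        matrix = np.full((n_m, len(bi_idx)), np.nan)
        for j, i in enumerate(bi_idx):
            df = pd.read_csv(pdir / f"block{i:02d}_decoded.csv")
            _, y = _read_features(pdir / f"block{i:02d}_features.csv")
            for k in range(n_m):
                pred = df[f"model{k}"].to_numpy().astype(np.int8)
                keep = (y != EXCLUDED) & (pred != EXCLUDED)
                try:
                    from .decoding import balanced_accuracy

                    matrix[k, j] = balanced_accuracy(pred[keep], y[keep]).balanced
                except ValueError:
                    continue
        p = int(pdir.name.split("_")[1])
        np.savetxt(run_dir / f"consistency_p{p}.csv", matrix, delimiter=",", fmt="%.6f")

        def report_of(i: int) -> tuple[ReportTrace, dict]:
            binfo = blocks[i]
            duration = binfo["multistable_dur"] + binfo["disambig_dur"]
            rep = read_report_events(
                pdir / f"block{i:02d}_report.csv", rate=cfg.feature_rate,
                duration=duration,
            )
            return rep, binfo

        def hit(indices: list[int], disambig: str | None = None) -> float:
            vals = []
            for i in indices:
                rep, binfo = report_of(i)
                if disambig is not None and binfo["disambig_modality"] != disambig:
                    continue
                if binfo["report_modality"] != binfo["disambig_modality"]:
                    continue
                schedule = [(_STATE_CODE[s], d) for s, d in binfo["schedule"]]
                vals.append(score_hit_rate(rep, schedule, start_s=binfo["multistable_dur"]))
            return float(np.mean(vals))

        uv_reports = [
            _multistable_slice(*_dur_pair(report_of(i))) for i in uv_idx
        ]
        bi_reports = [
            _multistable_slice(*_dur_pair(report_of(i))) for i in bi_idx
        ]
        v_props = [cp.percept_proportions(r) for r in uv_reports]
        a_props = [cp.percept_proportions(r) for r in bi_reports]
        v = float(np.mean([x[0] for x in v_props]))
        a = float(np.mean([x[0] for x in a_props]))
        d = float(np.mean([m.eval_accuracy for m in models]))
        hit_ba = hit(bi_idx, disambig="auditory")
        bounds = cp.bounds_result(a=a, v=v, d=d, r=hit_ba / 100.0)

        summary = ParticipantSummary(
            participant=p,
            decoding_accuracy=d,
            visual_hit_rate=hit(uv_idx),
            auditory_hit_rate=hit(ua_idx),
            bimodal_auditory_hit_rate=hit_ba,
            prop_seg_visual=v,
            prop_seg_auditory=a,
            exclusive_fraction_visual=float(np.mean([x[2] for x in v_props])),
            exclusive_fraction_auditory=float(np.mean([x[2] for x in a_props])),
            median_phase_duration_s=float(
                np.mean([cp.median_phase_duration(r) for r in bi_reports])
            ),
            consistency=float(np.nanmean(matrix)),
            theo_max=bounds.theo_max,
            theo_min=bounds.theo_min,
            exp_max=bounds.exp_max,
            exp_min=bounds.exp_min,
            n_consistency_cells=int(matrix.size),
        )
        (pdir / "summary.json").write_text(json.dumps(summary.to_dict(), indent=2))


def _dur_pair(pair: tuple[ReportTrace, dict]) -> tuple[ReportTrace, float]:
    rep, binfo = pair
    return rep, binfo["multistable_dur"]


def stage_report(cfg: RunConfig, run_dir: Path) -> None:
    """Collect summaries into the participant table + group statistics."""
    summaries = []
    for pdir in _participants(run_dir):
        d = json.loads((pdir / "summary.json").read_text())
        d["exclusion_flags"] = tuple(d.get("exclusion_flags", ()))
        summaries.append(ParticipantSummary(**d))
    summaries = apply_inclusion_criteria(summaries)
    df = pd.DataFrame([s.to_dict() for s in summaries])
    df.to_csv(run_dir / "participants.csv", index=False, float_format="%.6f")
    group: dict = {"n": len(summaries)}
    if len(summaries) >= 2:
        for name in ("decoding_accuracy", "consistency"):
            vals = df[name].to_numpy(float)
            try:
                gs = cp.group_tests(vals, 0.5)
                group[name] = {
                    "mean": float(vals.mean()), "t": gs.statistic,
                    "df": gs.df, "p": gs.p_value,
                }
            except ValueError as err:
                group[name] = {"mean": float(vals.mean()), "error": str(err)}
    (run_dir / "group_stats.json").write_text(json.dumps(group, indent=2))


_STAGES = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "features": stage_features,
    "train": stage_train,
    "decode": stage_decode,
    "couple": stage_couple,
    "report": stage_report,
}


def run_stages(cfg: RunConfig, run_dir: str | Path, stages: list[str] | None = None) -> Path:
    """Run the named stages (default: all, in order) on a run directory."""
    run_dir = Path(run_dir)
    for name in stages or list(_STAGES):
        _STAGES[name](cfg, run_dir)
    return run_dir
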