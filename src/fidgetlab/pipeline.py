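"""End-to-end orchestration: simulate -> detect -> quantify -> cluster ->
decode -> modulate, with per-stage artifacts and a markdown report.

A single global seed fans out to per-stage seeds by fixed offsets so each
stage is individually reproducible; every run writes its resolved
configuration beside the results.  Stages run in dependency order and a
failure aborts with the stage name while keeping the artifacts already
written.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior, flow, io, modulation, neural, synthdata

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

# fixed per-stage seed offsets
_STAGE_SEED = {"simulate": 11, "behavior": 23, "flow": 37, "neural": 41, "decode": 53, "modulation": 67}


@dataclass
class RunConfig:
    out_dir: str = "fidgetlab_run"
    seed: int = 0
    # cohort
    n_sessions: int = 6
    n_video_sessions: int = 3  # leading sessions also get rendered video
    areas: tuple[str, ...] = ("VISp", "VISpm", "VISal", "VISl")
    depths: tuple[int, ...] = (175, 275, 375)
    cre_lines: tuple[str, ...] = ("Cux2", "Rorb", "Rbp4")
    area_effect: float = 0.0
    synth: dict = field(default_factory=lambda: {"session_duration": 240.0, "n_fidgets": 10, "n_neurons": 150})
    # behavior
    crop: tuple[int, int, int, int] | None = (16, 16, 112, 112)
    min_event_frames: int = 10
    merge_gap_frames: int = 5
    # decode
    label_sets: tuple[str, ...] = ("area", "layer")
    embedding_variant: str = "default"
    decode_grid: dict = field(
        default_factory=lambda: {"max_depth": [2, 4], "learning_rate": [0.3], "n_estimators": [100]}
    )
    n_shuffles: int = 5
    # modulation
    q_fdr: float = 0.05

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("areas", "depths", "cre_lines", "label_sets", "crop"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _synth_config(config: RunConfig) -> synthdata.SynthConfig:
    return synthdata.SynthConfig(
        seed=config.seed + _STAGE_SEED["simulate"],
        area_effect=config.area_effect,
        **config.synth,
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns a summary dict (also written as JSON)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "resolved_config.yaml")
    summary: dict = {"seed": config.seed}

    stage = "simulate"
    try:
        base = _synth_config(config)
        sessions = synthdata.generate_cohort(
            config.n_sessions,
            areas=config.areas,
            depths=config.depths,
            cre_lines=config.cre_lines,
            config=base,
            with_video=False,
        )
        video_sessions = []
        for i in range(min(config.n_video_sessions, config.n_sessions)):
            cfg_i = base.replace(seed=base.seed + 1000 + i)
            video_sessions.append(synthdata.generate_video_session(cfg_i))
        summary["n_sessions"] = len(sessions)

        stage = "behavior"
        bdir = out / "behavior"
        bdir.mkdir(exist_ok=True)
        crop = behavior.CropRectangle(*config.crop) if config.crop else None
        detected_events = None
        if len(video_sessions) >= 2:
            train = video_sessions[:-1]
            frames_t, track_t, events_t, _ = video_sessions[-1]
            model = behavior.fit_detector_on_sessions(
                [v[0] for v in train],
                [v[1] for v in train],
                crop=crop,
                seed=config.seed + _STAGE_SEED["behavior"],
            )
            model.save(bdir / "detector.zip")
            pred_track, detected_events = behavior.detect_session(
                model, frames_t, crop=crop,
                min_duration_frames=config.min_event_frames,
                merge_gap_frames=config.merge_gap_frames,
            )
            metrics = behavior.score_detection(detected_events, events_t)
            io.write_events(detected_events, bdir / "events_test.csv")
            summary["detection"] = {
                "recall": metrics.recall,
                "precision": metrics.precision,
                "n_events_true": metrics.n_events_true,
                "n_events_pred": metrics.n_events_pred,
            }
            (bdir / "metrics.json").write_text(json.dumps(summary["detection"]))

        stage = "flow"
        if detected_events:
            fdir = out / "flow"
            fdir.mkdir(exist_ok=True)
            pre = behavior.preprocess_frames(frames_t, crop=crop, gamma=0.5)
            mags = [
                flow.event_magnitude(pre, e.onset_frame, e.offset_frame)
                for e in detected_events
            ]
            stereo = flow.magnitude_stereotypy(mags)
            io.write_events(
                [dataclasses.replace(e, magnitude=m) for e, m in zip(detected_events, mags)],
                fdir / "events_with_magnitude.csv",
            )
            summary["stereotypy"] = {
                "fraction_within_30pct": stereo.fraction_within_30pct,
                "n_events": len(mags),
            }
            (fdir / "stereotypy.json").write_text(json.dumps(summary["stereotypy"]))

        stage = "neural"
        ndir = out / "neural"
        ndir.mkdir(exist_ok=True)
        resp, meta = neural.cohort_mean_responses(sessions)
        gap = neural.cluster_mean_responses(
            resp.mean_z, k_range=range(1, 7), n_ref=10, seed=config.seed + _STAGE_SEED["neural"]
        )
        assignments = neural.assign_response_types(resp.mean_z, gap_result=gap)
        table = assignments.merge(meta, on="neuron_id")
        table.to_csv(ndir / "assignments.csv", index=False)
        dist_area = neural.type_distribution(assignments, meta, "area")
        dist_layer = neural.type_distribution(assignments, meta, "layer")
        dist_area.to_csv(ndir / "distribution_area.csv")
        dist_layer.to_csv(ndir / "distribution_layer.csv")
        summary["neural"] = {
            "optimal_k": int(gap.optimal_k),
            "n_neurons": int(len(assignments)),
            "pct_non_neutral": float(100 * np.mean(assignments.type_label != "neutral")),
        }
        (ndir / "gap.json").write_text(
            json.dumps(
                {
                    "optimal_k": int(gap.optimal_k),
                    "k_values": gap.k_values.tolist(),
                    "gap": gap.gap.tolist(),
                    "s_k": gap.s_k.tolist(),
                }
            )
        )

        stage = "decode"
        from . import decode as decode_mod

        ddir = out / "decode"
        ddir.mkdir(exist_ok=True)
        emb = decode_mod.embed_variant(
            resp.mean_z[:, 100:], config.embedding_variant, seed=config.seed + _STAGE_SEED["decode"]
        )
        summary["decode"] = {}
        for label_set in config.label_sets:
            if label_set == "layer":
                y = meta["depth_um"].map(neural.layer_from_depth).to_numpy()
            elif label_set == "area":
                y = meta["area"].to_numpy()
            elif label_set in ("cre", "cre_line"):
                y = meta["cre_line"].to_numpy()
            else:
                raise ValueError(f"unknown label set {label_set!r}")
            res = decode_mod.decode_with_baseline(
                emb, y, label_set=label_set,
                n_shuffles=config.n_shuffles,
                grid=config.decode_grid,
                seed=config.seed + _STAGE_SEED["decode"],
            )
            payload = {
                "classes": res.classes,
                "f1": res.f1,
                "mean_f1": res.mean_f1,
                "shuffled_mean_f1": res.shuffled_mean_f1,
                "shuffled_sd_f1": res.shuffled_sd_f1,
                "best_params": res.best_params,
            }
            (ddir / f"decode_{label_set}.json").write_text(json.dumps(payload))
            summary["decode"][label_set] = {
                "mean_f1": res.mean_f1,
                "shuffled_mean_f1": res.shuffled_mean_f1,
            }

        stage = "modulation"
        mdir = out / "modulation"
        mdir.mkdir(exist_ok=True)
        per_cell, interactions = [], []
        offset = 0
        for si, sess in enumerate(sessions):
            pref = modulation.preferred_condition(sess.dff, sess.stim_table)
            n_frames = sess.dff.shape[1]
            fid = modulation.fidget_state_mask(sess.truth["events"], n_frames)
            run = modulation.running_state_mask(sess.running_speed, fps=base.fps)
            sm_f = modulation.state_modulation(
                sess.dff, sess.stim_table, fid, pref, "fidget/nonfidget", exclude_mask=run
            )
            sm_r = modulation.state_modulation(
                sess.dff, sess.stim_table, run, pref, "running/stationary", exclude_mask=fid
            )
            in_f, out_f = modulation.preferred_trial_samples(sess.dff, sess.stim_table, pref, fid, run)
            in_r, out_r = modulation.preferred_trial_samples(sess.dff, sess.stim_table, pref, run, fid)
            sig_f = modulation.per_cell_significance(in_f, out_f, q=config.q_fdr)
            sig_r = modulation.per_cell_significance(in_r, out_r, q=config.q_fdr)
            tun = modulation.tuning_metrics(sess.dff, sess.stim_table)
            df = pd.DataFrame(
                {
                    "neuron_id": np.arange(len(pref)) + offset,
                    "session": si,
                    "d_fidget": sm_f["cohens_d"],
                    "d_running": sm_r["cohens_d"],
                    "p_fidget": sig_f["p_value"],
                    "p_running": sig_r["p_value"],
                    "sig_fidget": sig_f["q_significant"],
                    "sig_running": sig_r["q_significant"],
                    "dsi": tun["dsi"],
                    "pref_direction_deg": tun["pref_direction_deg"],
                    "pref_tf_hz": tun["pref_tf_hz"],
                }
            )
            per_cell.append(df)
            offset += len(pref)
        cells = pd.concat(per_cell, ignore_index=True)
        cells.to_csv(mdir / "per_cell.csv", index=False)
        inter = modulation.modulation_interaction(
            cells["d_fidget"].to_numpy(),
            cells["d_running"].to_numpy(),
            cells["sig_fidget"].to_numpy(),
            cells["sig_running"].to_numpy(),
        )
        summary["modulation"] = {
            "correlation_d": inter.correlation,
            "covariance_d": inter.covariance,
            "joint_fraction": inter.joint_fraction,
            "n_sig_fidget": inter.n_sig_fidget,
            "n_sig_running": inter.n_sig_running,
        }
        (mdir / "interaction.json").write_text(json.dumps(summary["modulation"]))
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise PipelineError(stage, exc) from exc

    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    write_report(summary, out / "report.md")
    return summary


def write_report(summary: dict, path) -> None:
    lines = ["# fidgetlab run report", ""]
    if "detection" in summary:
        d = summary["detection"]
        lines += [
            "## Fidget detection (held-out session)",
            f"- event-level recall: {d['recall']:.3f}",
            f"- event-level precision: {d['precision']:.3f}",
            f"- events (true/pred): {d['n_events_true']}/{d['n_events_pred']}",
            "",
        ]
    if "stereotypy" in summary:
        s = summary["stereotypy"]
        lines += [
            "## Fidget magnitude stereotypy",
            f"- fraction of events within 30% of the maximum magnitude: "
            f"{s['fraction_within_30pct']:.3f} (n={s['n_events']})",
            "",
        ]
    if "neural" in summary:
        n = summary["neural"]
        lines += [
            "## Response clustering",
            f"- gap-statistic optimal k: {n['optimal_k']}",
            f"- neurons clustered: {n['n_neurons']}",
            f"- % non-neutral: {n['pct_non_neutral']:.1f}",
            "",
        ]
    if "decode" in summary:
        lines += ["## Decoding of anatomical identity"]
        for k, v in summary["decode"].items():
            lines.append(
                f"- {k}: mean F1 {v['mean_f1']:.3f} vs shuffled {v['shuffled_mean_f1']:.3f}"
            )
        lines.append("")
    if "modulation" in summary:
        m = summary["modulation"]
        jf = m["joint_fraction"]
        lines += [
            "## Fidget vs running modulation",
            f"- correlation of Cohen's d (fidget, running): {m['correlation_d']:.3f}",
            f"- running-modulated cells also fidget-modulated: "
            + (f"{100 * jf:.1f}%" if jf == jf else "undefined"),
            "",
        ]
    Path(path).write_text("\n".join(lines))
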