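"""Pipeline orchestration: simulate -> preprocess -> train -> loop -> stats.

Each stage writes its artifacts under ``<out>/<stage>/`` and a
:class:`RunManifest` records the config snapshot, derived seeds, artifact
digests and timestamps. Reruns with the same config and seed produce
bit-identical CSV outputs (timestamps live only in the manifest).

The pipeline operates at the feature level: per-event spectral features are
drawn directly from the generating model. Raw-signal simulation and the
sigproc chain are exercised through the library API (see
:mod:`memloop.synthgen` and :mod:`memloop.sigproc`).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from memloop import io as mio
from memloop import stimstats
from memloop.config import StudyConfig
from memloop.decoder import ClassifierModel, auc, predict, train
from memloop.loopsim import LoopPolicy, build_flanking_table, match_controls, run_closed_loop_session
from memloop.sigproc import normalize_features
from memloop.synthgen import (
    make_schedule,
    make_subject,
    simulate_features,
    simulate_recall,
    simulate_record_session,
)

STAGES = ("simulate", "preprocess", "train", "loop", "stats")


class DependencyError(RuntimeError):
    """A requested stage is missing an upstream artifact."""


@dataclass
class RunManifest:
    config: dict
    seed: int
    stages: list[str]
    artifacts: dict[str, str]  # relative path -> sha256
    started: str
    finished: str

    def to_dict(self) -> dict:
        return dict(
            schema_version=1, config=self.config, seed=self.seed,
            stages=self.stages, artifacts=self.artifacts,
            started=self.started, finished=self.finished,
        )


def _sites(config: StudyConfig) -> list[str]:
    return [make_subject(config, i).site for i in range(config.n_subjects)]


def run_pipeline(
    config: StudyConfig,
    out_dir: str,
    stages: Optional[Sequence[str]] = None,
    policy: Optional[LoopPolicy] = None,
) -> RunManifest:
    """Execute the requested stages (default: all, in order)."""
    stages = list(stages or STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}")
    stages = [s for s in STAGES if s in stages]
    out = Path(out_dir)
    started = _dt.datetime.now(_dt.timezone.utc).isoformat()
    artifacts: dict[str, str] = {}
    runner = _Runner(config, out, policy or LoopPolicy(), artifacts)
    for stage in stages:
        getattr(runner, stage)()
    finished = _dt.datetime.now(_dt.timezone.utc).isoformat()
    manifest = RunManifest(
        config=config.to_dict(), seed=config.seed, stages=stages,
        artifacts=artifacts, started=started, finished=finished,
    )
    mio.write_json(manifest.to_dict(), out / "manifest.json")
    return manifest


class _Runner:
    def __init__(self, config: StudyConfig, out: Path, policy: LoopPolicy,
                 artifacts: dict[str, str]) -> None:
        self.config = config
        self.out = out
        self.policy = policy
        self.artifacts = artifacts

    # -- helpers ---------------------------------------------------------
    def _dir(self, stage: str) -> Path:
        d = self.out / stage
        d.mkdir(parents=True, exist_ok=True)
        return d

    def _register(self, path: Path) -> None:
        self.artifacts[str(path.relative_to(self.out))] = mio.file_digest(path)

    def _require(self, path: Path, producer: str) -> Path:
        if not path.exists():
            raise DependencyError(
                f"missing artifact {path}: run the {producer!r} stage first"
            )
        return path

    # -- stages ----------------------------------------------------------
    def simulate(self) -> None:
        cfg = self.config
        d = self._dir("simulate")
        for i in range(cfg.n_subjects):
            profile = make_subject(cfg, i)
            for s in range(cfg.n_record_sessions):
                events, feats = simulate_record_session(cfg, profile, s)
                ep = d / f"record_events_{profile.site}_{s}.csv"
                fp = d / f"record_feats_{profile.site}_{s}.h5"
                mio.write_events(events, ep)
                mio.write_features(feats, fp, provenance={"stage": "simulate"})
                self._register(ep), self._register(fp)
            base = ("loop", profile.site)
            sched = make_schedule(cfg, cfg.seed_for(*base, "sched"), kind="closed_loop")
            events = simulate_recall(
                sched, cfg, seed=cfg.seed_for(*base, "recall"),
                profile=profile, session=cfg.n_record_sessions,
            )
            feats = simulate_features(events, cfg, seed=cfg.seed_for(*base, "feats"),
                                      profile=profile)
            ep = d / f"loop_events_{profile.site}.csv"
            fp = d / f"loop_feats_{profile.site}.h5"
            mio.write_events(events, ep)
            mio.write_features(feats, fp, provenance={"stage": "simulate"})
            self._register(ep), self._register(fp)

    def preprocess(self) -> None:
        cfg = self.config
        d = self._dir("preprocess")
        sim = self.out / "simulate"
        for i in range(cfg.n_subjects):
            profile = make_subject(cfg, i)
            for s in range(cfg.n_record_sessions):
                src = self._require(
                    sim / f"record_feats_{profile.site}_{s}.h5", "simulate"
                )
                feats = mio.read_features(src)
                normed = normalize_features(feats, mode="within_session")
                fp = d / f"record_zfeats_{profile.site}_{s}.h5"
                mio.write_features(normed, fp, provenance={"stage": "preprocess",
                                                           "mode": "within_session"})
                self._register(fp)

    def train(self) -> None:
        cfg = self.config
        d = self._dir("train")
        sim, pre = self.out / "simulate", self.out / "preprocess"
        for i in range(cfg.n_subjects):
            profile = make_subject(cfg, i)
            X, y = [], []
            for s in range(cfg.n_record_sessions):
                fsrc = self._require(
                    pre / f"record_zfeats_{profile.site}_{s}.h5", "preprocess"
                )
                esrc = self._require(
                    sim / f"record_events_{profile.site}_{s}.csv", "simulate"
                )
                X.append(mio.read_features(fsrc).values)
                y.append(mio.read_events(esrc)["recalled"].to_numpy())
            feats0 = mio.read_features(pre / f"record_zfeats_{profile.site}_0.h5")
            model = train(
                np.vstack(X), np.concatenate(y),
                pair_labels=feats0.pair_labels, freqs=feats0.freqs,
                training_sessions=list(range(cfg.n_record_sessions)),
            )
            scores = predict(model, np.vstack(X))
            meta = {"training_auc": auc(scores, np.concatenate(y))}
            mp = d / f"model_{profile.site}.json"
            model.save(mp)
            mio.write_json(meta, d / f"model_{profile.site}_meta.json")
            self._register(mp)

    def loop(self) -> None:
        cfg = self.config
        d = self._dir("loop")
        sim, tr = self.out / "simulate", self.out / "train"
        for i in range(cfg.n_subjects):
            profile = make_subject(cfg, i)
            model = ClassifierModel.load(
                self._require(tr / f"model_{profile.site}.json", "train")
            )
            events = mio.read_events(
                self._require(sim / f"loop_events_{profile.site}.csv", "simulate")
            )
            feats = mio.read_features(
                self._require(sim / f"loop_feats_{profile.site}.h5", "simulate")
            )
            sched = make_schedule(
                cfg, cfg.seed_for("loop", profile.site, "sched"), kind="closed_loop"
            )
            log, out_events = run_closed_loop_session(
                model, feats, sched, events, policy=self.policy,
                config=cfg, profile=profile,
            )
            out_events["group"] = cfg.group
            lp = d / f"loop_log_{profile.site}.csv"
            ep = d / f"loop_events_final_{profile.site}.csv"
            log.records.to_csv(lp, index=False)
            mio.write_events(out_events, ep)
            self._register(lp), self._register(ep)

    def stats(self) -> None:
        cfg = self.config
        d = self._dir("stats")
        loop_dir = self.out / "loop"
        all_events, trials, flanks = [], [], []
        for i in range(cfg.n_subjects):
            profile = make_subject(cfg, i)
            ep = self._require(
                loop_dir / f"loop_events_final_{profile.site}.csv", "loop"
            )
            events = mio.read_events(ep)
            all_events.append(events)
            analyzed = match_controls(None, events)
            trials.append(
                pd.DataFrame(dict(
                    recalled=analyzed["recalled"].astype(int),
                    stim=analyzed["condition"],
                    group=cfg.group,
                    subject=analyzed["subject"],
                    site=analyzed["site"],
                    serial_pos=analyzed["serial_pos"],
                    flank=0,
                ))
            )
            fl = build_flanking_table(events)
            if len(fl):
                flanks.append(
                    pd.DataFrame(dict(
                        recalled=fl["recalled"].astype(int),
                        stim=fl["condition"], group=cfg.group,
                        subject=fl["subject"], site=fl["site"],
                        serial_pos=fl["serial_pos"], flank=1,
                    ))
                )
        trial_table = pd.concat(trials, ignore_index=True)
        estimates = [stimstats.fit_stim_glme(trial_table)]
        estimates.append(stimstats.fit_log_binomial(trial_table))
        if flanks:
            flank_table = pd.concat(flanks, ignore_index=True)
            if flank_table["stim"].nunique() == 2:
                estimates.append(stimstats.fit_flanking_glme(flank_table))
        events_all = pd.concat(all_events, ignore_index=True)
        delta_tab = stimstats.build_delta_table(events_all)
        if len(delta_tab) and delta_tab["stim"].nunique() == 2:
            estimates.append(stimstats.delta_classifier_analysis(delta_tab))
        results = stimstats.estimates_frame(estimates)
        rp = d / "effect_estimates.csv"
        results.to_csv(rp, index=False)
        self._register(rp)
        tp = d / "trial_table.csv"
        trial_table.to_csv(tp, index=False)
        self._register(tp)


def render_report(out_dir: str) -> str:
    """Human-readable summary of the stats stage."""
    out = Path(out_dir)
    path = out / "stats" / "effect_estimates.csv"
    if not path.exists():
        raise DependencyError(f"missing artifact {path}: run the 'stats' stage first")
    df = pd.read_csv(path)
    lines = ["Stimulation effect estimates", "=" * 60]
    for _, r in df.iterrows():
        lines.append(
            f"{r['estimand']:<38} {r['estimate']:.4f} "
            f"(t({int(r['df'])}) = {r['t']:.2f}, p = {r['p']:.4f}) [{r['scale']}]"
        )
    return "\n".join(lines)
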