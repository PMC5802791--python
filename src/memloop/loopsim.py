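"""Closed-loop session simulation.

Online loop contract:

* Baseline normalization statistics are fit on the practice list plus lists
  1-3; every later event is z-scored with the statistics version current at
  decode time and classified.
* On Stim lists, a decoded recall probability strictly below the threshold
  (default 0.5) triggers 500 ms of stimulation; on NoStim lists stimulation
  is disabled but below-threshold events are flagged as matched controls.
* After each completed NoStim list the normalization statistics are refit on
  all non-Stim-list events so far (practice, baseline and completed NoStim
  lists); Stim-list events never enter the statistics.
* Stimulation effects are injected through generator hooks: the stimulated
  word's recall odds change by the generating log-odds, and the next word's
  features are shifted along the classifier direction so its decoded
  probability moves by the configured amount.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import ttest_ind

from memloop.config import LATERAL_TEMPORAL, StudyConfig
from memloop.decoder import ClassifierModel, predict
from memloop.sigproc import NormStats, PowerFeatures, compute_norm_stats
from memloop.synthgen import (
    NOSTIM,
    STIM,
    SubjectProfile,
    TaskSchedule,
    apply_stim_effects_to_recall,
)


class SelectionError(ValueError):
    """Target selection is impossible (e.g. a single-class recall record)."""


class NoValidParameterError(ValueError):
    """All pretest stimulation parameters exceed the safety cap."""


class SequencingError(RuntimeError):
    """The closed-loop simulation requested an unavailable statistics version."""


@dataclass
class LoopPolicy:
    """Closed-loop trigger policy."""

    threshold: float = 0.5
    stim_duration_ms: float = 500.0
    decode_latency_ms: float = 1366.0  # decode completes at epoch end

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must lie in [0, 1]")


@dataclass
class TargetSelection:
    pair_index: int
    pair_label: str
    priority_class: str  # "lateral_temporal" or "other"
    t_stats: np.ndarray


@dataclass
class ClosedLoopLog:
    """Per-event decode/trigger record plus per-session summary counts."""

    records: pd.DataFrame
    summary: pd.DataFrame


# ---------------------------------------------------------------------------
# target and parameter selection
# ---------------------------------------------------------------------------
def select_target(
    record_feats: PowerFeatures,
    labels,
    pair_regions: list[str],
    hfa_min_hz: float = 70.0,
) -> TargetSelection:
    """Pick the stimulation pair with the largest high-frequency memory effect.

    Per pair: two-sample t statistic (recalled vs forgotten) of mean z-power
    over frequencies >= 70 Hz. Lateral temporal pairs take priority when any
    exist; ties break to the lowest pair index.
    """
    y = np.asarray(labels).astype(bool)
    if y.all() or not y.any():
        raise SelectionError("need both recalled and forgotten events")
    if len(pair_regions) != len(record_feats.pair_labels):
        raise ValueError("one region label per pair is required")
    hfa_mask = record_feats.freqs >= hfa_min_hz
    if not hfa_mask.any():
        raise ValueError("no analysis frequencies in the high-frequency range")
    t_stats = np.empty(len(record_feats.pair_labels))
    for i in range(len(record_feats.pair_labels)):
        cols = record_feats.values[:, record_feats.columns_for_pair(i)][:, hfa_mask]
        hfa = cols.mean(axis=1)
        t_stats[i] = ttest_ind(hfa[y], hfa[~y], equal_var=True).statistic
    lateral = np.asarray([r == LATERAL_TEMPORAL for r in pair_regions])
    if lateral.any():
        candidates = np.flatnonzero(lateral)
        priority = "lateral_temporal"
    else:
        candidates = np.arange(len(t_stats))
        priority = "other"
    best = candidates[int(np.argmax(t_stats[candidates]))]
    return TargetSelection(int(best), record_feats.pair_labels[best], priority, t_stats)


def choose_stim_params(
    pretest: pd.DataFrame, amplitude_cap: float = 1.5
) -> tuple[float, float]:
    """Pick the (frequency, amplitude) maximizing the classifier-output change.

    ``pretest`` columns: frequency, amplitude, delta. Rows above the safety
    cap are excluded; ties break to lower amplitude, then lower frequency.
    Returns ``(frequency, amplitude)``.
    """
    if len(pretest) == 0:
        raise ValueError("pretest table is empty")
    ok = pretest[pretest["amplitude"] <= amplitude_cap]
    if len(ok) == 0:
        raise NoValidParameterError(
            f"all pretest amplitudes exceed the {amplitude_cap} mA cap"
        )
    ordered = ok.sort_values(
        ["delta", "amplitude", "frequency"], ascending=[False, True, True],
        kind="mergesort",
    )
    row = ordered.iloc[0]
    return float(row["frequency"]), float(row["amplitude"])


# ---------------------------------------------------------------------------
# closed-loop session
# ---------------------------------------------------------------------------
def run_closed_loop_session(
    model: ClassifierModel,
    raw_feats: PowerFeatures,
    schedule: TaskSchedule,
    events: pd.DataFrame,
    policy: Optional[LoopPolicy] = None,
    config: Optional[StudyConfig] = None,
    profile: Optional[SubjectProfile] = None,
    stim_enabled: bool = True,
) -> tuple[ClosedLoopLog, pd.DataFrame]:
    """Simulate one closed-loop session.

    ``raw_feats`` are the session's un-normalized features aligned row-wise
    with ``events`` (which must carry the latent recall draws written by
    :func:`memloop.synthgen.simulate_recall`). When ``config`` is given,
    stimulation effects are injected: recall odds via the generating model
    and the post-stimulation word's decoded probability via a feature shift
    back-solved through ``model``. ``stim_enabled=False`` runs the identical
    observation path without marking any event stimulated.
    """
    policy = policy or LoopPolicy()
    if raw_feats.n_events != len(events):
        raise ValueError("features and events are misaligned")
    if raw_feats.n_features != model.n_features:
        raise ValueError("model feature map does not match the session montage")

    roles = events["list_role"].to_numpy()
    lists = events["list_index"].to_numpy()
    order = np.lexsort((events["serial_pos"].to_numpy(), lists))
    values = raw_feats.values.copy()

    baseline_mask = np.isin(roles, ["practice", "baseline"])
    if baseline_mask.sum() < 2:
        raise SequencingError("no baseline events to fit normalization statistics")
    norm_mask = baseline_mask.copy()  # grows after each completed NoStim list
    stats = _fit_stats(values, norm_mask, version=0)

    n = len(events)
    prob = np.full(n, np.nan)
    trig = np.zeros(n, dtype=bool)
    matched = np.zeros(n, dtype=bool)
    version_used = np.full(n, -1)
    stim_to_next = np.full(n, np.nan)
    delta = config.stim_feature_delta if config is not None else 0.0

    onsets = events["onset_ms"].to_numpy()
    task_order = [i for i in order if roles[i] in (STIM, NOSTIM)]
    prev_triggered_in_list: Optional[int] = None
    current_list = None
    for i in task_order:
        if lists[i] != current_list:
            # list boundary: refit stats if the completed list was NoStim
            if current_list is not None and _role_of(roles, lists, current_list) == NOSTIM:
                norm_mask |= lists == current_list
                stats = _fit_stats(values, norm_mask, version=stats.version + 1)
            current_list = lists[i]
            prev_triggered_in_list = None
        if stats is None:  # pragma: no cover - defensive
            raise SequencingError("normalization statistics unavailable")
        x = (values[i] - stats.mean) / stats.sd
        s = float(x @ model.weights + model.intercept)
        p = float(expit(s))
        if prev_triggered_in_list is not None and delta != 0.0:
            # post-stimulation word: shift features along the classifier
            # direction so decoded probability moves by stim_feature_delta
            p_target = float(np.clip(p + delta, 1e-6, 1 - 1e-6))
            ds = logit(p_target) - s
            w2 = float(model.weights @ model.weights)
            if w2 > 0:
                dx = ds * model.weights / w2
                values[i] = values[i] + dx * stats.sd
                x = x + dx
                s += ds
                p = p_target
        prob[i] = p
        version_used[i] = stats.version
        prev_triggered_in_list = None
        if roles[i] == STIM:
            if stim_enabled and p < policy.threshold:
                trig[i] = True
                prev_triggered_in_list = i
                stim_onset = onsets[i] + policy.decode_latency_ms
                nxt = _next_in_list(events, order, i)
                if nxt is not None:
                    stim_to_next[i] = onsets[nxt] - stim_onset
        elif roles[i] == NOSTIM:
            if p < policy.threshold:
                matched[i] = True

    out = events.copy()
    out["classifier_prob"] = prob
    out["stimulated"] = trig
    out["matched_control"] = matched
    if config is not None and "_latent_u" in out.columns:
        out = apply_stim_effects_to_recall(out, config, profile)

    records = pd.DataFrame(
        dict(
            event=np.arange(n),
            subject=events["subject"].to_numpy(),
            site=events["site"].to_numpy(),
            list_index=lists,
            list_role=roles,
            serial_pos=events["serial_pos"].to_numpy(),
            classifier_prob=prob,
            triggered=trig,
            matched_control=matched,
            stats_version=version_used,
            stim_to_next_ms=stim_to_next,
        )
    )
    task = records[records["list_role"].isin([STIM, NOSTIM])]
    summary = (
        task.groupby("list_role")
        .agg(
            n_events=("event", "size"),
            n_triggered=("triggered", "sum"),
            n_below_threshold=("classifier_prob", lambda p: int((p < policy.threshold).sum())),
        )
        .reset_index()
    )
    return ClosedLoopLog(records, summary), out


def _role_of(roles: np.ndarray, lists: np.ndarray, list_index) -> str:
    return roles[lists == list_index][0]


def _fit_stats(values: np.ndarray, mask: np.ndarray, version: int) -> NormStats:
    sub = values[mask]
    mean = sub.mean(axis=0)
    sd = sub.std(axis=0)
    if (sd == 0).any():
        raise SequencingError("degenerate normalization statistics in closed loop")
    return NormStats(mean=mean, sd=sd, provenance="baseline_lists", version=version)


def _next_in_list(events: pd.DataFrame, order: np.ndarray, i: int) -> Optional[int]:
    lists = events["list_index"].to_numpy()
    pos = events["serial_pos"].to_numpy()
    nxt = np.flatnonzero((lists == lists[i]) & (pos == pos[i] + 1))
    return int(nxt[0]) if nxt.size else None


# ---------------------------------------------------------------------------
# matched controls and flanking sets
# ---------------------------------------------------------------------------
def match_controls(log: ClosedLoopLog, events: pd.DataFrame) -> pd.DataFrame:
    """Analyzed trial set: stimulated words plus matched NoStim words.

    Matched words are NoStim-list words whose decoded probability fell below
    the trigger threshold (stimulation would have been applied on a Stim
    list). The returned table carries ``condition`` (1 stim, 0 matched).
    """
    sel = events[events["stimulated"] | events["matched_control"]].copy()
    sel["condition"] = sel["stimulated"].astype(int)
    return sel


def build_flanking_table(events: pd.DataFrame) -> pd.DataFrame:
    """Flanking words of unrecalled stimulated (or matched) anchor words.

    Anchors are unrecalled words that were stimulated (Stim lists) or matched
    controls (NoStim lists) and are flanked forward and reverse by words that
    were not themselves stimulated / below threshold. The returned rows are
    the flanker words, labelled with the anchor's condition.
    """
    ev = events.reset_index(drop=True)
    lists = ev["list_index"].to_numpy()
    pos = ev["serial_pos"].to_numpy()
    stim = ev["stimulated"].to_numpy(dtype=bool)
    matched = ev["matched_control"].to_numpy(dtype=bool)
    recalled = ev["recalled"].to_numpy(dtype=bool)
    anchor = (stim | matched) & ~recalled
    treated = stim | matched  # words that were / would have been stimulated
    rows: dict[int, int] = {}
    for i in np.flatnonzero(anchor):
        nbr = np.flatnonzero((lists == lists[i]) & (np.abs(pos - pos[i]) == 1))
        if len(nbr) < 2:  # anchor at a list edge lacks one flank
            continue
        if treated[nbr].any():
            continue
        for j in nbr:
            rows[int(j)] = int(stim[i])
    if not rows:
        return ev.iloc[0:0].assign(condition=pd.Series(dtype=int))
    idx = sorted(rows)
    out = ev.iloc[idx].copy()
    out["condition"] = [rows[j] for j in idx]
    return out
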