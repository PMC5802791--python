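"""Synthetic delayed free-recall studies with the structure the analysis assumes.

The generator emulates, per subject-site:

* task schedules (1 practice + 25 task lists of 12 words; in closed-loop
  sessions lists 1-3 are baseline and lists 4-25 interleave 11 Stim and 11
  NoStim lists),
* trial-level recall from a logistic model with subject/site random effects,
  a stimulation effect on log-odds, and a flanking (spillover) effect,
* event x (pair x frequency) spectral features carrying a subsequent-memory
  effect: higher power at the two highest analysis frequencies and lower
  power at the three lowest for later-recalled words,
* raw multichannel iEEG (1/f^2 background, 60 Hz line noise, common-mode
  reference drift, event-locked oscillatory bursts whose amplitude encodes
  the memory effect).

It also provides direct trial-table generators at arbitrary design scale for
parameter-recovery studies of the effect models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from memloop.config import LATERAL_TEMPORAL, REGIONS, StudyConfig
from memloop.sigproc import BipolarLayout, PowerFeatures, RawSignal, analysis_freqs

#: Documented column order of the event table CSV.
EVENT_COLUMNS = [
    "subject", "site", "session", "session_kind", "list_index", "list_role",
    "serial_pos", "word", "recalled", "stimulated", "classifier_prob",
    "matched_control",
]

#: Frequency indices (into the 8-point grid) carrying the memory effect:
#: positive shift at the two highest, negative at the three lowest.
SME_POSITIVE_IDX = (6, 7)
SME_NEGATIVE_IDX = (0, 1, 2)

PRACTICE, BASELINE, STIM, NOSTIM, RECORD = "practice", "baseline", "Stim", "NoStim", "record"


class InvalidAssignmentError(ValueError):
    """Stimulation assigned to an event outside a Stim list."""


# ---------------------------------------------------------------------------
# schedules
# ---------------------------------------------------------------------------
@dataclass
class TaskSchedule:
    """One session's word-presentation timeline.

    ``words`` has one row per word slot (list_index, list_role, serial_pos,
    word, onset_ms); ``lists`` has one row per list with distractor and
    recall markers. List index 0 is the practice list.
    """

    words: pd.DataFrame
    lists: pd.DataFrame
    session_kind: str

    @property
    def end_ms(self) -> float:
        return float(self.lists["end_ms"].iloc[-1])

    def role_of(self, list_index: int) -> str:
        return self.lists.set_index("list_index").loc[list_index, "list_role"]


def make_schedule(
    config: StudyConfig, seed: int, kind: str = "closed_loop"
) -> TaskSchedule:
    """Build a session schedule: 1 practice list followed by 25 task lists.

    Closed-loop sessions: lists 1-3 are baseline; lists 4-25 are a random
    interleave of 11 Stim and 11 NoStim lists. Record-only sessions carry
    role ``record`` on every task list.
    """
    rng = np.random.default_rng(seed)
    if kind == "closed_loop":
        roles = [PRACTICE] + [BASELINE] * config.n_baseline_lists
        interleave = [STIM] * config.n_stim_lists + [NOSTIM] * config.n_stim_lists
        rng.shuffle(interleave)
        roles += interleave
    elif kind == "record_only":
        roles = [PRACTICE] + [RECORD] * config.n_task_lists
    else:
        raise ValueError(f"unknown session kind {kind!r}")

    lo_isi, hi_isi = config.isi_range_ms
    t = 2000.0  # leaves room for the pre-onset analysis buffer
    word_rows, list_rows = [], []
    for list_index, role in enumerate(roles):
        for pos in range(1, config.words_per_list + 1):
            word_rows.append(
                dict(list_index=list_index, list_role=role, serial_pos=pos,
                     word=f"WORD_{list_index:02d}_{pos:02d}", onset_ms=t)
            )
            t += config.word_duration_ms + rng.uniform(lo_isi, hi_isi)
        distractor_onset = t
        recall_onset = distractor_onset + config.distractor_ms
        end = recall_onset + config.recall_ms
        list_rows.append(
            dict(list_index=list_index, list_role=role,
                 distractor_onset_ms=distractor_onset,
                 recall_onset_ms=recall_onset, end_ms=end)
        )
        t = end + 1500.0
    return TaskSchedule(pd.DataFrame(word_rows), pd.DataFrame(list_rows), kind)


# ---------------------------------------------------------------------------
# subjects
# ---------------------------------------------------------------------------
@dataclass
class SubjectProfile:
    """Per-subject-site latent quantities shared across that subject's sessions."""

    subject: str
    site: str
    group: str
    random_intercept: float
    stim_slope_re: float
    sme_scale: float
    pair_labels: list[str]
    pair_regions: list[str]
    probes: dict[str, int]
    col_mean: np.ndarray  # baseline log-power level per feature column
    col_sd: np.ndarray    # baseline log-power scale per feature column


def make_subject(
    config: StudyConfig, subject_idx: int, site_suffix: str = "a"
) -> SubjectProfile:
    """Draw one subject-site's random effects, anatomy and feature scales."""
    rng = config.rng_for("subject", subject_idx, site_suffix)
    n_probes = max(1, math.ceil(config.electrodes_per_subject / 6))
    contacts_left = config.electrodes_per_subject
    probes: dict[str, int] = {}
    regions: dict[str, str] = {}
    if config.group == "lateral_temporal":
        region_cycle = [LATERAL_TEMPORAL] + [r for r in REGIONS if r != LATERAL_TEMPORAL]
    else:
        region_cycle = [r for r in REGIONS if r != LATERAL_TEMPORAL]
    for p in range(n_probes):
        name = chr(ord("A") + p)
        n = min(6, contacts_left)
        contacts_left -= n
        probes[name] = n
        regions[name] = region_cycle[p % len(region_cycle)]
    layout = BipolarLayout.from_probes(probes)
    pair_regions = [regions[_probe_of(a)] for a, _ in layout.pairs]
    n_cols = len(layout) * len(analysis_freqs())
    return SubjectProfile(
        subject=f"S{subject_idx:03d}",
        site=f"S{subject_idx:03d}{site_suffix}",
        group=config.group,
        random_intercept=rng.normal(0.0, config.intercept_sd),
        stim_slope_re=rng.normal(0.0, config.subject_sd),
        sme_scale=float(np.exp(rng.normal(0.0, config.sme_scale_sd))),
        pair_labels=layout.labels,
        pair_regions=pair_regions,
        probes=probes,
        col_mean=rng.normal(0.0, 1.5, size=n_cols),
        col_sd=np.exp(rng.normal(0.0, 0.25, size=n_cols)),
    )


def _probe_of(contact: str) -> str:
    i = len(contact)
    while i > 0 and contact[i - 1].isdigit():
        i -= 1
    return contact[:i]


# ---------------------------------------------------------------------------
# recall
# ---------------------------------------------------------------------------
def flanking_indicator(words: pd.DataFrame, stimulated: np.ndarray) -> np.ndarray:
    """Words adjacent (serial +/-1, same list) to a stimulated word, themselves unstimulated."""
    stim = np.asarray(stimulated, dtype=bool)
    flank = np.zeros(len(words), dtype=bool)
    lists = words["list_index"].to_numpy()
    pos = words["serial_pos"].to_numpy()
    for i in np.flatnonzero(stim):
        for j in np.flatnonzero((lists == lists[i]) & (np.abs(pos - pos[i]) == 1)):
            if not stim[j]:
                flank[j] = True
    return flank


def simulate_recall(
    schedule: TaskSchedule,
    config: StudyConfig,
    stim_assignment: Optional[np.ndarray] = None,
    seed: int = 0,
    profile: Optional[SubjectProfile] = None,
    session: int = 0,
) -> pd.DataFrame:
    """Draw recall outcomes from the generating logistic model.

    logit(p) = logit(baseline) + stim_log_odds * stimulated
             + flank_log_odds * flanking + subject random intercept
             + subject random slope * stimulated

    The returned event table carries hidden columns ``_latent_u`` (the uniform
    draw) and ``_eta0`` (the unstimulated linear predictor) so that a
    closed-loop simulation can re-apply stimulation effects to the same
    latent draws after online trigger decisions are known.
    """
    words = schedule.words
    n = len(words)
    if stim_assignment is None:
        stim = np.zeros(n, dtype=bool)
    else:
        stim = np.asarray(stim_assignment, dtype=bool)
        if stim.shape != (n,):
            raise ValueError("stim_assignment must have one entry per word")
        on_bad = stim & (words["list_role"].to_numpy() != STIM)
        if on_bad.any():
            i = int(np.flatnonzero(on_bad)[0])
            raise InvalidAssignmentError(
                f"stimulation assigned on a {words['list_role'].iloc[i]!r} list "
                f"(word row {i})"
            )
    rng = np.random.default_rng(seed)
    ri = profile.random_intercept if profile else 0.0
    rs = profile.stim_slope_re if profile else 0.0
    eta0 = logit(config.baseline_recall_prob) + ri
    flank = flanking_indicator(words, stim)
    eta = (
        eta0
        + (config.stim_log_odds + rs) * stim
        + config.flank_log_odds * flank
    )
    u = rng.random(n)
    events = pd.DataFrame(
        dict(
            subject=profile.subject if profile else "S000",
            site=profile.site if profile else "S000a",
            session=session,
            session_kind=schedule.session_kind,
            list_index=words["list_index"].to_numpy(),
            list_role=words["list_role"].to_numpy(),
            serial_pos=words["serial_pos"].to_numpy(),
            word=words["word"].to_numpy(),
            recalled=u < expit(eta),
            stimulated=stim,
            classifier_prob=np.nan,
            matched_control=False,
            onset_ms=words["onset_ms"].to_numpy(),
            _latent_u=u,
            _eta0=np.full(n, eta0),
        )
    )
    return events


def apply_stim_effects_to_recall(
    events: pd.DataFrame, config: StudyConfig, profile: Optional[SubjectProfile] = None
) -> pd.DataFrame:
    """Re-derive recall outcomes after the stimulated set is known.

    Uses the latent uniform draws stored by :func:`simulate_recall`, so an
    event's outcome changes only through the stimulation / flanking terms;
    the coupling is monotone (stimulation with positive log-odds can only
    flip forgotten -> recalled).
    """
    rs = profile.stim_slope_re if profile else 0.0
    stim = events["stimulated"].to_numpy(dtype=bool)
    flank = flanking_indicator(events, stim)
    eta = (
        events["_eta0"].to_numpy()
        + (config.stim_log_odds + rs) * stim
        + config.flank_log_odds * flank
    )
    out = events.copy()
    out["recalled"] = events["_latent_u"].to_numpy() < expit(eta)
    return out


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------
def sme_shift_pattern(n_pairs: int, sme_effect: float) -> np.ndarray:
    """Per-column class-conditional mean shift (recalled minus forgotten)."""
    per_freq = np.zeros(len(analysis_freqs()))
    per_freq[list(SME_POSITIVE_IDX)] = sme_effect
    per_freq[list(SME_NEGATIVE_IDX)] = -sme_effect
    return np.tile(per_freq, n_pairs)


def simulate_features(
    events: pd.DataFrame,
    config: StudyConfig,
    seed: int,
    profile: Optional[SubjectProfile] = None,
) -> PowerFeatures:
    """Per-event feature vectors with the generating subsequent-memory effect.

    Recalled events are shifted by +sme_effect (in SD units) at the two
    highest frequencies and -sme_effect at the three lowest; noise is unit
    variance. Columns are returned on a raw log-power-like scale (per-subject
    column means and SDs), i.e. un-normalized.
    """
    if len(events) == 0:
        raise ValueError("events table is empty")
    if profile is None:
        profile = make_subject(config, 0)
    rng = np.random.default_rng(seed)
    n_pairs = len(profile.pair_labels)
    shift = sme_shift_pattern(n_pairs, config.sme_effect * profile.sme_scale)
    recalled = events["recalled"].to_numpy(dtype=float)[:, None]
    z = rng.standard_normal((len(events), len(shift))) + recalled * shift
    values = profile.col_mean + profile.col_sd * z
    return PowerFeatures(
        values, list(profile.pair_labels), analysis_freqs(),
        event_index=events.index,
    )


# ---------------------------------------------------------------------------
# raw iEEG
# ---------------------------------------------------------------------------
def simulate_raw(
    events: pd.DataFrame,
    config: StudyConfig,
    seed: int,
    profile: Optional[SubjectProfile] = None,
    end_ms: Optional[float] = None,
    raw_sme: float = 0.2,
) -> tuple[RawSignal, BipolarLayout]:
    """Monopolar session recording with event-locked oscillatory bursts.

    Per contact: integrated-white (1/f^2) background plus white sensor noise;
    shared across contacts: slow reference drift and a 60 Hz line component
    (both removed exactly by bipolar re-referencing). During each word's
    encoding epoch, a ~110 Hz burst and a ~4.5 Hz oscillation are added with
    contact-specific gains; recalled words scale the burst amplitude by
    exp(+raw_sme/2) and the slow oscillation by exp(-raw_sme/2) (and
    conversely for forgotten words), producing the generating memory effect.
    """
    if profile is None:
        profile = make_subject(config, 0)
    rng = np.random.default_rng(seed)
    fs = config.sampling_rate
    if end_ms is None:
        end_ms = float(events["onset_ms"].max()) + 5000.0
    n = int(round(end_ms * fs / 1000.0))
    t = np.arange(n) / fs

    contacts = [f"{p}{i}" for p, cnt in profile.probes.items() for i in range(1, cnt + 1)]
    n_ch = len(contacts)

    # common-mode components: reference drift + line noise
    drift = np.zeros(n)
    for f in (0.05, 0.13, 0.31):
        drift += rng.uniform(20, 60) * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    line = 8.0 * np.sin(2 * np.pi * 60.0 * t + rng.uniform(0, 2 * np.pi))
    common = drift + line

    data = np.empty((n_ch, n))
    epoch_len = int(round(1366.0 * fs / 1000.0))
    env = np.hanning(epoch_len)
    onsets = events["onset_ms"].to_numpy()
    recalled = events["recalled"].to_numpy(dtype=bool)
    gamma_gain = rng.uniform(0.5, 1.5, size=n_ch)
    theta_gain = rng.uniform(0.5, 1.5, size=n_ch)
    sme = raw_sme * profile.sme_scale
    for c in range(n_ch):
        brown = np.cumsum(rng.standard_normal(n))
        brown *= 20.0 / max(brown.std(), 1e-12)
        white = rng.standard_normal(n) * 0.3
        sig = common + brown + white
        for onset, rec in zip(onsets, recalled):
            start = int(round(onset * fs / 1000.0))
            stop = min(start + epoch_len, n)
            seg = slice(start, stop)
            tt = t[seg]
            s = sme if rec else -sme
            amp_g = 3.0 * gamma_gain[c] * np.exp(s / 2.0)
            amp_t = 6.0 * theta_gain[c] * np.exp(-s / 2.0)
            burst = amp_g * np.sin(2 * np.pi * 110.0 * tt + rng.uniform(0, 2 * np.pi))
            slow = amp_t * np.sin(2 * np.pi * 4.5 * tt + rng.uniform(0, 2 * np.pi))
            sig[seg] += (burst + slow) * env[: stop - start]
        data[c] = sig
    raw = RawSignal(data, fs, contacts, montage="monopolar")
    return raw, BipolarLayout.from_probes(profile.probes)


# ---------------------------------------------------------------------------
# record-only convenience
# ---------------------------------------------------------------------------
def simulate_record_session(
    config: StudyConfig,
    profile: SubjectProfile,
    session: int,
) -> tuple[pd.DataFrame, PowerFeatures]:
    """One record-only session: events plus un-normalized features."""
    base = ("record", profile.site, session)
    schedule = make_schedule(config, config.seed_for(*base, "sched"), kind="record_only")
    events = simulate_recall(
        schedule, config, seed=config.seed_for(*base, "recall"),
        profile=profile, session=session,
    )
    feats = simulate_features(
        events, config, seed=config.seed_for(*base, "feats"), profile=profile
    )
    return events, feats


# ---------------------------------------------------------------------------
# recovery-design generators (trial tables at arbitrary scale)
# ---------------------------------------------------------------------------
def simulate_trial_table(
    n_sites: int,
    words_per_site: int,
    baseline_prob: float,
    stim_log_odds: float,
    intercept_sd: float = 0.30,
    slope_sd: float = 0.15,
    seed: int = 0,
    group: str = "lateral_temporal",
    n_two_site_subjects: int = 3,
    link: str = "logit",
) -> pd.DataFrame:
    """Trial-level recalled/not-recalled table from the generating model.

    Each site contributes ``words_per_site`` analyzed words, half stimulated
    and half matched NoStim controls. Random intercepts and stimulation
    slopes are drawn per site; the last ``n_two_site_subjects`` sites are
    assigned as second targets of the first subjects (mirroring subjects
    stimulated at two targets). With ``link="log"`` the model generates from
    a log-link binomial (relative-risk) model instead.
    """
    if n_sites < 1 or words_per_site < 2:
        raise ValueError("need at least one site and two words per site")
    rng = np.random.default_rng(seed)
    n_two = min(n_two_site_subjects, max(0, n_sites - n_two_site_subjects))
    rows = []
    for s in range(n_sites):
        subject = f"R{s:03d}" if s < n_sites - n_two else f"R{s - (n_sites - n_two):03d}"
        u0 = rng.normal(0.0, intercept_sd)
        u1 = rng.normal(0.0, slope_sd)
        stim = np.zeros(words_per_site, dtype=bool)
        stim[rng.permutation(words_per_site)[: words_per_site // 2]] = True
        if link == "logit":
            eta = logit(baseline_prob) + u0 + (stim_log_odds + u1) * stim
            p = expit(eta)
        elif link == "log":
            eta = np.log(baseline_prob) + u0 + (stim_log_odds + u1) * stim
            p = np.exp(np.minimum(eta, -1e-9))
        else:
            raise ValueError(f"unknown link {link!r}")
        rows.append(
            pd.DataFrame(
                dict(
                    recalled=(rng.random(words_per_site) < p).astype(int),
                    stim=stim.astype(int),
                    group=group,
                    subject=subject,
                    site=f"T{s:03d}",
                    serial_pos=rng.integers(1, 13, size=words_per_site),
                    flank=0,
                )
            )
        )
    return pd.concat(rows, ignore_index=True)


def simulate_delta_table(
    n_sites: int,
    pairs_per_site: int,
    delta: float,
    subject_sd: float = 0.02,
    site_sd: float = 0.01,
    resid_sd: float = 0.20,
    seed: int = 0,
) -> pd.DataFrame:
    """Consecutive-word classifier-output changes for the post-stimulation model.

    One row per (w_{i+1}, w_i) pair with word i stimulated (condition 1) or a
    matched NoStim control (condition 0); the generating mean difference in
    decoded probability is ``delta``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_sites):
        u_sub = rng.normal(0.0, subject_sd)
        u_site = rng.normal(0.0, site_sd)
        stim = np.zeros(pairs_per_site, dtype=int)
        stim[rng.permutation(pairs_per_site)[: pairs_per_site // 2]] = 1
        d = u_sub + u_site + delta * stim + rng.normal(0.0, resid_sd, size=pairs_per_site)
        rows.append(
            pd.DataFrame(
                dict(delta=d, stim=stim, subject=f"R{s:03d}", site=f"T{s:03d}",
                     group="lateral_temporal")
            )
        )
    return pd.concat(rows, ignore_index=True)
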