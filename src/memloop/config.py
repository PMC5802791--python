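"""Study configuration: generating parameters, group profiles, seed derivation.

A :class:`StudyConfig` bundles every tunable of the synthetic study: task
schedule shape, recording parameters, the generating recall model (baseline
rate, stimulation and flanking log-odds, random-effect SDs), the spectral
subsequent-memory effect carried by the features, and the post-stimulation
shift of decoded recall probability.

Two shipped group profiles mirror the two study arms: ``lateral_temporal``
(stimulation targets in lateral temporal cortex, baseline recall 26.1 %,
beneficial stimulation) and ``non_lateral`` (all other targets, baseline
29.8 %, a mild detrimental effect).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import yaml

SCHEMA_VERSION = 1

#: Lobe-level region labels used for synthetic anatomy.
REGIONS = ("frontal", "temporal", "parietal", "occipital", "mtl")

#: Region label that receives targeting priority (lateral temporal cortex).
LATERAL_TEMPORAL = "temporal"


@dataclass
class StudyConfig:
    """Generating parameters for one synthetic study arm.

    Parameters
    ----------
    n_subjects
        Number of subject-sites in the arm.
    n_record_sessions
        Record-only sessions per subject used for classifier training.
    electrodes_per_subject
        Monopolar contacts per subject; probes of 6 contacts yield
        ``electrodes_per_subject - n_probes`` bipolar pairs.
    sampling_rate
        Hz; must be at least 500 so the 3-180 Hz analysis band is resolvable.
    baseline_recall_prob
        Conditional (median-subject) probability of recalling an
        unstimulated, unflanked word.
    sme_effect
        Standardized class-conditional mean shift (recalled minus forgotten)
        per informative frequency: applied positively at the two highest
        frequencies and negatively at the three lowest.
    stim_log_odds
        Generating effect of stimulation on recall log-odds.
    flank_log_odds
        Generating log-odds effect on words flanking a stimulated word.
    stim_feature_delta
        Mean shift of decoded recall probability for the word following a
        stimulation train, back-solved through the trained classifier.
    subject_sd
        SD of the random stimulation slope across subjects/sites (log-odds).
    intercept_sd
        SD of the random intercept across subjects/sites (log-odds).
    sme_scale_sd
        Lognormal sigma of the per-subject multiplier on ``sme_effect``;
        spreads classifier performance across subjects.
    seed
        Master seed; all per-subject and per-session seeds derive from it.
    """

    n_subjects: int = 18
    n_record_sessions: int = 3
    electrodes_per_subject: int = 12
    sampling_rate: float = 500.0
    baseline_recall_prob: float = 0.261
    sme_effect: float = 0.09
    stim_log_odds: float = math.log(1.18)
    flank_log_odds: float = math.log(1.15)
    stim_feature_delta: float = 0.01
    subject_sd: float = 0.15
    intercept_sd: float = 0.30
    sme_scale_sd: float = 0.25
    group: str = "lateral_temporal"
    seed: int = 0

    # Schedule constants (task structure, shared by every session kind).
    n_task_lists: int = 25
    n_baseline_lists: int = 3
    words_per_list: int = 12
    n_stim_lists: int = 11
    word_duration_ms: float = 1600.0
    isi_range_ms: tuple[float, float] = (750.0, 1000.0)
    distractor_ms: float = 20_000.0
    recall_ms: float = 30_000.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not 0.0 < self.baseline_recall_prob < 1.0:
            raise ValueError("baseline_recall_prob must lie in (0, 1)")
        for name in ("n_subjects", "n_record_sessions", "electrodes_per_subject"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.sampling_rate < 500.0:
            raise ValueError("sampling_rate must be >= 500 Hz")
        if self.subject_sd < 0 or self.intercept_sd < 0:
            raise ValueError("random-effect SDs must be non-negative")
        if 2 * self.n_stim_lists + self.n_baseline_lists != self.n_task_lists:
            raise ValueError("task lists must split into baseline + Stim/NoStim")

    # ------------------------------------------------------------------
    # seed derivation
    # ------------------------------------------------------------------
    def seed_for(self, *path: Any) -> int:
        """Derive a deterministic child seed (< 2**31) for a pipeline stage.

        ``path`` is any hashable sequence of labels, e.g.
        ``config.seed_for("subject", 3, "session", 1)``.
        """
        return derive_seed(self.seed, *path)

    def rng_for(self, *path: Any) -> np.random.Generator:
        return np.random.default_rng(self.seed_for(*path))

    # ------------------------------------------------------------------
    # serialization
    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["isi_range_ms"] = list(d["isi_range_ms"])
        d["schema_version"] = SCHEMA_VERSION
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        version = d.pop("schema_version", SCHEMA_VERSION)
        if version != SCHEMA_VERSION:
            raise ValueError(f"unsupported config schema version {version}")
        if "isi_range_ms" in d:
            d["isi_range_ms"] = tuple(d["isi_range_ms"])
        return cls(**d)

    def to_yaml(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "StudyConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def replace(self, **kw: Any) -> "StudyConfig":
        return dataclasses.replace(self, **kw)


def derive_seed(master: int, *path: Any) -> int:
    """Hash a master seed and a label path into a child seed below 2**31."""
    entropy = [int(master)] + [
        int.from_bytes(str(p).encode(), "little") % (2**63) for p in path
    ]
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] % (2**31))


#: Shipped group profiles for the two study arms.
GROUP_PROFILES: dict[str, dict[str, float]] = {
    "lateral_temporal": {
        "baseline_recall_prob": 0.261,
        "stim_log_odds": math.log(1.18),
        "flank_log_odds": math.log(1.15),
        "stim_feature_delta": 0.01,
    },
    "non_lateral": {
        "baseline_recall_prob": 0.298,
        "stim_log_odds": math.log(0.87),
        "flank_log_odds": 0.0,
        "stim_feature_delta": 0.0,
    },
}


def profile_config(group: str, **overrides: Any) -> StudyConfig:
    """Build a :class:`StudyConfig` from a shipped group profile."""
    if group not in GROUP_PROFILES:
        raise KeyError(f"unknown group profile {group!r}; have {sorted(GROUP_PROFILES)}")
    kw: dict[str, Any] = {"group": group, **GROUP_PROFILES[group]}
    n_default = 18 if group == "lateral_temporal" else 11
    kw.setdefault("n_subjects", n_default)
    kw.update(overrides)
    return StudyConfig(**kw)
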