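"""Spectral feature extraction for intracranial EEG.

Pipeline: 60 Hz band-stop filter -> bipolar re-referencing -> Morlet wavelet
power over the word-encoding epoch -> log transform and time average ->
z-scoring, either within session or against frozen baseline statistics.

Conventions
-----------
* Time is milliseconds, 0-based from word onset; epochs are half-open in
  sample units.
* The encoding epoch is [0, 1366) ms; 1365 ms buffers of surrounding
  recording are included on both sides during wavelet convolution and
  discarded afterwards, keeping convolution edge effects out of the epoch.
* Eight analysis frequencies are geometrically spaced from 3 to 180 Hz.
* Feature columns are ordered pair-major, frequency-minor:
  ``(pair_0, f_0), (pair_0, f_1), ..., (pair_1, f_0), ...``
* Log transform is the natural log; any base only rescales features and is
  absorbed by z-scoring.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps
from mne.time_frequency import tfr_array_morlet

EPOCH_MS = 1366.0
BUFFER_MS = 1365.0
N_FREQS = 8
FREQ_MIN = 3.0
FREQ_MAX = 180.0
WAVE_NUMBER = 5.0


def analysis_freqs(n: int = N_FREQS, lo: float = FREQ_MIN, hi: float = FREQ_MAX) -> np.ndarray:
    """Geometrically spaced analysis frequencies with exact endpoints."""
    return np.geomspace(lo, hi, n)


class EpochingError(ValueError):
    """An event epoch (plus buffers) falls outside the recording."""


class DegenerateFeatureError(ValueError):
    """A feature column has zero variance and cannot be z-scored."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------
@dataclass
class RawSignal:
    """Multichannel time series.

    ``data`` is channels x samples; ``montage`` is ``"monopolar"`` or
    ``"bipolar"`` (virtual channels from adjacent-contact differences).
    """

    data: np.ndarray
    sfreq: float
    ch_names: list[str]
    montage: str = "monopolar"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if len(self.ch_names) != self.data.shape[0]:
            raise ValueError("ch_names length must match channel count")
        if not np.isfinite(self.data).all():
            raise ValueError("raw data contains non-finite samples")
        if self.sfreq <= 2 * FREQ_MAX:
            raise ValueError(
                f"sampling rate {self.sfreq} Hz cannot resolve {FREQ_MAX} Hz"
            )

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def copy(self) -> "RawSignal":
        return RawSignal(self.data.copy(), self.sfreq, list(self.ch_names), self.montage)


@dataclass
class BipolarLayout:
    """Ordered adjacent-contact pairs, each within a single probe.

    Contact labels follow ``<probe><index>`` (e.g. ``"A3"``); adjacency means
    consecutive indices on the same probe.
    """

    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        seen = set()
        for anode, cathode in self.pairs:
            if (anode, cathode) in seen:
                raise ValueError(f"duplicate pair {(anode, cathode)}")
            seen.add((anode, cathode))
            pa, ia = _split_label(anode)
            pc, ic = _split_label(cathode)
            if pa != pc:
                raise ValueError(f"pair {(anode, cathode)} spans probes {pa}/{pc}")
            if abs(ia - ic) != 1:
                raise ValueError(f"contacts {(anode, cathode)} are not adjacent")

    @classmethod
    def from_probes(cls, probes: dict[str, int]) -> "BipolarLayout":
        """All adjacent pairs on each probe: a probe of n contacts gives n-1 pairs."""
        pairs = []
        for name, n in probes.items():
            pairs.extend((f"{name}{i}", f"{name}{i + 1}") for i in range(1, n))
        return cls(pairs)

    @property
    def labels(self) -> list[str]:
        return [f"{a}-{c}" for a, c in self.pairs]

    def __len__(self) -> int:
        return len(self.pairs)


def _split_label(label: str) -> tuple[str, int]:
    i = len(label)
    while i > 0 and label[i - 1].isdigit():
        i -= 1
    if i == len(label):
        raise ValueError(f"contact label {label!r} lacks a numeric index")
    return label[:i], int(label[i:])


@dataclass
class SpectralParams:
    """Morlet decomposition parameters."""

    freqs: np.ndarray = field(default_factory=analysis_freqs)
    wave_number: float = WAVE_NUMBER
    epoch_ms: float = EPOCH_MS
    buffer_ms: float = BUFFER_MS

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if not np.all(np.diff(self.freqs) > 0):
            raise ValueError("frequencies must be strictly increasing")


@dataclass
class NormStats:
    """Per-column normalization statistics with provenance."""

    mean: np.ndarray
    sd: np.ndarray
    provenance: str = "within_session"
    version: int = 0


@dataclass
class PowerFeatures:
    """Events x (pair x frequency) matrix of log spectral power.

    ``values[i, j]`` is event ``i``, column ``j``; columns are pair-major,
    frequency-minor. ``norm`` records how (and whether) columns were z-scored.
    """

    values: np.ndarray
    pair_labels: list[str]
    freqs: np.ndarray
    event_index: Optional[pd.Index] = None
    norm: Optional[NormStats] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        n_feat = len(self.pair_labels) * len(self.freqs)
        if self.values.ndim != 2 or self.values.shape[1] != n_feat:
            raise ValueError(
                f"values must be events x {n_feat} (pairs x freqs), got {self.values.shape}"
            )
        if not np.isfinite(self.values).all():
            raise ValueError("power features contain non-finite entries")

    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def feature_labels(self) -> list[str]:
        return [
            f"{pair}@{freq:.1f}Hz" for pair in self.pair_labels for freq in self.freqs
        ]

    def columns_for_pair(self, pair_idx: int) -> slice:
        k = len(self.freqs)
        return slice(pair_idx * k, (pair_idx + 1) * k)

    def columns_for_freqs(self, mask: np.ndarray) -> np.ndarray:
        """Boolean column mask replicating a frequency mask over all pairs."""
        return np.tile(np.asarray(mask, dtype=bool), len(self.pair_labels))

    def to_frame(self) -> pd.DataFrame:
        cols = pd.MultiIndex.from_product(
            [self.pair_labels, np.round(self.freqs, 3)], names=["pair", "freq"]
        )
        return pd.DataFrame(self.values, index=self.event_index, columns=cols)

    def select_events(self, mask: np.ndarray) -> "PowerFeatures":
        idx = self.event_index[mask] if self.event_index is not None else None
        return PowerFeatures(self.values[mask], list(self.pair_labels), self.freqs.copy(),
                             idx, self.norm)

    def copy(self) -> "PowerFeatures":
        return PowerFeatures(
            self.values.copy(), list(self.pair_labels), self.freqs.copy(),
            None if self.event_index is None else self.event_index.copy(),
            None if self.norm is None else dataclasses.replace(self.norm),
        )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------
def notch_filter(
    raw: RawSignal, center: float = 60.0, width: float = 5.0, order: int = 4
) -> RawSignal:
    """Zero-phase Butterworth band-stop centered on the line frequency.

    A fourth-order design applied forward-backward (effective order doubles),
    stop band ``center +/- width/2``.
    """
    lo, hi = center - width / 2.0, center + width / 2.0
    if hi >= raw.sfreq / 2.0:
        raise ValueError(
            f"stop band edge {hi} Hz is at or above Nyquist ({raw.sfreq / 2} Hz)"
        )
    sos = sps.butter(order, [lo, hi], btype="bandstop", fs=raw.sfreq, output="sos")
    filtered = sps.sosfiltfilt(sos, raw.data, axis=1)
    return RawSignal(filtered, raw.sfreq, list(raw.ch_names), raw.montage)


def bipolar_rereference(raw: RawSignal, layout: BipolarLayout) -> RawSignal:
    """Difference adjacent contacts into virtual channels (anode - cathode).

    Removes any signal common to all contacts (reference noise, line pickup)
    exactly.
    """
    if raw.montage != "monopolar":
        raise ValueError("bipolar re-referencing expects a monopolar recording")
    index = {name: i for i, name in enumerate(raw.ch_names)}
    rows = []
    for anode, cathode in layout.pairs:
        for label in (anode, cathode):
            if label not in index:
                raise KeyError(f"contact {label!r} not present in recording")
        rows.append(raw.data[index[anode]] - raw.data[index[cathode]])
    return RawSignal(np.asarray(rows), raw.sfreq, layout.labels, montage="bipolar")


def wavelet_power(
    raw: RawSignal,
    onsets_ms: Sequence[float],
    params: Optional[SpectralParams] = None,
    event_index: Optional[pd.Index] = None,
) -> PowerFeatures:
    """Morlet log-power per event, channel and frequency, time-averaged.

    For each word onset, the [0, 1366) ms epoch is extracted together with
    1365 ms buffers of surrounding recording on both sides; the padded
    segment is convolved with Morlet wavelets (wave number 5), the buffers
    are discarded so convolution edge effects never reach the epoch, and
    power is natural-log-transformed and averaged over time. Output is
    un-normalized. Every epoch plus its buffers must lie within the
    recording.
    """
    params = params or SpectralParams()
    fs = raw.sfreq
    n_epoch = int(round(params.epoch_ms * fs / 1000.0))
    n_buf = int(round(params.buffer_ms * fs / 1000.0))

    epochs = np.empty((len(onsets_ms), raw.data.shape[0], n_epoch + 2 * n_buf))
    for i, onset in enumerate(onsets_ms):
        start = int(round(onset * fs / 1000.0))
        stop = start + n_epoch
        if start - n_buf < 0 or stop + n_buf > raw.n_samples:
            raise EpochingError(
                f"event {i} at {onset} ms: epoch plus buffer "
                f"[{start - n_buf}, {stop + n_buf}) exceeds recording of "
                f"{raw.n_samples} samples"
            )
        epochs[i] = raw.data[:, start - n_buf:stop + n_buf]

    power = tfr_array_morlet(
        epochs, sfreq=fs, freqs=params.freqs, n_cycles=params.wave_number,
        output="power", zero_mean=False,
    )
    power = power[..., n_buf:n_buf + n_epoch]
    logpow = np.log(np.maximum(power, np.finfo(float).tiny)).mean(axis=-1)
    # (events, channels, freqs) -> pair-major flat matrix
    values = logpow.reshape(logpow.shape[0], -1)
    return PowerFeatures(values, list(raw.ch_names), params.freqs, event_index)


def compute_norm_stats(
    feats: PowerFeatures, provenance: str = "baseline_lists", version: int = 0
) -> NormStats:
    """Per-column mean and SD (population convention, ddof=0)."""
    if feats.n_events < 2:
        raise ValueError("need at least 2 events to estimate normalization statistics")
    mean = feats.values.mean(axis=0)
    sd = feats.values.std(axis=0)
    _check_sd(sd, feats)
    return NormStats(mean=mean, sd=sd, provenance=provenance, version=version)


def normalize_features(
    feats: PowerFeatures,
    mode: str = "within_session",
    stats: Optional[NormStats] = None,
) -> PowerFeatures:
    """z-score feature columns.

    ``within_session`` refits mean/SD on the given events, so output columns
    have mean 0 and SD 1 exactly. ``baseline_stats`` applies supplied
    statistics without refitting (the closed-loop convention).
    """
    if mode == "within_session":
        stats = compute_norm_stats(feats, provenance="within_session")
    elif mode == "baseline_stats":
        if stats is None:
            raise ValueError("baseline_stats mode requires supplied statistics")
        _check_sd(np.asarray(stats.sd), feats)
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    values = (feats.values - stats.mean) / stats.sd
    return PowerFeatures(values, list(feats.pair_labels), feats.freqs.copy(),
                         feats.event_index, stats)


def _check_sd(sd: np.ndarray, feats: PowerFeatures) -> None:
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        label = feats.feature_labels[bad[0]]
        raise DegenerateFeatureError(
            f"feature column {bad[0]} ({label}) has zero variance"
        )
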