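"""File formats: event-table CSV, HDF5 signal/feature containers, model JSON.

CSV conventions: UTF-8, '.' decimal, documented column order, booleans as
True/False, probabilities at full precision. Signals and features live in an
HDF5 container with channel metadata and a provenance block.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Union

import h5py
import numpy as np
import pandas as pd

from memloop.sigproc import BipolarLayout, NormStats, PowerFeatures, RawSignal
from memloop.synthgen import EVENT_COLUMNS

PathLike = Union[str, Path]

_BOOL_COLUMNS = ("recalled", "stimulated", "matched_control")


class SchemaError(ValueError):
    """A file does not conform to the documented schema."""


# ---------------------------------------------------------------------------
# event tables
# ---------------------------------------------------------------------------
def write_events(events: pd.DataFrame, path: PathLike) -> None:
    """Write an event table CSV in the documented column order.

    Internal columns (prefixed ``_``) and extra columns such as ``onset_ms``
    are appended after the documented ones so round-trips are lossless.
    """
    cols = [c for c in EVENT_COLUMNS if c in events.columns]
    extra = [c for c in events.columns if c not in cols]
    events[cols + extra].to_csv(path, index=False, encoding="utf-8")


def read_events(path: PathLike) -> pd.DataFrame:
    """Read an event table CSV, validating types row by row."""
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in EVENT_COLUMNS if c not in df.columns and c != "classifier_prob"]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    for col in _BOOL_COLUMNS:
        if col not in df.columns:
            continue
        vals = df[col].astype(str).str.strip()
        ok = vals.isin(["True", "False"])
        if not ok.all():
            row = int(np.flatnonzero(~ok.to_numpy())[0])
            raise SchemaError(
                f"{path}: column {col!r} row {row}: {vals.iloc[row]!r} is not a boolean"
            )
        df[col] = vals == "True"
    if "classifier_prob" in df.columns:
        probs = pd.to_numeric(df["classifier_prob"], errors="coerce")
        bad = probs.notna() & ((probs < 0) | (probs > 1))
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SchemaError(
                f"{path}: classifier_prob row {row} outside [0, 1]"
            )
        df["classifier_prob"] = probs
    return df


# ---------------------------------------------------------------------------
# signals
# ---------------------------------------------------------------------------
def write_signal(raw: RawSignal, path: PathLike) -> None:
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("data", data=raw.data)
        ds.attrs["sfreq"] = raw.sfreq
        ds.attrs["montage"] = raw.montage
        f.create_dataset(
            "ch_names", data=np.asarray(raw.ch_names, dtype=h5py.string_dtype())
        )


def read_signal(path: PathLike) -> RawSignal:
    with h5py.File(path, "r") as f:
        if "data" not in f or "ch_names" not in f:
            raise SchemaError(f"{path}: not a signal container")
        ds = f["data"]
        return RawSignal(
            data=ds[()],
            sfreq=float(ds.attrs["sfreq"]),
            ch_names=[s.decode() if isinstance(s, bytes) else str(s) for s in f["ch_names"][()]],
            montage=str(ds.attrs.get("montage", "monopolar")),
        )


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------
def write_features(feats: PowerFeatures, path: PathLike, provenance: Optional[dict] = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=feats.values)
        f.create_dataset("freqs", data=feats.freqs)
        f.create_dataset(
            "pair_labels", data=np.asarray(feats.pair_labels, dtype=h5py.string_dtype())
        )
        if feats.norm is not None:
            g = f.create_group("norm")
            g.create_dataset("mean", data=feats.norm.mean)
            g.create_dataset("sd", data=feats.norm.sd)
            g.attrs["provenance"] = feats.norm.provenance
            g.attrs["version"] = feats.norm.version
        if provenance:
            f.attrs["provenance"] = json.dumps(provenance, sort_keys=True)


def read_features(path: PathLike) -> PowerFeatures:
    with h5py.File(path, "r") as f:
        if "values" not in f:
            raise SchemaError(f"{path}: not a feature container")
        norm = None
        if "norm" in f:
            g = f["norm"]
            norm = NormStats(
                mean=g["mean"][()], sd=g["sd"][()],
                provenance=str(g.attrs["provenance"]), version=int(g.attrs["version"]),
            )
        return PowerFeatures(
            values=f["values"][()],
            pair_labels=[s.decode() if isinstance(s, bytes) else str(s) for s in f["pair_labels"][()]],
            freqs=f["freqs"][()],
            norm=norm,
        )


# ---------------------------------------------------------------------------
# misc
# ---------------------------------------------------------------------------
def file_digest(path: PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_json(obj: dict, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_json_default)


def read_json(path: PathLike) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
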