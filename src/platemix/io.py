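"""Readers and writers for the package's file formats.

All interchange is plain CSV (comma separator, '.' decimal, UTF-8, header
row): the event table (mouse_id, group, fsc), the bead table (size_um, fsc)
and the survival table (subject_id, group, time_days, event). Values are
written at full precision so that a write-then-read round trip is lossless.
FCS container support is not included; export events to CSV upstream.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, InputError

__all__ = [
    "read_events",
    "write_events",
    "read_beads",
    "write_beads",
    "read_survival",
    "write_survival",
    "read_config",
    "config_digest",
]

PathLike = Union[str, Path]


def read_events(path: PathLike, format: str = "csv", fsc_channel: str = "fsc") -> pd.DataFrame:
    """Read and validate an event table.

    Raises FormatError naming the offending rows (1-based data rows) for
    missing columns, non-numeric FSC, or FSC <= 0. Only CSV is supported.
    """
    if format != "csv":
        raise FormatError(
            f"unsupported format {format!r}: only 'csv' event tables are supported"
        )
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"mouse_id", "group", fsc_channel}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required columns {sorted(missing)}")
    fsc = pd.to_numeric(df[fsc_channel], errors="coerce")
    bad = df.index[fsc.isna() | ~np.isfinite(fsc) | (fsc <= 0)].tolist()
    if bad:
        rows = ", ".join(str(i + 1) for i in bad[:20])
        more = f" (+{len(bad) - 20} more)" if len(bad) > 20 else ""
        raise FormatError(
            f"{path}: invalid fsc (non-numeric, non-finite or <= 0) on data rows: "
            f"{rows}{more}"
        )
    out = df[["mouse_id", "group", fsc_channel]].rename(columns={fsc_channel: "fsc"})
    out["fsc"] = fsc
    grp_per_mouse = out.groupby("mouse_id")["group"].nunique()
    multi = grp_per_mouse[grp_per_mouse > 1].index.tolist()
    if multi:
        raise FormatError(f"{path}: mice assigned to multiple groups: {multi}")
    return out


def write_events(events: pd.DataFrame, path: PathLike) -> None:
    events[["mouse_id", "group", "fsc"]].to_csv(path, index=False)


def read_beads(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    if not {"size_um", "fsc"}.issubset(df.columns):
        raise FormatError(f"{path}: bead table needs columns size_um, fsc")
    return df[["size_um", "fsc"]].astype(float)


def write_beads(beads: pd.DataFrame, path: PathLike) -> None:
    beads[["size_um", "fsc"]].to_csv(path, index=False)


def read_survival(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"subject_id", "group", "time_days", "event"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: survival table missing columns {sorted(missing)}")
    t = pd.to_numeric(df["time_days"], errors="coerce")
    bad = df.index[t.isna() | (t <= 0)].tolist()
    if bad:
        raise FormatError(
            f"{path}: invalid time_days on data rows: "
            + ", ".join(str(i + 1) for i in bad[:20])
        )
    if not df["event"].isin([0, 1]).all():
        raise FormatError(f"{path}: event column must contain only 0 or 1")
    return df[list(("subject_id", "group", "time_days", "event"))]


def write_survival(records: pd.DataFrame, path: PathLike) -> None:
    records[["subject_id", "group", "time_days", "event"]].to_csv(path, index=False)


def read_config(path: PathLike) -> dict:
    """Load a YAML run/simulation configuration as a plain dict."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a YAML mapping")
    return cfg


def config_digest(cfg: dict) -> str:
    """Stable SHA-256 digest of a configuration, for run provenance."""
    canonical = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode("utf-8")).hexdigest()[:16]
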