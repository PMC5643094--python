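"""Readers and writers for the package's exchange formats.

Track CSV dialect: comma-separated, dot decimals, UTF-8, mandatory header
``track_id,kind,frame,t_s,x_um,y_um``, one row per point.  Floats are written
with ``repr`` (shortest round-trip form), so write -> read -> write is
byte-stable.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .tracks import COLUMNS, TrackSet, TrackValidationError


class ParseError(ValueError):
    pass


def read_tracks(path) -> TrackSet:
    """Read and validate a track CSV; errors name the offending column/row."""
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"track_id": str, "kind": str}, float_precision="round_trip")
    except FileNotFoundError:
        raise
    except Exception as err:
        raise ParseError(f"{path}: not parseable as CSV: {err}") from None
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    for col in ("frame", "t_s", "x_um", "y_um"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0])
            raise ParseError(f"{path}: non-numeric value in column {col!r} at data row {row}")
        if coerced.isna().any():
            row = int(np.nonzero(coerced.isna().to_numpy())[0][0])
            raise ParseError(f"{path}: empty value in column {col!r} at data row {row}")
        df[col] = coerced
    try:
        return TrackSet(df)
    except TrackValidationError as err:
        raise ParseError(f"{path}: {err}") from None


def write_tracks(ts: TrackSet, path) -> None:
    df = ts.df.copy()
    df["frame"] = df["frame"].astype(int)
    df.to_csv(path, index=False)


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if hasattr(o, "__dict__"):
            return o.__dict__
        return str(o)

    Path(path).write_text(json.dumps(obj, indent=1, default=default))


def write_manifest(out_dir, command: str, config: dict, seed, inputs=None) -> Path:
    """One manifest per output directory: command, config hash, seed, inputs."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    manifest = {
        "command": command,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "config": config,
        "seed": seed,
        "inputs": [str(p) for p in (inputs or [])],
        "package_version": __version__,
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
    }
    path = out_dir / "manifest.json"
    write_json(manifest, path)
    return path


# ---------------------------------------------------------------------------
# best-effort adapters for deposited supplementary tables

SOURCEDATA_KEYWORDS = {
    "speed": ("speed", "velocity", "um/s", "µm/s"),
    "direction": ("direction", "angle", "deg"),
    "distance": ("distance", "um", "µm"),
    "lifespan": ("lifespan", "lifetime", "life"),
    "dwell": ("dwell", "persistence"),
}


def import_sourcedata(path, quantity: str | None = None) -> pd.DataFrame:
    """Sniff a deposited quantity table (CSV or XLSX) into tidy long form.

    The deposited files' column layouts are not standardised, so this adapter
    matches column names against per-quantity keywords and fails loudly when
    nothing matches.  Returns columns ``(column, value)``.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    if quantity is not None and quantity not in SOURCEDATA_KEYWORDS:
        raise ParseError(f"unknown quantity {quantity!r}; options: {sorted(SOURCEDATA_KEYWORDS)}")
    keys = SOURCEDATA_KEYWORDS[quantity] if quantity else tuple(
        k for kws in SOURCEDATA_KEYWORDS.values() for k in kws
    )
    picked = [c for c in df.columns if any(k in str(c).lower() for k in keys)]
    picked = [c for c in picked if pd.to_numeric(df[c], errors="coerce").notna().any()]
    if not picked:
        raise ParseError(
            f"{path}: no column matched keywords {keys}; columns were {list(df.columns)}"
        )
    frames = []
    for c in picked:
        vals = pd.to_numeric(df[c], errors="coerce").dropna()
        frames.append(pd.DataFrame({"column": str(c), "value": vals}))
    return pd.concat(frames, ignore_index=True)
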