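"""Track containers.

A track is one particle trajectory: ordered, uniformly sampled, timed 2D
points.  The single exchange format for every module is a long-form CSV with
columns ``track_id,kind,frame,t_s,x_um,y_um`` (one row per point); in memory
a :class:`TrackSet` wraps the equivalent :class:`pandas.DataFrame`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

COLUMNS = ["track_id", "kind", "frame", "t_s", "x_um", "y_um"]

#: maximum jitter (s) tolerated in the frame interval within one track
FRAME_DT_TOL = 1e-6


class TrackValidationError(ValueError):
    pass


@dataclass(frozen=True)
class Track:
    """One trajectory: arrays are aligned and ordered by time."""

    track_id: str
    kind: str
    frame: np.ndarray
    t: np.ndarray
    xy: np.ndarray

    def __len__(self) -> int:
        return len(self.t)

    @property
    def frame_dt(self) -> float:
        if len(self.t) < 2:
            return float("nan")
        return float(self.t[1] - self.t[0])

    @property
    def net_displacement(self) -> float:
        return float(np.hypot(*(self.xy[-1] - self.xy[0])))


class TrackSet:
    """Ordered collection of tracks backed by a long-form DataFrame."""

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        if validate:
            df = _validate(df)
        self.df = df

    @classmethod
    def from_tracks(cls, tracks) -> "TrackSet":
        frames = []
        for tr in tracks:
            frames.append(
                pd.DataFrame(
                    {
                        "track_id": tr.track_id,
                        "kind": tr.kind,
                        "frame": tr.frame.astype(int),
                        "t_s": tr.t,
                        "x_um": tr.xy[:, 0],
                        "y_um": tr.xy[:, 1],
                    }
                )
            )
        if not frames:
            return cls(pd.DataFrame(columns=COLUMNS), validate=False)
        return cls(pd.concat(frames, ignore_index=True), validate=False)

    def __len__(self) -> int:
        return self.df["track_id"].nunique()

    def __iter__(self):
        for tid, g in self.df.groupby("track_id", sort=False):
            yield Track(
                track_id=str(tid),
                kind=str(g["kind"].iloc[0]),
                frame=g["frame"].to_numpy(),
                t=g["t_s"].to_numpy(dtype=float),
                xy=g[["x_um", "y_um"]].to_numpy(dtype=float),
            )

    def filter_min_points(self, min_points: int) -> "TrackSet":
        sizes = self.df.groupby("track_id", sort=False)["frame"].transform("size")
        return TrackSet(self.df[sizes >= min_points].reset_index(drop=True), validate=False)

    def transformed(self, rotation_deg: float = 0.0, shift=(0.0, 0.0)) -> "TrackSet":
        """Rigidly rotate (about the origin) and translate every point."""
        th = np.radians(rotation_deg)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        xy = self.df[["x_um", "y_um"]].to_numpy(dtype=float) @ R.T + np.asarray(shift, float)
        out = self.df.copy()
        out[["x_um", "y_um"]] = xy
        return TrackSet(out, validate=False)


def _validate(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise TrackValidationError(f"track table missing column(s) {missing}")
    df = df[COLUMNS].copy()
    for col in ("frame", "t_s", "x_um", "y_um"):
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as err:
            raise TrackValidationError(f"non-numeric value in column {col!r}: {err}") from None
    if not np.all(np.isfinite(df[["t_s", "x_um", "y_um"]].to_numpy(dtype=float))):
        raise TrackValidationError("non-finite coordinate or time")
    for tid, g in df.groupby("track_id", sort=False):
        t = g["t_s"].to_numpy(dtype=float)
        if len(t) > 1:
            dt = np.diff(t)
            if np.any(dt <= 0):
                raise TrackValidationError(f"track {tid!r}: time not strictly increasing")
            if np.any(np.abs(dt - dt[0]) > FRAME_DT_TOL):
                raise TrackValidationError(f"track {tid!r}: non-uniform frame interval")
        if g["frame"].duplicated().any():
            raise TrackValidationError(f"track {tid!r}: duplicated frame index")
    return df.reset_index(drop=True)
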