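"""Shared trajectory container for simulated and tracked bead motion."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mucorheo.errors import InvalidInputError

#: Required columns of the canonical trajectory table.
TRACK_COLUMNS = ("track_id", "frame", "x_um", "y_um")


@dataclass
class TrajectorySet:
    """Per-bead 2-D positions over frames.

    ``data`` is a tidy table with columns ``track_id, frame, x_um, y_um``;
    frames are strictly increasing within a track.  Positions are in
    micrometres; the pixel-origin convention (when derived from images) is
    pixel centers at integer coordinates, origin top-left, x = column.
    """

    data: pd.DataFrame
    frame_interval_s: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = [c for c in TRACK_COLUMNS if c not in self.data.columns]
        if missing:
            raise InvalidInputError(f"trajectory table missing columns {missing}")
        if self.frame_interval_s <= 0:
            raise InvalidInputError("frame_interval_s must be > 0")
        if len(self.data):
            frames = self.data.groupby("track_id", sort=False)["frame"]
            if not (frames.apply(lambda f: bool(np.all(np.diff(f.to_numpy()) > 0)))).all():
                raise InvalidInputError("frames must be strictly increasing per track")

    @property
    def n_tracks(self) -> int:
        return self.data["track_id"].nunique()

    @property
    def track_ids(self) -> list:
        return list(dict.fromkeys(self.data["track_id"].tolist()))

    def track(self, track_id) -> pd.DataFrame:
        """Rows of one track, frame-ordered."""
        return self.data[self.data["track_id"] == track_id]

    def iter_tracks(self):
        """Yield (track_id, frames array, xy array [n, 2] in um)."""
        for tid, sub in self.data.groupby("track_id", sort=False):
            yield tid, sub["frame"].to_numpy(), sub[["x_um", "y_um"]].to_numpy(float)

    def track_lengths(self) -> pd.Series:
        return self.data.groupby("track_id", sort=False).size()
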