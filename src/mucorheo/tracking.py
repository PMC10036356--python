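"""Bead localization and trajectory linking for particle-tracking microrheology.

A Crocker–Grier-style chain: band-pass filtering (Gaussian smooth minus
boxcar background), local-maximum candidate detection, iterative
brightness-weighted-centroid sub-pixel refinement, greedy
nearest-neighbor frame-to-frame linking with gap memory, track-length
filtering and ensemble drift correction.

Coordinate convention: pixel centers at integer coordinates, origin at
the top-left pixel, x = column index, y = row index.  Positions convert
to micrometres via the stack's pixel size.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from mucorheo.errors import InvalidInputError
from mucorheo.trajectories import TrajectorySet

logger = logging.getLogger(__name__)

__all__ = [
    "ImageStack",
    "bandpass_filter",
    "locate_beads",
    "link_trajectories",
    "filter_tracks",
    "drift_correct",
]


@dataclass
class ImageStack:
    """A grayscale video: (t, y, x) intensities with pixel size and frame rate."""

    frames: np.ndarray
    pixel_size_um: float
    frame_rate_hz: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise InvalidInputError("frames must be a (t, y, x) array with >= 1 frame")
        if np.any(self.frames < 0):
            raise InvalidInputError("intensities must be non-negative")
        if self.pixel_size_um <= 0 or self.frame_rate_hz <= 0:
            raise InvalidInputError("pixel_size_um and frame_rate_hz must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.frames.shape[1:]


def bandpass_filter(
    stack: ImageStack, noise_sigma_px: float, feature_diameter_px: int
) -> ImageStack:
    """Gaussian smooth minus boxcar background, clipped at zero.

    ``noise_sigma_px`` sets the smoothing scale (suppresses pixel noise);
    ``feature_diameter_px`` sets the boxcar width (removes slowly varying
    background).  Requires feature_diameter > 2 * noise_sigma.
    """
    if noise_sigma_px <= 0 or feature_diameter_px <= 2 * noise_sigma_px:
        raise InvalidInputError(
            "need noise_sigma > 0 and feature_diameter > 2 * noise_sigma"
        )
    out = np.empty(stack.frames.shape, float)
    for t in range(stack.n_frames):
        frame = stack.frames[t].astype(float)
        smooth = ndimage.gaussian_filter(frame, noise_sigma_px)
        background = ndimage.uniform_filter(frame, int(feature_diameter_px))
        out[t] = np.clip(smooth - background, 0.0, None)
    return ImageStack(out, stack.pixel_size_um, stack.frame_rate_hz, dict(stack.meta))


def _refine_centroid(
    frame: np.ndarray,
    y0: int,
    x0: int,
    radius: int,
    disk: np.ndarray,
    offsets: np.ndarray,
    max_iter: int = 10,
) -> tuple[float, float, float, float]:
    """Iterative masked centroid around an integer peak.

    Returns (y, x, mass, radius_of_gyration).  The circular mask is
    re-centered on the nearest pixel of the running estimate until the
    estimate stops crossing pixel boundaries.  ``disk`` is the
    precomputed circular mask and ``offsets`` the matching -r..r grid.
    """
    ny, nx = frame.shape
    cy, cx = y0, x0
    y_sub, x_sub = float(y0), float(x0)
    mass = 0.0
    for _ in range(max_iter):
        patch = frame[cy - radius : cy + radius + 1, cx - radius : cx + radius + 1] * disk
        mass = float(patch.sum())
        if mass <= 0:
            return y_sub, x_sub, 0.0, 0.0
        y_sub = cy + float(patch.sum(axis=1) @ offsets) / mass
        x_sub = cx + float(patch.sum(axis=0) @ offsets) / mass
        ny_c, nx_c = int(round(y_sub)), int(round(x_sub))
        if (ny_c, nx_c) == (cy, cx):
            break
        cy = min(max(ny_c, radius), ny - 1 - radius)
        cx = min(max(nx_c, radius), nx - 1 - radius)
    r2 = (offsets[:, None] + cy - y_sub) ** 2 + (offsets[None, :] + cx - x_sub) ** 2
    patch = frame[cy - radius : cy + radius + 1, cx - radius : cx + radius + 1] * disk
    mass = float(patch.sum())
    rg = float(np.sqrt((patch * r2).sum() / mass)) if mass > 0 else 0.0
    return y_sub, x_sub, mass, rg


def locate_beads(
    stack: ImageStack,
    feature_diameter_px: int = 7,
    min_mass: float = 0.0,
    separation_px: int | None = None,
    candidate_threshold: float | None = None,
) -> pd.DataFrame:
    """Detect bead-like spots in every frame with sub-pixel positions.

    Local maxima found by grayscale dilation; each candidate is refined
    by an iterative brightness-weighted centroid within a circular mask
    of radius feature_diameter // 2.  Detections with integrated mass
    below ``min_mass`` are dropped.  ``candidate_threshold`` prunes
    local maxima before refinement; the default — the larger of 20% of
    the frame maximum and median + 10 scaled-MAD — sits above residual
    noise maxima on both raw and zero-clipped band-passed frames.  Set
    it explicitly for fields mixing bright and very dim beads.  Returns
    a table with columns ``frame, x, y, mass, size`` (x, y in pixels).

    Sub-pixel accuracy assumes background-free input — run
    :func:`bandpass_filter` first on raw video; residual background
    under the centroid mask biases positions toward the mask center.
    """
    if feature_diameter_px % 2 == 0:
        raise InvalidInputError("feature_diameter_px must be odd")
    radius = feature_diameter_px // 2
    sep = separation_px or feature_diameter_px
    offsets = np.arange(-radius, radius + 1, dtype=float)
    disk = (offsets[:, None] ** 2 + offsets[None, :] ** 2) <= radius**2
    rows = []
    for t in range(stack.n_frames):
        frame = stack.frames[t].astype(float)
        dil = ndimage.grey_dilation(frame, size=(sep, sep), mode="constant")
        if candidate_threshold is not None:
            thr = candidate_threshold
        else:
            med = float(np.median(frame))
            mad = float(np.median(np.abs(frame - med)))
            thr = max(0.2 * float(frame.max()), med + 10.0 * 1.4826 * mad)
        peaks = (frame == dil) & (frame > max(thr, 0.0))
        # exclude the margin where the refinement mask would clip
        peaks[:radius, :] = peaks[-radius:, :] = False
        peaks[:, :radius] = peaks[:, -radius:] = False
        for y0, x0 in zip(*np.nonzero(peaks)):
            y, x, mass, size = _refine_centroid(
                frame, int(y0), int(x0), radius, disk, offsets
            )
            if mass >= min_mass and mass > 0:
                rows.append((t, x, y, mass, size))
    df = pd.DataFrame(rows, columns=["frame", "x", "y", "mass", "size"])
    if len(df):
        # dilation plateaus can yield duplicate peaks for one spot; keep the
        # brightest detection within half a separation
        df = _deduplicate(df, sep / 2.0)
    return df.reset_index(drop=True)


def _deduplicate(df: pd.DataFrame, min_dist: float) -> pd.DataFrame:
    keep = []
    for _, sub in df.groupby("frame", sort=True):
        sub = sub.sort_values("mass", ascending=False)
        taken: list[tuple[float, float]] = []
        for idx, row in sub.iterrows():
            if all(
                (row.x - tx) ** 2 + (row.y - ty) ** 2 >= min_dist**2
                for tx, ty in taken
            ):
                keep.append(idx)
                taken.append((row.x, row.y))
    return df.loc[sorted(keep)]


def link_trajectories(
    detections: pd.DataFrame,
    pixel_size_um: float,
    frame_rate_hz: float,
    search_radius_px: float = 5.0,
    memory: int = 0,
) -> TrajectorySet:
    """Greedy nearest-neighbor linking of per-frame detections.

    Candidate (track, detection) pairs within ``search_radius_px`` are
    assigned in order of increasing distance (ties broken toward the
    lower track id), each track and detection used at most once per
    frame.  A track may skip up to ``memory`` frames before being
    terminated.  Output positions are in micrometres.
    """
    if search_radius_px <= 0:
        raise InvalidInputError("search_radius_px must be > 0")
    required = {"frame", "x", "y"}
    if not required.issubset(detections.columns):
        raise InvalidInputError(f"detections need columns {sorted(required)}")

    next_id = 0
    active: dict[int, tuple[float, float, int]] = {}  # id -> (x, y, last_frame)
    rows = []
    for frame in sorted(detections["frame"].unique()):
        sub = detections[detections["frame"] == frame]
        pts = sub[["x", "y"]].to_numpy(float)
        # drop tracks whose gap exceeded memory
        active = {
            tid: st for tid, st in active.items() if frame - st[2] <= memory + 1
        }
        pairs = []
        for tid, (tx, ty, _) in active.items():
            d = np.hypot(pts[:, 0] - tx, pts[:, 1] - ty)
            for j in np.nonzero(d <= search_radius_px)[0]:
                pairs.append((float(d[j]), tid, int(j)))
        pairs.sort(key=lambda p: (p[0], p[1]))
        used_tracks: set[int] = set()
        used_dets: set[int] = set()
        assign: dict[int, int] = {}
        for dist, tid, j in pairs:
            if tid in used_tracks or j in used_dets:
                continue
            assign[j] = tid
            used_tracks.add(tid)
            used_dets.add(j)
        for j, (x, y) in enumerate(pts):
            tid = assign.get(j)
            if tid is None:
                tid = next_id
                next_id += 1
            active[tid] = (float(x), float(y), int(frame))
            rows.append((tid, int(frame), x * pixel_size_um, y * pixel_size_um))

    df = pd.DataFrame(rows, columns=["track_id", "frame", "x_um", "y_um"])
    df = df.sort_values(["track_id", "frame"], kind="stable").reset_index(drop=True)
    return TrajectorySet(
        df,
        frame_interval_s=1.0 / frame_rate_hz,
        meta={"pixel_size_um": pixel_size_um, "origin": "top-left, x=column"},
    )


def filter_tracks(ts: TrajectorySet, min_length: int) -> TrajectorySet:
    """Keep tracks observed in at least ``min_length`` frames; ids preserved."""
    lengths = ts.track_lengths()
    keep = lengths[lengths >= min_length].index
    df = ts.data[ts.data["track_id"].isin(keep)].reset_index(drop=True)
    return TrajectorySet(df, ts.frame_interval_s, dict(ts.meta))


def drift_correct(ts: TrajectorySet) -> TrajectorySet:
    """Subtract the cumulative ensemble-mean displacement from every track.

    Drift is estimated from frame-to-frame displacements (not positions)
    so staggered track starts do not bias it; frames with no shared bead
    get linearly interpolated drift.  After correction the ensemble-mean
    displacement per frame is zero to machine precision.
    """
    if ts.n_tracks < 2:
        warnings.warn("drift correction with < 2 tracks is unreliable", stacklevel=2)
        if ts.n_tracks <= 1:
            return ts
    df = ts.data
    f_min, f_max = int(df["frame"].min()), int(df["frame"].max())
    n = f_max - f_min + 1
    sums = np.zeros((n, 2))
    counts = np.zeros(n)
    for _, frames, xy in ts.iter_tracks():
        idx = frames - f_min
        contiguous = np.diff(frames) == 1
        d = np.diff(xy, axis=0)
        tgt = idx[1:][contiguous]
        np.add.at(sums, tgt, d[contiguous])
        np.add.at(counts, tgt, 1.0)
    disp = np.zeros((n, 2))
    have = counts > 0
    disp[have] = sums[have] / counts[have, None]
    if not have.all() and have[1:].any():
        missing = ~have
        missing[0] = False  # frame 0 has no incoming displacement by definition
        if missing.any():
            logger.info("interpolating drift over %d empty frames", missing.sum())
            xs = np.nonzero(have)[0]
            for ax in range(2):
                disp[missing, ax] = np.interp(np.nonzero(missing)[0], xs, disp[xs, ax])
    drift = np.cumsum(disp, axis=0)
    out = df.copy()
    idx = out["frame"].to_numpy(int) - f_min
    out["x_um"] = out["x_um"].to_numpy() - drift[idx, 0]
    out["y_um"] = out["y_um"].to_numpy() - drift[idx, 1]
    return TrajectorySet(out, ts.frame_interval_s, dict(ts.meta))
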