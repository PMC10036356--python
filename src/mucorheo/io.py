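"""Readers and writers for the pipeline's plain-text and TIFF formats.

All tabular formats are UTF-8 CSV with a required header; trajectory and
sweep files carry ``#``-prefixed metadata comments including a format
version tag that readers verify.  Videos are multi-page 16-bit TIFF.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from mucorheo.errors import InvalidInputError
from mucorheo.sample_qc import PoolRecipe, SampleRecord, TonicityReference
from mucorheo.tracking import ImageStack
from mucorheo.trajectories import TRACK_COLUMNS, TrajectorySet

TRAJ_FORMAT = "mucorheo-trajectories v1"
SWEEP_FORMAT = "mucorheo-sweep v1"

SAMPLE_COLUMNS = [
    "sample_id",
    "age",
    "sex",
    "volume_ul",
    "pct_solids",
    "na_mM",
    "k_mM",
    "flags",
]


def read_sample_table(path: str | Path) -> list[SampleRecord]:
    """Read a sample CSV; row numbers are attached to parse errors."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidInputError(f"{path}: missing column(s) {missing}")
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                SampleRecord(
                    sample_id=row["sample_id"],
                    age=float(row["age"]) if row["age"] else None,
                    sex=row["sex"] or "unknown",
                    volume_ul=float(row["volume_ul"]),
                    pct_solids=float(row["pct_solids"]),
                    na_mM=float(row["na_mM"]),
                    k_mM=float(row["k_mM"]),
                    flags=frozenset(t for t in row["flags"].split(";") if t),
                )
            )
        except (ValueError, InvalidInputError) as exc:
            raise InvalidInputError(f"{path} row {i + 2}: {exc}") from exc
    return records


def write_sample_table(records: list[SampleRecord], path: str | Path) -> None:
    rows = [
        {
            "sample_id": s.sample_id,
            "age": "" if s.age is None else s.age,
            "sex": s.sex,
            "volume_ul": s.volume_ul,
            "pct_solids": s.pct_solids,
            "na_mM": s.na_mM,
            "k_mM": s.k_mM,
            "flags": ";".join(sorted(s.flags)),
        }
        for s in records
    ]
    pd.DataFrame(rows, columns=SAMPLE_COLUMNS).to_csv(path, index=False)


def write_trajectories(ts: TrajectorySet, path: str | Path) -> None:
    """Trajectory CSV with commented metadata header; positions to 1e-6 um."""
    lines = [f"# {TRAJ_FORMAT}"]
    lines.append(f"# frame_interval_s={ts.frame_interval_s!r}")
    for key in ("pixel_size_um", "origin"):
        if key in ts.meta:
            lines.append(f"# {key}={ts.meta[key]}")
    body = ts.data[list(TRACK_COLUMNS)].to_csv(index=False, float_format="%.6f")
    Path(path).write_text("\n".join(lines) + "\n" + body, encoding="utf-8")


def read_trajectories(path: str | Path) -> TrajectorySet:
    text = Path(path).read_text(encoding="utf-8").splitlines()
    meta: dict = {}
    n_comments = 0
    for line in text:
        if not line.startswith("#"):
            break
        n_comments += 1
        content = line[1:].strip()
        if "=" in content:
            k, v = content.split("=", 1)
            meta[k.strip()] = v.strip()
    if not text or text[0] != f"# {TRAJ_FORMAT}":
        raise InvalidInputError(f"{path}: not a {TRAJ_FORMAT} file")
    frame_interval = float(meta.pop("frame_interval_s"))
    df = pd.read_csv(
        Path(path),
        skiprows=n_comments,
        dtype={"track_id": int, "frame": int, "x_um": float, "y_um": float},
    )
    return TrajectorySet(df, frame_interval_s=frame_interval, meta=meta)


def write_sweep(df: pd.DataFrame, path: str | Path, kind: str, fixed: str = "") -> None:
    """Sweep CSV (strain or frequency) with a commented header.

    ``fixed`` records the held-constant variable, e.g. "strain_pct=1".
    """
    if kind not in ("strain", "freq"):
        raise InvalidInputError("kind must be 'strain' or 'freq'")
    header = f"# {SWEEP_FORMAT}\n# kind={kind}\n"
    if fixed:
        header += f"# fixed={fixed}\n"
    Path(path).write_text(header + df.to_csv(index=False), encoding="utf-8")


def read_sweep(path: str | Path) -> tuple[pd.DataFrame, str]:
    text = Path(path).read_text(encoding="utf-8").splitlines()
    if not text or text[0] != f"# {SWEEP_FORMAT}":
        raise InvalidInputError(f"{path}: not a {SWEEP_FORMAT} file")
    kind = ""
    n_comments = 0
    for line in text:
        if not line.startswith("#"):
            break
        n_comments += 1
        if line[1:].strip().startswith("kind="):
            kind = line.split("=", 1)[1].strip()
    df = pd.read_csv(Path(path), skiprows=n_comments)
    return df, kind


def write_image_stack(stack: ImageStack, path: str | Path) -> None:
    tifffile.imwrite(
        path,
        stack.frames.astype(np.uint16),
        metadata={
            "pixel_size_um": stack.pixel_size_um,
            "frame_rate_hz": stack.frame_rate_hz,
        },
    )


def read_image_stack(
    path: str | Path, pixel_size_um: float | None = None, frame_rate_hz: float | None = None
) -> ImageStack:
    """Read a multi-page TIFF; calibration from embedded metadata or arguments."""
    with tifffile.TiffFile(path) as tf:
        frames = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    if frames.ndim == 2:
        frames = frames[None]
    px = pixel_size_um or float(meta.get("pixel_size_um", 0) or 0)
    fr = frame_rate_hz or float(meta.get("frame_rate_hz", 0) or 0)
    if px <= 0 or fr <= 0:
        raise InvalidInputError(
            f"{path}: pixel size / frame rate not in metadata; pass them explicitly"
        )
    return ImageStack(frames, pixel_size_um=px, frame_rate_hz=fr)


def write_pool_recipe(
    recipe: PoolRecipe, ref: TonicityReference, path: str | Path
) -> None:
    """Emit a pool recipe as JSON, with reference-value provenance."""
    payload = {
        "format": "mucorheo-recipe v1",
        "entries": [
            {"sample_id": sid, "aliquot_volume_ul": vol} for sid, vol in recipe.entries
        ],
        "added_nacl_mg": recipe.added_nacl_mg,
        "added_kcl_mg": recipe.added_kcl_mg,
        "expected_na_mM": recipe.expected_na_mM,
        "expected_k_mM": recipe.expected_k_mM,
        "note": "added-salt masses neglect solid-volume change (<0.5%)",
        "reference": {
            "na_ref_mM": ref.na_ref,
            "k_ref_mM": ref.k_ref,
            "iso_window": list(ref.iso_window),
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True), encoding="utf-8")


def read_pool_recipe(path: str | Path) -> PoolRecipe:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    if payload.get("format") != "mucorheo-recipe v1":
        raise InvalidInputError(f"{path}: not a mucorheo-recipe v1 file")
    return PoolRecipe(
        entries=tuple(
            (e["sample_id"], e["aliquot_volume_ul"]) for e in payload["entries"]
        ),
        added_nacl_mg=payload["added_nacl_mg"],
        added_kcl_mg=payload["added_kcl_mg"],
        expected_na_mM=payload["expected_na_mM"],
        expected_k_mM=payload["expected_k_mM"],
    )
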