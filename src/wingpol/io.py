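"""Readers, writers, configuration and run metadata.

Formats: TIFF for images (via tifffile), CSV for tracks and cell tables
(via pandas), JSON for histograms/summaries/metadata, YAML for run
configuration.  Every pipeline run writes a metadata record (parameters,
package version, seed) beside its outputs so any result can be
regenerated.
"""

from __future__ import annotations

import json
import platform
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .errors import FormatError, InvalidParameterError
from .tracks import Track

TRACK_COLUMNS = ["track_id", "frame", "t_seconds", "x", "y"]


def read_image(path: str | Path) -> np.ndarray:
    """Read a TIFF as float array; multi-channel images come back as
    (channels, height, width)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"image file not found: {path}")
    try:
        arr = tifffile.imread(path)
    except Exception as exc:  # tifffile raises several types
        raise FormatError(f"cannot read TIFF {path}: {exc}") from exc
    if arr.ndim not in (2, 3):
        raise FormatError(f"{path}: expected 2-D or channel-stacked image, got shape {arr.shape}")
    return np.asarray(arr, dtype=float)


def write_image(path: str | Path, image: np.ndarray | list[np.ndarray]) -> None:
    """Write one image or a channel list as TIFF (float32)."""
    if isinstance(image, (list, tuple)):
        image = np.stack(image, axis=0)
    tifffile.imwrite(Path(path), np.asarray(image, dtype=np.float32))


def read_tracks(path: str | Path) -> list[Track]:
    """Read tracks from CSV with columns track_id, frame, t_seconds, x, y.

    Optional columns (truth_label, apical, ...) are preserved on the
    returned frame attribute ``read_tracks.last_frame``.  Raises
    :class:`FormatError` on missing columns, duplicate (track_id, frame)
    pairs or non-increasing timestamps, naming the offending row.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"track file not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    dup = df.duplicated(subset=["track_id", "frame"])
    if dup.any():
        row = int(np.nonzero(dup.to_numpy())[0][0])
        raise FormatError(f"{path}: duplicate (track_id, frame) at row {row}")
    df = df.sort_values(["track_id", "frame"]).reset_index(drop=True)
    tracks = []
    for tid, sub in df.groupby("track_id", sort=True):
        t = sub["t_seconds"].to_numpy(float)
        if t.size >= 2 and np.any(np.diff(t) <= 0):
            bad = int(sub.index[np.argmax(np.diff(t) <= 0) + 1])
            raise FormatError(f"{path}: non-increasing t_seconds near row {bad}")
        apical = sub["apical"].to_numpy(bool) if "apical" in sub.columns else None
        tracks.append(
            Track(
                track_id=int(tid), t=t,
                x=sub["x"].to_numpy(float), y=sub["y"].to_numpy(float),
                apical=apical,
            )
        )
    read_tracks.last_frame = df
    return tracks


def write_tracks(path: str | Path, df: pd.DataFrame) -> None:
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidParameterError(f"track frame missing columns {missing}")
    df.to_csv(Path(path), index=False)


def load_config(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"config file not found: {path}")
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return cfg


def write_json(path: str | Path, obj: dict) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(Path(path), "w") as fh:
        json.dump(obj, fh, indent=2, default=default)
        fh.write("\n")


def write_run_metadata(out_dir: str | Path, stage: str, params: dict, seed: int | None) -> Path:
    """Record what produced the outputs in ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = {
        "stage": stage,
        "parameters": params,
        "seed": seed,
        "wingpol_version": __version__,
        "python": platform.python_version(),
    }
    path = out_dir / f"{stage}_metadata.json"
    write_json(path, meta)
    return path


def child_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from one global seed."""
    tag = zlib.crc32(stage.encode("utf8"))
    ss = np.random.SeedSequence([int(seed), int(tag)])
    return int(ss.generate_state(1)[0] % (2**31))
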