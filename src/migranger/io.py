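"""Containers and delimited-table I/O.

Two tidy tables carry all object-level data (coordinates in µm, areas in µm²,
time as 0-based frame indices at a fixed frame interval in minutes):

``cells.csv``
    condition, repeat, cell_id, frame, centroid_x_um, centroid_y_um,
    polygon_wkt

``cmacs.csv``
    condition, repeat, cell_id, cmac_id, frame, centroid_x_um, centroid_y_um,
    area_um2, major_axis_um, minor_axis_um, ch1_pixels, ch2_pixels,
    ch1_bg, ch2_bg

``ch1`` is the EGFP-Paxillin (CMAC marker) channel and ``ch2`` the
RubyRed-LifeAct (F-actin marker) channel.  Pixel vectors are ``;``-joined
floats so that colocalization is computable without image access.

Feature panels are tidy DataFrames keyed by (condition, repeat, cell_id,
frame) with one column per catalog feature.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

TRACK_KEYS = ["condition", "repeat", "cell_id"]
CMAC_KEYS = TRACK_KEYS + ["cmac_id"]
FRAME = "frame"

CELLS_COLUMNS = TRACK_KEYS + [FRAME, "centroid_x_um", "centroid_y_um", "polygon_wkt"]
CMACS_COLUMNS = TRACK_KEYS + [
    "cmac_id",
    FRAME,
    "centroid_x_um",
    "centroid_y_um",
    "area_um2",
    "major_axis_um",
    "minor_axis_um",
    "ch1_pixels",
    "ch2_pixels",
    "ch1_bg",
    "ch2_bg",
]


def encode_pixels(values) -> str:
    return ";".join(format(float(v), ".6g") for v in np.asarray(values).ravel())


def decode_pixels(text: str) -> np.ndarray:
    if not isinstance(text, str) or not text:
        return np.empty(0)
    return np.array([float(t) for t in text.split(";")])


@dataclass
class TrackedDataset:
    """Per-condition/repeat collections of cell tracks and their CMACs."""

    cells: pd.DataFrame
    cmacs: pd.DataFrame
    frame_interval_min: float = 5.0
    pixel_size_um: float = 0.21
    meta: dict = field(default_factory=dict)

    def copy(self) -> "TrackedDataset":
        return TrackedDataset(
            self.cells.copy(),
            self.cmacs.copy(),
            self.frame_interval_min,
            self.pixel_size_um,
            dict(self.meta),
        )

    @property
    def n_cell_tracks(self) -> int:
        return len(self.cells.drop_duplicates(TRACK_KEYS))


def _check_contiguous(df: pd.DataFrame, keys: list[str], what: str) -> None:
    for key, grp in df.groupby(keys, sort=False):
        frames = np.sort(grp[FRAME].to_numpy())
        if len(frames) != len(set(frames)):
            raise ValueError(f"duplicate frame in {what} track {key}")
        if len(frames) > 1 and not np.all(np.diff(frames) == 1):
            raise ValueError(f"non-contiguous frames in {what} track {key}")


def write_tracked_tables(dataset: TrackedDataset, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = {
        "frame_interval_min": dataset.frame_interval_min,
        "pixel_size_um": dataset.pixel_size_um,
    }
    for name, df, cols in (
        ("cells.csv", dataset.cells, CELLS_COLUMNS),
        ("cmacs.csv", dataset.cmacs, CMACS_COLUMNS),
    ):
        path = out / name
        with open(path, "w") as fh:
            fh.write(f"# {json.dumps(header)}\n")
            df[cols].to_csv(fh, index=False)


def read_tracked_tables(in_dir) -> TrackedDataset:
    """Read and validate ``cells.csv``/``cmacs.csv`` from a directory.

    Rejects missing columns, non-contiguous frames within a track and
    negative CMAC areas.
    """
    in_dir = Path(in_dir)
    meta = {}
    frames_meta = {"frame_interval_min": 5.0, "pixel_size_um": 0.21}
    tables = {}
    for name, cols in (("cells.csv", CELLS_COLUMNS), ("cmacs.csv", CMACS_COLUMNS)):
        path = in_dir / name
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#"):
                frames_meta.update(json.loads(first[1:].strip()))
                df = pd.read_csv(fh)
            else:
                fh.seek(0)
                df = pd.read_csv(fh)
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValueError(f"{name}: missing columns {missing}")
        tables[name] = df

    cells, cmacs = tables["cells.csv"], tables["cmacs.csv"]
    _check_contiguous(cells, TRACK_KEYS, "cell")
    _check_contiguous(cmacs, CMAC_KEYS, "CMAC")
    bad = cmacs.index[cmacs["area_um2"] <= 0]
    if len(bad):
        raise ValueError(f"non-positive CMAC areas at rows {list(bad[:5])}")
    return TrackedDataset(
        cells,
        cmacs,
        frame_interval_min=float(frames_meta["frame_interval_min"]),
        pixel_size_um=float(frames_meta["pixel_size_um"]),
        meta=meta,
    )


# ---------------------------------------------------------------------------
# Feature panels
# ---------------------------------------------------------------------------

PANEL_KEYS = TRACK_KEYS + [FRAME]


def feature_columns(panel: pd.DataFrame) -> list[str]:
    """Columns of a tidy feature panel that hold feature values."""
    return [c for c in panel.columns if c not in PANEL_KEYS]


def write_panel(panel: pd.DataFrame, path, config_hash: str | None = None) -> None:
    with open(path, "w") as fh:
        if config_hash is not None:
            fh.write(f"# config_hash={config_hash}\n")
        panel.to_csv(fh, index=False)


def read_panel(path) -> pd.DataFrame:
    with open(path) as fh:
        pos = fh.tell()
        first = fh.readline()
        if not first.startswith("#"):
            fh.seek(pos)
        return pd.read_csv(fh)
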