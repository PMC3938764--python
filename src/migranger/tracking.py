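"""Object linking and the CMAC parsing rules.

Tracking uses greedy mutual nearest-neighbor linking between consecutive
frames with a hard 2 µm displacement gate.  Parsing removes detections that
are most plausibly noise — single-frame tracks, records with a sub-pixel
(< 0.21 µm) minor axis, records at or below the 0.05 µm² segmentation floor —
and flags tracks touching the first or final frame of a sequence as censored,
so that incomplete lifetimes never enter per-cell lifetime aggregates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CMAC_KEYS, FRAME

MAX_DISPLACEMENT_UM = 2.0
MIN_MINOR_AXIS_UM = 0.21
MIN_AREA_UM2 = 0.05


def link_nearest_neighbor(
    detections: pd.DataFrame,
    max_displacement: float = MAX_DISPLACEMENT_UM,
    id_col: str = "id",
) -> pd.DataFrame:
    """Link per-frame detections into tracks.

    ``detections`` must carry ``frame``, ``centroid_x_um``, ``centroid_y_um``
    and a per-frame ``id``.  Links longer than ``max_displacement`` are
    forbidden; unmatched detections open new tracks.  Candidate links are
    accepted greedily in order of increasing distance (ties broken by the
    smaller previous-object id, then smaller new-object id), which yields a
    mutual nearest-neighbor assignment.

    Returns a copy of ``detections`` with a ``track_id`` column.
    """
    df = detections.copy()
    if df.duplicated(subset=[FRAME, id_col]).any():
        raise ValueError("duplicate (frame, id) detection")
    df = df.sort_values([FRAME, id_col], kind="mergesort").reset_index(drop=True)
    df["track_id"] = -1

    next_track = 1
    prev_idx: dict[int, int] = {}  # track_id -> row index of its last detection
    for frame, grp in df.groupby(FRAME, sort=True):
        cur_rows = grp.index.to_numpy()
        if prev_idx:
            prev_tracks = np.array(sorted(prev_idx))
            prev_rows = np.array([prev_idx[t] for t in prev_tracks])
            p = df.loc[prev_rows, ["centroid_x_um", "centroid_y_um"]].to_numpy()
            c = df.loc[cur_rows, ["centroid_x_um", "centroid_y_um"]].to_numpy()
            dist = np.linalg.norm(p[:, None, :] - c[None, :, :], axis=2)
            cand = np.argwhere(dist <= max_displacement)
            order = sorted(
                (float(dist[i, j]),
                 int(df.loc[prev_rows[i], id_col]),
                 int(df.loc[cur_rows[j], id_col]),
                 int(i), int(j))
                for i, j in cand
            )
            used_prev: set[int] = set()
            used_cur: set[int] = set()
            for _, _, _, i, j in order:
                if i in used_prev or j in used_cur:
                    continue
                used_prev.add(i)
                used_cur.add(j)
                df.loc[cur_rows[j], "track_id"] = prev_tracks[i]
        new_prev: dict[int, int] = {}
        for row in cur_rows:
            t = df.loc[row, "track_id"]
            if t == -1:
                t = next_track
                next_track += 1
                df.loc[row, "track_id"] = t
            new_prev[int(t)] = int(row)
        prev_idx = new_prev
    return df


@dataclass
class ParsingReport:
    """Counts of records/tracks removed or flagged by each parsing rule."""

    input_records: int = 0
    input_tracks: int = 0
    removed_single_frame_tracks: int = 0
    removed_minor_axis_records: int = 0
    removed_small_area_records: int = 0
    split_displacement_violations: int = 0
    censored_tracks: int = 0
    surviving_tracks: int = 0
    surviving_records: int = 0
    notes: list = field(default_factory=list)


def _contiguous_segments(frames: np.ndarray) -> list[np.ndarray]:
    breaks = np.where(np.diff(frames) != 1)[0]
    return np.split(np.arange(len(frames)), breaks + 1)


def parse_cmac_tracks(
    cmacs: pd.DataFrame,
    sequence_bounds: dict | None = None,
    min_minor_axis: float = MIN_MINOR_AXIS_UM,
    min_area: float = MIN_AREA_UM2,
    max_displacement: float = MAX_DISPLACEMENT_UM,
) -> tuple[pd.DataFrame, ParsingReport]:
    """Apply the parsing filters to linked CMAC records.

    Record-level rules first (minor axis below one pixel; area at or below
    the segmentation floor), then track-level rules: tracks are split at
    inter-frame displacements beyond the gate (keeping the longest contiguous
    segment), single-frame tracks are dropped, and tracks touching the first
    or final frame of their (condition, repeat) sequence are flagged
    ``censored_start``/``censored_end``.

    ``sequence_bounds`` maps (condition, repeat) to (first_frame, last_frame);
    when omitted the bounds are inferred from the data.

    Returns the surviving records (with ``censored_start``, ``censored_end``
    and ``lifetime_frames`` columns) and a :class:`ParsingReport`.
    """
    report = ParsingReport(
        input_records=len(cmacs),
        input_tracks=int(cmacs.drop_duplicates(CMAC_KEYS).shape[0]),
    )
    df = cmacs.sort_values(CMAC_KEYS + [FRAME], kind="mergesort").reset_index(drop=True)

    bad_minor = df["minor_axis_um"] < min_minor_axis
    report.removed_minor_axis_records = int(bad_minor.sum())
    bad_area = (df["area_um2"] <= min_area) & ~bad_minor
    report.removed_small_area_records = int(bad_area.sum())
    df = df[~(bad_minor | bad_area)]

    if sequence_bounds is None:
        g = cmacs.groupby(["condition", "repeat"])[FRAME]
        sequence_bounds = {
            key: (int(lo), int(hi)) for key, lo, hi in zip(g.min().index, g.min(), g.max())
        }

    kept = []
    for key, grp in df.groupby(CMAC_KEYS, sort=False):
        frames = grp[FRAME].to_numpy()
        xy = grp[["centroid_x_um", "centroid_y_um"]].to_numpy()
        # split at contiguity breaks from record removal and at gate violations
        segments = []
        for seg in _contiguous_segments(frames):
            start = 0
            for k in range(1, len(seg)):
                d = np.linalg.norm(xy[seg[k]] - xy[seg[k - 1]])
                if d > max_displacement:
                    report.split_displacement_violations += 1
                    segments.append(seg[start:k])
                    start = k
            segments.append(seg[start:])
        best = max(segments, key=len)
        if len(best) < 2:
            report.removed_single_frame_tracks += 1
            continue
        sub = grp.iloc[best].copy()
        lo, hi = sequence_bounds[(key[0], key[1])]
        cs = bool(sub[FRAME].iloc[0] <= lo)
        ce = bool(sub[FRAME].iloc[-1] >= hi)
        sub["censored_start"] = cs
        sub["censored_end"] = ce
        sub["lifetime_frames"] = len(sub)
        if cs or ce:
            report.censored_tracks += 1
        kept.append(sub)

    if kept:
        out = pd.concat(kept, ignore_index=True)
    else:
        out = df.iloc[0:0].copy()
        out["censored_start"] = pd.Series(dtype=bool)
        out["censored_end"] = pd.Series(dtype=bool)
        out["lifetime_frames"] = pd.Series(dtype=int)
        report.notes.append("no CMAC tracks survived parsing")
    report.surviving_tracks = int(out.drop_duplicates(CMAC_KEYS).shape[0]) if len(out) else 0
    report.surviving_records = len(out)
    return out, report
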