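"""Feature extraction: per-CMAC (29) and single-cell (88) catalogs.

The extraction runs in four steps:

1. :func:`build_cmac_records` decodes pixel vectors, computes Pearson
   colocalization between channels and applies local-background correction.
2. :func:`standardize_intensities` rescales all intensities per channel and
   experimental repeat by the median corrected mean intensity of
   reference-condition CMACs with area in [0.15, 0.2] µm² — a size window
   above optical/digital resolution that anchors gain differences between
   repeats.
3. :func:`compute_cmac_features` evaluates the 29-entry per-CMAC catalog,
   including geometry relative to the parent cell outline.
4. :func:`compute_cell_features` evaluates the 88-entry single-cell catalog:
   cell-scale morphology, per-cell aggregates of the CMAC population, and
   Instantaneous Cell Speed from a spline-smoothed trajectory.

Standardized distance to the cell edge is
``s = d(P, ∂Ω) / (d(P, ∂Ω) + |P − C|)`` with ``C`` the cell center of area:
0 on the boundary, 1 at the center.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import shapely
from scipy.interpolate import make_smoothing_spline
from shapely import wkt as shapely_wkt

from . import catalog
from .io import CMAC_KEYS, FRAME, TRACK_KEYS, TrackedDataset, decode_pixels

CHANNEL_NAMES = {"ch1": "EGFP-Paxillin", "ch2": "RubyRed-LifeAct"}


# ---------------------------------------------------------------------------
# Record-level intensity handling
# ---------------------------------------------------------------------------

def correct_local_background(raw_mean, background, area):
    """Background-corrected mean and total intensity for one CMAC record.

    corrected mean = raw mean − local background (clamped at 0);
    corrected total = corrected mean × area.  Returns
    ``(mean, total, clamped_flag)``.
    """
    if background is None or (np.isscalar(background) and not np.isfinite(background)):
        raise ValueError("missing local background estimate")
    mean = float(raw_mean) - float(background)
    clamped = mean < 0
    mean = max(mean, 0.0)
    return mean, mean * float(area), clamped


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0 or len(x) < 2:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def build_cmac_records(cmacs: pd.DataFrame) -> pd.DataFrame:
    """Decode pixels and attach corrected intensities and colocalization.

    Adds per-channel ``raw_mean``, ``corr_mean``, ``corr_total`` columns,
    ``coloc`` (NaN with ``coloc_undefined`` set when a pixel vector is
    constant) and a ``bg_clamped`` flag.
    """
    df = cmacs.copy()
    n = len(df)
    out = {
        "ch1_raw_mean": np.empty(n), "ch2_raw_mean": np.empty(n),
        "coloc": np.empty(n), "coloc_undefined": np.zeros(n, dtype=bool),
    }
    px1 = df["ch1_pixels"].to_numpy()
    px2 = df["ch2_pixels"].to_numpy()
    for i in range(n):
        v1, v2 = decode_pixels(px1[i]), decode_pixels(px2[i])
        out["ch1_raw_mean"][i] = v1.mean() if len(v1) else np.nan
        out["ch2_raw_mean"][i] = v2.mean() if len(v2) else np.nan
        r = _pearson(v1, v2) if len(v1) == len(v2) else np.nan
        out["coloc"][i] = r
        out["coloc_undefined"][i] = not np.isfinite(r)
    for k, v in out.items():
        df[k] = v
    area = df["area_um2"].to_numpy()
    clamped = np.zeros(n, dtype=bool)
    for ch in ("ch1", "ch2"):
        mean = df[f"{ch}_raw_mean"].to_numpy() - df[f"{ch}_bg"].to_numpy()
        clamped |= mean < 0
        mean = np.maximum(mean, 0.0)
        df[f"{ch}_corr_mean"] = mean
        df[f"{ch}_corr_total"] = mean * area
    df["bg_clamped"] = clamped
    return df


def standardize_intensities(
    records: pd.DataFrame,
    reference_condition: str,
    area_window: tuple[float, float] = (0.15, 0.2),
) -> tuple[pd.DataFrame, dict]:
    """Divide all intensities per (repeat, channel) by the reference median.

    The divisor is the median corrected mean intensity of CMACs from
    ``reference_condition`` whose area lies in ``area_window``.  Repeats with
    no reference CMACs in the window are flagged and left unstandardized.
    """
    df = records.copy()
    divisors: dict = {"reference_condition": reference_condition, "per_repeat": {}, "flagged": []}
    intensity_cols = {
        "ch1": ["ch1_corr_mean", "ch1_corr_total", "ch1_raw_mean", "ch1_bg"],
        "ch2": ["ch2_corr_mean", "ch2_corr_total", "ch2_raw_mean", "ch2_bg"],
    }
    for cols in intensity_cols.values():
        df[cols] = df[cols].astype(float)
    for rep in sorted(df["repeat"].unique()):
        in_rep = df["repeat"] == rep
        window = (
            in_rep
            & (df["condition"] == reference_condition)
            & (df["area_um2"] >= area_window[0])
            & (df["area_um2"] <= area_window[1])
        )
        if not window.any():
            divisors["flagged"].append(int(rep))
            continue
        for ch, cols in intensity_cols.items():
            div = float(df.loc[window, f"{ch}_corr_mean"].median())
            if div <= 0:
                divisors["flagged"].append(int(rep))
                continue
            divisors["per_repeat"][f"repeat={rep},{ch}"] = div
            df.loc[in_rep, cols] = df.loc[in_rep, cols] / div
    return df, divisors


# ---------------------------------------------------------------------------
# Per-CMAC features
# ---------------------------------------------------------------------------

def _ellipse_perimeter(major: np.ndarray, minor: np.ndarray) -> np.ndarray:
    # Ramanujan approximation on semi-axes
    a, b = major / 2.0, minor / 2.0
    h = ((a - b) / (a + b)) ** 2
    return np.pi * (a + b) * (1 + 3 * h / (10 + np.sqrt(4 - 3 * h)))


def standardized_edge_distance(point_xy, polygon) -> float:
    """s = d_edge / (d_edge + d_center); 0 on the boundary, 1 at the center."""
    pt = shapely.points(point_xy[0], point_xy[1])
    d_edge = float(shapely.distance(pt, polygon.exterior))
    centroid = polygon.centroid
    d_cent = float(shapely.distance(pt, centroid))
    if d_edge + d_cent == 0:
        return 1.0
    return d_edge / (d_edge + d_cent)


def compute_cmac_features(
    parsed: pd.DataFrame,
    cells: pd.DataFrame,
    frame_interval_min: float = 5.0,
) -> pd.DataFrame:
    """Evaluate the 29 per-CMAC instantaneous features.

    ``parsed`` must come from :func:`~migranger.tracking.parse_cmac_tracks`
    after record building and standardization; ``cells`` supplies the parent
    cell polygon and centroid per frame.
    """
    df = parsed.sort_values(CMAC_KEYS + [FRAME], kind="mergesort").reset_index(drop=True)
    cell_geo = cells.set_index(TRACK_KEYS + [FRAME])
    # parse each distinct polygon once
    poly_cache: dict[str, shapely.Geometry] = {}

    n = len(df)
    F: dict[str, np.ndarray] = {name: np.full(n, np.nan) for name in catalog.CMAC_FEATURE_NAMES}

    area = df["area_um2"].to_numpy(float)
    major = df["major_axis_um"].to_numpy(float)
    minor = df["minor_axis_um"].to_numpy(float)
    perim = _ellipse_perimeter(major, minor)
    F["CMAC Area"] = area
    F["CMAC Major Axis Length"] = major
    F["CMAC Minor Axis Length"] = minor
    F["CMAC Axis Ratio"] = major / minor
    F["CMAC Eccentricity"] = np.sqrt(np.clip(1 - (minor / major) ** 2, 0, 1))
    F["CMAC Perimeter"] = perim
    F["CMAC Form Factor"] = 4 * np.pi * area / perim ** 2

    for ch, chname in CHANNEL_NAMES.items():
        F[f"CMAC Mean {chname} Intensity"] = df[f"{ch}_corr_mean"].to_numpy(float)
        F[f"CMAC Total {chname} Intensity"] = df[f"{ch}_corr_total"].to_numpy(float)
        F[f"CMAC Local Background {chname} Intensity"] = df[f"{ch}_bg"].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = df["ch1_corr_mean"].to_numpy(float) / df["ch2_corr_mean"].to_numpy(float)
    F["CMAC EGFP-Paxillin / RubyRed-LifeAct Intensity Ratio"] = np.where(
        np.isfinite(ratio), ratio, np.nan
    )
    F["EGFP-Paxillin - RubyRed-LifeAct Colocalization per CMAC"] = df["coloc"].to_numpy(float)

    xy = df[["centroid_x_um", "centroid_y_um"]].to_numpy(float)

    # track-wise dynamics
    frames = df[FRAME].to_numpy()
    track_codes = df.groupby(CMAC_KEYS, sort=False).ngroup().to_numpy()
    starts = np.r_[0, np.where(np.diff(track_codes) != 0)[0] + 1, n]
    for s, e in zip(starts[:-1], starts[1:]):
        seg = slice(s, e)
        L = e - s
        disp = np.full(L, np.nan)
        if L > 1:
            disp[1:] = np.linalg.norm(np.diff(xy[seg], axis=0), axis=1)
        F["CMAC Displacement"][seg] = disp
        F["CMAC Sliding Speed"][seg] = disp / frame_interval_min
        F["CMAC Cumulative Displacement"][seg] = np.nancumsum(np.nan_to_num(disp))
        age = frames[seg] - frames[s] + 1
        F["CMAC Lifetime to Date"][seg] = age
        censored = bool(df["censored_start"].iloc[s] or df["censored_end"].iloc[s])
        F["CMAC Lifetime"][seg] = np.nan if censored else L
        F["CMAC Age Fraction"][seg] = np.nan if censored else age / L
        for ch, chname in CHANNEL_NAMES.items():
            for kind in ("Total", "Mean"):
                col = f"CMAC {kind} {chname} Intensity"
                vals = F[col][seg]
                delta = np.full(L, np.nan)
                if L > 1:
                    delta[1:] = np.diff(vals)
                F[f"Change in {col}"][seg] = delta

    # geometry relative to parent cell, grouped by (cell, frame)
    d_edge = np.full(n, np.nan)
    d_cent = np.full(n, np.nan)
    frame_groups = df.groupby(TRACK_KEYS + [FRAME], sort=False).indices
    for key, idx in frame_groups.items():
        try:
            row = cell_geo.loc[key]
        except KeyError:
            continue
        wkt_str = row["polygon_wkt"]
        poly = poly_cache.get(wkt_str)
        if poly is None:
            poly = shapely_wkt.loads(wkt_str)
            poly_cache[wkt_str] = poly
        ii = np.asarray(idx)
        pts = shapely.points(xy[ii, 0], xy[ii, 1])
        d_edge[ii] = shapely.distance(pts, poly.exterior)
        d_cent[ii] = shapely.distance(pts, poly.centroid)
    F["CMAC Distance to Cell Edge"] = d_edge
    F["CMAC Distance to Cell Centroid"] = d_cent
    with np.errstate(invalid="ignore", divide="ignore"):
        s = d_edge / (d_edge + d_cent)
    s[(d_edge + d_cent) == 0] = 1.0
    F["Standardized CMAC Distance to Cell Edge"] = s

    # displacement relative to the cell centroid motion
    cell_xy = np.full((n, 2), np.nan)
    for key, idx in frame_groups.items():
        try:
            row = cell_geo.loc[key]
        except KeyError:
            continue
        cell_xy[np.asarray(idx)] = (row["centroid_x_um"], row["centroid_y_um"])
    rel = np.full(n, np.nan)
    for s_, e_ in zip(starts[:-1], starts[1:]):
        if e_ - s_ > 1:
            seg = slice(s_, e_)
            d_obj = np.diff(xy[seg], axis=0)
            d_cell = np.diff(cell_xy[seg], axis=0)
            rel[s_ + 1:e_] = np.linalg.norm(d_obj - d_cell, axis=1)
    F["CMAC Displacement Relative to Cell"] = rel

    out = df[CMAC_KEYS + [FRAME, "censored_start", "censored_end"]].copy()
    for name in catalog.CMAC_FEATURE_NAMES:
        out[name] = F[name]
    return out


# ---------------------------------------------------------------------------
# Single-cell features
# ---------------------------------------------------------------------------

def smooth_trajectory(frames: np.ndarray, xy: np.ndarray, lam=None) -> np.ndarray:
    """Smoothing-spline fit of a centroid trajectory.

    ``lam=None`` selects the penalty by generalized cross-validation; tracks
    too short to smooth (< 5 frames) are returned unchanged.
    """
    if len(frames) < 5:
        return xy
    t = frames.astype(float)
    out = np.empty_like(xy)
    for k in range(2):
        try:
            spl = make_smoothing_spline(t, xy[:, k], lam=lam)
            out[:, k] = spl(t)
        except Exception:
            out[:, k] = xy[:, k]
    return out


def instantaneous_speed(frames: np.ndarray, xy: np.ndarray,
                        frame_interval_min: float, smoothing="gcv") -> np.ndarray:
    """Per-frame centroid speed (µm/min); the first frame is undefined."""
    if smoothing == "gcv":
        sm = smooth_trajectory(frames, xy, lam=None)
    elif smoothing in (None, "off", False):
        sm = xy
    else:
        sm = smooth_trajectory(frames, xy, lam=float(smoothing))
    speed = np.full(len(frames), np.nan)
    if len(frames) > 1:
        speed[1:] = np.linalg.norm(np.diff(sm, axis=0), axis=1) / frame_interval_min
    return speed


def compute_cell_features(
    dataset: TrackedDataset,
    cmac_features: pd.DataFrame,
    smoothing="gcv",
) -> pd.DataFrame:
    """Evaluate the 88-entry single-cell catalog as a tidy feature panel.

    Frames with zero CMACs keep their cell-scale features; CMAC aggregates are
    emitted as missing.  Lifetime aggregates use only uncensored CMAC tracks
    (their per-record lifetime values are already missing).
    """
    cells = dataset.cells.sort_values(TRACK_KEYS + [FRAME], kind="mergesort").reset_index(drop=True)
    agg_defs = [f for f in catalog.CELL_FEATURES if f.aggregator is not None]
    keys = TRACK_KEYS + [FRAME]

    panel = cells[keys].copy()
    polys = shapely.from_wkt(cells["polygon_wkt"].to_numpy())
    area = shapely.area(polys)
    perim = shapely.length(polys)  # exterior length for hole-free polygons
    panel["Cell Area"] = area
    panel["Cell Perimeter"] = perim
    panel["Cell Compactness"] = perim ** 2 / (4 * np.pi * area)

    speed = np.full(len(cells), np.nan)
    for _, grp in cells.groupby(TRACK_KEYS, sort=False):
        frames = grp[FRAME].to_numpy()
        xy = grp[["centroid_x_um", "centroid_y_um"]].to_numpy(float)
        speed[grp.index] = instantaneous_speed(
            frames, xy, dataset.frame_interval_min, smoothing)
    panel["Instantaneous Cell Speed"] = speed

    bases = sorted({f.base for f in agg_defs})
    if len(cmac_features):
        group = cmac_features.groupby(keys)
        counts = group.size().rename("Number of CMACs per Cell")
        tables = {
            "Mean": group[bases].mean(),
            "Median": group[bases].median(),
            "Sum": group[bases].sum(min_count=1),
            "SD": group[bases].std(ddof=1),
            "IDR": group[bases].quantile(0.9) - group[bases].quantile(0.1),
        }
        panel = panel.merge(counts.reset_index(), on=keys, how="left")
        panel["Number of CMACs per Cell"] = (
            panel["Number of CMACs per Cell"].fillna(0).astype(int))
        wide = {}
        for fd in agg_defs:
            wide[fd.name] = tables[fd.aggregator][fd.base]
        agg_df = pd.DataFrame(wide).reset_index()
        panel = panel.merge(agg_df, on=keys, how="left")
    else:
        panel["Number of CMACs per Cell"] = 0
        for fd in agg_defs:
            panel[fd.name] = np.nan

    ordered = keys + list(catalog.CELL_FEATURE_NAMES)
    return panel[ordered]


def extract_features(
    dataset: TrackedDataset,
    reference_condition: str | None = None,
    smoothing="gcv",
):
    """Full extraction: records → parsing → standardization → catalogs.

    Returns ``(cell_panel, cmac_features, parsing_report, divisors)``.
    """
    from .tracking import parse_cmac_tracks

    records = build_cmac_records(dataset.cmacs)
    bounds = {
        key: (int(grp[FRAME].min()), int(grp[FRAME].max()))
        for key, grp in dataset.cells.groupby(["condition", "repeat"])
    }
    parsed, report = parse_cmac_tracks(records, sequence_bounds=bounds)
    if reference_condition is None:
        reference_condition = sorted(dataset.cells["condition"].unique())[0]
    parsed, divisors = standardize_intensities(parsed, reference_condition)
    cmac_feats = compute_cmac_features(parsed, dataset.cells, dataset.frame_interval_min)
    cell_panel = compute_cell_features(dataset, cmac_feats, smoothing=smoothing)
    return cell_panel, cmac_feats, report, divisors
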