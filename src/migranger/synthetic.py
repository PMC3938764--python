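"""Synthetic data with known causal ground truth.

Two generators make every downstream stage testable without external data:

* :func:`simulate_var_panel` draws stationary vector-autoregressive (VAR)
  feature panels — one independent realization per simulated cell — directly
  in feature space.  This is the workhorse for calibrating and power-testing
  the Granger stage.

* :func:`simulate_microscopy_panel` emulates the object tables produced by
  live-cell imaging at 5-min sampling: per-frame cell polygons and centroids,
  plus CMAC populations with birth/death, areas, axes and per-channel pixel
  intensities.  Configurable lagged couplings between named catalog features
  (including sign inversions) are injected via latent driver processes, and
  the injected graph is returned as :class:`GroundTruth`.

Cell outlines are noisy star-convex polygons (radial Fourier perturbation of
a circle) so that area, perimeter and compactness vary smoothly; CMACs are
quasi-stationary substrate-anchored points with small positional jitter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import json
import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .io import TrackedDataset, encode_pixels, TRACK_KEYS, FRAME

__all__ = [
    "VarSpec",
    "MicroscopySimSpec",
    "GroundTruth",
    "DRIVABLE_FEATURES",
    "simulate_var_panel",
    "simulate_microscopy_panel",
    "inject_missingness",
    "write_groundtruth",
    "read_groundtruth",
]


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CausalEdge:
    source: str
    target: str
    sign: str  # "+" or "-"
    lag: int   # frames

    def __post_init__(self):
        if self.sign not in ("+", "-"):
            raise ValueError(f"sign must be '+' or '-', got {self.sign!r}")


@dataclass
class GroundTruth:
    """The generator's true coupling graph."""

    edges: frozenset[CausalEdge]
    params: dict = field(default_factory=dict)

    def directed_pairs(self) -> set[tuple[str, str]]:
        return {(e.source, e.target) for e in self.edges}


def write_groundtruth(gt: GroundTruth, path) -> None:
    payload = {
        "edges": [
            {"source": e.source, "target": e.target, "sign": e.sign, "lag": e.lag}
            for e in sorted(gt.edges, key=lambda e: (e.source, e.target, e.lag))
        ],
        "params": gt.params,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, default=str)


def read_groundtruth(path) -> GroundTruth:
    with open(path) as fh:
        payload = json.load(fh)
    return GroundTruth(
        frozenset(CausalEdge(**e) for e in payload["edges"]), payload.get("params", {})
    )


# ---------------------------------------------------------------------------
# VAR panels
# ---------------------------------------------------------------------------

@dataclass
class VarSpec:
    """A VAR(p) process specification.

    ``coupling[l, i, j]`` is the coefficient with which feature ``j`` at lag
    ``l + 1`` drives feature ``i``.  Stationarity requires the companion
    matrix to have spectral radius < 1.
    """

    n_features: int
    lag_order: int
    coupling: np.ndarray
    noise_sd: np.ndarray | float = 1.0
    feature_means: np.ndarray | float = 0.0
    feature_names: Sequence[str] | None = None

    def __post_init__(self):
        self.coupling = np.asarray(self.coupling, dtype=float)
        if self.lag_order < 1:
            raise ValueError("lag_order must be >= 1")
        expect = (self.lag_order, self.n_features, self.n_features)
        if self.coupling.shape != expect:
            raise ValueError(f"coupling must have shape {expect}, got {self.coupling.shape}")
        self.noise_sd = np.broadcast_to(
            np.asarray(self.noise_sd, dtype=float), (self.n_features,)
        ).copy()
        if np.any(self.noise_sd <= 0):
            raise ValueError("noise_sd must be positive")
        self.feature_means = np.broadcast_to(
            np.asarray(self.feature_means, dtype=float), (self.n_features,)
        ).copy()
        if self.feature_names is None:
            self.feature_names = [f"F{i + 1}" for i in range(self.n_features)]
        self.feature_names = list(self.feature_names)
        if len(self.feature_names) != self.n_features:
            raise ValueError("feature_names length mismatch")

    def companion_matrix(self) -> np.ndarray:
        d, p = self.n_features, self.lag_order
        comp = np.zeros((d * p, d * p))
        comp[:d, :] = np.concatenate(list(self.coupling), axis=1)
        if p > 1:
            comp[d:, :-d] = np.eye(d * (p - 1))
        return comp

    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.companion_matrix()))))

    def ground_truth(self, include_self: bool = False) -> GroundTruth:
        edges = set()
        for l in range(self.lag_order):
            for i in range(self.n_features):
                for j in range(self.n_features):
                    c = self.coupling[l, i, j]
                    if c != 0 and (include_self or i != j):
                        edges.add(
                            CausalEdge(
                                self.feature_names[j],
                                self.feature_names[i],
                                "+" if c > 0 else "-",
                                l + 1,
                            )
                        )
        return GroundTruth(
            frozenset(edges),
            params={"kind": "var", "lag_order": self.lag_order,
                    "spectral_radius": self.spectral_radius()},
        )


def _resolve_lengths(track_length_dist, n_cells: int, rng: np.random.Generator,
                     minimum: int) -> np.ndarray:
    if callable(track_length_dist):
        lengths = np.array([int(track_length_dist(rng)) for _ in range(n_cells)])
    elif np.isscalar(track_length_dist):
        lengths = np.full(n_cells, int(track_length_dist))
    else:
        lengths = np.asarray(track_length_dist, dtype=int)
        if len(lengths) != n_cells:
            raise ValueError("track length list must have n_cells entries")
    if np.any(lengths < minimum):
        raise ValueError(f"track lengths must be >= {minimum}")
    return lengths


def simulate_var_panel(
    spec: VarSpec,
    n_cells: int,
    track_length_dist=60,
    seed: int = 0,
    burn_in: int = 50,
    condition: str = "control",
    repeat: int = 1,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate one independent VAR realization per cell.

    Returns a tidy feature panel keyed by (condition, repeat, cell_id, frame)
    and the ground-truth coupling graph.  Non-stationary specifications are
    rejected with the spectral radius reported.
    """
    rho = spec.spectral_radius()
    if rho >= 1:
        raise ValueError(f"non-stationary VAR spec: companion spectral radius {rho:.4f} >= 1")
    rng = np.random.default_rng(seed)
    lengths = _resolve_lengths(track_length_dist, n_cells, rng, spec.lag_order + 1)

    d, p = spec.n_features, spec.lag_order
    blocks = []
    for cell in range(n_cells):
        T = int(lengths[cell])
        total = T + burn_in
        x = np.zeros((total + p, d))
        eps = rng.normal(size=(total + p, d)) * spec.noise_sd
        for t in range(p, total + p):
            acc = eps[t].copy()
            for l in range(p):
                acc += spec.coupling[l] @ x[t - 1 - l]
            x[t] = acc
        x = x[p + burn_in:] + spec.feature_means
        block = pd.DataFrame(x, columns=spec.feature_names)
        block.insert(0, FRAME, np.arange(T))
        block.insert(0, "cell_id", cell + 1)
        block.insert(0, "repeat", repeat)
        block.insert(0, "condition", condition)
        blocks.append(block)
    panel = pd.concat(blocks, ignore_index=True)
    gt = spec.ground_truth()
    gt.params.update({"n_cells": n_cells, "seed": seed})
    return panel, gt


# ---------------------------------------------------------------------------
# Microscopy-like object tables
# ---------------------------------------------------------------------------

# Catalog features the simulator can drive directly.  Each is rendered as a
# monotone increasing function of its latent driver, so injected couplings
# between latents carry through (with their sign) to extracted features.
DRIVABLE_FEATURES = (
    "Cell Area",
    "Cell Compactness",
    "Instantaneous Cell Speed",
    "Median [CMAC Area] per Cell",
    "Sum [CMAC Total EGFP-Paxillin Intensity] per Cell",
    "Sum [CMAC Total RubyRed-LifeAct Intensity] per Cell",
    "Mean [CMAC Lifetime] per Cell",
)


@dataclass
class MicroscopySimSpec:
    """Configuration of the simulated imaging experiment."""

    n_cells: int = 50
    n_frames: int = 60
    frame_interval: float = 5.0  # minutes
    pixel_size: float = 0.21     # µm
    cmac_birth_rate: float = 2.0  # expected new CMACs per frame per cell
    cmac_lifetime_dist: dict = field(
        default_factory=lambda: {"kind": "geometric", "mean": 8.0, "min": 1}
    )
    coupling_edges: list = field(default_factory=list)  # (source, target, lag, coef)
    cell_shape_model: dict = field(
        default_factory=lambda: {
            "base_area_um2": 800.0,
            "base_roughness": 0.12,
            "n_vertices": 36,
            "n_modes": 4,
        }
    )
    seed: int = 0
    # latent driver dynamics
    latent_ar: float = 0.6
    base_step_um: float = 0.8
    base_cmac_area_um2: float = 1.0
    base_cell_total_intensity: dict = field(
        default_factory=lambda: {"ch1": 60.0, "ch2": 40.0}
    )
    conditions: list = field(default_factory=lambda: ["control"])
    n_repeats: int = 1
    entry_exit_rate: float = 0.0

    def __post_init__(self):
        if self.n_frames < 3:
            raise ValueError("n_frames must be >= 3")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        for edge in self.coupling_edges:
            src, tgt = edge[0], edge[1]
            for name in (src, tgt):
                if name not in DRIVABLE_FEATURES:
                    raise ValueError(
                        f"coupling edge references unknown/undrivable feature {name!r}; "
                        f"drivable features: {DRIVABLE_FEATURES}"
                    )

    def ground_truth(self) -> GroundTruth:
        edges = frozenset(
            CausalEdge(src, tgt, "+" if coef > 0 else "-", int(lag))
            for src, tgt, lag, coef in self.coupling_edges
            if coef != 0
        )
        return GroundTruth(
            edges,
            params={
                "kind": "microscopy",
                "n_cells": self.n_cells,
                "n_frames": self.n_frames,
                "seed": self.seed,
            },
        )


def _draw_lifetime(dist: dict, mean_override: float | None, rng) -> int:
    kind = dist.get("kind", "geometric")
    mean = float(mean_override if mean_override is not None else dist.get("mean", 8.0))
    mean = max(mean, 1.05)
    lo = int(dist.get("min", 1))
    if kind == "geometric":
        return max(lo, int(rng.geometric(1.0 / mean)))
    if kind == "fixed":
        return max(lo, int(round(mean)))
    raise ValueError(f"unknown lifetime distribution kind {kind!r}")


def _star_polygon(center: np.ndarray, target_area: float, roughness: float,
                  n_vertices: int, n_modes: int, rng) -> Polygon:
    """Star-convex polygon with radial Fourier perturbation, scaled to hit
    ``target_area`` exactly (up to float rounding)."""
    theta = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    r = np.ones(n_vertices)
    for k in range(2, 2 + n_modes):
        amp = roughness * rng.uniform(0.3, 1.0) / k
        phase = rng.uniform(0, 2 * np.pi)
        r += amp * np.cos(k * theta + phase)
    r = np.clip(r, 0.2, None)
    xy = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    poly = Polygon(xy)
    scale = np.sqrt(target_area / poly.area)
    xy *= scale
    return Polygon(xy + center)


class _Latents:
    """Coupled AR latent drivers, one per drivable feature."""

    def __init__(self, edges, ar: float, rng):
        self.names = list(DRIVABLE_FEATURES)
        self.idx = {n: i for i, n in enumerate(self.names)}
        self.ar = ar
        self.rng = rng
        self.edges = [(self.idx[s], self.idx[t], int(lag), float(c)) for s, t, lag, c in edges]
        self.max_lag = max([lag for _, _, lag, _ in self.edges], default=1)
        # innovation scale for roughly unit marginal variance of the AR part
        self.innov_sd = np.sqrt(1.0 - ar ** 2)
        self.history: list[np.ndarray] = []

    def step(self) -> np.ndarray:
        z = self.rng.normal(scale=self.innov_sd, size=len(self.names))
        if self.history:
            z = z + self.ar * self.history[-1]
            for s, t, lag, c in self.edges:
                if len(self.history) >= lag:
                    z[t] += c * self.history[-lag][s]
        self.history.append(z)
        return z


def simulate_microscopy_panel(spec: MicroscopySimSpec) -> tuple[TrackedDataset, GroundTruth]:
    """Simulate tracked-cell/CMAC object tables with injected causal couplings.

    Every generated CMAC has area > 0.05 µm² (the segmentation floor) and at
    least 8 paired pixel intensities per channel.
    """
    rng_master = np.random.default_rng(spec.seed)
    shape = spec.cell_shape_model
    cell_rows = []
    cmac_rows = []

    for cond_i, condition in enumerate(spec.conditions):
        for rep in range(1, spec.n_repeats + 1):
            for cell in range(1, spec.n_cells + 1):
                rng = np.random.default_rng(rng_master.integers(0, 2 ** 31 - 1))
                _simulate_one_cell(
                    spec, condition, rep, cell, rng, shape, cell_rows, cmac_rows
                )

    cells = pd.DataFrame(
        cell_rows,
        columns=["condition", "repeat", "cell_id", FRAME,
                 "centroid_x_um", "centroid_y_um", "polygon_wkt"],
    )
    cmacs = pd.DataFrame(
        cmac_rows,
        columns=["condition", "repeat", "cell_id", "cmac_id", FRAME,
                 "centroid_x_um", "centroid_y_um", "area_um2",
                 "major_axis_um", "minor_axis_um",
                 "ch1_pixels", "ch2_pixels", "ch1_bg", "ch2_bg"],
    )
    dataset = TrackedDataset(
        cells, cmacs,
        frame_interval_min=spec.frame_interval,
        pixel_size_um=spec.pixel_size,
        meta={"generator": "simulate_microscopy_panel", "seed": spec.seed},
    )
    if spec.entry_exit_rate > 0:
        dataset = inject_missingness(
            dataset, spec.entry_exit_rate, seed=int(rng_master.integers(0, 2 ** 31 - 1))
        )
    return dataset, spec.ground_truth()


def _simulate_one_cell(spec, condition, rep, cell, rng, shape, cell_rows, cmac_rows):
    latents = _Latents(spec.coupling_edges, spec.latent_ar, rng)
    center = rng.uniform(-50, 50, size=2)
    heading = rng.uniform(0, 2 * np.pi)
    next_cmac_id = 1
    live: dict[int, dict] = {}

    # warm up latents so couplings act from the first emitted frame
    for _ in range(max(10, 3 * latents.max_lag)):
        latents.step()

    base_total = spec.base_cell_total_intensity
    base_bg = {"ch1": 3.0, "ch2": 3.0}
    px_area = spec.pixel_size ** 2

    for frame in range(spec.n_frames):
        z = latents.step()
        g = lambda name: z[latents.idx[name]]

        # --- cell geometry and motion -------------------------------------
        step = max(0.0, spec.base_step_um * (1.0 + 0.4 * g("Instantaneous Cell Speed")))
        heading += rng.normal(scale=0.5)
        center = center + step * np.array([np.cos(heading), np.sin(heading)])
        target_area = max(150.0, shape["base_area_um2"] * (1.0 + 0.25 * g("Cell Area")))
        roughness = float(np.clip(
            shape["base_roughness"] * (1.0 + 0.45 * g("Cell Compactness")), 0.01, 0.45
        ))
        poly = _star_polygon(center, target_area, roughness,
                             shape["n_vertices"], shape["n_modes"], rng)

        cell_rows.append((condition, rep, cell, frame,
                          center[0], center[1], poly.wkt))

        # --- CMAC demography ----------------------------------------------
        lt_mean = max(2.0, spec.cmac_lifetime_dist.get("mean", 8.0)
                      * (1.0 + 0.3 * g("Mean [CMAC Lifetime] per Cell")))
        n_birth = rng.poisson(spec.cmac_birth_rate) if frame > 0 else rng.poisson(
            spec.cmac_birth_rate * spec.cmac_lifetime_dist.get("mean", 8.0))
        for _ in range(n_birth):
            u = rng.uniform(0.35, 0.9)
            ang = rng.uniform(0, 2 * np.pi)
            radius = np.sqrt(target_area / np.pi)
            pos = center + u * radius * np.array([np.cos(ang), np.sin(ang)])
            live[next_cmac_id] = {
                "pos": pos,
                "death": frame + _draw_lifetime(spec.cmac_lifetime_dist, lt_mean, rng),
                "size_factor": float(rng.lognormal(0.0, 0.25)),
                "aspect": float(rng.uniform(1.2, 3.0)),
                "coloc": float(np.clip(rng.normal(0.5, 0.2), -0.9, 0.95)),
                "weight": float(rng.lognormal(0.0, 0.3)),
            }
            next_cmac_id += 1
        dead = [cid for cid, st in live.items() if frame >= st["death"]]
        for cid in dead:
            del live[cid]
        if not live:  # keep at least one adhesion per frame
            live[next_cmac_id] = {
                "pos": center + np.array([1.0, 0.0]),
                "death": frame + _draw_lifetime(spec.cmac_lifetime_dist, lt_mean, rng),
                "size_factor": 1.0, "aspect": 2.0, "coloc": 0.5, "weight": 1.0,
            }
            next_cmac_id += 1

        # --- CMAC rendering -------------------------------------------------
        area_scale = max(0.08, spec.base_cmac_area_um2
                         * (1.0 + 0.3 * g("Median [CMAC Area] per Cell")))
        totals = {
            "ch1": max(1.0, base_total["ch1"]
                       * (1.0 + 0.3 * g("Sum [CMAC Total EGFP-Paxillin Intensity] per Cell"))),
            "ch2": max(1.0, base_total["ch2"]
                       * (1.0 + 0.3 * g("Sum [CMAC Total RubyRed-LifeAct Intensity] per Cell"))),
        }
        wsum = sum(st["weight"] for st in live.values())
        for cid, st in sorted(live.items()):
            st["pos"] = st["pos"] + rng.normal(scale=0.04, size=2)
            area = max(0.06, area_scale * st["size_factor"])
            b = np.sqrt(area / (np.pi * st["aspect"]))  # semi-minor
            minor, major = 2 * b, 2 * b * st["aspect"]
            n_px = max(8, int(round(area / px_area)))
            shared = rng.normal(size=n_px)
            pixels = {}
            for ch in ("ch1", "ch2"):
                corrected_mean = totals[ch] * (st["weight"] / wsum) / area
                raw_mean = corrected_mean + base_bg[ch]
                rho = st["coloc"]
                noise = rho * shared + np.sqrt(1 - rho ** 2) * rng.normal(size=n_px)
                pixels[ch] = raw_mean * (1.0 + 0.08 * noise)
            cmac_rows.append((
                condition, rep, cell, cid, frame,
                st["pos"][0], st["pos"][1], area, major, minor,
                encode_pixels(pixels["ch1"]), encode_pixels(pixels["ch2"]),
                base_bg["ch1"], base_bg["ch2"],
            ))


def inject_missingness(dataset: TrackedDataset, entry_exit_rate: float,
                       seed: int = 0) -> TrackedDataset:
    """Truncate cell tracks at random entry/exit frames.

    Emulates cells entering and leaving the imaging field: affected tracks
    lose a random prefix and/or suffix but remain contiguous, never dropping
    below 2 frames.  ``entry_exit_rate`` is the per-track probability of
    truncation at each end.
    """
    if not 0 <= entry_exit_rate < 1:
        raise ValueError("entry_exit_rate must be in [0, 1)")
    if entry_exit_rate == 0:
        return dataset
    rng = np.random.default_rng(seed)
    out = dataset.copy()
    keep_cells = []
    keep_cmacs = []
    for key, grp in out.cells.groupby(TRACK_KEYS, sort=False):
        frames = grp[FRAME].to_numpy()
        lo, hi = int(frames.min()), int(frames.max())
        start, end = lo, hi
        if rng.random() < entry_exit_rate:
            start = lo + int(rng.integers(0, max(1, (hi - lo) // 2)))
        if rng.random() < entry_exit_rate:
            end = hi - int(rng.integers(0, max(1, (hi - lo) // 2)))
        if end - start < 1:  # enforce >= 2 frames
            start, end = lo, min(hi, lo + 1)
        keep_cells.append(grp[(grp[FRAME] >= start) & (grp[FRAME] <= end)])
        mask = (
            (out.cmacs["condition"] == key[0])
            & (out.cmacs["repeat"] == key[1])
            & (out.cmacs["cell_id"] == key[2])
        )
        sub = out.cmacs[mask]
        keep_cmacs.append(sub[(sub[FRAME] >= start) & (sub[FRAME] <= end)])
    out.cells = pd.concat(keep_cells, ignore_index=True)
    out.cmacs = pd.concat(keep_cmacs, ignore_index=True)
    return out
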