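"""Synthetic benchmark studies exercising the pipeline end to end.

Each function simulates data with known ground truth, runs the relevant
stages, and returns summary numbers.  They are shared between the test suite
and ``scripts/acceptance.py`` so that every reported figure is recomputed
from scratch at run time.
"""

from __future__ import annotations

import hashlib

import numpy as np
import pandas as pd

from . import catalog
from .features import extract_features
from .granger import (LagModelPair, build_graph,
                      build_lagged_design, fit_pooled_ar, granger_sargent_test,
                      infer_edge, reciprocal_analysis, significance_grid,
                      assemble_chain, compare_conditions)
from .population import select_n_subpopulations
from .selection import cva_rank_features, elastic_net_rank, top_overlap
from .synthetic import MicroscopySimSpec, VarSpec, simulate_microscopy_panel, simulate_var_panel
from .transforms import boxcox_normalize, normalize_panel


def derive_seed(master: int, label: str) -> int:
    """Stable sub-seed below 2^31 from a master seed and a label."""
    blob = f"{label}:{master}".encode()
    return int.from_bytes(hashlib.sha256(blob).digest()[:4], "big") % (2 ** 31)


def _pair_spec(coef_xy=0.0, coef_yx=0.0, rho=0.5):
    coupling = np.zeros((1, 2, 2))
    np.fill_diagonal(coupling[0], rho)
    coupling[0, 1, 0] = coef_xy  # X drives Y
    coupling[0, 0, 1] = coef_yx
    return VarSpec(2, 1, coupling, feature_names=["X", "Y"])


# ---------------------------------------------------------------------------
# Granger-Sargent statistics
# ---------------------------------------------------------------------------

def granger_sargent_oracle_agreement(seed: int, n_designs: int = 50) -> dict:
    """Max |p difference| between the Granger-Sargent implementation and an
    independent brute-force nested-OLS F test on random small designs."""
    import statsmodels.api as sm

    rng = np.random.default_rng(seed)
    max_diff = 0.0
    for _ in range(n_designs):
        py, px = int(rng.integers(1, 5)), int(rng.integers(1, 5))
        spec = _pair_spec(coef_xy=float(rng.normal()) * 0.3)
        panel, _ = simulate_var_panel(
            spec, int(rng.integers(3, 8)), int(rng.integers(12, 30)),
            seed=int(rng.integers(2 ** 31)))
        Zu, yu, _ = build_lagged_design(panel, "Y", "X", py, px)
        fit_u = fit_pooled_ar(Zu, yu)
        fit_r = fit_pooled_ar(Zu[:, :1 + py], yu)
        pair = LagModelPair("Y", "X", py, px, fit_u.n, fit_r.rss, fit_u.rss,
                            np.nan, np.nan)
        _, p = granger_sargent_test(pair)
        p_ref = sm.OLS(yu, Zu).fit().compare_f_test(
            sm.OLS(yu, Zu[:, :1 + py]).fit())[1]
        max_diff = max(max_diff, abs(p - float(p_ref)))
    return {"max_abs_p_diff": max_diff, "n": n_designs}


def null_calibration(seed: int, n_panels: int = 500, n_cells: int = 100,
                     n_frames: int = 30) -> dict:
    """Type-I error of the (1,1)-lag test and of the default edge criterion
    on independent AR(1) feature panels."""
    rng = np.random.default_rng(seed)
    spec = _pair_spec()
    rejections = 0
    edges = 0
    for _ in range(n_panels):
        panel, _ = simulate_var_panel(spec, n_cells, n_frames,
                                      seed=int(rng.integers(2 ** 31)))
        Zu, yu, _ = build_lagged_design(panel, "Y", "X", 1, 1)
        fit_u = fit_pooled_ar(Zu, yu)
        fit_r = fit_pooled_ar(Zu[:, :2], yu)
        pair = LagModelPair("Y", "X", 1, 1, fit_u.n, fit_r.rss, fit_u.rss,
                            np.nan, np.nan)
        _, p = granger_sargent_test(pair)
        rejections += p < 0.05
        grid = significance_grid(panel, "Y", "X", L_max=10)
        edges += infer_edge(grid).declared
    return {
        "rejection_rate_pct": 100.0 * rejections / n_panels,
        "edge_rate_pct": 100.0 * edges / n_panels,
        "n": n_panels,
    }


def directed_recovery(seed: int, n_seeds: int = 20, coef: float = -0.5,
                      n_cells: int = 100, n_frames: int = 50) -> dict:
    """Recovery of a unidirectional signed coupling X -> Y."""
    rng = np.random.default_rng(seed)
    spec = _pair_spec(coef_xy=coef)
    correct = reverse_only = 0
    for _ in range(n_seeds):
        panel, _ = simulate_var_panel(spec, n_cells, n_frames,
                                      seed=int(rng.integers(2 ** 31)))
        gxy, _, cls = reciprocal_analysis(panel, "X", "Y", L_max=10)
        sign = "-" if coef < 0 else "+"
        if cls == "X->Y" and gxy.sign == sign:
            correct += 1
        elif cls == "Y->X":
            reverse_only += 1
    return {
        "recovery_rate_pct": 100.0 * correct / n_seeds,
        "reverse_only_count": reverse_only,
        "n": n_seeds,
    }


def plasticity_detection(seed: int, n_cells: int = 100, n_frames: int = 50) -> dict:
    """Two conditions with the speed -> shape coupling sign flipped yield
    exactly one sign-inverted edge in the plasticity report."""
    feats = ["speed", "shape", "adhesion", "actin"]
    graphs = {}
    for cond, coef in (("control", 0.5), ("rho", -0.5)):
        coupling = np.zeros((1, 4, 4))
        np.fill_diagonal(coupling[0], 0.5)
        coupling[0, 1, 0] = coef  # speed drives shape
        spec = VarSpec(4, 1, coupling, feature_names=feats)
        panel, _ = simulate_var_panel(
            spec, n_cells, n_frames, seed=derive_seed(seed, f"plast-{cond}"),
            condition=cond)
        pairs = [(a, b) for a in feats for b in feats if a != b]
        graphs[cond] = build_graph(panel, pairs, condition=cond, L_max=10)
    report = compare_conditions(graphs, reference="control")
    counts = report["status"].value_counts().to_dict()
    inverted = report[report["status"] == "sign-inverted"]
    right_edge = (len(inverted) == 1
                  and inverted.iloc[0]["source"] == "speed"
                  and inverted.iloc[0]["target"] == "shape")
    return {
        "sign_inverted_edges": int(counts.get("sign-inverted", 0)),
        "inverted_edge_is_speed_to_shape": bool(right_edge),
        "n": int(len(report)),
    }


CHAIN = [
    "Median [CMAC Area] per Cell",
    "Sum [CMAC Total RubyRed-LifeAct Intensity] per Cell",
    "Instantaneous Cell Speed",
    "Cell Area",
]
CHAIN_SIGNS = ["-", "-", "+"]


def chain_recovery(seed: int, n_cells: int = 80, n_frames: int = 60) -> dict:
    """End-to-end recovery of an injected causal chain through the
    microscopy simulator: object tables -> features -> normalization ->
    Granger -> chain assembly."""
    edges = [
        (CHAIN[0], CHAIN[1], 1, -0.5),
        (CHAIN[1], CHAIN[2], 1, -0.5),
        (CHAIN[2], CHAIN[3], 1, 0.5),
    ]
    spec = MicroscopySimSpec(
        n_cells=n_cells, n_frames=n_frames, seed=derive_seed(seed, "chain"),
        coupling_edges=edges,
    )
    dataset, gt = simulate_microscopy_panel(spec)
    panel, _, _, _ = extract_features(dataset)
    keep = tuple(CHAIN)  # chain features must survive normalization
    norm, discarded, _ = normalize_panel(panel, keep=keep)
    pairs = list(zip(CHAIN[:-1], CHAIN[1:]))
    graph = build_graph(norm, pairs, condition="control", L_max=10)
    links, intact, first_break = assemble_chain(graph, CHAIN)
    signs_ok = [l.declared and l.sign == s for l, s in zip(links, CHAIN_SIGNS)]
    return {
        "links_recovered": int(sum(l.declared for l in links)),
        "links_with_correct_sign": int(sum(signs_ok)),
        "intact": bool(intact),
        "n": len(links),
    }


def mixture_k_recovery(seed: int, n_replicates: int = 20, dim: int = 3,
                       separation: float = 8.0, n_per_component: int = 500) -> dict:
    """AIC model selection on well-separated 4-component Gaussian draws."""
    centers = np.zeros((4, dim))
    for i in range(1, 4):
        centers[i, (i - 1) % dim] = separation
    chosen = []
    for rep in range(n_replicates):
        rng = np.random.default_rng(derive_seed(seed, f"mix-{rep}"))
        X = np.concatenate(
            [rng.normal(c, 1.0, size=(n_per_component, dim)) for c in centers])
        k, _, _ = select_n_subpopulations(
            X, restarts=10, final_restarts=1, seed=derive_seed(seed, f"em-{rep}"))
        chosen.append(k)
    return {"k4_recovery_count": int(sum(k == 4 for k in chosen)),
            "chosen": chosen, "n": n_replicates}


def selection_recovery(seed: int, n_obs: int = 3000) -> dict:
    """CVA and elastic-net rankings on a panel where 3 designated
    organizational features drive speed."""
    rng = np.random.default_rng(seed)
    org = list(catalog.ORGANIZATIONAL_FEATURES)
    X = rng.normal(size=(n_obs, len(org)))
    driver_idx = [5, 20, 40]
    betas = [1.0, -0.8, 0.6]
    drivers = [org[i] for i in driver_idx]
    speed = sum(b * X[:, i] for i, b in zip(driver_idx, betas))
    speed = speed + rng.normal(0, 0.7, n_obs)
    panel = pd.DataFrame(X, columns=org)
    panel.insert(0, "condition", "control")
    panel.insert(1, "repeat", 1)
    panel.insert(2, "cell_id", np.arange(n_obs) // 30)
    panel.insert(3, "frame", np.arange(n_obs) % 30)
    panel[catalog.BEHAVIORAL_FEATURE] = speed
    cv = cva_rank_features(panel)
    en = elastic_net_rank(panel)
    top_cva = set(cv.ranking.head(15)["feature"])
    top_en = set(en.ranking.head(15)["feature"])
    overlap = top_overlap(cv.ranking, en.ranking, k=15)
    return {
        "drivers_in_cva_top15": int(sum(d in top_cva for d in drivers)),
        "drivers_in_en_top15": int(sum(d in top_en for d in drivers)),
        "drivers_in_overlap": int(sum(d in overlap for d in drivers)),
        "overlap_size": int(len(overlap)),
        "n": n_obs,
    }


def boxcox_recovery(seed: int, n: int = 2000) -> dict:
    """Recovery error of the Box-Cox exponent for lambda* in {0, 0.5, 1}."""
    from scipy.special import inv_boxcox

    designs = {0.0: (1.0, 0.7), 0.5: (2.0, 1.0), 1.0: (4.0, 2.0)}
    errors = {}
    for lam, (mu, sd) in designs.items():
        rng = np.random.default_rng(derive_seed(seed, f"bc-{lam}"))
        z = rng.normal(mu, sd, int(n * 1.2))
        if lam > 0:
            z = z[lam * z + 1 > 0.01]
        x = inv_boxcox(z[:n], lam)
        res = boxcox_normalize(x)
        errors[lam] = abs(res.lam - lam)
    return {"max_abs_lambda_error": max(errors.values()),
            "per_lambda": errors, "n": n}


def schema_counts(seed: int) -> dict:
    """Feature extraction on a small simulated dataset emits exactly the
    88-single-cell / 29-CMAC catalogs."""
    spec = MicroscopySimSpec(n_cells=3, n_frames=12, seed=derive_seed(seed, "schema"))
    dataset, _ = simulate_microscopy_panel(spec)
    panel, cmac_feats, _, _ = extract_features(dataset)
    feat_cols = [c for c in panel.columns
                 if c not in ("condition", "repeat", "cell_id", "frame")]
    organizational = [c for c in feat_cols if c != catalog.BEHAVIORAL_FEATURE]
    cm_cols = [c for c in cmac_feats.columns if c in catalog.CMAC_FEATURE_NAMES]
    return {
        "cell_feature_count": len(feat_cols),
        "organizational_feature_count": len(organizational),
        "cmac_feature_count": len(cm_cols),
        "n": int(len(panel)),
    }


def make_parsing_toy():
    """Ten CMAC tracks with known violations of each parsing rule.

    Survivors by hand enumeration: tracks 1, 4, 5, 7 (after splitting),
    8 and 10 -> 6 tracks.
    """
    from .io import encode_pixels

    def row(cmac_id, frame, x, y, area=0.5, minor=0.6):
        return {
            "condition": "c", "repeat": 1, "cell_id": 1, "cmac_id": cmac_id,
            "frame": frame, "centroid_x_um": x, "centroid_y_um": y,
            "area_um2": area, "major_axis_um": 1.2, "minor_axis_um": minor,
            "ch1_pixels": encode_pixels([5.0] * 8),
            "ch2_pixels": encode_pixels([4.0] * 8),
            "ch1_bg": 1.0, "ch2_bg": 1.0,
        }

    rows = []
    rows += [row(1, f, 1.0 + 0.1 * f, 1.0) for f in range(3, 7)]
    rows += [row(2, 4, 5.0, 5.0)]
    rows += [row(3, f, 8.0, 1.0, minor=0.20) for f in range(2, 6)]
    rows += [row(4, f, 1.0, 8.0 + 0.1 * f) for f in range(0, 4)]
    rows += [row(5, f, 12.0, 2.0) for f in range(7, 10)]
    rows += [row(6, f, 3.0, 3.0, area=0.04 if f == 3 else 0.5)
             for f in range(2, 5)]
    rows += [row(7, f, (20.0 if f < 4 else 26.0) + 0.1 * f, 4.0)
             for f in range(1, 6)]
    rows += [row(8, f, 30.0, 1.0) for f in range(5, 7)]
    rows += [row(9, 0, 40.0, 1.0)]
    rows += [row(10, f, 45.0, 1.0 + 0.05 * f) for f in range(4, 9)]
    return pd.DataFrame(rows), {("c", 1): (0, 9)}


def parsing_fixture_survivors() -> dict:
    """Survivor count of the hand-enumerated parsing toy."""
    from .tracking import parse_cmac_tracks

    toy, bounds = make_parsing_toy()
    parsed, report = parse_cmac_tracks(toy, sequence_bounds=bounds)
    return {
        "surviving_tracks": report.surviving_tracks,
        "expected_by_hand": 6,
        "n": report.input_tracks,
    }
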