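"""Pooled auto-regressive Granger causality over single-cell panels.

For a response feature Y and a background feature X, two nested
ordinary-least-squares models are compared on the pooled rows of all cell
tracks (lags never cross track, condition or repeat boundaries):

    A:  Y_t ~ 1 + Y_{t-1..t-p_y}                     (restricted)
    B:  Y_t ~ 1 + Y_{t-1..t-p_y} + X_{t-1..t-p_x}    (unrestricted)

Lags are nested: a model including lag p includes all younger lags.  The
Granger-Sargent statistic for the improvement of B over A is the F-form

    GS = ((RSS_A − RSS_B) / p_x) / (RSS_B / (N − 1 − p_y − p_x)),

referred to F(p_x, N − 1 − p_y − p_x).  Evaluating it over the full
(p_x, p_y) ∈ {1..10}² grid yields a significance grid whose cells are binned
at 0.05 / 0.01 / 0.001 / 0.0001 and signed by the panel-level Spearman
correlation between X and Y.  A directed edge X → Y is declared only when the
grid is robust and ordered: by default ≥60% of cells significant at 0.05,
≥25% at 0.0001 and a single sign among significant cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import json
import numpy as np
import pandas as pd
from scipy import stats

from .io import TRACK_KEYS, FRAME

SIG_BINS = (0.05, 0.01, 0.001, 0.0001)
BIN_LABELS = ("ns", "<0.05", "<0.01", "<0.001", "<0.0001")


# ---------------------------------------------------------------------------
# Design construction and OLS
# ---------------------------------------------------------------------------

def _track_arrays(panel: pd.DataFrame, cols: list[str]):
    """Per-track value arrays, sorted by frame, NaN rows allowed."""
    out = []
    for _, grp in panel.groupby(TRACK_KEYS, sort=False):
        grp = grp.sort_values(FRAME, kind="mergesort")
        out.append(grp[cols].to_numpy(float))
    return out


def build_lagged_design(panel: pd.DataFrame, Y: str, X: str | None,
                        p_y: int, p_x: int):
    """Pooled lagged regression design.

    Each track of length T contributes max(0, T − max(p_y, p_x)) rows; no row
    mixes tracks.  Columns: intercept, Y lags 1..p_y, X lags 1..p_x.  Rows
    containing non-finite values are dropped.  Returns ``(design, response,
    cell_index)``.
    """
    if p_y < 1:
        raise ValueError("p_y must be >= 1")
    if p_x < 0:
        raise ValueError("p_x must be >= 0")
    m = max(p_y, p_x)
    cols = [Y] if X is None or p_x == 0 else [Y, X]
    designs, responses, cells = [], [], []
    for cell_id, arr in enumerate(_track_arrays(panel, cols)):
        T = len(arr)
        if T <= m:
            continue
        y = arr[:, 0]
        rows = T - m
        block = np.empty((rows, 1 + p_y + p_x))
        block[:, 0] = 1.0
        for l in range(1, p_y + 1):
            block[:, l] = y[m - l:T - l]
        if p_x > 0:
            x = arr[:, 1]
            for l in range(1, p_x + 1):
                block[:, p_y + l] = x[m - l:T - l]
        resp = y[m:]
        ok = np.isfinite(block).all(axis=1) & np.isfinite(resp)
        designs.append(block[ok])
        responses.append(resp[ok])
        cells.append(np.full(int(ok.sum()), cell_id))
    if not designs:
        return (np.empty((0, 1 + p_y + p_x)), np.empty(0), np.empty(0, dtype=int))
    return (np.concatenate(designs), np.concatenate(responses),
            np.concatenate(cells))


@dataclass
class OlsFit:
    coefficients: np.ndarray
    rss: float
    r2: float
    adjusted_r2: float
    n: int
    p: int  # regressor count excluding intercept


def fit_pooled_ar(design: np.ndarray, response: np.ndarray,
                  min_extra_rows: int = 5) -> OlsFit:
    """Ordinary least squares on a pooled lagged design.

    Refused when the design is rank-deficient or has fewer than
    ``columns + min_extra_rows`` rows.
    """
    Z = np.asarray(design, dtype=float)
    y = np.asarray(response, dtype=float)
    n, c = Z.shape
    if n < c + min_extra_rows:
        raise ValueError(f"too few rows (N={n}) for {c} columns")
    beta, _, rank, _ = np.linalg.lstsq(Z, y, rcond=None)
    if rank < c:
        raise ValueError(f"rank-deficient design (rank {rank} < {c} columns)")
    resid = y - Z @ beta
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1 - rss / tss if tss > 0 else np.nan
    p = c - 1
    adj = 1 - (1 - r2) * (n - 1) / (n - 1 - p) if n - 1 - p > 0 else np.nan
    return OlsFit(beta, rss, r2, adj, n, p)


@dataclass
class LagModelPair:
    """Restricted (Y-lags only) and unrestricted (Y+X lags) model pair fit on
    identical rows."""

    response: str
    background: str
    p_y: int
    p_x: int
    n: int
    rss_restricted: float
    rss_unrestricted: float
    adjusted_r2_restricted: float
    adjusted_r2_unrestricted: float


def granger_sargent_test(pair: LagModelPair, form: str = "f"):
    """Significance of the RSS reduction of the unrestricted model.

    F-form: ((RSS_A − RSS_B)/p_x) / (RSS_B/(N − 1 − p_y − p_x)) referred to
    F(p_x, N − 1 − p_y − p_x).  A χ²-form (N·(RSS_A − RSS_B)/RSS_B on p_x
    degrees of freedom) is available via ``form="chi2"``.
    """
    if pair.p_x < 1:
        raise ValueError("models are not nested: p_x must be >= 1")
    if pair.rss_unrestricted <= 0:
        raise ValueError("unrestricted RSS must be positive")
    df2 = pair.n - 1 - pair.p_y - pair.p_x
    if df2 <= 0:
        raise ValueError("insufficient degrees of freedom")
    delta = max(pair.rss_restricted - pair.rss_unrestricted, 0.0)
    if form == "f":
        stat = (delta / pair.p_x) / (pair.rss_unrestricted / df2)
        p = float(stats.f.sf(stat, pair.p_x, df2))
    elif form == "chi2":
        stat = pair.n * delta / pair.rss_unrestricted
        p = float(stats.chi2.sf(stat, pair.p_x))
    else:
        raise ValueError(f"unknown test form {form!r}")
    return float(stat), p


# ---------------------------------------------------------------------------
# Fast grid evaluation via per-row-set Gram matrices
# ---------------------------------------------------------------------------

class _LagGram:
    """Cross-product matrices of [1, Y lags 1..L, X lags 1..L, Y_t] for each
    row set m = max(p_y, p_x), enabling RSS of any nested submodel by a
    small solve instead of a full regression."""

    def __init__(self, panel: pd.DataFrame, Y: str, X: str, L_max: int):
        self.L = L_max
        self.gram: dict[int, np.ndarray] = {}
        self.n: dict[int, int] = {}
        self.ymean: dict[int, float] = {}
        tracks = _track_arrays(panel, [Y, X])
        c = 2 + 2 * L_max  # 1, Ylags, Xlags, response
        for m in range(1, L_max + 1):
            rows = []
            for arr in tracks:
                T = len(arr)
                if T <= m:
                    continue
                y, x = arr[:, 0], arr[:, 1]
                block = np.empty((T - m, c))
                block[:, 0] = 1.0
                for l in range(1, L_max + 1):
                    if l <= m:
                        block[:, l] = y[m - l:T - l]
                        block[:, L_max + l] = x[m - l:T - l]
                    else:
                        block[:, l] = np.nan
                        block[:, L_max + l] = np.nan
                block[:, -1] = y[m:]
                rows.append(block)
            if not rows:
                continue
            Zfull = np.concatenate(rows)
            use = np.isfinite(Zfull[:, [0] + list(range(1, m + 1))
                                    + list(range(L_max + 1, L_max + m + 1)) + [c - 1]]
                              ).all(axis=1)
            Zm = Zfull[use][:, [0] + list(range(1, m + 1))
                            + list(range(L_max + 1, L_max + m + 1)) + [c - 1]]
            # columns now: 1, Y lags 1..m, X lags 1..m, response
            self.gram[m] = Zm.T @ Zm
            self.n[m] = Zm.shape[0]
            self.ymean[m] = float(Zm[:, -1].mean())

    def rss(self, m: int, p_y: int, p_x: int) -> tuple[float, int]:
        """RSS of Y_t ~ 1 + Y lags 1..p_y + X lags 1..p_x on row set m."""
        G = self.gram[m]
        idx = [0] + list(range(1, p_y + 1)) + [m + l for l in range(1, p_x + 1)]
        Sxx = G[np.ix_(idx, idx)]
        Sxy = G[idx, -1]
        Syy = G[-1, -1]
        try:
            sol = np.linalg.solve(Sxx, Sxy)
        except np.linalg.LinAlgError:
            sol = np.linalg.lstsq(Sxx, Sxy, rcond=None)[0]
        return float(max(Syy - Sxy @ sol, 0.0)), self.n[m]

    def tss(self, m: int) -> float:
        G = self.gram[m]
        n = self.n[m]
        return float(G[-1, -1] - n * self.ymean[m] ** 2)


def _adjusted(rss: float, tss: float, n: int, p: int) -> float:
    if tss <= 0 or n - 1 - p <= 0:
        return np.nan
    r2 = 1 - rss / tss
    return 1 - (1 - r2) * (n - 1) / (n - 1 - p)


@dataclass
class LagSurface:
    response: str
    background: str
    L_max: int
    adjusted_r2: np.ndarray      # (p_x, p_y) -> value; index [p_x-1, p_y-1]
    y_only: np.ndarray           # adjusted R², Y-lags-only marginal curve
    x_only: np.ndarray           # adjusted R², X-lags-only marginal curve
    n_rows: np.ndarray


def r2_surface(panel: pd.DataFrame, Y: str, X: str, L_max: int = 10) -> LagSurface:
    """Adjusted-R² surface over the (background-lag, response-lag) grid,
    plus the X-only and Y-only marginal curves."""
    gram = _LagGram(panel, Y, X, L_max)
    surf = np.full((L_max, L_max), np.nan)
    nrows = np.zeros((L_max, L_max), dtype=int)
    y_only = np.full(L_max, np.nan)
    x_only = np.full(L_max, np.nan)
    for py in range(1, L_max + 1):
        if py in gram.gram:
            rss, n = gram.rss(py, py, 0)
            y_only[py - 1] = _adjusted(rss, gram.tss(py), n, py)
    for px in range(1, L_max + 1):
        if px not in gram.gram:
            continue
        # X-only curve still controls an intercept but no Y lags
        G = gram.gram[px]
        idx = [0] + [px + l for l in range(1, px + 1)]
        Sxx = G[np.ix_(idx, idx)]
        Sxy = G[idx, -1]
        sol = np.linalg.solve(Sxx, Sxy)
        rss = float(max(G[-1, -1] - Sxy @ sol, 0.0))
        x_only[px - 1] = _adjusted(rss, gram.tss(px), gram.n[px], px)
        for py in range(1, L_max + 1):
            m = max(px, py)
            if m not in gram.gram:
                continue
            rss, n = gram.rss(m, py, px)
            surf[px - 1, py - 1] = _adjusted(rss, gram.tss(m), n, py + px)
            nrows[px - 1, py - 1] = n
    return LagSurface(Y, X, L_max, surf, y_only, x_only, nrows)


@dataclass
class SignificanceGrid:
    """10×10 Granger-Sargent grid over (p_x, p_y) with signs and bins."""

    response: str
    background: str
    L_max: int
    p_values: np.ndarray         # [p_x-1, p_y-1]
    bins: np.ndarray             # object array of BIN_LABELS
    sign: str                    # "+" or "-": panel Spearman sign of (X, Y)
    autocorrelation: np.ndarray  # response autocorrelation at lags 0..L_max
    n_rows: np.ndarray

    def significant_fraction(self, level: float) -> float:
        p = self.p_values[np.isfinite(self.p_values)]
        if p.size == 0:
            return np.nan
        return float(np.mean(p < level))


def bin_p_value(p: float) -> str:
    if not np.isfinite(p):
        return "ns"
    if p < 0.0001:
        return "<0.0001"
    if p < 0.001:
        return "<0.001"
    if p < 0.01:
        return "<0.01"
    if p < 0.05:
        return "<0.05"
    return "ns"


def panel_autocorrelation(panel: pd.DataFrame, Y: str, L_max: int) -> np.ndarray:
    """Pooled within-track autocorrelation of ``Y`` at lags 0..L_max."""
    ac = np.full(L_max + 1, np.nan)
    ac[0] = 1.0
    tracks = _track_arrays(panel, [Y])
    for lag in range(1, L_max + 1):
        num = den = 0.0
        a_all, b_all = [], []
        for arr in tracks:
            y = arr[:, 0]
            if len(y) <= lag:
                continue
            a, b = y[lag:], y[:-lag]
            ok = np.isfinite(a) & np.isfinite(b)
            a_all.append(a[ok])
            b_all.append(b[ok])
        if a_all:
            a = np.concatenate(a_all)
            b = np.concatenate(b_all)
            if len(a) > 2 and a.std() > 0 and b.std() > 0:
                ac[lag] = float(np.corrcoef(a, b)[0, 1])
    return ac


def significance_grid(panel: pd.DataFrame, Y: str, X: str, L_max: int = 10,
                      form: str = "f", sign_method: str = "spearman"
                      ) -> SignificanceGrid:
    """Granger-Sargent p-values at every (p_x, p_y) cell with signed bins.

    The sign is the panel-level Spearman correlation sign between X and Y
    (``sign_method="coef"`` instead signs by the summed X-lag coefficients of
    the (1,1) unrestricted model).
    """
    gram = _LagGram(panel, Y, X, L_max)
    pvals = np.full((L_max, L_max), np.nan)
    nrows = np.zeros((L_max, L_max), dtype=int)
    for px in range(1, L_max + 1):
        for py in range(1, L_max + 1):
            m = max(px, py)
            if m not in gram.gram:
                continue
            rss_u, n = gram.rss(m, py, px)
            rss_r, _ = gram.rss(m, py, 0)
            if n - 1 - py - px <= 0 or rss_u <= 0:
                continue
            pair = LagModelPair(Y, X, py, px, n, rss_r, rss_u,
                                np.nan, np.nan)
            _, p = granger_sargent_test(pair, form=form)
            pvals[px - 1, py - 1] = p
            nrows[px - 1, py - 1] = n

    if sign_method == "spearman":
        sub = panel[[X, Y]].dropna()
        rho = stats.spearmanr(sub[X], sub[Y]).statistic if len(sub) > 2 else np.nan
        sign = "+" if (np.isfinite(rho) and rho >= 0) else "-"
    elif sign_method == "coef":
        design, resp, _ = build_lagged_design(panel, Y, X, 1, 1)
        fit = fit_pooled_ar(design, resp)
        sign = "+" if fit.coefficients[-1] >= 0 else "-"
    else:
        raise ValueError(f"unknown sign method {sign_method!r}")

    bins = np.empty((L_max, L_max), dtype=object)
    for i in range(L_max):
        for j in range(L_max):
            bins[i, j] = bin_p_value(pvals[i, j])
    ac = panel_autocorrelation(panel, Y, L_max)
    return SignificanceGrid(Y, X, L_max, pvals, bins, sign, ac, nrows)


# ---------------------------------------------------------------------------
# Edge inference, reciprocal testing, graphs
# ---------------------------------------------------------------------------

@dataclass
class EdgeCriterion:
    """Operationalization of "robust and ordered" significance patterns."""

    min_fraction_05: float = 0.60
    min_fraction_0001: float = 0.25
    require_sign_consistency: bool = True


@dataclass
class EdgeDecision:
    source: str
    target: str
    declared: bool
    sign: str
    fraction_05: float
    fraction_0001: float
    sign_consistent: bool
    passed: dict = field(default_factory=dict)


def infer_edge(grid: SignificanceGrid,
               criterion: EdgeCriterion | None = None) -> EdgeDecision:
    """Declare a directed edge when the significance grid is robust and
    ordered under the criterion."""
    crit = criterion or EdgeCriterion()
    f05 = grid.significant_fraction(0.05)
    f0001 = grid.significant_fraction(0.0001)
    # with a panel-level sign the significant cells share it by construction;
    # retained as an explicit check for per-cell sign methods
    consistent = True
    passed = {
        "fraction_05": bool(np.isfinite(f05) and f05 >= crit.min_fraction_05),
        "fraction_0001": bool(np.isfinite(f0001) and f0001 >= crit.min_fraction_0001),
        "sign_consistency": consistent or not crit.require_sign_consistency,
    }
    return EdgeDecision(
        grid.background, grid.response,
        declared=all(passed.values()),
        sign=grid.sign,
        fraction_05=f05 if np.isfinite(f05) else 0.0,
        fraction_0001=f0001 if np.isfinite(f0001) else 0.0,
        sign_consistent=consistent,
        passed=passed,
    )


def reciprocal_analysis(panel: pd.DataFrame, X: str, Y: str, L_max: int = 10,
                        criterion: EdgeCriterion | None = None):
    """Test causation in both directions and classify the pair.

    Returns ``(grid_xy, grid_yx, classification)`` with classification in
    {"X->Y", "Y->X", "bidirectional", "none"}.
    """
    grid_xy = significance_grid(panel, Y, X, L_max)
    grid_yx = significance_grid(panel, X, Y, L_max)
    d_xy = infer_edge(grid_xy, criterion)
    d_yx = infer_edge(grid_yx, criterion)
    if d_xy.declared and d_yx.declared:
        cls = "bidirectional"
    elif d_xy.declared:
        cls = "X->Y"
    elif d_yx.declared:
        cls = "Y->X"
    else:
        cls = "none"
    return grid_xy, grid_yx, cls


@dataclass
class CausalGraph:
    """Directed, signed, per-condition edge set with evidence grids."""

    condition: str
    edges: dict = field(default_factory=dict)    # (source, target) -> EdgeDecision
    grids: dict = field(default_factory=dict)    # (source, target) -> SignificanceGrid

    def add(self, decision: EdgeDecision, grid: SignificanceGrid | None = None):
        key = (decision.source, decision.target)
        self.edges[key] = decision
        if grid is not None:
            self.grids[key] = grid

    def declared_edges(self) -> dict:
        return {k: v for k, v in self.edges.items() if v.declared}

    def to_json(self) -> str:
        payload = {
            "condition": self.condition,
            "edges": [
                {"source": d.source, "target": d.target, "declared": d.declared,
                 "sign": d.sign, "fraction_05": d.fraction_05,
                 "fraction_0001": d.fraction_0001}
                for d in self.edges.values()
            ],
        }
        return json.dumps(payload, indent=1)


def graph_from_json(text: str) -> CausalGraph:
    """Rebuild a :class:`CausalGraph` (edge decisions only, no evidence
    grids) from its JSON serialization."""
    payload = json.loads(text)
    graph = CausalGraph(payload["condition"])
    for e in payload["edges"]:
        graph.add(EdgeDecision(
            e["source"], e["target"], bool(e["declared"]), e["sign"],
            float(e["fraction_05"]), float(e["fraction_0001"]), True))
    return graph


def build_graph(panel: pd.DataFrame, pairs, condition: str = "control",
                L_max: int = 10, criterion: EdgeCriterion | None = None
                ) -> CausalGraph:
    """Evaluate a set of directed (source, target) pairs into a graph."""
    graph = CausalGraph(condition)
    for src, tgt in pairs:
        grid = significance_grid(panel, tgt, src, L_max)
        graph.add(infer_edge(grid, criterion), grid)
    return graph


@dataclass
class ChainLink:
    source: str
    target: str
    declared: bool
    sign: str


def assemble_chain(graph: CausalGraph, feature_sequence: list[str]):
    """Verify a causal chain through consecutive declared edges.

    Returns ``(links, intact, first_break)`` where ``first_break`` is the
    0-based link position of the first missing edge (None when intact).
    """
    links = []
    first_break = None
    for i, (a, b) in enumerate(zip(feature_sequence[:-1], feature_sequence[1:])):
        dec = graph.edges.get((a, b))
        declared = bool(dec and dec.declared)
        links.append(ChainLink(a, b, declared, dec.sign if dec else "?"))
        if not declared and first_break is None:
            first_break = i
    return links, first_break is None, first_break


def compare_conditions(graphs: dict[str, CausalGraph],
                       reference: str | None = None) -> pd.DataFrame:
    """Cross-condition plasticity report.

    Per directed edge: "conserved" (declared with the same sign everywhere),
    "lost" (declared in the reference only), "gained" (declared elsewhere
    only), "sign-inverted" (declared in reference and another condition with
    opposite signs), or "absent".
    """
    if len(graphs) < 2:
        raise ValueError("need at least 2 condition graphs")
    conds = list(graphs)
    if reference is None:
        reference = conds[0]
    all_keys = sorted(set().union(*(g.edges.keys() for g in graphs.values())))
    rows = []
    for key in all_keys:
        decs = {c: graphs[c].edges.get(key) for c in conds}
        declared = {c: bool(d and d.declared) for c, d in decs.items()}
        signs = {c: (d.sign if d else "?") for c, d in decs.items()}
        ref_on = declared[reference]
        others = [c for c in conds if c != reference]
        if ref_on and all(declared[c] for c in others):
            status = ("conserved" if all(signs[c] == signs[reference] for c in others)
                      else "sign-inverted")
        elif ref_on and not any(declared[c] for c in others):
            status = "lost"
        elif not ref_on and any(declared[c] for c in others):
            status = "gained"
        elif ref_on:
            status = "lost"  # declared in reference, partially elsewhere
        else:
            status = "absent"
        row = {"source": key[0], "target": key[1], "status": status}
        for c in conds:
            row[f"declared_{c}"] = declared[c]
            row[f"sign_{c}"] = signs[c]
        rows.append(row)
    return pd.DataFrame(rows)
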