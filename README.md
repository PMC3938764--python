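# migranger

Perturbation-independent mapping of causal influence in the cell-migration
system, from tracked single-cell and cell–matrix adhesion complex (CMAC)
object data.

Live-cell imaging of migrating cells expressing a CMAC marker
(EGFP-Paxillin) and an F-actin marker (RubyRed-LifeAct) yields, per 5-minute
frame, a cell outline and a population of segmented adhesion complexes.
`migranger` turns such object tables into a quantitative account of how the
*organizational* state of the migration machinery (CMAC morphology,
dynamics, composition and localization; cell shape) and its *behavioral*
output (migration speed) causally influence one another — without
perturbing the cells.  The key idea is to exploit natural cell-to-cell and
frame-to-frame heterogeneity: if past values of a background feature X,
alongside past values of a response feature Y, improve the prediction of
present Y, then X Granger-causes Y.

The pipeline stages are importable modules and CLI verbs:

1. **`synthetic`** — generators for stationary VAR feature panels and for
   simulated tracked-cell/CMAC object tables with configurable lagged causal
   couplings and a known ground-truth graph.
2. **`tracking`** — nearest-neighbor linking (2 µm gate) and parsing:
   removal of single-frame CMAC tracks, sub-pixel (< 0.21 µm) minor axes and
   sub-resolution (≤ 0.05 µm²) areas; censoring of tracks that touch the
   first/last frame.
3. **`features`** — local-background correction, per-repeat intensity
   standardization (median corrected mean intensity of reference-condition
   CMACs with area in 0.15–0.2 µm²), the 29-entry per-CMAC catalog and the
   88-entry single-cell catalog (87 organizational features + Instantaneous
   Cell Speed from a GCV-smoothed trajectory).
4. **`transforms`** — feature-wise Box-Cox normalization with a profile-ML
   exponent on a λ ∈ [−3, 3] grid, a normalizability screen, and augmented
   Dickey-Fuller stationarity verification.
5. **`population`** — PCA, Gaussian-mixture EM with AIC model selection over
   K ∈ {2..8}, canonical variate analysis, Mahalanobis distances,
   single-linkage clustering of group means, MANOVA (Wilks' Λ), KS tests and
   Gaussian KDE.
6. **`selection`** — speed-quintile CVA ranking, elastic-net path ranking
   and the global Spearman correlation map.
7. **`granger`** — the core: pooled auto-regressive Granger causality.  For
   each directed feature pair, nested OLS models with 1..10 response lags and
   1..10 background lags are compared by the Granger-Sargent test

       GS = ((RSS_A − RSS_B)/p_x) / (RSS_B/(N − 1 − p_y − p_x)) ~ F(p_x, N − 1 − p_y − p_x)

   over the full 10×10 lag grid, producing signed significance grids; a
   directed edge is declared only for robust, ordered grids (default: ≥60%
   of cells significant at 0.05, ≥25% at 0.0001, one sign).  Reciprocal
   testing classifies pairs as X→Y, Y→X, bidirectional or none; causal
   chains are assembled from declared edges; per-condition graphs are
   compared into a plasticity report (conserved / lost / gained /
   sign-inverted edges).

## Worked example

Simulate 100 cells for 50 frames with a single negative coupling — adhesion
size suppressing next-frame speed — and test both directions:

```python
import numpy as np
from migranger.synthetic import VarSpec, simulate_var_panel
from migranger.granger import reciprocal_analysis

coupling = np.zeros((1, 2, 2))
np.fill_diagonal(coupling[0], 0.5)          # AR(1) memory in each feature
coupling[0, 1, 0] = -0.5                    # X (CMAC area) -> Y (speed), lag 1
spec = VarSpec(2, 1, coupling, feature_names=["X", "Y"])
panel, truth = simulate_var_panel(spec, n_cells=100, track_length_dist=50, seed=8)

grid_xy, grid_yx, cls = reciprocal_analysis(panel, "X", "Y", L_max=10)
print(cls, grid_xy.sign)
print(round(grid_xy.significant_fraction(0.0001), 2),
      round(grid_yx.significant_fraction(0.05), 2))
```

prints

```
X->Y -
1.0 0.0
```

All 100 lag-grid cells for the X→Y direction are significant at the
10⁻⁴ level with a negative panel sign — the injected inhibitory edge — while
the reverse direction shows no significant cell at even the 5% level, so the
pair is classified as unidirectional X→Y, matching the ground truth.

The same analysis runs from the shell:

```sh
migranger simulate microscopy --seed 1 --out sim/
migranger features --in sim/ --out feat/
migranger transform --in feat/features_cell.csv --out norm/
migranger granger --in norm/features_cell_normalized.csv \
    --pairs "Median [CMAC Area] per Cell>Instantaneous Cell Speed" --out out/
```

or end-to-end via `migranger run-all --config config.yaml`.

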