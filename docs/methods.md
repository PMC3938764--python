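# Methods

## The model

The cell migration system is represented per cell and per 5-minute frame by
88 features: 87 *organizational* features describing the state of the core
macromolecular machinery (cell-matrix adhesion complexes, their associated
F-actin, and cell morphology) and one *behavioral* feature, Instantaneous
Cell Speed (ICS).  Causal influence between a background feature X and a
response feature Y is assessed in the Granger sense on pooled per-cell time
series: two nested ordinary-least-squares models

    A:  Y_t = a0 + Σ_{l=1..p_y} a_l Y_{t−l} + ε_t
    B:  Y_t = b0 + Σ_{l=1..p_y} b_l Y_{t−l} + Σ_{l=1..p_x} c_l X_{t−l} + η_t

are fit on rows pooled over all cell tracks of a condition; lags never cross
a track, condition or repeat boundary, and models are nested — including lag
p implies including all younger lags.  Both models are always evaluated on
the identical row set (the rows where max(p_x, p_y) lags exist), which the
nested F test requires.  The Granger-Sargent statistic

    GS = ((RSS_A − RSS_B)/p_x) / (RSS_B/(N − 1 − p_y − p_x))

is referred to F(p_x, N − 1 − p_y − p_x); a χ²-form
(N·(RSS_A − RSS_B)/RSS_B on p_x df) is available via `test_form="chi2"`.
Evaluating GS at every (p_x, p_y) ∈ {1..10}² yields a significance grid,
binned at 0.05/0.01/0.001/0.0001 and signed by the panel-level Spearman
correlation between X and Y (alternative: the sign of the summed X-lag
coefficients, `sign_method="coef"`).  The grid is computed from per-row-set
cross-product (Gram) matrices, so each cell is a small linear solve rather
than a fresh regression; this is algebraically identical to refitting.

**Edge criterion.** "Robust and ordered" significance patterns are
operationalized as: ≥ 60% of grid cells significant at 0.05, ≥ 25% at
0.0001, and one sign among significant cells.  All three thresholds are
configuration parameters.  With the default panel-level sign the third
clause is satisfied by construction; it is enforced explicitly for per-cell
sign methods.  No multiple-testing correction is applied across the 100
grid cells: the grid is reported with raw per-cell bins and robustness is
delegated to the aggregate edge criterion, whose specificity is measured
directly (on 500 null panels of 100 cells × 30 frames the criterion
declares an edge in ~0% of runs, and the (1,1) cell rejects at ~4–5%).

Reciprocal testing runs both directed grids and classifies the pair
(X→Y / Y→X / bidirectional / none); chains are verified link-by-link against
declared edges; per-condition graphs are compared edge-by-edge into
conserved / lost / gained / sign-inverted states relative to a reference
condition.

## Feature extraction

Objects arrive as two delimited tables (cells with WKT polygon outlines;
CMACs with centroid, area, axes, per-channel pixel-intensity vectors and a
local-background estimate), in µm and 0-based frame indices at a stated
frame interval.

Parsing removes CMAC records with minor axis < 0.21 µm (one pixel) or area
≤ 0.05 µm² (segmentation floor), splits tracks at inter-frame displacements
> 2 µm (keeping the longest contiguous segment), drops single-frame tracks,
and flags tracks touching the first or final frame of a sequence as
censored; censored tracks are excluded from all lifetime aggregation but
retain their instantaneous features.

Intensities are corrected as mean := raw mean − local background (clamped
at zero and flagged) and total := corrected mean × area, then standardized
per channel and experimental repeat by the median corrected mean intensity
of reference-condition CMACs with area in [0.15, 0.2] µm² — a size window
above optical and digital resolution, so the divisor tracks instrument gain
rather than biology.

The per-CMAC catalog has 29 instantaneous features (morphology from the
fitted ellipse axes; displacement-based dynamics; lifetime bookkeeping;
per-channel corrected mean/total intensities and their frame-to-frame
changes; Pearson colocalization across the paired pixel vectors; distance
to the cell edge and centroid).  Standardized distance to the cell edge is
s = d(P, ∂Ω) / (d(P, ∂Ω) + |P − C|), with C the cell's center of area: 0 on
the boundary, 1 at the center, well-defined for non-convex outlines.

The single-cell catalog has 88 entries: Cell Area, Cell Perimeter, Cell
Compactness = P²/(4πA) (1 for a disk; larger is less round), Number of
CMACs per Cell, ICS, and 83 per-cell aggregates of CMAC base features under
Mean / Median / Sum / SD / IDR (interdecile range, q90 − q10).  Sums are
restricted to additive bases (area, total intensities).  The exact 88/29
composition is a package convention pinned by the catalog module and
asserted in tests, built by crossing base CMAC features with aggregators
within the seven feature classes.  ICS is the norm of the frame-to-frame
displacement of
the spline-smoothed centroid divided by the frame interval; the smoothing
penalty is chosen by generalized cross-validation (scipy
`make_smoothing_spline`), overridable or disabled per run.  Tracks shorter
than 5 frames are not smoothed.

## Transforms

Each feature is Box-Cox transformed with an individually tuned exponent:
profile maximum likelihood on the grid λ ∈ [−3, 3], step 0.01 (a vectorized
computation equal to scipy's `boxcox_llf` pointwise), after a positivity
shift of −min(x) + max(10⁻⁶, 10⁻³·range) when needed, then standardized to
zero mean and unit variance.  A feature is kept only if the transformed
values pass D'Agostino's normality test at α = 0.01, with a manual-override
keep-list for features that must survive.  Two caveats are documented
deliberately: (i) at large sample sizes the normality screen is extremely
powerful and can discard many mildly non-normal features — the screen
matches a supervised step that is not mechanically reproducible, and the
keep-list is the escape hatch; (ii) re-transforming already-normalized data
recovers λ within one or two grid steps of 1 (not exactly 1), because the
min-based shift places the data near zero where the profile likelihood is
slightly asymmetric; ranks are preserved exactly (the transform is
monotone) and the output changes by < 0.1.

Stationarity is verified, not enforced: the augmented Dickey-Fuller test
(constant-only regression, lag order by AIC) is applied per feature to each
sufficiently long track (default ≥ 30 frames); a feature is stationary when
the unit root is rejected at α = 0.05 in ≥ 80% of tested tracks, and
non-stationary features are flagged with a warning while analysis proceeds.

## Subpopulation structure

PCA (SVD of the centered matrix) reduces the 87-dimensional organizational
data; the retained component count defaults to the smallest reaching 85%
of variance.  Subpopulations are sought with a full-covariance Gaussian
mixture fit by EM: random seeding (means drawn from observations, pooled
covariance), relative log-likelihood convergence at 10⁻⁸ with a
500-iteration cap, ridge regularization of singular covariances (flagged).
Model selection takes the best of 10 randomly seeded restarts per
K ∈ {2..8} and the AIC argmin, with the final assignment refit at 100
restarts; restart sweeps run through a batched implementation that
reproduces the per-seed fits exactly.  Restarts whose solution is a
spurious likelihood maximizer (a component supported by fewer than d+1
effective points, or with covariance eigenvalue ratio below 10⁻⁴) are
screened out unless no restart is clean.

**Known limitation.** AIC with the full free-parameter count
k = (K−1) + K·d + K·d(d+1)/2 systematically over-estimates the component
count on data drawn from an exact Gaussian mixture: the maximized
log-likelihood gain of one redundant component is empirically ≈ 0.9–1.5×
its own parameter count (measured here at d = 2–25, and reproduced
independently with scikit-learn's GaussianMixture), i.e. at or above the
AIC penalty.  On well-separated 4-component draws with n = 2000 the argmin
typically lands at 5–7.  This is the documented behaviour of AIC for
mixture-order selection, not an implementation defect: the EM fits at the
true K recover the generating components essentially perfectly, and the
AIC curve drops steeply up to the true K before flattening.  The
alternative penalty k = K (config `aic_penalty="groups"`) is weaker still.
Consumers who need a consistent order estimate should read the elbow of
the AIC curve or apply a BIC-style criterion externally.

Group comparisons: canonical variate analysis by the generalized
eigenproblem B·v = λ·W·v; Mahalanobis distances on the pooled within-group
covariance; single-linkage agglomeration of group means (Euclidean);
MANOVA via Wilks' Λ = det(W)/det(B+W) with Bartlett's χ² approximation;
two-sample KS tests decided against the asymptotic critical value
c(α)√((n+m)/nm); fixed-bandwidth Gaussian KDE (single observations
allowed).

## Feature selection

Speed-linked organizational features are identified two ways: (i) CVA
contrasting the slowest (S1, 1–20%) and fastest (S5, 81–100%) ICS
quintiles, ranking by |loading| on the first canonical vector; (ii) an
elastic-net regression of ICS on all surviving organizational features
(mixing parameter 0.5, 100 log-spaced penalties plus a near-zero endpoint),
ranking by |coefficient| at the path point maximizing adjusted R² computed
from the elastic-net residuals with p = support size (no refit).  The
elastic net is used for its grouping effect on multicollinear predictors.
Spearman correlations use average ranks and pairwise deletion with a
10-observation minimum.

## The synthetic generators

`simulate_var_panel` draws one independent stationary VAR realization per
cell (50-frame burn-in; stationarity checked via the companion-matrix
spectral radius) — the reference instrument for calibration and power
studies, since extracted features are exactly the simulated ones.

`simulate_microscopy_panel` emulates the object tables: star-convex cell
outlines (radial Fourier perturbation of a circle, 36 vertices, rescaled to
the target area), persistent-random-walk centroid motion,
substrate-anchored CMACs with Poisson births (2/frame), geometric lifetimes
(mean 8 frames), log-normal size factors, and per-channel pixel vectors
(≥ 8 pixels) whose inter-channel correlation encodes colocalization.
Defaults: 5-min frames, 0.21 µm pixels, ~800 µm² cells, ~1 µm² CMACs —
magnitudes typical of adherent carcinoma cells imaged at 60×.  Causal
structure is injected through latent AR(0.6) drivers, one per "drivable"
feature (cell area, compactness, speed, median CMAC area, per-channel total
CMAC intensity, mean CMAC lifetime); coupling edges add lagged cross-terms
between latents, and each drivable feature is rendered as a monotone
increasing function of its latent, so edge signs survive extraction and
Box-Cox normalization (both monotone).  The generator does **not** emulate:
segmentation error, photobleaching, uneven illumination, cell division or
contact, merge/split adhesion events, or non-stationary drift.  Passing
tests therefore demonstrate correctness of the statistical machinery under
the stated generative model, not robustness to all imaging pathology.

Entry/exit of cells from the field is emulated by seeded random truncation
of track ends (never interior gaps, minimum 2 frames), keeping lag
semantics unambiguous under the consecutive-sampling assumption.

## Numerical choices

- OLS by `numpy.linalg.lstsq`; rank-deficient designs refused, as are
  designs with fewer than columns + 5 rows.
- Grid evaluation via Gram submatrices with Cholesky/solve; RSS floored at
  0 against round-off.
- Ridge 10⁻⁶ (scaled by mean variance) wherever a covariance must be
  inverted and is singular; always flagged.
- Ties in nearest-neighbor linking broken by smaller previous-object id,
  then smaller new id; candidate links accepted greedily by distance.
- Benchmark problem sizes (100 cells × 30–50 frames for calibration and
  recovery; 80 cells × 60 frames for the end-to-end chain; 500 null
  replicates; 20-seed recovery sweeps) were chosen as the smallest sizes at
  which the measured quantities are stable to within their reported
  tolerance.
- All randomness flows from explicit integer seeds; sub-seeds derive from
  SHA-256 of "label:seed" truncated below 2³¹.
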