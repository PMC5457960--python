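# Methods

This note records the statistical model, the numerical conventions, the
synthetic-data design and the open design choices behind `cephpls`.

## The estimator

A PLS path model has two layers. The **outer (measurement) model**
assigns every latent variable (LV) a block of manifest variables (MVs)
and a mode: *reflective* (Mode A — the LV is conceived as causing its
indicators) or *formative* (Mode B — the indicators form the LV as a
composite). The **inner (structural) model** is a DAG over the LVs.

Estimation (`cephpls.engine.fit`) is the classical alternating
algorithm:

1. Standardise every MV column (sample mean 0, variance 1 with the n−1
   denominator; the same denominator is used in every correlation and
   OLS step, so identities between correlations and regression
   coefficients hold exactly).
2. Initialise all outer weights at 1; set each LV score to the
   variance-scaled weighted MV sum.
3. Inner update: for LV j, the proxy is Z_j = Σ_k e_jk Y_k over LVs
   adjacent to j in either direction, with e_jk = sign(corr) (centroid),
   corr (factorial), or — under the path scheme — multiple-regression
   coefficients for predecessors and correlations for successors. An
   exactly zero correlation keeps the neighbour with e = 1 rather than
   dropping it.
4. Outer update: Mode A sets w ∝ corr(x, Z_j); Mode B solves the
   within-block normal equations (the block covariance is checked once
   for invertibility; a condition number above 1e10 raises an error
   naming the block). Weights are rescaled so Var(score) = 1.
5. Stop when the largest outer-weight change falls below `tol`
   (default 1e-6; `max_iter` 300). Hitting the cap flags the result
   `converged=False` and emits a warning rather than raising.

Defaults follow the conventions of the R `plspm` lineage: centroid
scheme, weights-change convergence. After convergence, loadings are
corr(MV, own score), communality = loading², path coefficients are OLS
fits of each endogenous score on its predecessor scores (intercepts are
structurally zero), redundancy = communality × own-LV R², and
GoF = √(mean communality × mean R²).

**Sign convention.** PLS composites are sign-indeterminate. Each LV is
oriented so its largest-|loading| MV loads positively; the applied
flips are recorded in `PLSPMResult.orientation` so callers can match
any published sign pattern. Negating a non-dominant MV column therefore
flips only that MV's weight/loading and leaves everything else fixed.

**Shared columns.** The SFA model reuses four columns in two blocks
(LV_overall contains all indicators of LV_10 and LV_1). Blocks treat a
shared column as their own indicator; no cross-block constraint is
imposed.

**Single-MV reflective blocks** degenerate to the standardised column
itself (weight 1/sd, loading 1, communality 1). Because their
communality is 1 by construction, the engine reports GoF under two
variants — over all MVs, and over multi-MV blocks only — and `gof`
carries the variant selected at fit time (`all_mvs` by default).

**Two GoF caveats** surfaced while auditing the published tables: the
printed global GoF (0.7236) is not reproducible from the printed
communality and R² cells under either variant (the audit reports both
recomputations, 0.754 and 0.778, without asserting either), and two
printed redundancy cells (the A-point and coronoid rows of the overall
block) violate the redundancy identity and are flagged as suspected
typos rather than used as fixtures.

**Regression from a printed correlation matrix**
(`ols_from_correlation`) exists for auditing published tables, not for
estimation: with predictors correlated at 0.991 and inputs rounded to
three decimals, the predictor submatrix has condition number ≈ 5100, so
back-solved individual coefficients are meaningless even though the
quadratic-form R² is stable to ~3e-3. The function therefore returns
the condition number, and the audit validates the printed coefficients
only through the forward residual ‖R_xx·β_printed − r_xy‖_∞ (observed
≈ 1e-3). Fitted models never take this route; path coefficients always
come from full-precision scores.

## Geometry layer

The lateral cephalogram is treated as a Euclidean plane in mm, y
increasing upward in input files. The frame is built from porion,
orbitale and sella: the FH axis is the unit vector Po→Or, the
perpendicular axis is oriented toward an "inferior witness" (any
gnathic landmark; without one, inputs are assumed y-up). Horizontal
values are components along the FH axis measured from sella (signed
distance to the S-perpendicular line, anterior positive); **vertical
values are measured from the line through sella parallel to FH**
(inferior positive). Anchoring both coordinates at sella keeps the
frame a single orthonormal chart and makes landmark synthesis an exact
inverse of measurement derivation; it differs from referencing vertical
distances to the FH line itself only by a per-patient constant (the
sella-to-FH offset), which cancels in every increment variable the
model uses. The occlusal vertical dimension is the absolute difference
of the two molar mesial-contact verticals, i.e. the projection of that
segment on the S-perp direction.

All distances are rigid-motion invariant to 1e-9, and
`derive_measurements ∘ synthesize_landmarks` is the identity on
measurement rows to 1e-9 (both are tested properties).

## Synthetic data

Two generators, with different jobs:

**Latent-structure simulation** (`simulate_latent`) draws data with a
fully known truth. Exogenous LVs are independent; endogenous LVs follow
their structural equation with a residual that defaults to
√(1 − explained variance), so the supplied standardised paths are the
truth. Realised latent draws are sample-standardised, putting the
recorded truth on exactly the scale the estimator works on (in the
noiseless limit the refit reproduces the truth to machine precision).
Reflective MVs are loading·LV + scaled noise. Formative MVs are drawn
with exchangeable intra-block correlation and then conditioned so that
the weighted composite *equals* the latent draw — formative constructs
have no generative loading model, so the composite is the well-defined
ground truth, and the construction leaves the block covariance exactly
exchangeable. Near-non-PD correlation inputs are repaired by eigenvalue
clipping at 1e-8 and logged.

A note on **composite attenuation**: reflective blocks with loading λ
and k indicators yield scores correlating
q = λ/√(λ² + (1−λ²)/k) with the factor, so fitted paths shrink by
≈ q² (e.g. 7% at λ=0.9, k=3). This is a property of composite-based
estimation, not a bug; recovery tests either use formative blocks
(whose composites are exact) or enough indicators for q² to sit inside
the stated band.

**The model-shaped spec** (`paper_shaped_spec`) mirrors the SFA wiring
with three formative blocks and a single-indicator sink. Its
calibration targets are the published LV correlations: the
LV_10→LV_overall path is 0.99, and the sink coefficients (−0.9, 1.8,
0.3) are the feasible standardised rescaling of the published
(−0.9914, 1.9065, 0.0013) pattern with the third path raised to give
LV_1 an identifiable contribution — implied sink correlations 0.88 /
0.91 / 0.30 against the published 0.898 / 0.925 / 0.409. (Taking the
published 0.0013 literally would make the LV_1→sink edge contribute
under 0.001 R², i.e. the published wiring would be statistically
indistinguishable from a model without that edge; the printed path
values cannot identify it, so the generator uses a strong-path
version.) Recovery at n=2000 over 50 replicates shows |bias| < 0.01
per path; the per-replicate RMSE of the two coefficients on
0.99-correlated predictors is ≈ 0.05-0.07, consistent with the OLS
variance formula — accuracy claims for those coefficients are
therefore made about the Monte-Carlo mean, not single fits.

**The shared-indicator generator** (`simulate_sfa_dataset`) produces
the six actual model columns, with the overall composite *defined* as
a weighted sum of the other blocks' columns plus VD_10 (negative
weight). Defaults are calibrated to the same published correlation
targets (overall-vs-LV_10 ≈ 0.98, VD loading ≈ −0.56 vs published
−0.522). Because the overall composite literally contains the other
blocks' columns, the generative inner graph of this dataset includes an
implicit LV_1→LV_overall contribution — fine for fitting and for the
sign-pattern property, but structure-search tests use `simulate_latent`
with `paper_shaped_spec`, where the generating DAG is exactly the four
model edges.

**Moment-calibrated cohorts** (`simulate_cohort`) draw
(variable × timepoint) vectors from one multivariate normal whose
means/SDs follow the published cohort summary (27 variables × 3
timepoints). The correlation model is synthetic and configurable —
never an estimate of the real cohort, which published no correlations:
exchangeable 0.9 within the distal-segment block (B, Pog, Me, L1, L6;
the rigid-segment collinearity the method targets), 0.3 across blocks,
and 0.8 between timepoints per variable (chosen to make increment SDs
plausible; timepoints are drawn jointly, not independently, so
increments inherit realistic correlation). VD draws below zero are
clipped (a length cannot be negative; at the published moments this
touches ~0.02% of draws and shifts the mean by < 1e-3 mm). What passing
tests show is that the *pipeline* behaves correctly under known
moments and collinearity — not that real cohorts satisfy Gaussianity,
exchangeable correlation, or the absence of measurement error, none of
which the generator attempts to emulate.

## Inner-model search

`enumerate_inner_candidates` lists every DAG over the four LVs in which
the sink has no outgoing edges and every other LV reaches the sink (79
candidates), in deterministic order. `select_inner` fits all of them
and ranks by sink R², then GoF, then fewer edges, then lexicographic
edge order. The first two comparisons are **tolerance-grouped** (0.01
on R², 0.005 on GoF) before the structural tie-breaks apply, because
exact comparison is degenerate by construction: reversing the upstream
edge between two near-collinear LVs leaves scores, sink R² and GoF
identical to machine precision under the centroid scheme, so an exact
ranking would be decided by floating-point noise. Full-precision
statistics are reported for every candidate, so any alternative ranking
can be recomputed from the output. Non-convergent candidates rank last
and stay flagged.

## Problem sizes

Default verification sizes were chosen to make sampling error small
relative to the tolerances they support: n = 10⁴ for generator moment
checks (SE of the VD mean ≈ 0.033 mm against a ±0.066 acceptance band),
n = 2000 × 50 replicates for path recovery (Monte-Carlo SE of the worst
path mean ≈ 0.009 against a 0.03 bias bound), and n = 1000 for the
structure search. A cohort-sized fit (n = 40) runs in ~2 ms, the full
79-candidate search in ~2 s.

## Known limitations

- No bootstrap/jackknife standard errors or significance tests, no
  missing-data handling, no categorical indicators, no higher-order
  constructs.
- The geometry layer is strictly 2-D; the midsagittal reference plane
  has no 2-D counterpart and is omitted (its only role — defining the
  S-perp orthogonality — survives trivially).
- Formative Mode B assumes an invertible within-block covariance;
  perfectly collinear indicator blocks are rejected rather than
  pseudo-inverted.
- The cohort generator's correlation structure is a stylised stand-in;
  conclusions about real data require the real correlations.
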