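# Methods

## Setting

A visual field is a vector `e ∈ [0, 40]^M` of perceived sensitivities (PS,
dB) on the standard 24-2 grid (M = 54; 6° spacing; rows of 4/6/8/9/9/8/6/4
points with the y = ±3 rows extending nasally to 30°; blind spot at
(15, ±3), right-eye orientation).  The two blind-spot locations are kept in
all matrices — clinical exports include them — and every metric accepts a
flag to exclude them; the default includes them.

The default normative surface is a smooth hill of vision,
`nv_l = clamp(34 − 0.5·ecc_l/6, 0, 40)` rounded to 0.1 dB, where `ecc_l` is
eccentricity in degrees.  Any normative table can be substituted; only
smoothness matters for the simulations here.

## Patient simulator

A simulated responder answers a stimulus of intensity `s` dB at a location
with true sensitivity `t` with probability

    p(seen) = fp + (1 − fp − fn) · (1 − Φ((s − t)/σ(t))),
    σ(t) = min(exp(A·t + B), cap),

with defaults `fp = 0.03`, `fn = 0.01`, `A = −0.081`, `B = 3.27`,
`cap = 6` dB (a Henson-style spread: the psychometric curve flattens as
sensitivity drops, so damaged locations respond less consistently).  The
false-positive/negative floors make `p` range over `[fp, 1 − fn]`.  All
randomness flows through an explicitly passed `numpy` generator; there is
no hidden global state.  The simulator does not model fatigue, learning,
or fixation losses.

## Per-location estimators

**ZEST.**  A probability mass function over integer dB values 0..40 with
prior `PMF_l ∝ G(nv_l, σ_l) + α·G(0, 1) + ε_l` (defaults `σ_l = 5` dB,
`α = 0.1`, `ε_l = 0.001`; the floor guarantees no value has zero
probability).  Each trial presents the posterior mean (rounded to the
support), multiplies in the psychometric likelihood of the observed
response, and renormalizes.  Testing stops when the posterior SD falls
below 2 dB or after 4 presentations, whichever comes first; the final
estimate is the posterior mean.  The likelihood inside ZEST uses the
*assumed* response model (defaults equal to the simulator's), not the
individual patient's parameters.  `σ_l` and `ε_l` would be tuned per
dataset in practice; the defaults are reasonable stand-ins, and the known
consequence (a mild over-estimation bias in damaged fields, and the
stopping rule rarely firing before the 4-presentation cap) is visible in
the benchmarks.

**Dynamic staircase.**  Stimuli move brighter (lower dB) after "not seen"
and dimmer after "seen", with steps from a table keyed by the current
level: 10 dB below 10 dB, 6 dB in 10–20, 4 dB at or above 20 — larger
steps where the psychometric curve is shallow.  One reversal terminates
the location with the midpoint of the two straddling stimuli as estimate;
being pinned at a range bound (0 or 40 dB) twice terminates with the bound.
The quantization error of this rule is about half the local step.

## Baselines

*Full-field ZEST* visits all 54 locations in a seeded random permutation.
*DTS* staircases all locations: four anchors (the innermost point of each
quadrant) start at `nv_l`; the rest are visited breadth-first from the
anchors, starting at the mean of already-estimated 8-neighbors.  *TOP*
splits the grid into four interleaved subgrids, presents exactly one
stimulus per location (first group at `nv_l/2`), adjusts by
`±nv_l·(4,3,2,1)/8` for groups 1–4, and after each group updates untested
locations to the mean of tested 8-neighbors.  The TOP step fractions and
the DTS anchor/ordering rules are configurable; published device behaviour
is proprietary at that level of detail, so these follow the standard
published descriptions (one presentation per location, decaying
deterministic steps, neighbor propagation).

## The meta-strategy

Training operates on the training matrix only through its Gram matrix
`G = X Xᵀ`: the optimal residual of a candidate prefix `w` is
`tr(G) − tr(G[:,w] G[w,w]^{-1} G[w,:])`, making the greedy sweep
independent of N.  Ties in the argmin break toward the lowest location
index for determinism.  The per-prefix bases `D_k` (fit by the closed-form
normal equations, Cholesky-probed; a ridge `λ = 1e-8·tr(Y Yᵀ)` is added
with a warning when `Y Yᵀ` is singular, e.g. when S exceeds the data rank)
are stored in the model and reused at examination time.

At examination step k the measurement vector contains the local
estimator's final estimates at `l*_1..l*_k`; the reconstruction
`ê_k = D_k y` (clamped to [0, 40]) seeds step k+1: SORS-Z recentres the
prior's healthy Gaussian on `ê_k(l*_{k+1})` (the first location uses the
standard normative prior); SORS-D starts the staircase at
`ê_k(l*_{k+1}) − τ` with `τ = 4` dB (starting slightly brighter than the
prediction biases the first response toward "seen" and shortens the
staircase).  The final field keeps measured estimates at tested locations
and fills untested ones from the last reconstruction, so tested/untested
errors can be analyzed separately.  Ablation trainers are included:
random location subsets (RS), best-of-50 random subsets by training
residual (ORS), and a no-intermediate-reconstruction examination mode
(normative seeding, single final reconstruction).

A caution on the exact-interpolation regime: when S equals the numerical
rank of the training data, `D_S` interpolates and is ill-conditioned, so
measurement errors — in particular the ~5 dB floor error at truly dead
locations, where an at-threshold 0 dB stimulus is seen 50% of the time —
can be amplified arbitrarily at untested locations.  With S above the data
rank the overdetermined basis averages measurement error instead; the
package's recovery guarantees are stated for that regime.

## Synthetic cohorts

The generator emulates the statistical structure the meta-strategy relies
on, not clinical realism per se.  A patient's base field is
`nv + correlated noise`; glaucomatous patients (default fraction 0.86 of
160 patients, 32 fields each, mirroring a mixed clinic population)
additionally subtract 1–3 archetypal defects — superior/inferior arcuate
bands peaking near 15° eccentricity, a superior nasal step, diffuse loss —
each scaled by an exponential severity (mean 10 dB), plus an exponential
global depression (mean 2 dB).  Arcuate masks carry zero weight across the
horizontal midline, as nerve-fiber-bundle defects do.  Correlated noise is
sampled in a truncated eigenbasis of a squared-exponential covariance over
grid coordinates (scale 10°, patient-level SD 2 dB); repeat visits redraw
a correlated visit term (SD 1 dB) around the patient's base field.
Components with eigenvalues below 1e-9 of the largest are dropped, and
`gp_rank` caps the component count exactly when a known-rank cohort is
needed.

Because severe defects clamp at the 0 dB floor, the realized matrix is not
exactly low-rank; "numerical rank" for this package means the number of
singular values above 1e-3 of the largest (the dB-resolution scale), which
is ~31 of 54 at defaults.  What passing tests show, therefore, is that the
method exploits low-dimensional *correlation* structure; they do not show
performance on the things the generator omits: longitudinal progression,
visit-order fatigue, eye-specific mirroring beyond orientation, or the
real dataset's within-patient visit structure (modeled here as independent
redraws).

Against this generator the S = 16 and S = 36 accuracy gap is smaller than
on clinical data — 16 well-chosen measurements already capture most of the
generator's structure — so benchmark assertions target the robust
orderings (TOP fastest-but-least-accurate at exactly 54 presentations;
sparse staircase testing faster than DTS at a median RMSE within 0.5 dB;
full ZEST longest).

## Problem sizes and numerical choices

The test suite trains on cohorts of 120–5,120 fields and benchmarks on
100–500 held-out fields; the speed–accuracy comparison uses the
generator's default training size (160 × 32 fields) with 500-field test
cohorts at three seeds, and the calibration checks draw 1e5 responses.
PMF normalization is maintained to 1e-9; reconstruction and estimates are
clamped to [0, 40] dB; greedy scoring tolerates ties at 1e-12.  Fold
assignment for patient-wise cross-validation is greedy largest-first into
the smallest fold, balancing fold sizes to within one patient's field
count.  All examinations are reproducible given a seed; benchmark drivers
hand each field an independent child generator so strategies see identical
response streams.

## Known limitations

No early-stopping criterion at examination time (the location order and S
are fixed by training); location selection is population-, not
patient-specific; SITA-family strategies are out of scope (their internals
are unpublished); ZEST prior parameters are not auto-tuned per dataset.
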