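# Methods

`gradsim` implements a multiscale case-control analysis of structural brain
connectomes: low-dimensional manifold coordinates summarise each subject's
white-matter connectivity, a biophysical mean-field model inverts functional
connectivity into regional microcircuit parameters, permutation statistics
compare groups, and an elastic-net pipeline predicts symptom severity from
manifold features. Everything runs end-to-end on seeded synthetic cohorts
with known ground truth, so every stage has a recovery experiment.

## Connectome processing

Subject structural connectomes (SC) are symmetric nonnegative parcel-by-parcel
matrices of streamline cross-section weights. The pipeline log-transforms
them (`ln(1+w)`, zeros preserved) and builds a group-representative matrix by
distance-dependent consistency thresholding: candidate edges are split into
`n_bins = 10` equal-count bins of inter-parcel Euclidean distance; within a
bin, edges are ranked by the fraction of subjects expressing them (ties by
mean weight, then edge index) and the top `m_b` kept, where `m_b` is the mean
per-subject edge count in the bin. Binning by distance protects long-range
connections that a global consistency threshold would discard, because
short-range connections are systematically more reproducible across subjects.
Community reduction averages matrix entries between (and within, excluding
the diagonal) the seven functional communities.

## Manifold embedding

A cosine-similarity affinity between log-SC connectivity profiles feeds a
diffusion-map embedding: density normalisation `W' = D^-α W D^-α` with
`α = 0.5`, row normalisation to a transition matrix, eigendecomposition via
the symmetric conjugate, and eigenvalue scaling `λ/(1-λ)` at diffusion time
`t = 0` (a `λ^t` alternative is available). The first three coordinates
(M1–M3) are the analysis space. Individual embeddings are computed from each
subject's own affinity and aligned to the template embedding of the
group-representative connectome by orthogonal Procrustes rotation (no scaling
or translation, so per-parcel norms are preserved). Eigenvector signs are
fixed by making each column's largest-magnitude entry positive. Variance
explained is each nontrivial transition-matrix eigenvalue's share of the
positive nontrivial spectrum, so the reported fractions sum to at most one.
Manifold eccentricity is the per-parcel Euclidean distance from the template
manifold centroid (configurable center). Weighted manifolds multiply M1–M3
elementwise by a seed structure's streamline weights to cortical parcels.

## Mean-field model and BOLD forward model

Each region is a neural mass with average synaptic gating `S_i`:

    dS_i/dt = -S_i/τ_s + r (1 - S_i) H(x_i) + σ ν_i(t)
    H(x)    = (a x - b) / (1 - exp(-d (a x - b)))
    x_i     = W_i J S_i + G J Σ_j C_ij S_j + I_i

with region-specific recurrent strength `W_i` (excitation/inhibition) and
excitatory subcortical/external input `I_i`, shared constants
`J = 0.2609 nA`, `a = 270 n/C`, `b = 108 Hz`, `d = 0.154 s`, `r = 0.641`,
`τ_s = 0.1 s`, a global coupling `G`, and white noise of amplitude `σ`. The
singularity of `H` at `a x = b` is evaluated by series (limit `1/d`).
Integration is Euler–Maruyama with `dt = 1 ms` by default (coarser steps are
configurable; the step must not exceed `τ_s/10`); `S` is clamped to `[0, 1]`
(gating interpretation) and clamp events are counted.

Synaptic activity drives a Balloon–Windkessel cascade per region
(vasodilatory signal `z`, inflow `f`, volume `v`, deoxyhemoglobin `q`) with
`ρ = 0.34`, `κ = 0.65 s⁻¹`, `γ = 0.41 s⁻¹`, `τ = 0.98 s`, Grubb exponent
`α = 0.32`, and BOLD read-out
`V0 [k1 (1-q) + k2 (1-q/v) + k3 (1-v)]`, `V0 = 0.02`,
`k1 = 4.3 θ0 ρ TE`, `k2 = ε r0 ρ TE`, `k3 = 1-ε`, `θ0 = 28.265 B0`,
`B0 = 3 T`, `TE = 15 ms`, `ε = 0.47`. The intravascular slope constant `r0`
is not pinned down by the sources that print these equations; the default
`r0 = 25 s⁻¹` follows the hemodynamic-modelling literature and is
configurable. Simulated FC (FC') is the Pearson correlation of TR-sampled
BOLD after a burn-in (defaults: TR = 2 s, 8-minute sessions, 1–2 minute
burn-in).

### Connectome normalisation and dynamical regime

The coupling matrix `C` is the log-SC scaled to unit spectral radius. With
the largest eigenvalue of `C` at 1, the inter-regional input stays on the
order of the recurrent input for `G` near 1 and the network retains a stable
low-firing-rate operating point. Unit-maximum or row-sum scalings push the
default parameterisation into a saturated high-activity state whose FC is
essentially uncorrelated noise. The synthetic ground truth uses `G = 0.5`,
`σ = 0.005`, `W_i ~ N(0.53, 0.15²)` and `I_i ~ N(0.325, 0.05²)` (clipped to
the fitting bounds): the regional means follow the values reported for
cortical populations, the spatial spread of `W` matches the range seen in
cortex-wide maps of recurrent excitation, and the regime places regions on
heterogeneous operating points between threshold and saturation — the regime
in which microcircuit parameters actually shape FC.

### Model inversion

`fit_parameters` estimates `(W, I, G, σ)` from an empirical FC (and,
optionally, the per-region log BOLD variance profile). Two design problems
dominate:

1. **Identifiability.** The Pearson correlation between FC matrices is
   invariant to the overall FC level and discards region variances. Many
   parameter configurations reproduce the FC *pattern* (correlation ≈ 0.9)
   with scrambled regional parameters. The inversion therefore minimises a
   moment-matching score: squared error on the FC entries themselves (levels
   matter), plus a weighted squared error on mean-centred log BOLD variance
   profiles, plus a weak ridge toward the initial values — the analogue of
   the Gaussian parameter priors in EM-style neural-mass inversions, pinning
   directions the data leave unconstrained. `σ` is not optimised by default:
   near a stable fixed point both FC and the normalised variance profile are
   scale-invariant in `σ`.
2. **Cost and landscape.** A stochastic-simulation objective is noisy and
   slow; the inversion instead evaluates the model's *linear-response*
   moments: the gating equations are linearised at their deterministic fixed
   point (short noise-free integration plus damped Newton), the hemodynamic
   cascade at its driven rest state, and the stationary BOLD covariance
   solves a Lyapunov equation of the joint linear system. In the small-noise
   regime this matches long stochastic simulations at r > 0.95 and costs
   milliseconds, making a deterministic, smooth objective available to
   standard optimisers.

The landscape is still multimodal: its barriers correspond to per-region
fixed-point *branch assignments*, which behave combinatorially — gradient
descent cannot move a region across a branch boundary, and generic starts
strand several regions on the wrong branch. The search therefore constructs
its initial candidates directly on target branches: the gating fixed point
is (anti)monotone in a region's BOLD variance, so the ranks of the inverted
empirical log-variance profile define candidate target gating profiles over
several spreads, and for each (spread, G) the regional inputs that make the
target profile an exact fixed point are computed in closed form by inverting
the stationarity condition (`x = H⁻¹(S/(τ_s r (1-S)))`,
`I = x − W J S − G J C S`). The top-scoring candidates get a full bounded
L-BFGS-B polish over `(W, I, G)`; a ridge continuation step (prior weight
reduced tenfold, re-polish) then releases weakly constrained coordinates
from the prior centre, and seeded jittered restarts guard against residual
local optima. Bounds: `W ∈ [0.1, 1.5]`, `I ∈ [0.1, 0.6]`, `G ∈ [0, 10]`,
`σ ∈ [0.001, 0.1]`. The reported
`objective` is the Pearson correlation between the fitted model's simulated
FC' and the empirical FC, with FC' averaged over several simulated sessions
(a single finite session's sampling noise would attenuate the correlation
that a well-averaged empirical FC supports).

Cross-validated fitting splits subjects into folds, fits the training
subjects' mean log SC against their mean FC, and scores FC' against training
and held-out mean FC; final parameters are fold means and fold-wise parameter
cross-correlations quantify stability. Bootstrap fitting resamples subjects
with replacement within group, community-reduces SC and FC to the 7-network
scale, and fits the reduced system. The model-vs-baseline permutation test
compares `corr(FC', FC) - corr(SC, FC)` against a null that independently
permutes the upper-triangle entries of FC' and SC (independent permutations,
so a model identical to SC sits in the middle of its null).

## Group statistics

Per-parcel multivariate comparisons use two-sample Hotelling T² on the
aligned M1–M3 coordinates with pooled covariance (ridge fallback for
singular cases). Covariates (age, sex, site, optionally head motion and
morphology) are residualised out before permutation; the null permutes group
labels, and p-values use +1 smoothing, `p = (1 + #{null ≥ obs})/(n_perm+1)`,
so they are never zero. Benjamini–Hochberg FDR corrects across parcels.
Stratification reports class means over the four hierarchy levels or seven
communities; hemispheric asymmetry is `100 (mean|v|_R - mean|v|_L)/mean|v|_L`
per class.

The spin test builds a spatial null by uniform random rotations of the
left-hemisphere spherical centroids, mirrored (`x → -x` conjugation) to the
right, reassigning each parcel to the nearest rotated source (duplicates
allowed). The reported p takes the tail on the side of the observed
correlation and doubles it: conditioning the tail on the observed sign alone
squashes null p-values into `[0, ½]` and can never be calibrated, while the
doubled version is uniform under rotation exchangeability. Calibration is
validated against map pairs generated from the null's own exchangeability
class (a smooth field passed through a random rotation-reassignment);
genuinely independent smooth maps are *not* exchangeable under the
mirror-coupled rotation family, and no spin-test variant is calibrated for
them.

Edge-wise comparisons run pooled-variance t-tests on log weights over the
group-representative support with label-permutation p-values and BH
correction; significant edges split into increased/decreased sets whose
tract lengths are compared by a permutation test on the mean difference.
The cell-type overlap-ratio test computes
`100 |list ∩ set| / |set ∩ universe|` per cell type against a null of
equal-size random sets drawn from the union of all cell-type genes, BH
corrected across types.

## Symptom prediction

Elastic-net prediction of ADOS-like scores uses nested cross-validation:
outer folds hold out test subjects; inner folds choose the mixing parameter
(grid 0.1–1.0) and penalty strength by the *lowest-overfitting* rule — the
smallest absolute gap between inner-training and inner-validation
correlation, ties broken by validation accuracy; candidates whose
predictions are constant are excluded. Feature standardisation and covariate
removal use training-fold statistics only. The elastic net selects features
(nonzero coefficients); an ordinary least-squares model on the selected
features produces test predictions, so accuracy is not biased by coefficient
shrinkage. Out-of-fold predictions are pooled within a repeat before
computing r and MAE; the whole procedure repeats with fresh partitions.
Significance comes from re-running the pipeline on permuted scores (reduced
repeats per permutation). Selection-frequency maps count the fraction of
repeats in which any of a parcel's three manifold features was selected.

## Synthetic cohorts

`make_atlas` samples parcels uniformly on a unit sphere per hemisphere (the
geometry of surface-based spherical registration); the right hemisphere
mirrors the left (`x → -x`). Seven communities are contiguous caps around
seed parcels (a seed is nearest to itself, so every community is represented
in each hemisphere at any size); four hierarchy levels are contiguous
latitude bands. Physical distances scale the spheres to a 70 mm radius and
offset the hemisphere centres by ±35 mm along x.

`make_structural_connectome` wires edges with probability proportional to
`exp(-d/30 mm) (1 + same_community)`, scaled to a target density, patches
the graph to a single component, and draws log-normal weights whose location
decays with distance (stronger short-range connections, emulating streamline
cross-section statistics). Defaults: density 15%, weight σ = 1.

`make_cohort` plants the group effect as a connectivity *redistribution* at
the effect parcels: within-community edges scaled by `1 + effect_size`,
cross-community edges by its inverse. A uniform row/column scaling would be
nearly invisible to the cosine-affinity embedding at the scaled parcel
itself — cosine similarity is row-scale-invariant, and after the log
transform a uniform scaling reduces to a shared additive offset — whereas
the push-pull form changes the profile shape locally while approximately
preserving total strength. Subject-level noise is element-wise log-normal
jitter (σ = 0.25) plus a 3% edge dropout (isolated parcels keep their
strongest dropped edge). Phenotypes (age, sex, site, head motion, thickness,
curvature) are drawn with smooth spatial structure where appropriate.
ADOS-like scores are `intercept + factor × (weights · manifold features of
the effect parcels) + N(0, noise_sd × factor)`, truncated at zero and
rounded to one decimal; the total and three subscores share the weight
vector with score-specific factors. Functional connectivity is generated on
request (`include_fc`) by the mean-field BOLD forward model from the known
ground-truth parameters and each subject's own connectome; it is opt-in
because the forward simulation dominates generation cost at 200 parcels and
most analyses consume SC only.

### What passing tests do and do not show

The generator reproduces the *statistical structure* the analysis assumes —
distance- and community-dependent topology, log-normal weights, exchangeable
groups under a zero effect, FC generated by the very model the inversion
assumes. Real data violate several of these: empirical FC contains
measurement noise, vascular structure, and dynamics outside the mean-field
family; real group effects are not confined to a known parcel set; real
ADOS scores are not linear in manifold coordinates. Passing recovery tests
therefore validates the implementation and the internal consistency of the
pipeline, not the biological claims. Two observed properties are worth
keeping in mind when reading real-data results: (i) with a genuine group
effect, manifold coordinates shift at most parcels, not only the perturbed
ones — a global embedding delocalises local anomalies (the null calibration
is unaffected); (ii) the recovered `W` is intrinsically less identifiable
than `I` at low operating points, where the recurrent term's leverage on the
dynamics vanishes.

## Numerical choices and scaled-down experiment sizes

Validation experiments use sizes chosen to exercise the full pipeline at
desk scale: 20-region networks for parameter recovery (32 simulated sessions
averaged into the empirical FC, emulating group-averaged FC), 14-region
cohorts of 10 subjects per group for cross-validated fitting, 200-parcel
cohorts of 25 per group for the planted-effect power analysis, 200 subjects
for prediction. Permutation counts are 199–1000 depending on the experiment;
all seeds are explicit. Fixed points are solved to 1e-12; Procrustes uses
SVD; ridge 1e-8 stabilises singular pooled covariances; degenerate inputs
(all-zero connectivity rows, disconnected affinities, constant BOLD
channels, rank-deficient designs, empty communities) raise informative
errors rather than propagating NaNs.

## Known limitations

- The inversion's validation surface is parameter recovery on synthetic
  data; fidelity to any particular published estimation code is not claimed.
- The two regional parameter maps are not equally identifiable from zero-lag
  BOLD moments. Recovery of the subcortical/external input `I` is robust
  (truth correlation typically ≥ 0.95); recovery of the recurrent strength
  `W` plateaus around 0.7 on typical 20-region instances (and varies widely
  between instances), for two demonstrable reasons: the covariance
  sensitivity directions of `W_i` and `I_i` are nearly collinear for regions
  at low operating points, and the surrogate's linearisation bias displaces
  the global optimum of the moment fit slightly but systematically away from
  the generating parameters — profiling the coupling on a fine grid shows
  the best attainable score at a shifted G even when the search starts at
  the truth. Estimated `W` maps should be read as regularised effective
  parameters, consistent with the field's practice of reporting their
  refit *stability* rather than accuracy.
- The linear-response surrogate assumes a stable low-activity fixed point;
  parameter sets without one receive a graded stability penalty during
  optimisation rather than a likelihood.
- `σ` and overall variance scale are confounded; variance profiles enter the
  objective mean-centred.
- The spin test applies to hemispherically mirror-matched atlases; maps must
  live on the atlas's spherical centroids.
- Site is a fixed covariate; no mixed-effects modelling.
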