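# Methods

This note documents the models and estimators the package implements, the
choices made where the problem left the design open, what the synthetic-data
generators do and do not emulate, and the numerical conventions the tests
rely on.

## Intrinsic neural timescale estimation

The ACF estimator is the biased form: the denominator is the total sum of
squares over all retained frames at every lag (no lag-dependent
normalisation). INT is the TR-scaled sum of the coefficients of the initial
positive period; the sum is empty (INT = 0) when ACF(1) ≤ 0, which is
distinct from the undefined case of a constant series (reported missing with
a warning, never as 0). The lag horizon is min(T−1, ⌈100 s / TR⌉); the sum
stops at the first non-positive coefficient regardless.

**Censoring.** Censored frames are handled pairwise-complete by default: a
lag-k product contributes only when both frames are retained, and the
denominator runs over retained frames (implemented by zeroing censored
entries of the demeaned signal, which removes exactly the right terms from
both sums). `censor_mode="concatenate"` compacts retained frames instead.
The pairwise form avoids manufacturing spurious fast decorrelation at
censored joins; with no censoring both reduce to the same estimator.

**Cleaning order.** Confounds (plus first backward-difference derivatives
and an intercept) are regressed out on the full contiguous series, a
zero-phase second-order Butterworth band-pass (default 0.01–0.1 Hz) follows,
and censoring then only updates the mask — filtering needs contiguous
samples. Frames with FD > 0.3 mm are dropped together with both immediate
neighbours. Estimation requires at least 8 retained frames plus one per
confound regressor.

**Comparator.** The optional exponential timescale fits A·exp(−kTR/τ) to the
initial positive ACF segment by nonlinear least squares, τ initialised from
a log-linear fit.

**Reliability.** ICC(2,1) (two-way random effects, absolute agreement,
single measure) is computed per unit across subjects from the two-way ANOVA
mean squares; the unit tests cross-check it against pingouin. Units with
zero between-subject variance are flagged undefined.

## Hierarchy selection

Each sensory system has exactly four anatomically admissible 7-level
orderings (two swap pairs, all other regions fixed) and the winner gains two
prefrontal extensions (the PFC pair at levels 8/9). All candidates share
dimensionality, so goodness of fit alone decides.

The scoring model is a linear mixed-effects regression of level on z-scored
T1w/T2w and cortical thickness with a per-subject random intercept and
independent random slopes (diagonal random-effects covariance, which
stabilises estimation on 7–9 parcels per subject). R² is the squared Pearson
correlation between observed levels and conditional predictions (random
effects included); a `conditional=False` switch gives the marginal version.
Failures cascade: full model → random-intercept only → OLS, flagged by
`converged=False`. Ties break to the first candidate in canonical
enumeration order, with a warning.

The permutation null reassigns levels 1..L uniformly over all regions of the
scored hierarchy (one-sided p, add-one estimator); an exhaustive mode
enumerates all L! assignments for small L. Spearman validation against any
parcel metric uses a two-sided permutation p on |ρ|.

## Symptom-gradient inference

**M1.** Ordinary least squares per parcel. `M1_primary` (patients only)
regresses INT on the seven 0–5 symptom severities, age, a binary gender
dummy, mean FD, and treatment-coded site dummies with the largest site as
reference. `M1_exploratory` (patients + controls) replaces the symptom block
with a diagnosis indicator. Rank-deficient designs raise an error naming the
collinear columns. PANSS items are mapped onto the 0–5 scale by subtracting
one point and merging the two most severe levels (`rescale_panss`).

**M2.** The hallucination- and delusion-severity t-statistics from M1 are
sampled at the nine levels of the three winning hierarchies (prefrontal
parcels shared across systems contribute one point per system: 54 points)
and modelled by OLS with full symptom × level × system interactions
(12 coefficients, residual df 42). Treatment coding with switchable
references exposes each simple effect as a named coefficient: with
hallucinations/auditory as references, `level` is the auditory hallucination
gradient and `sym[delusions]:level` the auditory symptom-by-level
interaction. Two-system (stream comparison) and single-symptom (specificity)
variants use the same machinery. Cohen's f² per term is
(R²_full − R²_minus-term)/(1 − R²_full) by explicit column-drop refit.

**Permutation.** Surrogates jointly permute the rows of the seven-symptom
block across patients — preserving the inter-symptom correlation matrix
exactly — then refit M1 at every parcel and M2 on top (two-sided add-one p).
The M2 null is noticeably wider than Student t (shared parcels across
systems violate iid errors), which is the reason permutation inference is
the primary test. A vectorised engine makes a surrogate cost two small
least-squares solves; it is verified against the plain pipeline to 1e-10.

**Set-level tests.** Within each surrogate a term is "significant" when it
falls beyond the two-sided 95% plug-in thresholds of its own null
distribution with the expected sign; predicates are conjunctions of
"at least k of m effects" clauses. The plug-in threshold (not nested
permutation) is an approximation made for tractability.

**BCa bootstrap.** Patients are resampled with replacement and both stages
refit per draw; z₀ comes from the bootstrap CDF at the observed value (ties
counted half) and the acceleration from the jackknife-over-patients skewness.
Draws in which a site dummy loses all variance keep the (pinv-handled)
column and are flagged; degenerate bootstrap distributions collapse the
interval to a point, flagged. The implementation is validated against
scipy's independent BCa on a textbook statistic, and its coverage checked on
a skewed-mean problem.

**Exemplary cases.** Fitted INT per hierarchy level at the four
(hallucination, delusion) score settings {(0,0),(5,0),(0,5),(5,5)}, all
other predictors at patient-sample means; ΔINT is the difference from the
(0,0) case. By linearity the combined case is exactly the sum of the two
single-symptom profiles.

**Controls.** The diagnosis-level "overall effect" is the count of parcels
beyond the two-sided Student threshold, tested against a diagnosis-permuted
null. The rank-binned control ranks voxels by a reference INT map into
equally sized bins (remainder to the last bin, warned) and regresses bin
mean t on bin index.

## Biophysical model

Rate equations per node (state v_E, v_I; SI units internally):

- τ_E dv_E/dt = −v_E + β_E [I_E]₊ with
  I_E = (1+ηh)(w_EE v_E + μ_EE Σ_j FLN_ij v_E^j) − w_EI v_I + I_ext,
- τ_I dv_I/dt analogous with w_IE, μ_IE, w_II.

Defaults are the reference set (τ_E = 20 ms, τ_I = 10 ms, β_E = 0.066,
β_I = 0.351 Hz/pA, w_EE = 24.3, w_IE = 12.2, w_EI = 19.7, w_II = 12.5,
μ_EE = 33.7, μ_IE = 25.3 pA/Hz, η = 0.68). Hierarchy values h ∈ [0,1] are
fit from SLN by fractional-response logistic regression on a ±1
level-difference design, each projection weighted by log₁₀(FLN) shifted to
be positive (raw log-FLN is negative; the shift preserves the "stronger
projections count more" intent), gauge fixed by one node and min-max
normalised. A flat solution returns zeros with a warning.

**Calibration.** Background currents put every node at the 10/35 Hz
operating point in closed form (both rectifications active there); the
linearised system's eigenvalues are checked and a non-negative real part
raises "unstable operating point". The Jacobian is validated against
finite differences, and the simulated stationary covariance against the
continuous Lyapunov solution.

**Integration.** Euler–Maruyama at dt = 0.2 ms (heavy test paths use
0.5 ms; the precondition is dt ≤ τ_I/10), numba-compiled, recorded at 1 ms.
Noise is white external current on both populations; the Hz-equivalent
`noise_sd` (default 1e−5 Hz) is converted through the respective f-I slope
and scaled by 1/√dt so the injected variance is step-size independent.
Divergence is reported with the first affected node and time.

**Hemodynamics.** Balloon–Windkessel per node (vasodilatory signal, flow,
volume, deoxyhemoglobin; κ = 0.65 s⁻¹, γ = 0.41 s⁻¹, τ_MTT = 0.98 s,
α = 0.32, ρ = 0.34, V₀ = 0.02, θ₀ = 40.3 Hz, r₀ = 25 Hz, ε = 1.43,
TE = 40 ms — a standard 3T set, all overridable; k₁–k₃ always derived from
their defining formulas). The neural drive is v_E minus a baseline (per-node
temporal mean by default) so the operating point maps to the hemodynamic
fixed point s = 0, f = v = q = 1, B = 0. BOLD is decimated to TR = 2 s after
a burn-in; the first 20 s of rates are also discarded so a perturbed network
has settled into its new operating point. In-silico INT applies the same
estimator as in vivo, with ACFs averaged across repetitions before the sum;
perturbed and unaltered runs share noise seeds (common random numbers), so a
null perturbation gives ΔINT ≡ 0 exactly.

**E/I perturbations.** A triangle profile over hierarchical levels: ΔE/I(L)
= min + (peak − min)(1 − |L − peak|/D), D the largest level distance among
free nodes; peak level 1–8, peak magnitude 0–40%, minimum −30–40%; node 46d
is always fixed (zero change). Mechanisms: scale w_IE by (1 − Δ/100)
(error at ≥100%) or w_EE by (1 + Δ/100); multiple perturbations sum their
profiles before application. Perturbations keep the unaltered background
(the operating point moves — the state-perturbation reading used for the
symptom scenarios). A uniform global E/I change (`scale_global_ei`) instead
uses `recalibrate=True`: the top of the hierarchy is so input-sensitive that
any global reduction beyond ~1% with frozen backgrounds silences it
entirely, so the global trait scenario compares matched 10/35 Hz operating
points and then shows the expected INT decrease at every node.

**Fitting.** The three symptomatic exemplary-case ΔINT profiles over the six
matched levels (V1=1, V2=2, V4=4, MT=5, 8l=8, 46d=9; 18 points) are fit by
an outer grid over the two peak levels and an inner bounded Nelder–Mead over
the four magnitudes (deterministic restarts: the default start plus a
small-magnitude start that survives cells where the default destabilises
the network, then seeded random starts). Every simulation in the objective
shares noise seeds. Parameter sets that destabilise the linearised network
receive a finite penalty graded by the excess eigenvalue — cheaper and
better-behaved for the simplex than letting the simulation diverge. The
combined case is modelled by the summed profiles.

## Synthetic data: what it emulates, and what not

**Time series.** Exact-discretisation OU processes (x_{t+1} = φx_t +
√(1−φ²)ε, φ = e^{−TR/τ}), so the ground-truth discrete-sum INT
TR·φ/(1−φ) is known in closed form; optional white observation noise.

**Cohorts.** Default 127 patients / 158 controls (the study's sample
sizes). Seven 0–5 symptom scores arise by thresholding a latent Gaussian at
quantiles of a fixed category distribution (mean severity ≈ 2.4); the
hallucination–delusion latent correlation is calibrated analytically
(bivariate-normal cell probabilities + midrank grade correlation, root-found
by Brent) to a target sample Spearman of 0.62, other pairs share a moderate
latent correlation of 0.3. INT per subject × parcel = a per-system level
gradient (0.55 s + 0.05 s/level), a −5% global diagnosis effect in patients,
score-weighted symptom effects with level-linear profiles (hallucinations
+0.020 − 0.004·level s per point in the auditory system; delusions the
mirror image in auditory + somatosensory — compression vs expansion),
small covariate effects, a subject random offset (SD 0.08 s) and residual
noise (SD 0.10 s). Effect scales were chosen to land the second-stage
t-statistics in the single-digit range the in vivo analysis reports.
Ground truth is returned for recovery tests.

**Structural maps.** T1w/T2w decreasing (−0.05/level from 1.7) and
thickness increasing (+0.08 mm/level from 2.2 mm) in level, with per-subject
random intercepts and slopes plus residual noise; default 100 subjects (the
structural sample size).

**Tract tracing.** Row-normalised log-normal FLN with distance decay and
feedforward dominance, SLN = logistic(4·Δh) with logit-scale link noise.
The default network holds the six matched nodes (level→h compressed at the
bottom, ((L−1)/8)², as empirical SLN-derived values are) plus eight
high-hierarchy association nodes. The association cluster exists because a
six-node row-normalised graph concentrates long-range loop gains far beyond
a full cortical graph: with the reference weights it is either unstable or
loses the seconds-scale top timescales. The extra nodes carry the
near-critical slow mode (they are never perturbed), and the feedforward
dominance (asym 2.3) and decay (1.0) were set by linear analysis (Jacobian
spectrum + linearised Balloon transfer) so that the operating point is
stable across seeds, perturbations at the fitted scales (≈20% at level 1,
≈4% at level 8) remain stable while larger ones destabilise — mirroring the
hypersensitivity of area 46d — and BOLD INT increases along the matched
hierarchy.

**Not emulated:** spatial structure within parcels, scanner artefacts,
non-Gaussian physiological noise, site-by-covariate interactions, genuinely
ordinal symptom measurement error, and the full 29-area macaque graph.
Passing tests therefore demonstrate correctness of the estimators and
pipelines under the assumed generative structure, not robustness to real
acquisition artefacts.

## Test budgets and problem sizes

The suite runs in roughly 15–20 minutes on one CPU. Scale choices: the
permutation type-I calibration uses 200 seeds × 199 permutations at n = 40;
BCa coverage uses a closed-form skewed-mean check (200 seeds) plus
planted-interaction exclusion over 40 cohorts; structural-ordering recovery
runs 12 seeds at the 100-subject condition (mixed-model cost bounds the
count); the in-silico INT hierarchy pools ACFs over 10 repetitions of 900 s
on one fixture network; the E/I fit self-consistency uses a reduced grid
({1,8} × {8}), 90 s simulations and common random numbers, under which the
planted peaks are recovered exactly and magnitudes to well within a 25%
relative tolerance. `scripts/acceptance.py` integrates the noiseless calibrated
network for 60 s and reports steady-state rates.

## Known limitations

- The mixed-model R² uses conditional predictions; model comparison across
  candidates of equal dimensionality is insensitive to this choice, but
  absolute R² values are not comparable to fixed-effects-only reports.
- Set-level p-values use plug-in thresholds, not nested permutations.
- The in-silico ΔINT profile of a low-level perturbation peaks at mid/high
  matched nodes (the perturbation tilts the shared slow mode) rather than at
  the perturbed level itself; peak identification in the fit rests on
  profile shape differences, which common random numbers keep identifiable.
- Exhaustive permutation enumeration of the symptom-block null requires more
  patients than the M1 design has columns, so the exhaustive oracle is only
  exercised for the ordering null; the fast permutation engine is instead
  validated against independent slow-path refits of replayed surrogates.
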