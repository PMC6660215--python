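# Methods

## The generative model behind the synthetic cohorts

The generator produces the data the downstream analyses assume, with one
shared latent layer that couples behavior and neural signal.

**Trial structure.** Audio-visual (AV) and auditory (A) trials alternate,
the AV trial always first; visual catch trials, when requested, are
inserted only after A trials so that no AV→A pair is interrupted. Stimulus
locations come from five azimuths {−17, −8.5, 0, 8.5, 17}°. The nine
within-pair discrepancies ΔVA = V_AV − A_AV ∈ {−34 … +34}° in 8.5° steps
are balanced by construction: the discrepancy multiset (each value
`n_per_discrepancy` times, default 40 → 360 pairs, 790 trials with 70 V
trials) is shuffled, and for each ΔVA the sound location is drawn uniformly
among locations for which V_AV = A_AV + ΔVA is also a valid location. The
A-trial sound is uniform over the five locations. A consequence of the
feasibility constraint is that the marginal distribution of A_AV is not
uniform and A_AV correlates with ΔVA; this is a property of the balanced
design, not an artifact.

**Behavior.** Each stimulus gives rise to a noisy internal estimate,
Ã = A + ε_A and Ṽ = V + ε_V with ε ~ N(0, σ²); defaults σ_A = 7°,
σ_V = 2° (audition much less precise than vision at these eccentricities).
Responses are

    R_AV = c · [(1 − w_V)·Ã_AV + w_V·Ṽ_AV]                    + δ_s + motor
    R_A  = c · b_A·Ã_A − g_A·Ã_AV(prev) + g_V·Ṽ_AV(prev)      + δ_s + motor

with central-bias gain c ∈ (0, 1] (compression toward the midline),
visual weight w_V, auditory gain b_A (default 1), per-subject constant
offset δ_s ~ N(0, 1°) (this is what the mixed models' random intercept
absorbs), and motor noise (default 2°). The VE regression slopes implied by
the AV rule are b_A = c(1 − w_V) − 1 on the sound and b_V = c·w_V on the
visual stimulus; `weights_for_ve_targets` inverts this, and the defaults
c = 0.74, w_V ≈ 0.297 target slopes (−0.48, +0.22). The recalibration
gains default to (g_A, g_V) = (0.09, 0.03) — the asymmetric weak
aftereffect — and may be given as a single scalar λ, which reduces the rule
to the symmetric form R_A = c·Ã_A + λ·(Ṽ − Ã)(prev). Response clipping to
the ±25° screen is available but off by default; an optional dropout rate
emulates trial exclusions.

**Source epochs.** The grid is a regular lattice (default 12³ voxels at
8 mm; tests and examples use 6³–10³) with an ellipsoidal interior mask;
x > 0 is the right hemisphere and hemispheric mirroring negates x. Five
disjoint 7-voxel regions (placed at fixed fractions of the grid extent,
loosely echoing temporal/occipital/parietal anatomy) encode, linearly and
with a Gaussian temporal profile (peak latencies 100–160 ms, width 50 ms):
the current sound estimate, the visual estimate, the combined estimate
(1 − w_V)Ã + w_V·Ṽ, and — in A trials, scaled by a persistence gain
(default 0.5) — the previous trial's sound, visual, and combined
estimates. Per-voxel gains are set so that the signal SD across trials at
the peak equals `snr` times the noise SD. Noise is Gaussian, temporally
white, and spatially correlated by Gaussian-kernel smoothing over the
lattice (correlation length 12 mm), renormalized to unit marginal
variance. Because the *same* internal estimates drive responses and
epochs, cross-validated decoder projections genuinely predict the
single-trial biases — which is exactly what the neuro-behavioral
regressions are designed to recover.

**What the generator does not emulate.** No sensor-level physics, forward
model or beamformer; no 1/f or oscillatory temporal structure (noise is
white in time); no trial-order drift, fatigue or learning; fixed encoding
latencies across subjects; no eye movements. Passing tests therefore
demonstrate correctness of the analysis chain under its own assumptions,
not robustness to the full complexity of real MEG recordings.

## Behavioral statistics

VE rows exist only for AV trials, VAE rows only for A trials; the VAE
mean-centers within (subject, sound-position) cells, making cell sums
exactly zero and removing any stationary localization bias. Group tests
per non-zero discrepancy use two-sided Wilcoxon signed-rank tests on
subject means (a deliberate choice: the group-level test; pooled-trial
testing would conflate within- and between-subject variance) with Holm
step-down correction over the family of 8 non-zero bins. Fewer than ~12
subjects cannot reject after Holm at family-wise 0.05 (the minimal
signed-rank p times 8 exceeds it) — cohort sizes below that are only
useful for estimation, not for the per-discrepancy tests.

Dissociation trials (visual-attraction and recalibration predictions in
opposite directions) are selected by the two case rules
`ΔVA < 0 ∧ A_A ≤ V_AV` and `ΔVA > 0 ∧ A_A ≥ V_AV`; ΔVA = 0 is excluded by
strictness.

## Mixed models and model comparison

Fixed effects plus a subject random intercept, fit by maximum likelihood
(not REML — required for likelihood-based comparison across fixed-effect
structures). Several optimizers are tried and the best finite-likelihood
fit kept, because a near-zero random-intercept variance (which arises when
subject offsets are small) puts the ML estimate on the boundary. BIC/AIC
are recomputed from the log-likelihood with k = n_fixed + 2 (random
intercept + residual variance) so the reported criteria always satisfy
BIC = −2ℓ + k·ln n. t-values are reported with residual dof = n − n_fixed.

PXP uses the variational random-effects scheme: responsibilities
u_sk ∝ exp(lme_sk + ψ(α_k) − ψ(Σα)), Dirichlet updates α_k = α0 + Σ_s u_sk
(α0 = 1), exceedance probabilities by Monte-Carlo sampling of the fitted
Dirichlet (default 10⁵ samples, seedable), and protection by the Bayes
omnibus risk computed from the variational free energy against the
equal-frequency null. Per-subject log evidences default to −BIC/2 of
per-subject OLS fits. Two consequences are worth knowing. First, the free
energy slightly under-approximates the mixture evidence, so the BOR (and
hence PXP) can deviate by a few hundredths from the exact posterior on
weak-evidence inputs; the Monte-Carlo exceedance step itself is exact up
to sampling error. Second, per-subject BIC penalizes a weak extra
regressor (per-subject t ≈ 1) by more than it earns, so for the faint
visual recalibration weight the PXP can favor the one-term model even when
the pooled mixed-model BIC — which aggregates the effect across all
subjects' trials — clearly selects the two-term model. Both quantities are
reported; they answer different questions (population model frequency vs
pooled evidence).

## Decoding

Windows of 60 ms (6 samples at 100 Hz) stepped by 10 ms are reduced by the
within-window mean, giving 27 features per searchlight (averaging rather
than concatenating keeps the trials-per-feature ratio healthy at these
trial counts; concatenation would sextuple the dimension). Searchlights
are truncated at lattice/mask edges, never padded. The LDA covariance uses
Ledoit–Wolf analytic shrinkage toward (tr Σ/d)·I, computed in closed form
and batched over windows; shrinkage intensity 1 collapses to the scaled
identity (weights ∝ mean difference), intensity 0 to the Fisher
discriminant. The constant centers the two class-mean projections on zero.
All-constant feature sets (e.g. masked-out voxels) get an identity target,
yielding a zero weight vector and chance AUC rather than a singular solve.

Labels: stimuli {−17, −8.5}° → left, {8.5, 17}° → right, center excluded;
responses by sign with exact zeros excluded. Folds are stratified by class
and seeded; excluded trials are still assigned to folds so that every
trial receives a projection from a model never trained on it. The map AUC
is the mean of per-fold AUCs (pooled-score AUC is available as an option);
AUC itself is the rank/Mann-Whitney statistic with ties counted ½.

Peak selection reduces a map to its spatial 95th-percentile time course
and finds local maxima within 0–500 ms with 50 ms minimum separation.
Because AUC saturates near 1 for strong encodings, the raw argmax of a
saturated stretch is noise-driven; each peak is therefore refined to the
center of its near-peak plateau (the contiguous run within 5% of the peak
height relative to the course's range), which tracks the underlying
response latency. Variables injected at two nearby latencies (e.g. a sound
encoded unisensorily at 100 ms and within the combined estimate at 150 ms)
produce a merged bump whose refined peak lies between them.

## Neuro-behavioral regressions

Ordinary least squares per subject, voxel and window; stimulus terms enter
in degrees, projections in their native units (no standardization — slopes
remain interpretable; an option exists). AV-trial models exclude the ±34°
pairs, where the two stimulus locations are fully anti-correlated and the
design degenerates. The bias models solve the 3×3 normal equations batched
across voxels×windows and refuse near-singular designs. Group inference is
a one-sample t across subjects (df = S − 1; 23 for a 24-subject cohort).
Cluster cross-testing averages projections over a cluster's member voxels
at their significant windows and refits the two bias models per subject;
between-cluster strength comparisons are one-sided paired t-tests oriented
along the group-mean effect direction, FDR-adjusted. Lateralization tests
mirror member voxels across the midline (x → −x, exact on the symmetric
lattice), drop mirrors outside the mask with a reported count, and use
two-sided paired t-tests with FDR adjustment.

## Cluster permutation inference

Under the symmetric null, each subject's whole map is flipped by ±1; 2000
draws by default (desk-scale runs use 100–500; p-values are reported with
the (1 + #{null ≥ obs})/(n_perm + 1) convention and can never be 0).
Statistic maps are the group mean (for chance-corrected AUC, i.e.
AUC − 0.5) or the one-sample t. Clusters are connected components of
suprathreshold voxels — 26-connectivity by default, consistent with the
27-voxel searchlight; 6-connectivity available — with positive and
negative maps processed separately against a common max-|sum| null; the
minimum size of 6 is enforced before summing, for observed and permuted
maps alike. Cluster-forming thresholds: the 99th percentile of the pooled
permuted maps for AUC (linear-interpolation quantile), the parametric
t-quantile (2.81 at df = 23, p = 0.01 two-sided) for regression betas,
with an elevated constant 6.60 for the AV-trial visual regressor whose
effect dwarfs the rest of its family. A-priori masks (the union of
significant AUC clusters for the matching variable, full-brain fallback
for the visual variable) zero both observed and permuted maps, so masked
inference cannot report clusters outside the mask. Overlap maps intersect
the significant-cluster voxels of several regressors across timepoints.

Calibration note: with spatially *white* subject maps, ≥6-voxel clusters
essentially never form at these thresholds and the test becomes
degenerately conservative; the type-I calibration therefore uses the
generator's spatially correlated noise, where the family-wise rejection
rate at α = 0.05 lands in the nominal band.

## Problem sizes and determinism

Default test and example sizes: 6³–10³ grids, 6–24 subjects, 100–200
permutations, 10⁵ PXP samples; the full study design (40 repeats per
discrepancy, 24 subjects, 2000 permutations) is a parameter choice away.
Every stochastic stage takes an explicit seed; cohorts are bit-identical
functions of their parameters (per-subject seeds spawned from the master
seed), and the pipeline manifest records checksums so re-runs are
verifiable. Epochs are float32.

## Known limitations

- The deposited-data path (`avrecal behavior` on the original study's
  behavioral tables) requires the user to download and convert the archive
  to the TSV schema; no `.mat` reader is bundled.
- The VB-based BOR is an approximation (see above); exact enumeration is
  exponential in the subject count and not attempted.
- Sign-flip draws pair with subjects by position: permuting subject order
  changes the draw (identically distributed, not bitwise identical);
  observed maps and cluster memberships are exactly order-invariant.
- Edge voxels have slightly reduced noise variance after spatial smoothing
  (interior-exact renormalization), marginally inflating their effective
  snr.
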