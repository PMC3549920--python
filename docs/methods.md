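# Methods

## The scientific question the pipeline operationalizes

A "network disease" hypothesis for a psychiatric disorder makes a specific
statistical claim: the joint distribution of voxel activity differs between
patients and controls even where every marginal (per-voxel) distribution is
the same. Task-based GLM analysis sees only the marginals — the correlation
of each voxel with the stimulus — so a pure-connectivity disruption is
invisible to it. The pipeline tests this dissociation on both axes:
hypothesis testing (which features show corrected group differences) and
generalization (which features let a classifier predict the group of a
held-out subject).

## Synthetic cohort model

Each masked voxel v of subject s in run r follows

    y_v(t) = b + a_v · (Σ_c g_c · (s_c ⊛ h)(t)) + Σ_f L_{v,f}(group) · z_f(t) + ε_v(t)

with baseline b = 100, white noise ε ~ N(0, σ²), σ = 1, latent series z_f
stationary AR(1) with coefficient 0.3 (innovation variance 1, so
Var z = 1/(1−0.09) ≈ 1.10), and condition gains g = (1, 0.8, 0) for
(native sentences, foreign sentences, silence). The activation amplitude
a_v ~ N(1, 0.1) on a bilateral "auditory" region — drawn from the *same*
distribution for both groups, which is the model's central assumption.

The group difference enters only through the factor loadings:

| factor | support | control | patient |
|---|---|---|---|
| bilateral auditory | two 20 mm spheres, one per hemisphere | 1.6 | 0.4 |
| left local | 29 mm sphere, left hemisphere | 1.6 | 1.6 |
| right local | 20 mm sphere, right hemisphere | 1.6 | 1.6 |
| per-hemisphere compensation | each auditory sphere separately | 0 | √(1.6² − 0.4²) |

Two consequences of this arrangement matter:

1. **Variance matching (default).** The compensation factors return to
   patients exactly the within-hemisphere coupling power they lose in the
   bilateral factor, so Σ_f L² is group-constant on every voxel. Without
   this, the group-specific factor would inflate controls' GLM residual
   variance and hence *systematically depress their activation t-values* —
   a marginal group difference the model is supposed to exclude. With it,
   per-voxel signal variances agree between groups in expectation (the
   tests assert within 5% at T = 2000), within-hemisphere correlations are
   group-identical, and only the *cross-hemisphere* correlation differs:
   r ≈ 0.75 in controls vs ≈ 0.1 in patients at the default loadings.
2. **A group-neutral normalization anchor.** Spatial normalization divides
   each map by its maximum, so a group difference in the maximum would leak
   into every voxel of the normalized map. The left local blob is sized to
   be the largest coupled set in *both* groups (≈ 104 voxels vs ≈ 56 for
   the control bilateral clique), anchoring the degree maximum identically
   and keeping group-identical factors null after normalization.

Effect sizes are not prescribed by any printed number (the source cohort is
not deposited); the loadings were chosen once so that within-factor Pearson
correlations sit just above the r = 0.7 edge threshold (0.75, a realistic
value for strongly coupled fMRI voxel pairs) while disrupted cross-
hemisphere correlations sit far below it, and were not revisited.

Geometry: 16 × 16 × 12 grid at 10 mm spacing, two ellipsoidal "hemisphere"
lobes strictly left/right of x = 0 mm (952 masked voxels, no midline
voxels). Runs default to T = 200 volumes at TR = 2 s with a balanced
three-condition paradigm (15 trials/condition at the acquisition-matched
mean spacing of 8.7 s/trial: 0.2 s tone, 3.5 s sentence, 0.75 s pause,
0.5 s probe, jittered inter-trial gap); an acquisition-scale preset
(T = 416, 32 trials/condition) exists. Randomness: one master seed; each (subject, run,
component) draws from a child stream keyed through `numpy.SeedSequence`
spawn keys, so adding subjects never perturbs existing ones. Motion traces
are AR(1) series from their own stream, independent of all BOLD components
by construction; an additive motion-artifact term exists but defaults off.

What the generator does **not** emulate: spatial autocorrelation outside
factor supports, scanner drift and physiological noise spectra, motion-
induced signal corruption, susceptibility artifacts, or any symptom time
course. Passing tests therefore demonstrate the *logic* of the pipeline —
calibration under the null, sensitivity to a designed connectivity
alternative, leakage-free validation — not performance on real scanner
data.

## GLM and activation maps

Canonical double-gamma HRF (response gamma shape 6, undershoot shape 16,
ratio 1/6, unit peak ≈ 5 s); condition boxcars built on a 0.1 s grid,
convolved, and sampled at volume times. Drift: unit-norm DCT-II basis
removing frequencies up to 1/128 Hz (⌊2·T·TR·f_c⌋ columns). OLS per voxel;
t = c′β̂ / √(σ̂²·c′(X′X)⁻¹c). The eight contrasts are the five pairwise
condition differences plus the three single-condition amplitudes (the
intercept absorbs the baseline, so the single-condition contrast vector is
the bare condition indicator). Zero-residual voxels with nonzero contrast
get a signed-infinity sentinel excluded from summaries and ranking.
Normalization divides by the maximum *absolute* value, keeping signed
t-maps in [−1, 1] (for nonnegative degree maps both conventions coincide).
A condition absent from a paradigm yields an all-zero regressor, which is
tolerated at design-construction time; collinear nonzero columns raise.

ROI analysis: spheres in mm space (boundary voxels included), spatial-mean
series residualized against the drift basis plus intercept, Pearson
correlation between ROI pairs, and a PPI contrast defined as the difference
of condition-weighted correlations with weights = the HRF-convolved
regressor clipped at zero and renormalized to sum 1 (clipping avoids
negative weights in the weighted-covariance formula).

## Network features

Edges require *strictly* r > threshold. Degree-type, strength-type, global
and distance features use raw correlations; clustering and local efficiency
use |r| (both modes are exposed — the asymmetry mirrors how these features
are conventionally defined). Strengths sum the full unthresholded
correlation row. Long-distance degree counts neighbors ≥ 5 voxel-index
units away (mm-space alternative via argument). Hemisphere labels come from
the sign of the mm x-coordinate; midline voxels (x = 0) are never counted
as inter-hemispheric in numerators but their links count in denominators.
The mean geodesic averages over *connected ordered pairs only* — the
thresholded networks are deliberately sparse and usually disconnected, and
infinite distances would otherwise dominate; the convention is recorded in
the feature's docstring and the report. Distance profiles use 5 mm bins
from zero; the power-law p(d) = a·d^(−γ) is fit by least squares in
log–log space over positive bins in [10, 150] mm. Constant voxel series
get correlation 0 to all partners and are flagged rather than propagating
NaNs.

## Group statistics

Pooled-variance two-sample t (df = n₁+n₂−2), two-sided p. The 44
run-samples are treated as independent observations — the convention the
sample count implies — and the resulting within-subject dependence is noted
in result metadata rather than corrected. Benjamini–Hochberg step-up
selection: largest k with p₍k₎ ≤ k·α/N, all features at or below that
cutoff selected (ties all-in); Bonferroni: p ≤ α/N. Ranking ties break by
ascending feature id, making every downstream pipeline bit-reproducible.
The motion-confound screen correlates every feature with a per-sample
motion summary (mean absolute frame-to-frame translation) and FDR-corrects
the t-transformed p-values at 0.05. The ROI-level group test is the
two-sided Wilcoxon rank-sum (exact when untied), Bonferroni-scaled by the
number of connectivity measures; a signed-rank variant exists behind a
flag but groups of distinct subjects call for the rank-sum form.

## Sparse Gaussian MRF classifier

Per class, the precision matrix maximizes
log det C − trace(SC) − λ‖C‖₁ over positive-definite C, where S is the
class's empirical covariance (1/n normalization, class-centered features)
and ‖C‖₁ is the elementwise ℓ1 norm over **all** entries, the MAP estimate
under independent zero-mean Laplace priors on every entry; a
diagonal-unpenalized variant sits behind `penalize_diagonal=False`. Solver:
block coordinate descent on the dual covariance W (each column solves a
lasso subproblem by numba-compiled coordinate descent; with the diagonal
penalized, W_ii is fixed at S_ii + λ). Convergence is certified by the
duality gap trace(SC) + λ‖C‖₁ − p ≤ 1e−5 (the off-diagonal ℓ1 when the
diagonal is unpenalized); failure to converge raises with the achieved gap.
Entries below one tenth of the gap tolerance are snapped to exact zero so
the recovered sparsity pattern is well defined. λ = 0 returns S⁻¹ directly
and requires S nonsingular. λ is *not* tuned inside cross-validation folds
(deliberately, to keep the experiment cheap and honest); the grid
10⁻⁴…10 is exercised in tests and the pipeline reports per-λ results.

Classification: equal class priors (balanced cohorts), label = argmax of
½ log det C_c − ½ (x−μ_c)′C_c(x−μ_c); ties break toward the
lexicographically first label. GNB uses per-class means/variances with a
1e−9 relative variance floor; the linear max-margin classifier is a
hinge-loss separator at the default regularization constant C = 1. The MRF
accepts at most 500 features — its per-class covariance comes from ~21
samples, and the cap keeps the estimation regime explicit.

## Cross-validation and the study pipeline

Leave-one-subject-out: 22 folds on 44 samples; the held-out subject's two
runs are predicted independently (samples, not subjects, are scored).
Feature ranking (t-test p-values) is recomputed on training rows only; the
tests assert that permuting held-out rows cannot change the selected ids,
and that pure-noise features yield chance-level error — the signature that
no selection leakage exists. Error, false-positive and false-negative
rates are pooled over folds with "patient" as the positive class.
Reported error equals 1 − accuracy recomputed from stored per-fold
predictions (asserted). Errors are pooled over predictions rather than
averaged over folds; with equal-size test sets the two coincide.

The end-to-end study (`run_full_study`) simulates the cohort, builds all
feature tables, runs the corrected group tests and motion screen, the
stability analysis (fraction of top-k features common to all folds), the
classification sweep (GNB and linear margin at k ∈ {10, 100, 500}; MRF at
k = 100, λ = 0.01), and the distance-profile comparison, and emits one
deterministic JSON report. Default problem sizes (952 voxels, T = 200,
22 subjects) keep the whole study at desk scale — a few minutes on one
core — while remaining large enough for stable graph statistics.

## Numerical choices and degenerate inputs

- Correlations are clipped to [−1, 1] after the inner-product computation.
- Thresholding is strict (r > c), so r exactly at the threshold adds no
  edge.
- All-zero maps pass through normalization unchanged.
- Zero pooled variance in the t-test: equal means → t = 0, p = 1; unequal
  means → p = 0 with a sentinel flag.
- Empty graphs: global features return zeros with an undefined (NaN) mean
  geodesic; link-fraction operations raise.
- The full-correlation path caps at 6000 voxels; beyond that a sampled
  pair list is required (the fixed-pair design also guarantees feature
  correspondence across subjects).

## Known limitations

- Clustering-coefficient and local-efficiency maps are group-null under
  the default generator (coupled blobs are near-cliques in both groups),
  so they exercise the machinery but not a group difference; the degree
  and strength families carry the designed effect.
- The synthetic activation region coincides with the disrupted coupling
  region by design; the pipeline does not depend on this, but spatial
  colocation of effects is not itself tested.
- Rate computations assume exactly two classes throughout; multi-class
  problems are out of scope.
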