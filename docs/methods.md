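# Methods

This package implements a resting-state functional-connectivity (RSFC)
classification analysis for idiopathic normal pressure hydrocephalus
(iNPH), from ROI time series to interpreted linear-SVM weight maps.  No
patient data are distributed or downloadable; the analysis is exercised on
seeded synthetic cohorts whose statistical structure encodes the design the
method assumes.  This note records the model, the parameter choices, the
numerical decisions, and what conclusions the synthetic results do and do
not support.

## Pipeline model

For each subject with ROI time series $Y \in \mathbb{R}^{T\times 90}$ and
confound channels $C \in \mathbb{R}^{T\times 8}$ (six rigid-body motion
parameters, white-matter and CSF mean signals):

1. **Nuisance regression.** Each ROI column is replaced by its OLS residual
   against $[\mathbf{1}\,|\,C]$.  Residuals are exactly mean-zero and
   uncorrelated with every confound channel (checked at $10^{-8}$).
   Identically-zero confound columns are dropped with a log entry (the
   regression degrades gracefully to intercept-only); any other linear
   dependence in the design raises a collinearity error naming the
   offending columns.
2. **Band-pass filtering** of the residuals at 0.001–0.1 Hz: linear
   detrend, then a brick-wall discrete-Fourier mask retaining bins
   $k/(N\cdot TR)$ inside the band.  With $T=116$, $TR=3$ s the first
   nonzero bin is $\approx 0.0029$ Hz, so the low cut removes only the DC
   bin; this is logged, not an error.  The brick-wall choice is
   deterministic and exactly testable against an FFT oracle; it is a
   documented approximation of common toolbox practice, not a claim of
   bit-equivalence with any particular toolbox (a Butterworth variant sits
   behind `method="butterworth"`).  The linear detrend does not commute
   with the spectral mask (the fitted line leaks a small in-band
   component), so the filter core is exposed with a `detrend` switch and
   the exact passthrough/rejection properties are stated for the pure
   spectral projection.
3. **Connectivity features.** Pearson correlation between every ROI pair,
   Fisher $z = \operatorname{atanh}(r)$ per coefficient, vectorized in the
   frozen row-major upper-triangle order over the ROI table
   ($90 \cdot 89/2 = 4005$ edges).  $|r|$ is clamped to $1-10^{-7}$ before
   atanh (keeping $z \lesssim 8.05$) with a log entry; every vector carries
   a hash of the ROI table so vectors from different orderings cannot mix.
4. **Classification.** Univariate two-sample pooled-variance t-test filter
   at $\alpha = 0.05$ on the *diagnosis* contrast (iNPH vs HC) — also when
   the downstream labels are severity scores; per-edge standardization to
   zero mean / unit variance with train-set statistics only; linear
   soft-margin C-SVM with cost 1 and per-class weights $1/n_\text{class}$;
   leave-one-out cross-validation (LOOCV), one fold per subject.  Severity
   (grading-scale scores 0–4 for gait, cognition, urinary symptoms;
   controls fixed at 0) is predicted one-against-all: one binary machine
   per label value present in the training fold, prediction by maximal
   decision value, ties to the lowest label.  For severity tasks the
   accuracy restricted to patient test rounds is reported alongside the
   overall accuracy.
5. **Significance.** Exact two-sided binomial test,
   $p = \min(1,\, 2\min(P(X\le k), P(X\ge k)))$ under
   $\mathrm{Binomial}(n, p_0)$; $p_0 = 0.5$ for diagnosis and
   $1/\#\{\text{observed classes}\}$ for severity (always reported next to
   the p-value, since no canonical chance level exists for one-against-all
   with imbalanced labels).
6. **Weight interpretation.** The interpretation model is refit on the
   full cohort over the pooled-selection edge set (one weight table per
   task; per-fold averaging is available as a sensitivity flag).  Edge
   contribution is $|w|$; one-against-all machines are aggregated by
   summing $|w|$ across class machines (the rule is recorded in the report
   header).  Reports include the descending-$|w|$ ranking (ties broken by
   canonical edge index), top-$k$ cumulative weight fractions, the
   inter-/intra-hemispheric weight sums, the inter-hemispheric share of
   selected edges, and a two-sided Wilcoxon rank-sum comparison of the
   inter vs intra weight samples (exact by enumeration of the rank-sum
   distribution when $m+n \le 20$ without ties, otherwise normal
   approximation with midranks, tie correction, and continuity
   correction; the method used is recorded).

### Feature-selection scope

Whether the t-filter ran inside or outside the cross-validation loop is a
genuinely open design point.  Both are implemented and recorded in every
result: `pooled` filters once on the full cohort (selection sees all
subjects; scaling and training remain inside the fold), `per_fold`
(default) keeps the filter leakage-safe inside each fold.  A dedicated test
verifies that per-fold selection is unaffected by arbitrary corruption of
the held-out subject.

### Accuracy printing convention

Accuracies are reported as exact fractions plus a truncated integer percent
($\lfloor 100k/n \rfloor$; e.g. 14/22 → 63%, 18/22 → 81%).  Note that
rounding and truncation disagree for some counts (e.g. 6/11 truncates to
54% but rounds to 55%); the truncation convention is applied uniformly.

## Atlas model

The ROI table ships the 90 cerebral AAL region names in standard order
(left/right homologous pairs; 45 per hemisphere, no midline regions).
Hemisphere assignment comes from the name suffix; the barycenter
x-coordinate sign is only a consistency check that warns on mismatch.  The
packaged barycenter coordinates are approximate, mirror-symmetric synthetic
stand-ins for the true centroids — adequate for the sign check, used for
nothing else, and replaceable via `RunConfig.roi_table_path`.

Label-volume operations (ventricle-template masking, per-ROI voxel
averaging) operate on NIfTI-convention grids with 0-based voxel indices and
a voxel-to-MNI-mm affine.  Masking zeroes labels under the ventricle
template; an ROI losing more than half its voxels triggers a warning and an
emptied ROI is an error naming it.  The same modified label volume applies
to every subject.

## Synthetic cohort generator

The generator emulates the *statistical* structure the analysis assumes,
per subject:

- a target correlation matrix with unit diagonal: homotopic (left-right
  homologue) entries $\rho_\text{homo}\,(1 - \kappa\,GS_\text{max}/4)$
  where $GS_\text{max}$ is the subject's worst severity score;
  within-hemisphere, within-community entries $\rho_\text{intra}$
  (communities are five contiguous blocks of nine ROIs per hemisphere);
  all other entries 0.  The matrix is repaired to positive definiteness by
  eigenvalue clipping at $10^{-6}$ and re-normalization to unit diagonal;
  the repair is recorded in provenance.
- latent series: stationary unit-variance AR(1) innovations
  (coefficient 0.3, so the band-pass stage has realistic spectral work to
  do) mixed through the Cholesky factor of the target.
- confounds: six independent AR(1) motion channels; WM and CSF channels
  are noisy copies of one shared latent, and the same latent contaminates
  every ROI additively with per-ROI susceptibility drawn from
  $\lambda \cdot U(0, 2)$.  The heterogeneous susceptibility widens the raw
  correlation distribution, so nuisance regression shrinks both its mean
  and its SD — the quality-control phenomenon the denoising stage is
  designed to produce.  Because WM/CSF carry the same latent, the
  contamination is removable by the regression.
- white measurement noise of SD `noise_sd` on top.

Determinism: per-subject generators are derived from the master seed and a
CRC-32 of the subject id (counter-based split), so changing cohort
composition never reshuffles another subject's draws; identical seeds give
bitwise-identical cohorts.

### Default study conditions

| parameter | default | meaning |
|---|---|---|
| `n_rois` | 90 | AAL cerebral regions |
| `n_volumes` | 116 | 120 acquired − 4 discarded dummy volumes |
| `tr_seconds` | 3.0 | repetition time (s) |
| `rho_intra` | 0.3 | within-hemisphere community correlation |
| `rho_homo` | 0.6 | homotopic correlation in healthy subjects |
| `kappa` | 0.85 | severity attenuation coefficient |
| `confound_loading` | 0.5 | mean shared-confound mixing weight |
| `ar1_coef` | 0.3 | temporal autocorrelation |
| `noise_sd` | 0.4 | measurement noise (signal-SD units) |

The default cohort is 11 patients carrying the packaged per-patient
severity profiles (gait 3,2,2,3,3,2,2,1,1,2,2; cognition
3,1,2,3,2,2,2,2,1,2,3; urinary 0,1,0,3,2,2,0,0,0,4,2) plus 11 asymptomatic
controls.  Cohort size, series length, TR, ROI count, and severity profiles
are the study design; correlation levels, attenuation strength, confound
loading, and noise have no published values — they were fixed once at
magnitudes typical of ROI-level resting-state data (baseline homotopic
correlations around 0.6, raw pseudo-correlation means around 0.15–0.2)
and are deliberately strong enough that the severity signal is recoverable
at $n = 22$; they are calibration knobs of the generator, not estimates.

### What the generator does not emulate

No hemodynamic response, neural-mass dynamics, or voxel-level BOLD
realism; no motion spikes, scanner drift beyond the linear term, or
site effects; severity acts only through $GS_\text{max}$ on homotopic
edges (per-domain edge subsets would be a config extension).  Passing
recovery tests therefore shows that *the pipeline recovers the structure it
assumes when that structure is present at plausible strength* — it is
evidence about the code and the method's statistical behavior, not about
patients.

## Numerical choices

- OLS via `numpy.linalg.lstsq`; orthogonality and oracle comparisons at
  $10^{-8}$ absolute (double-precision headroom).
- Brick-wall filter asserts output spectra are exactly zero outside the
  retained bins; linearity holds to $10^{-8}$.
- Fisher clamp $\varepsilon = 10^{-7}$; correlation matrices symmetrized
  and clipped to $[-1, 1]$ before the transform.
- SVM solving delegates to libsvm (scikit-learn `SVC`, linear kernel);
  primal $w, b$ are exposed.  A 1-D grid-plus-polish minimizer of the
  regularized hinge objective serves as an independent oracle in tests.
- Exact Wilcoxon uses a subset-sum dynamic program over ranks; exact
  binomial tails come from the scipy binomial distribution and are tested
  against full pmf enumeration for $n \le 30$.
- Degenerate cases: zero-variance ROI series raise errors naming the ROI;
  constant feature columns are floored (SD $10^{-12}$) and scaled to 0
  with a log entry; LOOCV folds that lose a training class, or whose
  filter selects nothing, are flagged degenerate and logged, never
  silently dropped.

## Problem sizes

Multi-replicate properties run at the default cohort size (22 subjects,
90 ROIs, 116 volumes): 20 seeds for the denoising QC direction, 50 seeds
for the t-filter type-I error under a null generator ($\kappa = 0$), 50
seeds for severity-signal recovery, 100 seeds for homotopic-edge
detectability.  Because edges within one cohort are mutually correlated,
per-seed selected-edge counts are over-dispersed relative to a binomial;
the type-I property therefore constrains the *mean* selected fraction
across independent seeds to the central 99% binomial band for one cohort's
4,005 edges.

## Known limitations

- Voxel-level preprocessing (slice timing, realignment, normalization,
  smoothing, segmentation) is out of scope; inputs begin at ROI series or
  toy label volumes.
- The filter is not bit-equivalent to any specific toolbox implementation.
- Severity classification metrics on 11 patients are extremely coarse
  (one subject = 9 percentage points); their binomial p-values depend on a
  chance level that is genuinely ambiguous for imbalanced one-against-all
  designs, which is why the chance level used is always reported.
- The weight tables come from a full-cohort refit; weights from single
  folds can differ (the per-fold-average flag quantifies this).
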