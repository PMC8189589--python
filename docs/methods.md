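# Methods

## The analysis chain

The pipeline links two voxel modalities measured simultaneously per scan —
a small region-of-interest map (striatal D2/3 receptor availability,
BP_ND) and a whole-brain map (cerebral blood flow, CBF, in ml/100g/min) —
across a cohort of scans, and then links the resulting striatal pattern to
spatial gene expression. The stages, each exposed as library functions and
CLI subcommands:

1. **Map preparation.** CBF is quantified from perfusion-weighted (PW) and
   proton-density (PD) images by the multiplicative pcASL formula

   `CBF = 6000·λ · (1 − e^(−ST/T1t)) · e^(PLD/T1b) / (2·T1b·(1 − e^(−LT/T1b))·ε) · NEX_PW · PW/(SF_PW·PD)`

   with λ = 0.9 (unitless partition coefficient), T1b = 1.6 s (blood T1 at
   3 T), T1t = 1.2 s (grey-matter tissue T1, correcting the PD image's
   partial saturation at saturation time ST = 2 s), labeling efficiency
   ε = 0.6, post-labeling delay PLD = 2.025 s, labeling duration LT =
   1.45 s, and sequence constants SF_PW, NEX_PW. The saturation term is a
   numerator factor, per standard pcASL quantification; the formula is
   linear in PW. Each map is then divided by its within-mask mean (output
   mean exactly 1) so global drug effects and between-subject perfusion
   differences cancel; mean subtraction is available as an option.

2. **Mode of covariation.** Scans × voxels matrices are column-standardized
   and PCA-reduced per modality; CCA on the two score blocks yields the
   first canonical weight pair, solved in closed form by whitening both
   blocks (SVD) and taking the leading singular pair of the whitened cross
   matrix. Standardization and PCA are always estimated on training rows
   only and applied frozen to held-out rows.

3. **Inference.** The cross-validated mode test averages test-set
   first-variate correlations over `n_splits` random 80/20 splits and over
   the PCA grid K ∈ {2,…,10} (a single fixed K is a config switch; the
   full-sample model uses K = 8). The null permutes the brain-modality rows
   under an exchangeability scheme — `free`, or `block`, where a subject's
   two scans are exchanged as an unbreakable unit with another same-size
   block — and repeats the identical procedure; the same splits are reused
   for every permutation, which preserves exactness under the null
   (observed and permuted statistics are exchangeable) while removing
   split-resampling variance from the comparison. Optionally, splits are
   pair-preserving (a subject's scans never straddle the train/test
   boundary). The leave-two-out matching test counts a success when the
   rank order of two held-out scans agrees between modalities; ties count
   as failures. p-values use the add-one estimator (1+b)/(1+m) throughout,
   so no p is ever zero.

4. **Covariation influence.** Per-voxel Pearson correlation with the
   modality's canonical variate; constant voxels get influence 0. The map's
   global sign is tied to the canonical weights (fixed by making the
   largest-magnitude ROI weight positive); negating the weights flips both
   variates and both maps coherently.

5. **Pharmacological challenge.** Per paired subject, drug-minus-placebo
   deltas of the two canonical scores are correlated (Spearman, average
   ranks for ties, two-sided p). A placebo-trained variant refits
   standardization + PCA + CCA on placebo scans only. The subjective-effects
   analysis correlates each scan's mean canonical score with the sum of the
   10 five-point scale items; positive/negative subscales are a config
   option.

6. **Surrogate nulls.** The empirical variogram (half mean squared value
   difference per Euclidean-distance bin; 20 bins to the 25th percentile of
   pairwise distances by default) summarizes spatial autocorrelation.
   Surrogates permute the target values, smooth with a k-nearest-neighbour
   kernel with exponentially decaying weights at each candidate scale (a
   geometric ladder 1, 2, 4, … up to all voxels), select the scale by the
   amplitude-only variogram fit, refine the winner with an amplitude +
   white-noise-nugget fit, and by default remap ranks onto the target's
   sorted values so the value multiset is preserved exactly. Scale
   selection deliberately excludes the nugget: with it, every large scale
   could imitate every small one and targets without spatial structure
   would no longer select minimal smoothing. Network overlap compares each
   network's mean influence against the same statistic over surrogate maps,
   two-sided around the null mean.

7. **Imaging transcriptomics.** Probe-level expression is filtered to
   probes exceeding background noise in ≥ 50% of samples (at-threshold
   probes are kept), collapsed to one probe per gene by highest
   differential stability (mean inter-donor correlation over locations
   common to each donor pair; ties broken by probe id), matched to the
   nearest mask voxel within 3 mm (farther samples dropped), and normalized
   per donor with the scaled robust sigmoid
   `s(x) = 1/(1 + e^{−(x−median)/(IQR/1.35)})`, min-max rescaled to [0,1].
   The 1.35 constant makes IQR/1.35 a normal-consistent spread estimate; a
   zero IQR falls back to a flat 0.5. Normalization is gene-wise across a
   donor's samples by default — gene-wise comparability is what pooling
   across donors requires — with sample-wise normalization available
   (`axis='sample'`); neither mixes donors.

8. **PLS, VIP and enrichment.** A univariate-response NIPALS PLS regresses
   covariation influence at the matched voxels on standardized gene
   expression; with a single response the inner loop is closed-form per
   component (w = X'y/‖X'y‖), making the ~10⁵ fits of the permutation and
   bootstrap loops cheap. Accuracy is the Pearson correlation of pooled
   out-of-fold predictions with the observed response, averaged over 5
   repeats of 5-fold CV and over components 2–10 (the mean over the grid is
   also the permutation statistic). Significance uses permuted responses
   and, more stringently, variogram-matched surrogates of the influence
   map. Gene importance is VIP,
   `VIP_j = sqrt(p · Σ_k SS_k (w_jk/‖w_k‖)² / Σ_k SS_k)` (so Σ VIP² = p),
   stabilized over bootstrap resamples of the samples: z = bootstrap-mean
   VIP / bootstrap SE, ranked descending with ties broken by gene id. The
   default 6 components reflect the best out-of-sample accuracy in the
   motivating application. Median-rank enrichment takes |median rank of set
   members − (n+1)/2| against random same-size draws from the same ranked
   list (midpoint median for even counts; members absent from the list are
   ignored but counted). Ranked gene lists are exported in both orders for
   external GO tooling; GO statistics themselves are out of scope.

## The synthetic cohort

`striacov.synthetic` generates every input with known ground truth. Per
scan, a latent score z ~ N(0,1) — shifted by `drug_shift` (default 0.5) for
drug sessions — expresses itself in both modalities through unit-norm
smooth loading maps a and b:

`log-map = log_amplitude · (γ·z·loading + σ_s·ε + ν·η)`,  map = exp(log-map)

where ε is a smooth Gaussian field with exactly unit marginal voxel
variance (kernel covariance normalized by its diagonal), η is white noise
with sd ν (`voxel_noise_sd`, default 0.2), and the exponential keeps maps
strictly positive so relative-map division is defined. The signal gain
γ = sqrt(ρ/(1−ρ)) and the structured-noise scale σ_s (chosen so the
loading-projection noise variance is exactly 1) plant a population
correlation of ρ (`planted_rho`) between the modal projections a'log-ROI
and b'log-brain, conditional on condition. CCA can legitimately exceed ρ by
combining components to cancel the structured noise — the planted value
caps the projection correlation, not the canonical one.

The smoothing kernel is exponential-decay, `exp(−d/L)` — the same family
the surrogate engine uses — so autocorrelation-aware nulls face noise they
can actually emulate; default correlation lengths are 6 mm for noise and
8 mm for loadings, on 2 mm (ROI) and 4 mm (brain) lattices. Defaults mirror
the motivating study design: 23 paired + 5 single-session subjects = 51
scans (single-session subjects are assigned a condition at random, since
the design does not fix their split), 153 expression samples from 6 donors
over a shared site pool (so differential stability is estimable), a 10-item
1–5 subjective scale shifted by `slope·drug_shift` for drug scans, and a
7-network Voronoi parcellation. Signal genes follow `effect_beta ·
loading-at-sample + noise_sd·N(0,1)`; other genes are pure noise; per-donor
offsets (sd 0.3) give the within-donor normalization something real to
remove. The probe table carries duplicate low-stability probes and
low-background probes so filtering and probe selection are exercised.

What the generator does **not** emulate: registration error, motion,
partial-volume effects, heteroscedastic physiological noise, hemispheric
asymmetries, or realistic gene-gene covariance. Passing tests therefore
demonstrate the statistical machinery — calibration, power against planted
structure, invariances — not robustness to those acquisition artifacts.

## Numerical choices and conventions

- Zero-variance columns standardize to 0 (sd treated as 1).
- PCA via SVD of the train-standardized matrix; component signs fixed by
  making each component's largest-magnitude loading positive. Canonical
  weights are unit-norm with canonical r ≥ 0 by construction; the joint
  sign is fixed on the ROI weight vector.
- Rank-deficient CCA blocks raise (relative singular-value tolerance
  1e−10) rather than returning arbitrary weights.
- The mode-test inner loop exploits the orthogonality of training PCA
  scores: whitening reduces to a diagonal rescaling and the canonical pair
  comes from one small SVD; the test suite asserts bit-level equivalence
  with the general CCA solver.
- One master seed spawns independent per-stage generator streams
  (`numpy.random.Generator.spawn`), so each stage is reproducible in
  isolation and whole runs are bit-identical; results carry the seed, a
  configuration hash and the package version.
- Degenerate inputs error loudly rather than producing NaN: constant
  correlation inputs, empty permutation partners, empty gene-set
  intersections, non-positive PD voxels (named in the error).
- Reduced problem sizes used by the test suite and the acceptance script —
  tens to hundreds of ROI voxels and hundreds to 2,000 brain voxels, with
  100–200 permutations and 500 bootstrap draws at the demo scale — were
  chosen so calibration claims rest on the counts that matter (cohorts,
  permutations, splits), which follow the study design; type-I error and
  planted-effect recovery do not depend on voxel count.

## Known limitations

- Only the first canonical mode is fitted and tested; no sparse or
  regularized CCA.
- Surrogate distances are Euclidean in mm; no geodesic/surface distances.
- The matching test's power depends on how low-rank the structured noise
  is relative to the sample size: with 51 scans the out-of-sample score
  correlation plateaus a little above the planted value, so near-ceiling
  accuracies require smooth (suppressible) noise.
- Enrichment's random sets are drawn from the same ranked list being
  tested (the natural exchangeable null); drawing from a larger background
  list is not implemented.
- GO enrichment and semantic clustering are exports for external services,
  not computations.
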