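# Methods

## Model and procedure

`spotdist` analyzes Visium-style spot data: a hexagonal lattice of 55 µm
capture areas at ~100 µm center spacing, each sampling an admixture of
roughly 10–20 cells. The pipeline has five stages.

**Quality control.** Spot filters run in the order brightness →
minimum-detected-genes → contiguity. The order matters only for the last
step: contiguity operates on the currently retained set, so it must run
after the other spot filters. Brightness is a per-spot mean-luminance
proxy; removal is one-sided (spot removed iff brightness > section mean +
`k`·SD, default `k = 1`) because abnormally *light* areas indicate absent
tissue while dark spots are tissue. Brightness statistics are per section,
since staining intensity varies by slide. The minimum-genes rule retains
spots with ≥ 100 genes at count > 0. The contiguity rule keeps spots whose
hex-connected component (6-neighbor adjacency, size including the spot
itself) has ≥ 200 spots, removing small detached debris. The
probe-specificity filter regresses probe-captured on polyA-captured
pseudobulk per gene (counts-per-million of summed counts per sample, gene
means across samples, log1p; OLS via statsmodels) and flags genes with
absolute residual > 3 residual-SD, two-sided. The log1p scale for the
pseudobulk regression is a package choice and is isolated in
`make_pseudobulk_pairs` so a raw-scale variant can be swapped in.

**Signature scoring.** The UCell-style Mann–Whitney statistic with average
ranks on ties (the standard convention, and critical for sparse counts
where most genes tie at zero), rank ceiling `r_max = 1500` (UCell's
published default; configurable), and a score floor at 0 to keep the
[0, 1] contract.
Signature genes absent from the matrix stay in the set at the capped worst
rank, so a signature is comparable across datasets with different panels.

**Spot classification.** Per section: HIGH iff score ≥ median + 1.5·SD
(sample SD, ddof = 1), LOW iff ≤ median, EXCLUDED between. Thresholds are
computed per individual section, strictly — not pooled across replicate
sections of one tumor — and over QC-surviving spots only. When a section's
score SD is zero the two rules overlap; the HIGH rule is evaluated first,
so all spots are HIGH. This tie-break is arbitrary but documented and
tested.

**Distance modeling.** Distances are exact Euclidean in physical
coordinates divided by the section's nearest-neighbor spacing ("spot
lengths"), not hex-path steps, computed per section from each LOW spot to
its nearest HIGH spot (k-d tree; an all-pairs brute force is the test
oracle); the direction is LOW spots anchored on HIGH regions — the
low-expression tissue is modeled as a function of its distance to the
feature. Sections with no HIGH spot yield infinite
distances and their LOW spots drop out of modeling with a logged warning.
The modeling set is LOW tumor spots (compartment = tumor, pathology class
= cancer) with d ≤ 10. The response is `log1p(count · 10⁴ / spot_total)`,
the field's default expression scale; corrected-count alternatives are
out of scope. Covariates: sample fixed-effect indicators
(reference = lexicographically first sample) and the signature score
detrended on distance per section. The detrending implements the
diffusion adjustment: it keeps the score covariate from absorbing the
distance effect itself, and it is isolated in
`adjust_signature_scores` so alternatives can be swapped. All genes of a
group share one design matrix, so the per-gene fits are a single
least-squares solve with classical coefficient SEs and two-sided t
p-values; this was cross-checked against statsmodels OLS to machine
precision. Genes detected in < 5% of modeling spots are not modeled (OLS
on near-all-zero responses is meaningless; threshold configurable), and
signature genes are never modeled. Degenerate designs (single sample,
constant adjusted score) drop the offending covariate with a logged note.

**Significance and group contrast.** Significant iff Bonferroni-adjusted p
< 0.05 (m = genes tested in the group) AND |β − mean(β)| > 3·SD(β), the
mean/SD over all tested genes of that group. The outlier rule is applied
two-sided because distance-dependent genes occur on both the proximal and
distal side; a strictly one-sided reading could not produce both.
`compare_groups` computes Δ = β_NR − β_R over genes modeled in both groups
(genes modeled in only one group are reported separately, never silently
dropped) and flags |Δ − mean| > 2·SD by default, with a signed upper-tail
variant behind `two_sided=False`.

## Synthetic data generator

There is no published generative model for these data; every simulator
choice below is a package decision, not a claim about any real dataset.

Counts are negative binomial with mean/dispersion parameterization
(`var = mu + mu²/θ`; θ → ∞ is the Poisson limit). For gene g and spot s:

```
log mu = baseline_g + β_g · d(s) + sample_effect(section)
         [+ bump_g if g is a signature gene and s lies in a focus]
```

with d(s) the distance in spot-lengths to the nearest focus spot, capped at
`d_cap = 10` — the same support as the analysis restriction, so truth and
inference live on the same scale. Foci are sampled spot centers dilated to
a radius in spot-lengths. Optional ambient bleed redistributes a fraction
of each spot's *expected* counts uniformly over its lattice neighbors
before sampling — the simplest testable stand-in for spot-to-spot
diffusion — conserving expected totals per gene exactly. Brightness is
Normal(0.45, 0.05) for tissue spots with a 2% light-debris component at
0.85, giving the brightness filter something real to remove. The outermost
lattice ring is labeled stroma/non-cancer so the compartment restriction
is exercised.

Packaged study conditions (`StudyDesign` defaults): 4 single-section
tumors on 33×33 lattices (~1,089 spots) at 100 µm spacing; 300 modeled
genes — 30 at β = +0.08 per spot-length, 30 at −0.08, 240 null — with NB
dispersion θ = 0.5 (strong overdispersion, appropriate for low-bulk UMI
counts); effect-gene baseline log-mean log 20 (distance modeling targets
robustly detected genes), null baselines Normal(log 5, 0.5²); per-section
sample effects Normal(0, 0.3²). The anchoring feature is a 16-gene
signature at baseline log 5 with a +2.5 log-mean bump inside 3 foci of
radius 2.5 spot-lengths per section. The signature is modeled as a
*coherent* program — dispersion θ = 5 across its genes — because that is
what a real transcriptional program looks like at the spot level (its
genes rise together); drawing signature genes independently at θ = 0.5
produces heavy-tailed single-gene spikes that scatter false signature-high
calls across the tissue, which is not the spatial coherence the generator
is meant to emulate. With the coherent signature the HIGH calls coincide
with the planted foci and the estimated distances track truth with slope
≈ 1.

What the generator does **not** emulate: cell-level composition and
deconvolution, H&E images (brightness is a scalar), spatially correlated
noise beyond the planted foci, batch/chemistry effects, and real ambient
diffusion (the bleed model is a uniform one-step kernel). Passing tests
therefore demonstrate correctness of the algorithms and calibration under
the stated noise model — not robustness to every artifact of real tissue.

## Numerical choices and scene sizes

- Sample SD (ddof = 1) everywhere a threshold uses an SD.
- Distance comparisons use a 1e-9 absolute tolerance against brute force;
  rank scores match their counting oracle to 1e-12.
- The null-calibration check uses 20 replicate simulations of the 4-section
  study with all β = 0 (~6,000 pooled p-values); family-wise error is
  compared to 0.05 plus twice its binomial SE.
- Sign recovery and null false-positive rate use 2 replicates of the
  ±0.08 mixture; confidence-interval coverage uses 100 single-gene
  replicates on a reduced scene (2 sections, the signature, one focal gene
  at β = +0.08, 60 genes total) — the per-gene answer is identical to the
  full mixture but the simulation is ~5× cheaper, which keeps the whole
  suite fast.
- The group-difference scene uses 16 tumors (8 responders, 8
  non-responders, one section each) with 10 genes planted at Δβ = 0.1:
  with only 2 tumors per group the delta noise (≈ √2 × coefficient SE)
  leaves the planted difference under the 2·SD rule's own threshold, so a
  cohort-sized scene is the appropriate power level for that check.

## Known limitations

- OLS on log1p-transformed NB counts is slightly attenuating: zeros and
  log1p curvature at small means shrink |β̂| by a few percent, and depth
  normalization couples genes compositionally (planted effects shift the
  library size, biasing other genes' coefficients by ~−0.5 SE in the dense
  ±0.08 mixture). Confidence-interval coverage of the planted value is
  therefore ≈ 90–94% rather than a calibrated 95%. This is a property of
  the published modeling choice, not of its implementation; the
  cross-check against statsmodels rules out solver error.
- The 3·SD coefficient-outlier rule is distribution-relative: when many
  genes carry effects (60 of 300 in the packaged mixture), the coefficient
  SD is dominated by the planted effects and mean + 3·SD exceeds the
  effect size, so the rule flags nothing by construction. Detection
  performance is therefore assessed at the Bonferroni stage; the
  conjunction rule is exercised by direct-rule tests with sparse outliers,
  the regime it is designed for.
- The coefficient mean/SD for the 3·SD rule is computed over all tested
  genes of the group, not over a significance-filtered subset.
- Brightness QC consumes a precomputed scalar; there is no image
  processing. Diffusion correction and normalization methods published
  elsewhere (e.g. count-correction or variance-stabilizing transforms) are
  deliberately not reimplemented.
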