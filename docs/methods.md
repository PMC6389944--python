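# Methods

## The model

`cnvtract` treats CNV penetrance as a continuous exposure. Each subject
carries two scores in percent — `P_Sz` and `P_DD`, the probability that
a carrier of their CNV manifests schizophrenia or intellectual
disability / developmental delay / autism — assigned by lookup from the
bundled per-CNV table (controls score zero on both). The penetrance of
a CNV is the Bayes-rate quantity

    penetrance = 100 · min(1, f_cases · prevalence / f_population),

where `f_cases` is the CNV's carrier rate among affected individuals
and `f_population` its rate in the general population. The prevalence
factor is exposed as an explicit parameter: setting it to 1 reproduces
the bare case/population rate ratio sometimes quoted, but the product
with prevalence is what makes the quantity a probability of manifesting
the phenotype. Scores are clamped at 100 %.

Imaging phenotypes come from three families:

* **shape** — per-bundle means of streamline projection weights on a
  PCA shape basis;
* **tract volume** — traversed-voxel counts × voxel volume (mm³);
* **microstructure** — per-bundle medians of scalar maps (FA, MD, AD,
  RD from the diffusion tensor; R1 and T1 from relaxometry; ICVF, ISOF,
  ODI from the NODDI tissue model).

Each phenotype is regressed on a penetrance score with ordinary least
squares. The covariate policy is fixed: age and gender always; total
brain volume additionally for volumetric phenotypes; the intra-scan
head-motion index additionally for diffusion-derived phenotypes
(everything except R1/T1). Gender enters as a single indicator; there
are no interaction terms. Tests are two-tailed.

## Permutation inference

Within one *family* (one metric across the 19 bundles; all shape
descriptors; all tract volumes) multiple comparisons are corrected with
max-|t| permutation testing under the Freedman–Lane scheme: the
nuisance-only model is fitted, its residuals are row-permuted and added
back to the nuisance fit, the full model is refitted on every permuted
response, and the permutation distribution of the maximum |t| across
the family yields

    p_corr = (1 + #{b : max|t|_b ≥ |t|_obs}) / (B + 1).

Freedman–Lane is the standard exchangeability-respecting choice when
nuisance covariates are present; the `+1` estimator never returns an
exactly-zero p. Corrected p-values are additionally floored at the
parametric p so the `p_corr ≥ p` contract holds even for one-feature
families, where Monte-Carlo noise could otherwise dip below it.
Permutations are drawn from a single seeded generator, making every
p_corr bit-exact reproducible given `(seed, B)`. Rows with a missing
value anywhere in a family are dropped for that family's correction
(complete-case per feature is used for single-feature fits).

Degenerate fits (zero residual variance, e.g. a response equal to the
predictor) are flagged and reported with the smallest representable p
rather than a division by zero.

Three companion analyses probe the dose interpretation:

* **binary contrast** — the same GLM with a carrier/control indicator;
  if effects scale with penetrance, the continuous model attains larger
  |t|;
* **leave-one-CNV-out** — each CNV class's carriers are dropped and the
  change in β̂ and t recorded, exposing single-variant leverage;
* **global PCA** — all imaging variables are z-scored (constant columns
  dropped with a warning; remaining missing cells mean-imputed for the
  decomposition only), decomposed by SVD, and the first
  `min(n_subjects − 2, 34)` component scores tested like any feature.
  Components mix volumetric and diffusion-derived variables, so their
  tests carry all four nuisance covariates. A post-hoc test regresses
  the corpus-callosum body/splenium volume ratio on penetrance; the
  ratio is dimensionless, so TBV is excluded while the motion covariate
  (tract volumes are diffusion-derived) is kept.

The Spearman correlation between `P_Sz` and `P_DD` uses average ranks
for ties, an exact full-enumeration permutation p for n ≤ 10 and the
t-approximation otherwise. Because it is not determinable whether such
a correlation is best reported over all subjects or carriers only, the
pipeline reports both.

## Streamline shape analysis

Streamlines are assumed to be in a common template space (an affine
utility is provided for registration output). Each is re-parameterised
to 30 knots at equal arc length: a natural cubic spline is fitted
through the points against cumulative chord length, arc length is
measured on a 10×-oversampled polyline along the spline, and knots are
placed by inverse interpolation; endpoints are preserved exactly and
inputs with fewer than four points fall back to piecewise-linear
interpolation. Orientation is canonicalised against the anterior axis
(0, 1, 0) — a streamline is reversed when its head→tail displacement
points posterior — with ties broken by the superior then right axes;
closed loops are left unchanged. Knot coordinates are centred on their
centroid and concatenated knot-major `(x1, y1, z1, x2, …)`, a frozen
convention (any consistent order is statistically equivalent).

The PCA basis is fitted on streamlines pooled across all subjects (one
common basis for the cohort). Two retention rules are available:
smallest m reaching a variance target (default 0.95), or a fixed
component count. The pipeline default is the fixed seven-component
basis — the canonical choice, which on whole-brain tractograms carries
~95 % of shape variance. With few, geometrically clean synthetic
bundles the variance rule stops earlier (between-bundle variance
saturates the target before within-bundle modes such as arc amplitude
are included), which is precisely when the fixed count matters.
Eigenvector signs are fixed (largest-|element| positive) so runs are
comparable; descriptor signs remain arbitrary in interpretation.

Weight vectors are clustered with k-means (k-means++ initialisation, 10
restarts, best inertia kept, seeded). The faithful setting is k = 800;
the desk profile uses k = 100, and k is never allowed above
n_streamlines/10. Clusters take the majority bundle label of a labelled
reference set; unlabelled clusters yield "unassigned" streamlines. In
the synthetic pipeline the generator's true labels stand in for the
labelled reference. Per-subject cluster-membership histograms are also
recorded; the per-bundle mean projection weights are the descriptor set
used for testing. A bundle descriptor requires at least 5 contributing
streamlines, otherwise it is marked missing (never zero-filled). The
number of descriptors is therefore configuration-determined
(bundles × components at the defaults).

## Tractometry numerics

Voxel traversal is approximated by dense point sampling: each
streamline is linearly oversampled at steps of a quarter of the
smallest voxel edge, points are mapped to voxels under the
voxel-centre convention (0-based indices; the NIfTI affine maps voxel
centre to mm), and distinct voxels are counted. Halving the step
changes volumes by well under 2 % on smooth bundles, the tolerance at
which the approximation is equivalent to exact segment–box
intersection. A streamline leaving the grid is an error naming the
offending extent.

Medians pool all points of all streamlines in a bundle (not
per-streamline medians of medians — frozen choice) with trilinear
interpolation; up to 10 % of points may fall outside the map (dropped
with a logged count), beyond which the call errors out.

## The synthetic study

The generator reproduces the statistical structure the analysis
assumes, not MRI physics. Defaults are the study conditions:

* **cohort** — 36 subjects: 21 carriers distributed over the twelve CNV
  classes with the real per-CNV counts, 15 controls. Age ~ N(38, 12²)
  years truncated to 18–65, gender Bernoulli with the per-group male
  fractions (14/21 carriers, 6/15 controls), total brain volume ~
  N(1.1·10⁶, (10⁵)²) mm³, motion index half-normal(1). The
  carrier-weighted mean scores are 5.4 % (Sz) and 36.7 % (DD).
* **bundles** — parametric templates in MNI-like mm axes: a dorsal
  cingulum as a long sagittal arc whose superior deflection is the
  amplitude parameter; corpus-callosum genu/splenium as axial arches
  opening anteriorly/posteriorly; the body as a coronal arch; an
  uncinate-like ventral hook. Templates differ in plane and orientation
  (only translation is removed by centring), which is what makes them
  separable by shape alone. The cingulum amplitude is
  a = 15 mm + 0.05 mm/% · P_DD + N(0, 1²) between subjects, with
  isotropic N(0, 1²) mm jitter per point; 50 streamlines of 60 points
  per bundle at the defaults.
* **maps** — 2 mm isotropic grids covering the subject's bundles. The
  whole grid sits at the metric's base value (e.g. ICVF 0.6, FA 0.45);
  inside bundle-mask voxels per-voxel N(0, 0.01²) noise is added, and
  inside the *effect* bundles' voxels the dose term slope · P (default
  ICVF −0.002/%) shifts the mean, truncated to the metric's physical
  range with a warning if the mean itself leaves the range.
* **seeding** — one master seed; per-subject, per-stage streams derive
  from hashing (seed, subject id, stage, template), so any piece can be
  regenerated independently and bit-exactly.

What the generator does **not** emulate: realistic bundle anatomy
beyond topology, crossing-fibre geometry, registration error,
field-dependent artefacts, spatially correlated map noise, or
between-subject variation in bundle *position* (centring removes
translation anyway). Passing tests therefore demonstrate that the
pipeline recovers dose effects of the stated size under honest noise
and nuisance structure — not that it would segment real whole-brain
tractograms, where bundle overlap and shape ambiguity are far harder.
A separate cheap generator produces feature tables directly from the
cohort nuisance model (slope · P + nuisance + noise); it drives the
null-calibration studies where the streamline machinery would only add
runtime, while the recovery studies run the full streamline path.

## Validation studies

* **FWER calibration** — 200 independent null cohorts (all effect
  slopes zero, nuisance structure kept), one 19-feature family each,
  B = 1000: the fraction of cohorts with any `p_corr ≤ 0.05` must fall
  in the 95 % binomial band around 0.05 ([0.02, 0.09]). Measured: 0.05
  at the default seed.
* **effect recovery** — 50 cohorts through the full pipeline at desk
  scale (4 templates, 30 streamlines/bundle, 7 components, k = 40,
  B = 500): the rates at which a dorsal-cingulum shape descriptor and
  the dorsal-cingulum ICVF median reach `p_corr ≤ 0.05` for `P_DD`,
  and the fraction of cohorts where the penetrance model beats the
  binary model on |t|, must all be ≥ 0.8. Measured: 1.0, 1.0, 1.0.
* **segmentation** — a three-bundle fixture, trained on six synthetic
  subjects and evaluated on held-out streamlines from four fresh
  subjects, must reach ≥ 95 % label accuracy. Measured: 1.0.
* **oracles** — PCA against a dense eigendecomposition of the sample
  covariance, k-means against an exhaustive Lloyd iteration from an
  identical initialisation, the GLM against explicit normal equations
  and statsmodels, the permutation correction against an independent
  re-implementation, and Spearman against rank-then-Pearson with
  brute-force permutation enumeration — all within 1e-8 (bit-exact
  where the same seed is shared).

## Design choices and limitations

* Problem sizes in the validation studies (streamlines per bundle,
  cluster counts, permutation counts) are desk-scale choices that keep
  the full suite in minutes; the `paper` profile carries the faithful
  settings (k = 800, B = 5000) for real use.
* The per-voxel map noise model makes bundle medians nearly
  deterministic given the dose (medians average thousands of voxels),
  so microstructure |t| values in the synthetic world are far larger
  than plausible in vivo; the shape route, with subject-level amplitude
  noise, is the realistic-power branch.
* Mean-imputation before the global PCA biases component variances
  downward when missingness is heavy; with the vocabulary-complete
  feature matrix, bundles absent from a dataset appear as dropped
  all-NaN columns instead, which is the intended path.
* The exact-permutation Spearman p enumerates n! permutations and is
  restricted to n ≤ 10.
* `ClusterModel` centroids live in weight space; transferring a trained
  segmentation to new data assumes the same shape basis and template
  space.
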