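# cnvtract

Penetrance-weighted tractometry for cohorts carrying neuropsychiatric
risk copy-number variants (CNVs).

Rare CNVs (22q11.2, 15q11.2, 1q21.1, 16p11.2, 17q12, 3q29, NRXN1, …)
are among the most penetrant genetic risk factors for schizophrenia and
developmental delay, but each variant is so rare that per-CNV imaging
studies stay underpowered. `cnvtract` implements the alternative design:
pool carriers of *different* CNVs and regress white-matter imaging
phenotypes on each variant's **penetrance** — the probability that a
carrier manifests the phenotype,

```
P(disease | CNV) = P(CNV | disease) · P(disease) / P(CNV),
```

used as a continuous dose score per subject (`P_Sz` for schizophrenia,
`P_DD` for intellectual disability / developmental delay / autism, in
percent). The package is aimed at imaging-genetics groups who have
tractograms and scalar microstructure maps per subject and want the
full phenotyping + inference chain, and at methodologists who want the
statistical machinery (max-|t| permutation FWER control with nuisance
covariates) with a calibrated synthetic testbed.

## What it computes

**Streamline shape descriptors.** Each tractography streamline is
re-parameterised to 30 knots at equal arc length along a natural cubic
spline, canonically oriented, centred at the origin and flattened to a
90-vector. PCA on the pooled vectors gives an orthonormal shape basis
(the canonical analysis keeps the first seven eigenvectors, ~95 % of
shape variance); k-means (faithful setting *k* = 800) clusters the
projection weights; clusters are mapped to 19 anatomical bundles
(bilateral arcuate, uncinate, ILF, SLF, IFOF, dorsal and
parahippocampal cingulum, fornix branches, corpus-callosum
splenium/body/genu) from a labelled reference set. A subject's shape
descriptor for bundle *b*, component *j* is the mean projection weight
of their bundle-*b* streamlines on component *j*; descriptor signs are
arbitrary up to eigenvector orientation.

**Tractometry.** Bundle volume = (distinct voxels traversed by the
bundle's streamlines) × voxel volume; per scalar map (FA, MD, AD, RD,
R1, T1, ICVF, ISOF, ODI) the bundle median of trilinearly interpolated
values at every streamline point. With 19 bundles and 9 metrics plus
volume this is the 19 × 10 = 190-column microstructure/volume block of
the feature matrix.

**Statistics.** Every feature is tested with OLS:

```
y = β0 + β1·P + β2·age + β3·gender [+ β4·TBV] [+ β5·motion] + ε
```

(total brain volume for volumetric features, head motion for
diffusion-derived features). Family-wise error within a feature family
(one metric across bundles; all shape descriptors; tract volumes) is
controlled by Freedman–Lane max-|t| permutation:
`p_corr = (1 + #{b : max|t|_b ≥ |t|_obs}) / (B + 1)`, B = 5000 at the
faithful setting. The same features are re-tested with a binary
carrier/control contrast (the dose model should win if effects scale
with penetrance), with leave-one-CNV-out sensitivity, a global PCA of
all imaging variables with per-component tests, and a post-hoc corpus
callosum body/splenium volume-ratio test.

**Synthetic cohort generator.** A drop-in data source replicating the
study design: 36 subjects (21 carriers with the real per-CNV counts, 15
controls), parametric bundle templates whose cingulum arc amplitude
grows 0.05 mm per penetrance-percent, ICVF maps that lose 0.002 per
percent inside the cingulum, and age/gender/TBV/motion nuisance
structure. Everything derives from one master seed.

## Worked example

`examples/06_association_stats.py` simulates a 19-feature family where
only `feat1` carries a penetrance effect (slope 0.06 per percent) and
corrects across the family (B = 2000):

```
feature   beta      t        p        p_corr
feat1    +0.0578   +6.40  3.92e-07 0.0005
feat3    +0.0110   +1.89  6.85e-02 0.7471
feat19   -0.0099   -1.75  8.92e-02 0.8371

family-wise significant: ['feat1']
feat1 |t|: penetrance 6.40 vs binary 3.22
Spearman rho(P_Sz, P_DD) = 0.93 (p = 1.4e-16, n = 36)
```

Only the feature with a real dose effect survives correction; the
continuous penetrance model out-scores the binary carrier model
(|t| 6.40 vs 3.22), and the two penetrance scores are strongly rank-
correlated across the cohort — all three hallmarks of the design. The
other examples walk through streamline featurisation, the shape model,
tractometry, the penetrance table (carrier-weighted means 5.4 % Sz /
36.7 % DD) and the end-to-end pipeline, which recovers the injected
cingulum curvature and ICVF effects:

```
                 feature predictor       t            p   p_corr
  cingulum_dorsal_L|ICVF      P_DD -412.33 1.57e-59 0.002
cingulum_dorsal_L|shape4      P_DD   -6.52 2.78e-07 0.002
```

## Command line

```
cnvtract run      --outdir out --seed 1 --profile desk   # full pipeline
cnvtract simulate --outdir sim --seed 1                  # cohort + TCK + NIfTI
cnvtract stats    --features out/features.tsv --cohort out/cohort.csv \
                  --outdir restats
```

Profiles: `desk` (k = 100 clusters, B = 1000, minutes on one CPU) and
`paper` (k = 800, B = 5000). Every run writes a `manifest.json` with the
config snapshot, seed and SHA-256 digests of all outputs; rerunning with
the same seed reproduces the digests bit-exactly.

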