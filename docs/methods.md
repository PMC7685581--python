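# Methods

## Scope and data model

The package analyses three co-registered tables over the same samples:
an OTU abundance matrix (counts or relative, samples in rows
everywhere in memory), a geochemistry matrix with per-cell status
(`measured` / `below_detection_limit` / `missing`), and a functional
layer derived from a taxon→KO annotation database plus a pathway→KO
catalog. The catalog is an input: the package ships no curated pathway
list, because pathway definitions and annotation content are
database-version-dependent; the synthetic generator provides a demo
catalog (seven hydrocarbon-degradation pathways plus housekeeping
pathways) for testing.

## Diversity

Shannon entropy is reported in nats; inverse Simpson as 1/Σp². Both
renormalize the input vector before computing, so tables truncated at
a display cutoff (entries below e.g. 0.05 % hidden, rows summing to
< 1) are handled under a declared convention. `diversity_variants`
additionally reports the *truncated* convention (formulas applied to
the shown values as-is) and the discrepancy between the two, since
published index values computed before truncation cannot be recovered
exactly from a truncated table. Reports round only at write time:
Shannon to 1 decimal, inverse Simpson to 2, matching the print
precision of field survey tables.

Degenerate inputs (empty or all-zero samples) raise with the sample id
rather than returning NaN.

## Pathway completeness

`completeness(i, P) = |K(i) ∩ K(P)| / |K(P)|` where K(i) is the union
of KO sets over taxa detected in sample *i*. Assumptions made explicit:

* **Detection** defaults to any nonzero relative abundance
  (`min_rel_abund = 0`); the pipeline default raises this to 5·10⁻⁴
  (≈ 10 reads at a 20 k depth) to suppress spurious singleton taxa.
* **Matching rank** defaults to genus: 16S OTUs rarely resolve species,
  and annotation databases keyed at species level are served by the
  species→genus→family fallback chain. Labels match exactly after
  lowercasing with rank prefixes kept; no fuzzy matching.
* The statistic is presence/absence — abundance never weights a taxon's
  KO contribution beyond the detection threshold.

Every value is an exact rational with the pathway KO-set size as
denominator; the matrix is deterministic and invariant to input row or
column order. Unmatched taxa are tallied per sample in a match report
instead of failing the run.

## Ordination and significance

Community data are Hellinger-transformed (square root of relative
abundance) before Euclidean-geometry methods. Geochemical variables
are heterogeneous in units (°C, pH units, mV, g/l, µg/l), so the
default preparation is log10 on concentration variables followed by
z-scoring. Concentration columns that are strictly positive are logged
as-is; if zeros are present (e.g. censored cells substituted by
policy), half the smallest positive value is added first. The
completeness block is centered but not scaled — its columns already
share the [0, 1] scale, and scaling would inflate near-constant
pathways. All of this is configurable; the `reproduce` sweep runs a
declared grid of variants (community transform × geochem scaling ×
missingness policy) precisely because published analyses rarely state
these choices.

2B-PLS computes the SVD of C = XᵀY/(n−1) on the prepared blocks.
Numerical conventions, chosen for byte-stable output across linear
algebra backends:

* singular values non-negative and sorted;
* each (u_k, v_k) pair is flipped jointly so the largest-|entry| of
  u_k is positive — this leaves d_k unchanged, and because
  cov(Xu_k, Yv_k) = d_k ≥ 0 on centered blocks, the axis correlations
  are automatically non-negative;
* PCA components are flipped so the largest-|loading| is positive.

The permutation test permutes rows of Y only (equivalent under
exchangeability to permuting either block), recomputes the
decomposition each draw, counts ties as exceeding the observed
statistic, and uses the add-one estimator p = (1 + k)/(1 + n_perm) —
unbiasedly conservative, with minimum attainable p of 1/(n_perm + 1);
resolving p < 10⁻⁴ therefore requires ≥ 10⁴ permutations. The default
statistic is the axis score correlation; the singular value (score
covariance) is available and tends to have more power when the
correlation is saturated. The two PLS analyses of a pipeline run are
reported with raw p-values and their permutation counts; no
multiple-testing correction is applied.

Left-censored geochemistry cells enter the analysis at their
policy-substituted value (0, DL/2 or NaN); truly missing cells are
median-imputed by default or rejected under the `fail` policy.
Variables with zero variance are dropped with a warning when scaling.

## Synthetic data generator

One standard-normal latent gradient z couples all blocks (rank-1
coupling): geochemistry g_ij = a_j·κ·z_i + σ_j ε_ij mapped to natural
scales (linear for T/pH/Eh with clipping to physical ranges, log-normal
for concentrations, with per-variable detection limits producing
`b.d.l.` cells and a small fraction of `n.d.` cells); community
log-abundance λ_ik = μ_k + b_k·κ·z_i + η_ik with per-sample softmax and
multinomial read counts (Dirichlet-multinomial overdispersion
optional); a configurable fraction of taxa are "degraders" with
positive gradient response whose annotations carry sparse random
slices of the degradation-pathway KOs, so completeness co-varies with
z only through which taxa are detected.

Default conditions mirror the target study system: 10 samples,
200 taxa, 20 geochemical variables, read depths 12,000–29,000,
κ = 0.9. The base log-abundance spread (SD 2.5) was set so per-sample
OTU richness falls in the surveyed 55–206 band at those depths. The
per-degrader KO inclusion probability (0.10) keeps single samples from
saturating a pathway, so the completeness gradient is graded rather
than binary; the background (non-degrader) inclusion probability
(0.005) keeps pooled background taxa from completing degradation
pathways on their own.

The ground-truth axis correlation ρ stored with each dataset is the
population axis-1 score correlation of the *latent linear* blocks,

    ρ = κ²·|a||b| / sqrt((κ²|a|² + s_x²)(κ²|b|² + s_y²)),

with s_x² = Σ a_j²σ_j²/|a|², s_y² the taxon noise variance. It is
exactly 0 at κ = 0. Pipeline estimates approach ρ only when the
nonlinear observation steps (exp scaling, softmax, multinomial
sampling, Hellinger) are near-linear perturbations, i.e. at low noise;
the recovery checks therefore use a low-noise condition
(taxon noise SD 0.05, geochem noise SD 0.1, fixed depth 3·10⁵, no
missing cells, n = 50).

What the generator does **not** emulate: phylogenetic correlation
among taxa, compositional interactions beyond the softmax, shared KOs
between pathways (catalog KO sets are disjoint), seasonal/spatial
replicate structure, geochemical speciation equilibria, and
sequencing artifacts (chimeras, PCR bias). Tests passing on this
generator demonstrate correctness of the statistics and calibration
of the permutation test under the stated model — not robustness to
those real-data features.

## Problem sizes in the checks

The acceptance-style checks run at desk scale chosen for statistical
stability: the coupled headline run at the default 10-sample condition;
significance and recovery comparisons at n = 50, where the axis
correlation's null bias (overfitting of a 20-variable block on few
samples) is small enough that coupled and decoupled runs separate
cleanly; type-I error over 200 decoupled replicates at 99 permutations
(the add-one estimator makes the nominal rejection probability exactly
0.05 there); 10⁴ permutations wherever a p below 10⁻³ must be
resolved.

## Known limitations

* Completeness inherits every bias of the annotation database; the
  match report quantifies unmatched taxa but cannot correct for
  missing annotations.
* With ~10 samples, 2B-PLS axis correlations are strongly biased
  upward under the null; rely on the permutation p, not on the size of
  r₁, when sample counts are small.
* The truncated-table diversity convention is a reproduction aid; for
  count data, compute indices before any display truncation.
* BIOM support covers the JSON (v1) dense/sparse dialect only.
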