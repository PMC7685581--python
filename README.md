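# thermopath

Linking hot-spring water chemistry to what lives there and what it can
metabolize. `thermopath` is a reusable analysis pipeline for 16S
amplicon surveys of extreme aquatic habitats (hydrothermal "oil site"
pools, acid-sulfate and chloride springs) where a handful of samples
carry three coupled layers of information:

1. **community structure** — an OTU abundance table with Greengenes-style
   taxonomy,
2. **functional potential** — KEGG-pathway completeness inferred from the
   KO (KEGG Orthology) repertoires of the detected taxa, and
3. **geochemistry** — temperature, pH, Eh, mineralization, major ions and
   trace elements, with below-detection-limit (`b.d.l.`) and no-data
   (`n.d.`) censoring.

It is aimed at microbial ecologists who want the standard desk analysis
of such surveys — α diversity, taxonomy-driven functional inference,
and community–environment ordination with permutation significance —
as tested, scriptable code rather than a spreadsheet workflow.

## The statistics at the core

**Pathway completeness.** For sample *i*, let K(i) be the non-redundant
union of KO sets of all taxa detected in that sample (annotation
database lookup at genus level, with optional species→genus→family
fallback). For a pathway P with required KO set K(P),

    completeness(i, P) = |K(i) ∩ K(P)| / |K(P)|  ∈ {0, 1/|K(P)|, …, 1}.

A presence/absence statistic: exact rational values, monotone under
addition of taxa or KOs.

**Two-block PLS (2B-PLS / PLS-SVD).** For column-centered blocks X
(n × p geochemistry) and Y (n × q community or completeness), the paired
axes (u_k, v_k) are the singular vectors of the cross-covariance
C = XᵀY/(n−1); d_k = u_kᵀ C v_k is the score covariance and
r_k = corr(X u_k, Y v_k) the axis correlation. Axis significance comes
from a permutation test on the rows of Y with the add-one estimator
p = (1 + #{perm ≥ obs}) / (1 + n_perm). Diversity indices are Shannon
entropy H = −Σ p ln p (nats) and inverse Simpson 1/Σp².

A seeded synthetic-data generator draws geochemistry, OTU counts and
annotations from a single latent environmental gradient with known
coupling strength κ and analytic ground-truth axis correlation, so
every stage of the pipeline is testable offline with no database
downloads.

## Worked example

```python
import thermopath as tp

cfg = tp.RunConfig(seed=1, outdir="demo", simulate={}, n_perm=999)
bundle = tp.run_pipeline(cfg)

t, c = bundle.pls_taxa, bundle.pls_completeness
print(f"taxa~geochem    axis-1 r = {t['axis_correlations'][0]:.3f}  (p = {t['p_value_axis1']:.4g})")
print(f"function~geochem axis-1 r = {c['axis_correlations'][0]:.3f}  (p = {c['p_value_axis1']:.4g})")
print(f"pathways with mean completeness >= 0.9: {bundle.summary['n_high_completeness_pathways']}")
print(bundle.diversity.round(2).head(3))
```

prints

```
taxa~geochem    axis-1 r = 0.974  (p = 0.002)
function~geochem axis-1 r = 0.914  (p = 0.016)
pathways with mean completeness >= 0.9: 4
        richness  shannon  inverse_simpson
sample
S01          148     3.54            19.65
S02          154     2.80             6.28
S03          144     3.27            11.85
```

The run simulated a 10-sample hot-spring survey with strong
environment–community coupling (κ = 0.9), then measured it back: both
blocks correlate with the geochemical axis (r = 0.97 for taxonomic
composition, r = 0.91 for degradation-pathway completeness, both
significant under 999 row permutations), four pathways exceed 90 % mean
completeness, and per-sample diversity sits in the range typical of
such habitats (Shannon ≈ 2.8–3.5 nats). All files (diversity TSV,
completeness matrix, match report, PLS scores, `summary.json`,
`run.log`) land in `demo/`.

The same stages exist as a CLI (`thermopath simulate | diversity |
completeness | pls | run | reproduce`); `thermopath reproduce` runs
the taxa~geochemistry analysis over a declared grid of preprocessing
variants on user-supplied supplement-shaped tables.

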