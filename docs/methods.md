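# Methods

This document records the statistical definitions, the synthetic cohort
generator's model and parameter choices, and numerical conventions.

## 1. Repertoire statistics

**Clonotype identity.** A clonotype is the triple (v_call, j_call,
junction).  Rows of an AIRR Rearrangement TSV sharing an identity are
merged by summing `duplicate_count`; rows with missing identity fields
or non-positive counts are dropped with a warning.

**Diversity.** With clone proportions *pᵢ* and Simpson concentration
λ = Σ pᵢ², three variants are supported: `simpson_concentration` (λ),
`gini_simpson` (1 − λ, the default), and `inverse_simpson` (1/λ).
Gini–Simpson is 0 for a monoclonal sample and 1 − 1/K for K equally
abundant clones, and can only decrease when two clones are merged.

**Paired change.** DI logFC = log2((DI_post + ε)/(DI_pre + ε)) with
ε = 1e-6.  The ε keeps monoclonal samples finite; with the default
variant its influence is negligible away from DI ≈ 0.  Negative DI
logFC is reported as clonal expansion.

**Top-N clone mass.** The N largest post-treatment clones (count
descending, ties broken by lexicographic identity, using a stable sort)
define a clone set; `mass_post` is their summed post proportion and
`mass_pre` the summed pre proportion of the same identities (0 for
clones absent pre-treatment).

## 2. Expression statistics

**Normalization.** Per cell: ln(1 + 10⁴ · x / Σx).  This is scale-free
per cell, so any cell subset can be normalized independently with
identical results — used to speed up pDC-only analyses.

**Cluster proportions.** Per-sample cluster fractions over a fixed
cluster universe.  Paired change uses a Haldane-style continuity
correction, log2[((n_post + ½)/(N_post + ½K)) / ((n_pre + ½)/(N_pre +
½K))], which stays finite when a cluster is empty in one sample.  Note
that when the two samples have different total cell counts the
correction terms do not cancel, so a cluster empty in both samples has
a logFC of exactly 0 only at equal totals.

**Pseudobulk and disturbance.** A stratum (patient × timepoint ×
cluster) with at least `min_cells` = 3 cells yields a per-gene mean of
normalized expression; smaller strata are reported as missing rather
than estimated.  The per-gene log fold change is log2((m_post +
c)/(m_pre + c)) with pseudocount c = 0.01, restricted by default to
genes detected (nonzero mean) in either timepoint.  The disturbance
score is the mean |log2FC| over those genes: a nonnegative summary of
how much a cluster's transcriptional state moved, regardless of
direction.

**Pathway score.** Per cell, the arithmetic mean of normalized
expression over a gene set's genes present in the matrix.

**Cluster annotation.** Per marker set, mean pathway score per cluster
is z-scored across clusters (degenerate, zero-variance sets dropped);
each cluster is labeled by its argmax set with deterministic
(sorted-label) tie-breaking.

## 3. Preranked GSEA

Genes are ranked by descending score (ties lexicographic).  The
enrichment score is the signed maximal deviation of a running sum that
increases by |s|^p / Σ_hits |s|^p at set members (weight p = 1 by
default; p = 0 recovers the classic unweighted KS walk) and decreases
by 1/(N − N_hits) at non-members, so ES ∈ [−1, 1].  The null is
gene-set permutation: random same-size gene sets drawn without
replacement from the ranked list, cached per set size.  The p-value is
the add-one estimator (1 + #{|ES_null| ≥ |ES|})/(n_perm + 1), never 0;
NES divides ES by the mean |null ES| of the same sign; FDR across
tested sets is Benjamini–Hochberg (statsmodels).  Everything is
reproducible given the seed.

## 4. Linking and exact inference

Spearman's r is Pearson's correlation of mid-ranks.  For n ≤ 9 the
two-sided p-value is exact: all n! permutations of one rank vector are
enumerated and permutations with |r| ≥ |r_obs| counted (the identity
permutation always counts, so p ≥ 1/n!).  For larger n a t
approximation with n − 2 degrees of freedom is used; the two agree to
within ~0.02 on average at the crossover.  The cohort-level linking
step correlates per-patient DI logFC against a per-patient activation
scalar, requiring at least 3 matched patients and reporting exclusions.

## 5. Synthetic cohort generator

**Repertoire arm.** Each patient has a personal clone universe of
`n_clones` = 2,000 identities with Zipf(`zipf_exponent` = 1.2)
baseline probabilities; pre and post samples are independent
multinomial draws of `reads_per_sample` = 50,000 reads.  Responders
have the top `expansion_top_fraction` = 1% of clones up-weighted by
`expansion_factor` γ = 5 in the post draw (weights renormalized).
These scales give per-sample diversity estimates whose sampling noise
is small relative to the planted effect: the planted expansion drives
DI logFC negative in ≈100% of responder replicates, while a γ = 1 null
centers within ±0.05 of zero.

**Expression arm.** Counts are negative-binomial via a gamma–Poisson
mixture (dispersion θ = 2, variance μ + μ²/θ) around per-cell expected
proportions from a per-cluster gene-weight model (gamma(0.5) baseline
weights; 8 marker genes per cluster up-weighted ×8; the 40-gene
interferon module given a baseline floor so it is detectable
everywhere).  Cluster assignments are multinomial over Dirichlet-drawn
proportions with baseline pseudo-counts (88, 72, 56, 48, 40, 32, 24,
20) over 8 clusters; responders shift the pDC cluster (index 7) log-odds
by `pdc_shift` = 1, multiply the interferon module by
2^`t1irg_effect` (= ×2) in the innate clusters (3, 5, 7), and add a
per-gene logFC drawn N(0, `disturbance_sd` = 0.7²).  Defaults of 800
cells/sample and 2,000 counts/cell were chosen during generator design
so the smallest cluster (pDC, ≈5% ≈ 40 cells) clears the pseudobulk
noise floor; with the earlier draft values (500 cells, looser Dirichlet,
sd 0.4) the planted coupling was not recoverable, and these scales were
fixed *before* the acceptance thresholds were frozen.

**Coupling.** Each responder draws one strength s ~ N(1, 0.2²) clipped
to [0.25, 2]; realized effects are γ_eff = 1 + (γ − 1)s and s-scaled
pdc_shift, t1irg_effect and disturbance_sd, so expansion and activation
co-vary across patients — the planted "link".  With
`couple_effects=False` the repertoire and expression arms draw
*independent* responder flags and strengths, giving a true null for the
linking test (empirical rejection ≈ 5% at α = 0.05).

**Reproducibility.** All draws come from
`numpy.random.SeedSequence(seed, spawn_key=(stream, patient))`
substreams (separate streams for gene model, cohort-level draws,
repertoire, expression, clone identities), so patients are independent
and any patient can be re-simulated alone, bit-identically.

## 6. Pipeline determinism

Report tables are written with `float_format="%.10g"`, fixed column
order and fixed row sort; `manifest.json` lists each file's SHA-256.
No timestamps or environment details enter the bundle, so equal seeds
give byte-identical bundles.

## 7. What the generator does and does not emulate

It emulates: heavy-tailed clone-size distributions, multinomial
sequencing sampling, overdispersed UMI counts, compositional cluster
structure, and patient-level effect-size heterogeneity.  It does not
emulate: V/J usage biases, junction sequence biology (identities are
arbitrary labels), batch effects, ambient RNA or doublets, cell-type
specific library sizes, or longitudinal kinetics beyond a single
pre/post pair.  Conclusions about method behavior on real data should
account for those gaps.

## 8. Numerical conventions

- ε = 1e-6 in DI logFC; pseudocount 0.01 in gene logFC; Haldane ½ in
  proportion logFC.
- The GSEA running sum is clipped to [−1, 1] to absorb cumsum rounding.
- Permutation-null comparisons use a 1e-12 slack so ties in |ES| count
  as exceedances.
- Exact Spearman enumeration is limited to n ≤ 9 (9! = 362,880
  permutations, vectorized).
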