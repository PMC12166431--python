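# Methods

`deathmark` predicts suppressors of a drug-induced cell-death pathway by
merging two independent lines of evidence per gene and ranking the merged
score. This note records the models, the defaults and why, the numerical
conventions, and what the synthetic studies do and do not establish.

## The two evidence arms

**Correlation arm.** Vulnerability of each cell line to a death inducer is
summarised by the *sensitivity AUC*: viability (% of untreated control) is
measured over an increasing log10 concentration series, and

    AUC = 100 − (trapezoid of viability over log10 concentration) / (log-range),

so 0 = fully resistant, 100 = fully sensitive. The AUC is computed on the
observed points, not on a fitted curve, which makes it invariant to
concentration-unit changes and to row order; values outside [0, 100] (possible
with viability > 100% noise) are clipped with a warning. Dose-response curves
are additionally fitted with a fixed-asymptote four-parameter logistic
v(x) = 100 / (1 + exp(b·(x − e))) (asymptotes pinned at 0 and 100), giving the
IC50 = 10^e used to choose treatment doses. The fit is plain least squares
started at b₀ = 1, e₀ = median(log concentration); with both asymptotes fixed
the problem is 2-dimensional and the start is uncritical (noise-free recovery
to 1e−6 over b ∈ [0.3, 5] is part of the suite). Replicates are fitted
separately and AUCs are computed per replicate on raw points, then averaged
per cell line.

Each gene's expression (log-TPM) and CRISPR gene effect ("depscore",
≈ 0 non-essential to ≈ −1 essential) across cell lines is Pearson-correlated
with the AUCs on pairwise-complete observations, per gene. Genes with fewer
than 3 complete pairs or zero variance are omitted rather than errored;
per-gene pairwise deletion tolerates the sparse coverage of essentiality
screens better than casewise deletion across the whole matrix. A gene whose
high expression (or strong essentiality) protects cells from the inducer
shows a *negative* correlation with the sensitivity AUC.

**Similarity arm.** Drug-vs-vehicle RNA-seq contrasts give per-gene moderated
t statistics (the "drug response signature"). Each public consensus-shRNA
knockdown signature contributes two gene sets — its top-20 and bottom-20
genes — which are scored against each drug signature with a camera-style
directional competitive test: for m set genes among n, a pooled-variance
two-sample t of set mean vs rest, with the set variance term inflated by
VIF = 1 + (m − 1)ρ to allow for inter-gene correlation (ρ defaults to 0.01,
the conventional camera default; at ρ = 0 the test is exactly the textbook
pooled t-test, which the suite asserts to 1e−10). The two-sided p is folded
into a signed score, +(−log10 p) for Up and −(−log10 p) for Down.

Scores are aggregated per knockdown gene: maximum over the 4–9 store cell
lines (separately for up and down sets, no imputation for missing cells),
competition-ranked across all knockdown genes (ascending min-rank, ties share
the smallest rank), and combined as

    total = rank(up score) − rank(down score)  ∈ [−(N−1), N−1].

A knockdown that mimics the drug response has a strongly Up-enriched up-set
and Down-enriched down-set, hence a large **positive** total. The polarity is
configurable (`similarity_best: positive|negative`) because the opposite sign
convention also circulates; the positive default is what planted-truth
recovery on synthetic data confirms, and every downstream rank direction keys
off this flag.

## Differential expression

Counts are normalised to offset log2-CPM, log2((c + 0.5)/(L + 1) · 10⁶), and
genes kept when CPM > 1 in at least `min_cpm_samples` (default 3) samples —
conventional defaults. Contrasts (always drug − vehicle within a cell line)
are estimated by per-gene OLS on a group-means design; residual variances are
shrunk by inverse-chi-square empirical-Bayes moderation with hyperparameters
(d0, s0²) estimated by method of moments on the log variances (digamma /
trigamma matching with Newton inversion of the trigamma), and the moderated t
uses d0 + residual df. Precision weights for the mean-variance trend are
deliberately not implemented; the shrinkage-only moderated t is guarded by a
null-calibration property (on null data the nominal two-sided 0.05 test
rejects at 0.05 ± 0.02), which is the behaviour the enrichment stage actually
depends on.

## Preranked GSEA (validation)

The pan-cancer validation correlates every gene's expression with the
inducers' AUCs, then tests the candidate set against this ranking with a
weighted Kolmogorov–Smirnov enrichment score (weight exponent 1, increments ∝
|value|). The hit curve is normalised by the last cumulative weight so it ends
exactly at 1; ES is the signed maximum deviation, with magnitude ties broken
toward the earlier position in the walk (a convention that matters only in
degenerate equal-weight cases). P-values come from gene-label permutation with
a mandatory seed and the (b + 1)/(n_perm + 1) estimator, n_perm = 1000 by
default. A set of true protectors is expected in the negative-correlation
tail (ES < 0).

## Rank aggregation ("best predictors")

Per gene: family means (expression correlations, depscore correlations,
similarity totals), competition rank of each mean, the elementwise max of the
two correlation ranks, the mean of that with the similarity rank, and a final
competition rank of the mean. **Orientation:** every family rank is oriented
so the strongest candidate gets the *highest* rank — most negative mean r for
the correlation families, best similarity under the polarity flag. With this
single orientation the max in the correlation step reads as "the better of
the two correlation arms", the top of the list is literally the genes with the
highest final rank, and output is sorted strongest-first (ties broken by mean
rank, then gene symbol, for byte-stable output). Genes with no similarity
value are dropped before ranking. The larger of the two mean correlations is
reported as `biggest_r` but never used for ranking. Rank means (not score
means) make the aggregation scale-free across heterogeneous predictors.

## Nearest-neighbours ranking

The standardized predictor matrix (complete rows only, sorted by gene;
columns to zero mean/unit variance, sd with n−1) is embedded in 2-D with UMAP
(min_dist 0.05, n_neighbors 15, fixed random_state — bit-identical across
runs at a fixed seed and input order). Candidates are the 75 genes nearest a
key pathway gene by Euclidean distance, ties at the cutoff all kept. A
neighbourhood *radius* is deliberately not used — selection is top-n only.
When too few complete rows exist for a stable UMAP (< 15), a PCA + k-means
fallback provides coordinates and cluster labels with the same determinism
contract.

## Novelty filter

Candidate lists are cross-checked against PubMed citation counts for
"GENE AND term" queries (live Entrez client with rate limiting and backoff,
or an offline JSON fixture; counts are never fabricated — absent fixture
genes count 0 with a warning). By default any pathway-term citation
disqualifies a gene (`citation_max` 0), filtering *after* truncation to the
top 75; the mean-similarity text-mining route forwards the top 100. Both
choices are configurable.

## Consensus weights (outlier drug signatures)

Pairwise Pearson correlations among the contrasts' fold-change vectors, with
self- and negative correlations zeroed; each signature's weight is its row sum
as a percent of the grand total (weights always sum to 100). Signatures below
the threshold (default 9%) are flagged and, when the filter is enabled,
removed *before* the max-over-cells aggregation, so an outlier response never
contributes a spurious maximum.

## Synthetic studies and what they show

The generator emulates all four inputs with planted ground truth. Default
conditions: 2000 genes, 20 cell lines, 2 inducers, 8 doses (3 replicates,
viability noise σ = 3%), 500 knockdown genes over 4–9 store cell lines,
10 planted suppressors, 10 correlation-only and 10 signature-only decoys,
negative-binomial counts with dispersion 0.1 and 3 replicates per condition
in 2 profiled cell lines. A per-cell-line latent sensitivity drives every
inducer's EC50, making inducer AUCs concordant, as for co-pathway death
inducers. Planted suppressors couple all three channels: expression
= a − 1.5·AUC_z + N(0, 0.4) and gene effect = c − 0.25·AUC_z + N(0, 0.1)
(clipped to [−1.5, 0.5]), knockdown signatures = 0.8·D + √(1−0.8²)·noise
where D is the latent drug-response direction also injected into the counts.
Decoys carry one channel only and exercise the aggregation. All draws flow
from one master seed through spawned child streams; a manifest reproduces
every emitted file byte for byte (GCTX written with HDF5 timestamps
disabled).

Known, accepted artefacts: viability noise is truncated at 0, which biases
the AUC of very sensitive lines slightly downward (well under a percentage
point at σ = 3); and background genes are independent, so the generator does
not emulate pan-cancer co-expression structure, batch effects, or lineage
confounding. Passing the planted-recovery checks therefore demonstrates that
the machinery ranks coupled-evidence genes above single-channel decoys and
noise at realistic effect sizes — not that real screens are free of
confounded hits.

Under the default conditions the pipeline places ≥ 8 of 10 planted
suppressors in the top 75 of both ranking methods, while the unplanted
("null") scenario yields a final ranking indistinguishable from uniform
(KS test) and no strong correlations. The problem sizes above are also the
sizes used by the test suite and the acceptance script; the worked-example
tables bundled with the package are small published-style examples (one
8-dose response series, a 7-line AUC table, a 7-gene predictor matrix) used
to pin exact values.

## Numerical conventions and degenerate inputs

- Competition ranks are scipy `rankdata(method="min")`; integer-valued.
- Top/bottom-k extraction breaks score ties by ascending gene id, so
  extraction on a negated signature swaps the sets exactly.
- Camera requires 2 ≤ m < n; sets below the overlap floor are recorded as
  missing, never scored zero. P-values are floored at the smallest positive
  double before the signed-log transform.
- Constant viability, constant fold-change vectors, zero library sizes,
  empty cell-line intersections and rank-deficient designs are hard errors
  naming the offending record; sparse or zero-variance genes in the
  correlation step are silently omitted (by design, they carry no signal).
- The logistic fit rejects inputs with fewer than 3 distinct concentrations;
  AUC needs 2.
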