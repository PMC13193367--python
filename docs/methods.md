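# Methods

This note documents the models, defaults and numerical choices behind
`ajstrat`, and what the synthetic cohort generator does and does not
emulate.

## Correlation network

Pearson correlations are computed per protein pair over
pairwise-complete observations. Pairs sharing fewer than
`corr_min_pairs = 10` samples, and pairs involving a protein with zero
variance on the shared samples, are undefined and excluded downstream
(the cohort's missingness mechanism is unknown, so a minimum-support
guard is safer than imputation). The diagonal is forced to 1 and the
matrix is checked symmetric to 1e-12.

Sparsification is the analysis' two-step filter: (1) remove pairs with
|r| < `corr_min_abs` (default 0.4); (2) each node marks its `top_k`
(default 3) strongest surviving edges by |r|, ties broken by
lexicographic partner id for determinism, and an edge is retained iff
at least one endpoint marks it. This *union* reading of "each protein
retains its three strongest correlations" preserves hub structure (a
protein can keep more than 3 edges by being ranked by many partners);
the stricter *mutual* rule is available (`topk_rule="mutual"`). The
filter is idempotent: re-applying it to its own output changes nothing.
Edges store signed r; clustering consumes |r| since the flow
simulation requires non-negative similarities (dropping negative edges
instead is a config switch, `use_abs_weights=False`).

## Markov clustering

MCL is implemented from scratch on sparse matrices. The
column-stochastic matrix starts from |r| plus a self-loop of weight
`mcl_self_loop = 1.0` per node; each iteration is expansion (matrix
power, `mcl_expansion = 2`), inflation (elementwise power
`mcl_inflation = 2.0`, then column renormalization), and pruning of
entries below `mcl_prune_below = 1e-5` (then renormalization). The
inflation/expansion defaults are the canonical ones for this algorithm
family; all are exposed in `RunConfig`. Iteration stops when
max |ΔM| < 1e-8 or after 100 iterations (non-convergence is flagged,
not fatal). Clusters: rows with positive diagonal are attractors;
attractors exchanging flow form one attractor system; every node joins
the system attracting it most strongly (ties to the smallest cluster
id). Flow positivity is read with eps = max(prune_below, 1e-7): limit
flows are O(1/cluster size), so this cleanly separates them from
transients that have not yet decayed when pruning is weak or disabled.
The output is asserted to be a partition on every run, and connected
components are only ever refined, never merged. Clusters below
`min_cluster_size = 10` proteins are dropped before annotation.

## Overrepresentation analysis

For a query set against each gene set: upper-tail hypergeometric
p = P(X ≥ k) with population N = quantified proteome (the only
defensible universe for proteomic enrichment — whole-genome universes
inflate significance), successes K = |set ∩ universe|, draws
n = |query ∩ universe|. Sets overlapping the query in fewer than
`ora_min_overlap = 2` proteins are reported with p = 1 and excluded
from adjustment. Benjamini–Hochberg is applied across the sets of one
call (one cluster = one call); Bonferroni is available for sensitivity.
The AJ cluster is the size-filtered cluster with the smallest adjusted
p for the configured adherens-junction set name, provided it clears
`ora_adj_p = 0.05`; if none does, the pipeline records "no AJ cluster"
and skips the downstream AJ stages instead of failing.

## Stratification

Both the Ward display ordering and the K-means split operate on
per-protein z-scores of the AJ-cluster submatrix (sample mean/SD over
observed values, ddof = 1): without scaling, mixed-abundance proteins
dominate the geometry. Samples missing more than half of the subset
are excluded (counted and reported); remaining gaps are imputed to the
protein mean (z = 0) — imputation is confined to clustering and never
used in differential expression. K-means is Lloyd's algorithm with
k = 2 and the best of `kmeans_restarts = 50` seeded restarts; the
cluster whose centroid has the larger mean is labeled "high", making
the orientation invariant to cluster indexing. A degenerate input
(fewer distinct profiles than k) yields a flagged single-group result,
not a crash. Ward linkage is the ward.D2 form (Euclidean input
distances, squared within the merge cost), as implemented by scipy.

## Differential expression

Two-group comparison, AJ-low minus AJ-high, so negative log2
fold-changes mean lower expression in AJ-low. Per protein, complete
cases within each group (proteins with fewer than
`de_min_per_group = 3` observations in either group are excluded and
logged); pooled equal-variance s²_g with d_g = n₁+n₂−2 residual df.
The empirical-Bayes prior (d₀, s₀²) is fitted by moment matching on
z = log s²: E[z] and Var[z] are linked to digamma/trigamma functions
of d_g/2 and d₀/2, and the trigamma equation is inverted by Newton
iteration. A non-positive excess variance of log s² gives d₀ = ∞
(all variances shrunk to s₀², normal reference distribution). The
moderated statistic uses the posterior variance
s̃² = (d₀s₀² + d_g s²)/(d₀+d_g) and a t reference with d₀+d_g df.
Forcing d₀ = 0 recovers the ordinary pooled t exactly (config
`moderation=False`). Significance is the dual rule p < `de_p` (0.05)
AND BH-adjusted p < `de_adj_p` (0.2). The fit is verified in the test
suite against the reference empirical-Bayes implementation in
R/Bioconductor (limma) to ~1e-8 relative agreement, and against the
ordinary-t limit, a null type-I simulation (0.05 ± 0.01), and prior
recovery on simulated variances.

## Exact categorical tests

Fisher's exact test on arbitrary r×c tables: two-sided p is the sum of
conditional table probabilities (given both margins) not exceeding
p_obs·(1+1e-7) — the tolerance convention of standard statistical
software, which makes printed values like 0.85 reproduce bit-for-bit.
Tables are enumerated by a recursive margin-respecting traversal in
log-factorial arithmetic; the 2×2 case is additionally cross-checked
internally against the direct hypergeometric-tail formulation on every
call. All-zero rows/columns are dropped first; a margin of zero yields
p = 1 with a warning. Totals above `fisher_max_total = 500` are
refused with a pointer to the seeded Monte Carlo mode
(`fisher_exact_mc`, permutation of one margin, (1+hits)/(1+B)).
"Unknown" levels (e.g. perineural invasion) are excluded from tests by
default — the printed tables include them but testing observed levels
is the standard choice — with an `include_unknown` flag to keep them.
P-values are never rounded internally.

Wilcoxon rank-sum: exact enumeration when the pooled sample has ≤ 20
observations without ties, otherwise the normal approximation with tie
and continuity corrections (the behavior of R's `wilcox.test`,
delegated to scipy's implementation and verified against a subset
enumeration oracle at n ≤ 6+6).

## Distance analysis

Euclidean distances on unscaled log2 intensities — the analysis
contrasts absolute proteome magnitudes, and z-scoring would destroy
the subset-vs-global comparison. Missing values are handled per sample
pair: squared differences are summed over proteins observed in both
samples and rescaled by p/m (total/observed protein count), the
convention of R's `dist()`. This keeps medians comparable across
comparisons that involve different samples; a strict complete-case
policy is available (`missing="complete_case"`) and is exactly
Euclidean. Cross-group summaries use all |A|·|B| pairs, internal
summaries all C(|A|,2) pairs; distributions are compared with the
Wilcoxon rank-sum test. The pipeline compares tubular AJ-low samples
against tubular AJ-high, diffuse and mixed groups on (a) the AJ
cluster and (b) the full proteome, plus the AJ-low group's internal
distances.

## Synthetic cohort generator

The generator emulates the study design so every stage is testable
with planted ground truth. Expression model per sample s, protein g:

    module protein      X = μ_g + λ f_s − δ·1[AJ-low] + ε
    decoy module        X = μ_g + λ h_s               + ε
    ECM-up protein      X = μ_g + δ·1[AJ-low]         + ε
    histology signature X = μ_g + γ·1[diffuse] + γ/2·1[mixed] + ε
    background          X = μ_g                        + ε

with μ_g ~ N(20, 2), ε ~ N(0, noise_sd²), and f, h ~ N(0,1) latent
factors shared within a module. Defaults: 157 samples, 1200 proteins
(kept below the ~4500 of a real cohort so the whole recovery harness
runs in seconds; full scale is a config change), module size 10,
λ = 1.5, δ = 2.0, noise_sd = 1, five 10-protein decoy modules, five
ECM-up proteins, a 150-protein histology signature with γ = 1.0, 5%
missing completely at random (the real mechanism is unreported; MCAR
is the neutral choice), ≥ 26 gene sets including an adherens-junction
set of the module plus 5 random members. The shared factor gives
module correlations r = λ²/(λ²+σ²) ≈ 0.69, so network recovery (λ) and
patient separation (δ) are controlled by distinct parameters. Clinical
draws: histology 55/18/22/5% tubular/diffuse/mixed/other; AJ-low
probability per histology 27/50/40/33%; FLOT with probability 0.459;
major response 35%/6% for FLOT high/low and 26% for CROSS regardless
of AJ group (the therapy-specific design); inflammation and ulceration
grade distributions per AJ group taken from the emulated cohort's
reported frequencies; post-treatment pathology (ypT, ypN, L, V, Pn,
gender, age class) drawn conditional on response from the emulated
cohort's printed response-conditional frequencies. Counts are drawn,
not forced to exact totals, so marginal checks use tolerance bands.
Same config + seed is bit-identical.

What the generator does *not* emulate: batch effects, peptide-level
quantification noise, intensity-dependent missingness, correlated
background structure beyond the planted modules, and any real
biological pathway overlap among gene sets. Passing recovery tests
therefore demonstrate that the pipeline's inference machinery works
under its stated assumptions, not that those assumptions hold in real
cohorts.

A deliberate modeling consequence worth knowing: the module factor f
is shared by all module proteins, so a sample's module profile is
effectively one-dimensional with within-group spread
√(λ²+σ²/module_size) ≈ 1.53 against an AJ-low/high gap of δ = 2.0.
The Bayes-optimal label-recovery accuracy under these defaults is
therefore ≈ 0.74–0.82, which the K-means stratification attains;
perfect group separation would require a substantially larger δ (≈ 4)
or weaker factor loading. The defaults were chosen once to mirror the
emulated study's reported frequencies and to keep module recovery and
the grade/histology associations detectable at n ≈ 157; accuracy
increases monotonically in δ (verified at δ ∈ {0, 1, 2, 3}) and falls
to chance at λ = δ = 0.

## Problem sizes used in the test and acceptance runs

Unit tests use cohorts of 60–300 proteins where the full default size
adds nothing; recovery harnesses use the default 157 × 1200 design
over 50 seeds; the moderated-t null calibration uses 100 replicates of
1000 proteins × 40 samples; the Fisher oracle battery checks 500
random tables with totals ≤ 20; the MCL oracle battery covers a
fixture set of structured and random graphs on ≤ 8 nodes.

## Known limitations

- The AJ-cluster selection rule (smallest adjusted ORA p among
  size-filtered clusters) is one reasonable formalization of "the
  cluster with notable enrichment"; alternatives (e.g. largest overlap
  fraction) could pick differently on borderline collections.
- MCL on sparse top-k graphs can split a planted module across two
  clusters when the union top-3 subgraph is weakly connected; the size
  filter then discards the fragments. This is inherent to flow
  clustering at inflation 2, not a defect of the implementation
  (observed in ~2% of default-condition seeds).
- Whether correlations should be computed per therapy arm or on the
  pooled cohort is not specified by the emulated design; the pooled
  cohort is used.
- The pairwise-rescaled distance estimator is unbiased for squared
  distances under MCAR but is not exactly a metric on incomplete data;
  metric properties are exact in the complete-case mode and on fully
  observed data.
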