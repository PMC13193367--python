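# ajstrat

Proteome co-expression network stratification for tumor cohorts.

`ajstrat` reimplements, as a tested and reusable pipeline, a
proteome-to-phenotype analysis for neoadjuvantly treated esophageal
adenocarcinoma (EAC): starting from a quantified protein × sample log2
intensity matrix from pre-treatment biopsies, it identifies a
co-expressed adherens-junction (AJ) protein module, splits patients
into AJ-high / AJ-low groups, and tests that stratification against
therapy response (FLOT chemotherapy vs. CROSS chemoradiotherapy),
histology, inflammation and ulceration grades, differential protein
expression, matrisome (extracellular matrix) remodeling, and
proteome-distance structure. A synthetic-cohort generator with planted
ground truth makes every stage runnable and verifiable without any
external data.

## Method

1. **Correlation network** — Pearson correlation r over all protein
   pairs (pairwise-complete observations, minimum 10 shared samples),
   then a two-step sparsification: drop |r| < 0.4, then keep each
   protein's 3 strongest absolute correlations (an edge survives if
   either endpoint ranks it; hubs may exceed degree 3).
2. **Markov Cluster Algorithm (MCL)** — from-scratch flow clustering of
   the sparsified graph (|r| weights + unit self-loops): iterate
   M ← normalize(prune(inflate(M², Γ=2))) to convergence and read
   clusters off the attractors. Clusters with < 10 proteins are
   discarded.
3. **Overrepresentation analysis (ORA)** — per-cluster upper-tail
   hypergeometric tests P(X ≥ k) against a GMT gene-set collection with
   Benjamini–Hochberg adjustment; the universe is the quantified
   proteome. The AJ cluster is the one most significantly enriched for
   the adherens-junction set.
4. **Stratification** — K-means (k = 2, Lloyd, best of 50 restarts) on
   per-protein z-scores of the AJ-cluster submatrix; the group with the
   higher centroid mean is AJ-high. Ward (ward.D2) leaf order is
   provided for heatmap display.
5. **Association tests** — exact two-sided Fisher tests on r×c
   contingency tables (full enumeration in log-factorial arithmetic,
   tail defined by conditional probabilities ≤ p_obs·(1+1e-7)):
   AJ × response per therapy arm, AJ × histology/ulceration/
   inflammation, and response × clinicopathology per arm.
6. **Differential expression** — empirical-Bayes moderated t (AJ-low −
   AJ-high): per-protein pooled variances shrunk toward a prior
   (d₀, s₀²) fitted by moment matching on log s²;
   t = log2FC / (s̃·√(1/n₁+1/n₂)) on d₀ + d_g df; significant means
   p < 0.05 **and** BH-adjusted p < 0.2. Matrisome proteins are
   partitioned by direction.
7. **Distance analysis** — Euclidean distances between tubular AJ-low
   samples and other subgroups on the AJ subset and the whole proteome
   (pairwise-complete with p/m rescaling), compared with Wilcoxon
   rank-sum tests (exact when the pooled n ≤ 20 without ties).

See `docs/methods.md` for model details, parameter defaults, and what
the synthetic generator does and does not emulate.

## Worked example

Generate a synthetic cohort (157 samples × 1200 proteins with a planted
10-protein AJ module) and run the full pipeline:

```bash
ajstrat simulate --seed 7 --out demo/cohort
ajstrat run-all \
    --expression demo/cohort/expression.tsv \
    --clinical   demo/cohort/clinical.csv \
    --gmt        demo/cohort/gene_sets.gmt \
    --matrisome  demo/cohort/matrisome.tsv \
    --seed 7 --out demo/reports
```

Key lines of `demo/reports/summary.tsv` from this exact run:

```
aj_cluster_found      True
aj_cluster_size       10
aj_cluster_adj_p      3.65e-21
n_aj_low              73
n_aj_high             84
n_de_significant      28
matrisome_up_in_low   10
matrisome_up_in_high  5
median_AJ_CLUSTER_tubular_low_vs_tubular_high  11.39
median_AJ_CLUSTER_tubular_low_vs_diffuse        6.21
median_AJ_CLUSTER_tubular_low_vs_tubular_low    5.54
median_ALL_tubular_low_vs_tubular_high         52.22
median_ALL_tubular_low_vs_diffuse              52.84
median_ALL_tubular_low_vs_tubular_low          51.57
```

Reading this: the pipeline recovered the planted 10-protein module
exactly (ORA adjusted p ≈ 4·10⁻²¹ for the AJ gene set) and split the
cohort into 73 AJ-low / 84 AJ-high patients. Differential expression
flags the module, the planted ECM proteins and a handful of histology
signature proteins. The distance block shows the characteristic
reversal: on AJ-cluster proteins alone, tubular AJ-low tumors sit
closer to diffuse tumors (6.21) than to tubular AJ-high tumors (11.39),
while on the whole proteome they remain closest to other tubular tumors
(52.22 vs. 52.84 to diffuse), with the AJ-low group internally tightest
in both views. Stage-wise subcommands (`network`, `cluster`, `enrich`,
`stratify`, `de`, `associate`, `distances`) expose the same steps on
files.

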