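# Methods

This note documents the models, statistics and design choices behind
`gemcentric`, in the order the pipeline runs them.

## Expression processing

**Filtering.** Genes with counts-per-million below 0.1 in at least half of
the samples are removed before normalization. The fraction is inclusive
("at least half"), so with six samples a gene failing in exactly three is
removed.

**geTMM normalization.** Counts are divided by gene length in kilobases
(reads per kilobase, RPK) and the RPK matrix is normalized by trimmed mean
of M-values: per-gene log-ratios M and average log-intensities A against a
reference sample, genes outside the central 40% of M-ranks (trim 0.30 per
tail) or the central 90% of A-ranks (trim 0.05) discarded, and the scale
factor taken as the precision-weighted mean of the surviving M values. The
reference sample is the one whose upper-quartile/library-size ratio is
closest to the mean of those ratios; factors are normalized to geometric
mean 1. One deliberate departure from the common implementation: the
precision weights are computed on the *proportion* scale,
w⁻¹ = (1−p_o)/p_o + (1−p_r)/p_r with p = y/N, rather than on raw counts.
This makes normalization exactly invariant to multiplying any sample's
counts by a constant (a contract the tests assert at 1e-8) while agreeing
with the count-scale weighting to well under a percent on realistic
libraries; the test suite cross-checks the factors against an independent R
implementation at 5% tolerance. If gene lengths are absent a 1 kb length is
assumed for every gene (plain TMM) with a warning.

**Gene categories.** Quartile thresholds q1/q3 are the 25th/75th percentiles
(linear interpolation) of the per-gene mean normalized expression of a cell
type, pooling both genotypes; classification is then per sample, strictly
below q1 = low and strictly above q3 = high. Pooled thresholds with
per-sample classification were chosen because the downstream model
extraction is per sample: sample-specific models need sample-specific gene
states, while the thresholds define what counts as high or low for the cell
type as a whole.

**Built-in differential test.** A two-sided Welch t-test on log2(geTMM+1) is
provided so synthetic runs need no external tool. It is deliberately not a
negative-binomial GLM: gene-level p-values enter the downstream graph
analysis as a ranking, and real-data runs should supply externally computed
p-values through `load_gene_pvalues`.

## Context-specific activity (iMAT)

Reaction states come from folding the GPR tree with AND → min, OR → max over
low < moderate < high; genes missing from the category table count as
moderate, and reactions without a GPR are never constrained by expression.
The MILP maximizes the number of satisfied states subject to steady state
(S·v = 0) and bounds, with indicator constraints

- high, forward: v_i + y⁺_i(lb_i − ε) ≥ lb_i (y⁺=1 ⇒ v_i ≥ ε)
- high, backward: v_i + y⁻_i(ub_i + ε) ≤ ub_i (y⁻=1 ⇒ v_i ≤ −ε), y⁺+y⁻ ≤ 1
- low: lb_i(1−x_i) ≤ v_i ≤ ub_i(1−x_i) (x=1 ⇒ v_i = 0).

Parameters: ε = 1.0 flux units (the "carrying flux" threshold; with default
bounds ±1000 this keeps the big-M coefficients well scaled and sits orders
of magnitude above solver feasibility tolerance), activity threshold
`activity_tol` = 1e-6 for binarization (|v| > tol ⇒ active), relative MIP
gap 1e-6. All are exposed in `ImatConfig`. The solver is HiGHS via
`scipy.optimize.milp`, which is deterministic for fixed input, so the
reproducibility contract is per-solver-build: identical samples give
identical activity columns. iMAT optima are generally non-unique; the
package guarantees the *objective*, not the specific flux support, and every
returned solution is re-verified against mass balance, bounds, and a
recount of satisfied states computed from the fluxes alone. On networks
small enough to enumerate, the MILP objective is asserted equal to an
exhaustive support-pattern enumeration with per-pattern LP feasibility
checks.

A plain PCA on the mean-centered binary columns is provided for QC of
sample structure (no logistic/deviance variant; binary PCA here is a
visualization aid, not an inference step).

## Altered-reaction calling and validation

For a 3-vs-3 design the rule set is the explicit pattern list
{(3,0),(0,3),(3,1),(1,3),(2,0),(0,2)} on per-group active counts; other
designs supply their own enumeration (the small-sample rules are ad hoc for
n = 3 and do not define a general family), or use the per-reaction
two-sided Fisher's exact test at nominal α = 0.05 (constant reactions get
p = 1). No multiple-testing correction is applied to per-reaction tests;
significance is nominal throughout the pipeline, and the enrichment output
offers an optional Benjamini–Hochberg column.

Two nulls quantify the altered count's surprise. The exact permutation test
enumerates all C(n_A+n_B, n_A) relabelings (identity included) and reports
the fraction with an altered count at least the observed one; because the
rule set is symmetric under a group swap, the full swap always reproduces
the observed count and the smallest attainable p is 2/C(n_A+n_B, n_A). The
Monte-Carlo null redraws each reaction's activities i.i.d. Bernoulli at its
observed across-sample frequency, with p = (1 + #{draws ≥ obs})/(1 + n);
it preserves per-reaction marginals but not inter-reaction correlation
(flux coupling makes reactions in a pathway co-activate), which the report
states explicitly — it is the simplest exchangeable null, and correlation
makes it conservative for coherent blocks.

## Reporter metabolites

The bipartite graph joins a metabolite and a gene when some reaction both
involves the metabolite and carries the gene in its GPR; reactions without
GPRs contribute no edges, and isolated nodes are dropped. Gene p-values are
clipped to [1e-15, 1−1e-15], transformed z_g = Φ⁻¹(1−p_g), and aggregated
per metabolite as z_agg = Σz/√k (Stouffer). The background (μ_k, σ_k) is
estimated from random size-k subsets of the scored gene pool (default
10,000 draws, without replacement within a draw, seeded); the corrected
score is z_corr = (z_agg−μ_k)/σ_k and p = 1−Φ(z_corr), one-sided upper
tail (direction-agnostic, since z comes from two-sided p-values).
Because the correction standardizes against the same statistic under the
null, replacing the Stouffer form with the plain mean Σz/k changes nothing
after correction — the tests assert the two forms agree to 1e-9 under a
shared seed, which is why the choice of aggregation form is immaterial.
If σ_k is numerically zero (all gene p-values identical; in floating point
this can be ~1 ulp above zero), z_corr is defined as 0 and p = 0.5 with a
warning. Compartmentalized metabolites are scored as distinct nodes; an
optional collapse takes min-p per base metabolite for reporting and
enrichment. An exclusion list for currency metabolites (ATP, H₂O, …) is
available but off by default.

## Metabolome processing

Fixed order: filter → impute → log2 → test. Metabolites missing in strictly
more than 30% of the cell type's samples (both genotypes pooled) are
removed; remaining missing values are replaced by half the limit of
detection of the metabolite's assay (a per-metabolite LOD overrides the
assay LOD when present) — missingness in targeted panels is left-censoring
at the LOD, so LOD/2 is a conventional censored fill and guarantees
positivity for the log transform without a pseudocount. The test is a
two-sided pooled-variance (Student's) t-test on log2 abundances, switchable
to Welch; zero-variance metabolites get p = 1 with a warning.

## Pathway statistics

Enrichment is the hypergeometric upper tail P(X ≥ x) with
X ~ Hypergeom(N, n_P, q), where the universe N is the set of metabolites
with at least one annotation in the local table (organism-restricted
background), not all model metabolites; query identifiers outside the
universe are logged and excluded from q, and terms with no query hit are
omitted. Identifier mapping is by an explicit two-column table only — no
fuzzy name matching, which is the main source of irreproducibility in
metabolite enrichment.

The overlap coefficient compares two sources' annotation unions:
OC = |A₁∩A₂|/min(|A₁|,|A₂|). The exact multi-set intersection test computes
the null pmf of |S₁∩…∩S_m| for independent uniform draws of the observed
sizes from the universe: by exchangeability the running intersection given
its size t is uniform over t-subsets, so each further set intersects it as
Hypergeom(N, t, n_j), and the pmf follows by iterated convolution. The pmf
is checked to sum to 1 (1e-12), to match brute-force enumeration on a
6-element universe, and to agree with 100,000-draw Monte Carlo within three
standard errors; its mean equals N·Π(n_i/N).

## Synthetic studies

The generator emulates a two-genotype, multi-cell-type iPSC study at toy
scale. The model is a set of linear pathway chains fed from one hub
metabolite (exchange in) and drained per chain (exchange out), bounds
[0, 1000], which makes every reaction flux-consistent by construction — no
gap-filling needed, and a chain's reactions co-activate, giving the
coherent activity blocks the alteration rules look for. Internal reactions
carry 1–2 pathway-unique genes joined by a random AND/OR; exchanges have no
GPR. The annotation table assigns each chain metabolite exactly its
pathway's term.

Counts are negative-binomial (default dispersion 0.1, matching bulk RNA-seq
replicates; 3 vs 3 samples by default, the replication level of the
emulated design) around log-normal expected RPK (log2 center 6, sd 0.6),
with gene lengths uniform [0.5, 5] kb and expected counts scaling with
length. Planted genes' baselines are drawn 1.5 log2 units below center —
the low tail — so the planted log2 fold-change of 3 carries them from
below Q1 to above Q3 of the pooled mean distribution; this is the
construction in which the planted pathway's reactions flip from lowly to
highly expressed between groups, which is the regime the alteration rules
target. The metabolome is log-normal (per-metabolite location N(10, 1),
log2 scale sd 0.8; 4 vs 4 samples) with the planted shift applied in group
B and left-censoring at the 20% quantile of each assay's pooled
distribution, recorded as that assay's LOD — so half-LOD imputation is
well defined by construction.

What the generator does *not* emulate: genome-scale network size and
redundancy (isozymes, compartment duplication), inter-gene correlation
structure, batch effects, and assay-specific variance heterogeneity.
Passing recovery tests therefore demonstrate the statistical machinery and
its calibration, not performance on real tissue data.

`end_to_end_recovery` chains everything and reports, per source, the
planted term's enrichment p-value and significance, plus cross-source
overlap coefficients and the multi-set intersection test. At the default
study conditions the planted pathway is recovered in ≥90% of seeds at an
8-fold effect and in ≤10% at zero effect, for the iMAT and metabolome paths
independently (the acceptance suite runs 20 seeds per condition; the
acceptance script re-measures the same rates).

## Numerical and interface choices

- Solver: HiGHS through scipy; any determinism claim is per solver build.
- Mass-balance verification tolerance 1e-6·max(1, ‖v‖∞); bound tolerance
  1e-6; objective recount slack 1e-6 on ε.
- Reporter ties in rankings break by descending neighbor count k, then
  lexical metabolite id.
- Problem sizes in the default test run and the acceptance script (toy
  networks ≤ 12 reactions for enumeration, 6-pathway × 4-reaction models,
  500-gene graphs, 1,000–2,000 background draws, 20 seeds per recovery
  condition) were chosen to make each statistical check well-powered at
  desk scale.
- The pipeline's tabular dialects (counts TSV + sample sheet, abundance TSV
  + assay/LOD sidecars, annotation TSV, activity-matrix TSV) are shared
  between synthetic and real runs, so both exercise one code path.

## Known limitations

- iMAT alternate optima: the active set reported for a sample is one
  optimum; only the objective is solver-independent.
- The Monte-Carlo alteration null ignores inter-reaction correlation and is
  conservative for coupled pathways.
- Hypergeometric enrichment p-values are discrete; at small term sizes the
  attainable significance levels sit below the nominal α (the calibration
  tests use term sizes where the exact level is ≈0.048).
- No multiple-testing correction by default anywhere in the pipeline;
  results are nominal, with an optional BH-FDR column in enrichment
  tables.
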