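# gemcentric

Metabolite-centric integration of transcriptomic and metabolomic data with
genome-scale metabolic models (GEMs).

Comparing two genotype groups (say, two alleles of a risk gene across brain
cell types) at the level of individual genes or individual metabolites often
misses coordinated, pathway-level rewiring. `gemcentric` implements a
framework that projects both omics layers onto the metabolic network and
reconciles them at the metabolite and pathway level:

1. **Context-specific model extraction (iMAT).** Raw RNA-seq counts are
   geTMM-normalized (gene-length-corrected TMM); genes below the first /
   above the third quartile of a cell type's mean expression are *lowly* /
   *highly* expressed per sample. Each reaction inherits a state through its
   gene–protein–reaction (GPR) rule (AND → min, OR → max), and a
   mixed-integer program finds a mass-balanced flux distribution maximizing
   agreement with those states:

   max Σ_{i∈R_H}(y⁺ᵢ + y⁻ᵢ) + Σ_{i∈R_L} xᵢ  s.t.  S·v = 0, lb ≤ v ≤ ub,
   with y⁺ᵢ = 1 forcing vᵢ ≥ ε, y⁻ᵢ = 1 forcing vᵢ ≤ −ε, xᵢ = 1 forcing vᵢ = 0.

   The solution is binarized into a reactions × samples activity matrix.
2. **Altered-reaction calling.** For three replicates per group, a reaction
   is *altered* when its per-group active counts match the 3-0 / 3-1 / 2-0
   patterns (either orientation); larger cohorts use a per-reaction
   two-sided Fisher's exact test. An exact permutation test over all group
   relabelings and a frequency-preserving Monte-Carlo null validate the
   calls.
3. **Reporter metabolites.** On the bipartite gene–metabolite graph, each
   metabolite aggregates its k neighbor genes' differential-expression
   p-values: z_agg = Σ Φ⁻¹(1−p_g)/√k, standardized against random size-k
   gene sets (z_corr), with p = 1 − Φ(z_corr).
4. **Metabolome differential analysis.** Metabolites missing in >30% of
   samples are dropped, the rest imputed at half the assay's limit of
   detection, and log2 abundances compared with a pooled-variance t-test.
5. **Pathway reconciliation.** The three metabolite sets (from altered
   reactions, reporters, and the differential metabolome) are tested for
   pathway over-representation with the hypergeometric upper tail against a
   local annotation table, compared with the overlap coefficient
   OC(M₁,M₂) = |A₁∩A₂| / min(|A₁|,|A₂|) on their annotation unions, and with
   an exact multi-set intersection test (iterated conditional hypergeometric
   convolution).

A synthetic-data module generates flux-consistent toy GEMs, negative-binomial
counts, and LOD-censored log-normal metabolomes with a planted genotype
effect on one pathway, so the entire pipeline is testable without downloads.

## Worked example

`examples/pathway_reconciliation.py` runs the complete pipeline on one
synthetic study with an 8-fold effect planted on one pathway:

```text
planted pathway: pathway_5

       imat: planted-term enrichment p = 6.59e-03  (SIGNIFICANT)
   reporter: planted-term enrichment p = 9.41e-05  (SIGNIFICANT)
 metabolome: planted-term enrichment p = 3.29e-03  (SIGNIFICANT)

overlap coefficients between sources' pathway annotations:
{
  "imat|reporter": 1.0,
  "imat|metabolome": 0.5,
  "metabolome|reporter": 1.0
}

multi-set intersection: 4 shared metabolites, fold 10.3 over expectation, exact p = 2.17e-05
```

All three sources recover the planted pathway term at nominal p < 0.05; the
overlap coefficients say the metabolome-derived metabolites' pathway
annotations are fully contained in the reporter set's annotations (OC = 1),
and the exact test says a 4-metabolite three-way intersection is a 10-fold
excess over independent draws. The other scripts in `examples/` demonstrate
each capability in isolation (model extraction, alteration calling,
reporter scoring, metabolome testing).

The same stages are scriptable from a shell:

```bash
gemcentric simulate --config cfg.yaml   # write a synthetic study as TSVs
gemcentric imat     --config cfg.yaml   # activity matrix from counts + model
gemcentric altered  --config cfg.yaml   # altered reactions + validation
gemcentric enrich   --config cfg.yaml   # per-source pathway enrichment
gemcentric compare  --config cfg.yaml   # cross-source reconciliation report
```

Real studies plug in at the same interfaces: an SBML (FBC) genome-scale
model, a counts TSV with a sample sheet, externally computed per-gene
p-values (e.g. from a negative-binomial GLM) via `load_gene_pvalues`, a
metabolite abundance TSV with assay LODs, and a metabolite → pathway
annotation TSV.

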