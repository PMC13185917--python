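"""Synthetic study generator: toy metabolic models with planted genotype effects.

The generator emulates the structure of a two-genotype, multi-omic cell-line
study at toy scale.  ``make_toy_gem`` builds a flux-consistent network of
linear pathway chains fed from a shared hub metabolite (one exchange in, one
exchange out per chain), each internal reaction carrying a 1-2 gene GPR with
genes unique to its pathway, plus a pathway annotation table over the chain
metabolites.  ``simulate_counts`` draws negative-binomial RNA-seq counts with
a planted log2 fold-change concentrated on one pathway's genes in one group;
``simulate_metabolome`` draws log-normal metabolite abundances with a planted
fold-change on that pathway's metabolites and missing-not-at-random left
censoring at an assay-level limit of detection.

Planted genes' baseline means sit in the low tail of the gene-mean
distribution so that the planted fold-change carries them across the pooled
Q1/Q3 quartile thresholds: the planted pathway's reactions are lowly
expressed in group A and highly expressed in group B, the construction under
which context-specific model extraction should flip their activity.

``end_to_end_recovery`` chains the full pipeline (counts -> normalization ->
iMAT -> altered reactions -> enrichment; counts -> DE -> reporter
metabolites -> enrichment; metabolome -> differential abundance ->
enrichment) and reports whether the planted pathway term is recovered by
each source.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import alterations, enrichment, expression, imat, metabolome, reporter
from .enrichment import AnnotationTable
from .expression import CountMatrix
from .metabolome import AbundanceTable
from .model_io import MetabolicModel, Metabolite, Reaction, parse_gpr

__all__ = [
    "SyntheticTruth",
    "RecoveryConfig",
    "make_toy_gem",
    "simulate_counts",
    "simulate_metabolome",
    "end_to_end_recovery",
]


@dataclass
class SyntheticTruth:
    """Ground truth of a planted genotype effect."""

    planted_pathway: str
    planted_reactions: list[str]
    planted_genes: list[str]
    planted_metabolites: list[str]
    expression_effect: float = 3.0   # log2 fold-change in group B
    metabolome_effect: float = 3.0   # log2 fold-change in group B
    nb_dispersion: float = 0.1
    lod_quantile: float = 0.2
    seed: int = 0


@dataclass
class RecoveryConfig:
    """Study conditions for an end-to-end synthetic run.

    Defaults mirror the emulated study design: three RNA-seq replicates per
    genotype, four metabolome samples per genotype, and a 3-vs-3 pattern rule
    set for alteration calling.
    """

    n_pathways: int = 6
    reactions_per_pathway: int = 4
    n_background_genes: int = 200
    n_expr_a: int = 3
    n_expr_b: int = 3
    n_met_a: int = 4
    n_met_b: int = 4
    expression_effect: float = 3.0
    metabolome_effect: float = 3.0
    nb_dispersion: float = 0.1
    lod_quantile: float = 0.2
    alpha: float = 0.05
    background_draws: int = 2000
    imat: imat.ImatConfig = field(default_factory=imat.ImatConfig)


# baseline gene expression distribution (log2 of expected RPK)
_EXPR_CENTER = 6.0
_EXPR_SD = 0.6
_PLANTED_OFFSET = -1.5  # planted baseline: low tail, crossed by an 8-fold shift
_PLANTED_SD = 0.2


def make_toy_gem(
    n_pathways: int = 6, reactions_per_pathway: int = 4, seed: int = 0
) -> tuple[MetabolicModel, dict[str, str], AnnotationTable]:
    """Build a flux-consistent toy GEM of hub-fed linear pathway chains.

    Returns (model, reaction -> pathway-term labels for internal reactions,
    annotation table assigning each chain metabolite its pathway term).
    Every reaction can carry flux >= 1 (chains run hub -> ... -> export with
    bounds [0, 1000]); exchange reactions have no GPR.
    """
    if n_pathways < 2 or reactions_per_pathway < 2:
        raise ValueError("need n_pathways >= 2 and reactions_per_pathway >= 2")
    rng = np.random.default_rng(seed)
    hub = "hub[c]"
    reactions: list[Reaction] = []
    met_ids: list[str] = [hub]
    labels: dict[str, str] = {}
    annotations: dict[str, frozenset[str]] = {}
    reactions.append(Reaction("EX_hub_in", {hub: 1.0}, 0.0, 1000.0, parse_gpr("")))
    for p in range(n_pathways):
        term = f"pathway_{p}"
        chain = [hub] + [f"P{p}M{i}[c]" for i in range(1, reactions_per_pathway)] + [f"P{p}X[c]"]
        met_ids.extend(chain[1:])
        for m in chain[1:]:
            annotations[m.split("[")[0]] = frozenset({term})
        for i in range(reactions_per_pathway):
            rid = f"R_{p}_{i}"
            n_genes = int(rng.integers(1, 3))
            genes = [f"g{p}_{i}_{a}" for a in range(n_genes)]
            conn = str(rng.choice(["and", "or"])) if n_genes == 2 else ""
            gpr = genes[0] if n_genes == 1 else f"{genes[0]} {conn} {genes[1]}"
            reactions.append(
                Reaction(rid, {chain[i]: -1.0, chain[i + 1]: 1.0}, 0.0, 1000.0, parse_gpr(gpr))
            )
            labels[rid] = term
        reactions.append(
            Reaction(f"EX_P{p}X", {chain[-1]: -1.0}, 0.0, 1000.0, parse_gpr(""))
        )
    metabolites = [Metabolite(mid) for mid in met_ids]
    model = MetabolicModel(metabolites=metabolites, reactions=reactions)
    return model, labels, AnnotationTable(annotations)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def simulate_counts(
    model: MetabolicModel,
    truth: SyntheticTruth,
    n_a: int = 3,
    n_b: int = 3,
    n_background_genes: int = 200,
    group_labels: tuple[str, str] = ("E3", "E4"),
) -> CountMatrix:
    """Negative-binomial counts over model genes plus background genes.

    Expected RPK is log-normal across genes; planted genes' means are
    multiplied by ``2**expression_effect`` in group B only.  Gene lengths are
    drawn uniform [0.5, 5] kb and recorded, and expected counts scale with
    length so that length correction recovers the intended expression levels.
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("need >= 2 replicates per group")
    rng = np.random.default_rng(truth.seed)
    genes = list(model.genes) + [f"bg_{i:04d}" for i in range(n_background_genes)]
    planted = set(truth.planted_genes)
    log2_rpk = np.where(
        np.isin(genes, list(planted)),
        rng.normal(_EXPR_CENTER + _PLANTED_OFFSET, _PLANTED_SD, len(genes)),
        rng.normal(_EXPR_CENTER, _EXPR_SD, len(genes)),
    )
    lengths_kb = rng.uniform(0.5, 5.0, len(genes))
    mu = (2.0 ** log2_rpk) * lengths_kb  # expected counts = expected RPK * length
    shift = 2.0 ** truth.expression_effect
    samples = [f"{group_labels[0]}_s{i+1}" for i in range(n_a)] + [
        f"{group_labels[1]}_s{i+1}" for i in range(n_b)
    ]
    groups = {s: (group_labels[0] if i < n_a else group_labels[1]) for i, s in enumerate(samples)}
    cols = {}
    for i, s in enumerate(samples):
        m = mu.copy()
        if i >= n_a:
            m = np.where(np.isin(genes, list(planted)), m * shift, m)
        cols[s] = _nb_draw(rng, m, truth.nb_dispersion)
    counts = pd.DataFrame(cols, index=genes)
    return CountMatrix(
        counts=counts,
        groups=groups,
        cell_type="synthetic",
        gene_lengths=pd.Series(lengths_kb, index=genes),
    )


def simulate_metabolome(
    truth: SyntheticTruth,
    metabolites: list[str],
    n_a: int = 4,
    n_b: int = 4,
    n_assays: int = 2,
    group_labels: tuple[str, str] = ("E3", "E4"),
) -> AbundanceTable:
    """Log-normal abundances with a planted shift and LOD left-censoring.

    Values below the ``lod_quantile`` quantile of each assay's pooled
    distribution are censored to missing; that quantile is recorded as the
    assay's LOD (so half-LOD imputation is well defined by construction).
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("need >= 2 samples per group")
    rng = np.random.default_rng(truth.seed + 1)
    samples = [f"{group_labels[0]}_m{i+1}" for i in range(n_a)] + [
        f"{group_labels[1]}_m{i+1}" for i in range(n_b)
    ]
    groups = {s: (group_labels[0] if i < n_a else group_labels[1]) for i, s in enumerate(samples)}
    loc = rng.normal(10.0, 1.0, len(metabolites))
    planted = np.isin(metabolites, list(truth.planted_metabolites))
    vals = np.empty((len(metabolites), len(samples)))
    for j in range(len(samples)):
        shift = truth.metabolome_effect if j >= n_a else 0.0
        vals[:, j] = 2.0 ** rng.normal(loc + np.where(planted, shift, 0.0), 0.8)
    ab = pd.DataFrame(vals, index=metabolites, columns=samples)
    assays = pd.Series(
        [f"assay_{i % n_assays}" for i in range(len(metabolites))], index=metabolites
    )
    assay_lod: dict[str, float] = {}
    if truth.lod_quantile > 0:
        for assay in sorted(assays.unique()):
            pool = ab.loc[assays == assay].values.ravel()
            lod = float(np.quantile(pool, truth.lod_quantile))
            assay_lod[assay] = lod
            block = ab.loc[assays == assay]
            ab.loc[assays == assay] = block.mask(block < lod)
    return AbundanceTable(
        abundances=ab, groups=groups, assays=assays, assay_lod=assay_lod,
        cell_type="synthetic",
    )


def end_to_end_recovery(config: RecoveryConfig = RecoveryConfig(), seed: int = 0) -> dict:
    """Run the full pipeline on one synthetic study and score recovery.

    Returns a report with, per source (iMAT-altered-reaction metabolites,
    reporter metabolites, differential metabolome), the planted term's
    enrichment p-value and significance flag, plus the overlap-coefficient
    matrix and the multi-set intersection test across the three metabolite
    sets.
    """
    model, labels, ann = make_toy_gem(
        config.n_pathways, config.reactions_per_pathway, seed=seed
    )
    rng = np.random.default_rng(seed)
    planted_term = f"pathway_{int(rng.integers(config.n_pathways))}"
    planted_rxns = sorted(r for r, t in labels.items() if t == planted_term)
    planted_genes = sorted(
        set().union(*[model.reaction(r).gpr.genes for r in planted_rxns])
    )
    planted_mets = sorted(m for m, t in ann.annotations.items() if planted_term in t)
    truth = SyntheticTruth(
        planted_pathway=planted_term,
        planted_reactions=planted_rxns,
        planted_genes=planted_genes,
        planted_metabolites=planted_mets,
        expression_effect=config.expression_effect,
        metabolome_effect=config.metabolome_effect,
        nb_dispersion=config.nb_dispersion,
        lod_quantile=config.lod_quantile,
        seed=seed,
    )

    report: dict = {"seed": seed, "truth": asdict(truth), "sources": {}}

    def term_result(table: enrichment.EnrichmentTable | None):
        if table is None or planted_term not in table.table.index:
            return {"pvalue": None, "significant": False}
        row = table.table.loc[planted_term]
        return {"pvalue": float(row["pvalue"]), "significant": bool(row["significant"])}

    # --- transcriptome -> iMAT -> altered reactions -> enrichment
    cm = simulate_counts(
        model, truth, config.n_expr_a, config.n_expr_b, config.n_background_genes
    )
    cmf = expression.filter_low_expression(cm)
    nm = expression.getmm_normalize(cmf)
    q1, q3 = expression.quartile_thresholds(nm)
    cats = expression.categorize_genes(nm, q1, q3)
    rsi = imat.gene_states_to_reaction_sets(model, cats)
    am = imat.run_imat_all(model, rsi, config.imat)
    altered = alterations.call_altered_pattern(am, cm.groups)
    imat_query = enrichment.metabolites_of_reactions(model, altered)
    try:
        e_imat = enrichment.enrich(imat_query, ann, alpha=config.alpha)
    except ValueError:
        e_imat = None
    report["sources"]["imat"] = {
        "n_altered_reactions": len(altered),
        "planted_reactions_altered": len(set(altered.reaction_ids) & set(planted_rxns)),
        **term_result(e_imat),
    }

    # --- transcriptome -> reporter metabolites -> enrichment
    de = expression.simple_de_test(cmf)
    graph = reporter.build_bipartite_graph(model)
    rt = reporter.score_metabolites(
        graph,
        de,
        reporter.BackgroundConfig(n_draws=config.background_draws, seed=seed),
        alpha=config.alpha,
    )
    base_of = {m.id: m.base_id for m in model.metabolites}
    reporter_ids = frozenset(base_of[m] for m in rt.reporters)
    rep_query = enrichment.MetaboliteQuerySet(source="reporter", base_ids=reporter_ids)
    try:
        e_rep = enrichment.enrich(rep_query, ann, alpha=config.alpha)
    except ValueError:
        e_rep = None
    report["sources"]["reporter"] = {
        "n_reporters": len(rt.reporters),
        **term_result(e_rep),
    }

    # --- metabolome -> differential abundance -> enrichment
    at = simulate_metabolome(
        truth, sorted(ann.universe), config.n_met_a, config.n_met_b
    )
    atf = metabolome.filter_missing(at)
    ati = metabolome.impute_half_lod(atf)
    mst = metabolome.differential_abundance(ati, alpha=config.alpha)
    met_query = enrichment.MetaboliteQuerySet(
        source="metabolome", base_ids=frozenset(mst.significant)
    )
    try:
        e_met = enrichment.enrich(met_query, ann, alpha=config.alpha)
    except ValueError:
        e_met = None
    report["sources"]["metabolome"] = {
        "n_significant_metabolites": len(mst.significant),
        **term_result(e_met),
    }

    # --- cross-source comparison: OC matrix and multi-set intersection
    queries = {
        "imat": imat_query.base_ids & ann.universe,
        "reporter": reporter_ids & ann.universe,
        "metabolome": frozenset(mst.significant) & ann.universe,
    }
    oc: dict[str, float | None] = {}
    for a in ("imat", "reporter", "metabolome"):
        for b in ("imat", "reporter", "metabolome"):
            if a >= b:
                continue
            aa = enrichment.annotations_of(queries[a], ann)
            bb = enrichment.annotations_of(queries[b], ann)
            oc[f"{a}|{b}"] = (
                enrichment.overlap_coefficient(aa, bb) if aa and bb else None
            )
    report["overlap_coefficients"] = oc
    if all(queries.values()):
        k, fold, p = enrichment.super_exact_test(
            list(queries.values()), ann.n_universe
        )
        report["super_exact"] = {"intersection": k, "fold": fold, "pvalue": p}
    else:
        report["super_exact"] = None
    return report
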