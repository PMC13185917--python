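"""Config-driven orchestration of the analysis stages.

A single YAML (or dict) configuration names the input tables, thresholds and
seeds; each stage function reads its inputs, calls the library, writes its
outputs under ``outdir`` and records a run manifest (config hash, seed,
library versions) so a run can be re-executed bit-identically.  The ``cli``
module wraps these functions for the shell.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import alterations, enrichment, expression, imat, metabolome, model_io, reporter, synthetic

__all__ = ["PipelineConfig", "load_config", "STAGES", "run_stage"]

_DEFAULTS = {
    "seed": 0,
    "outdir": "gemcentric_out",
    "alpha": 0.05,
    "cpm_cutoff": 0.1,
    "min_fraction": 0.5,
    "max_na_fraction": 0.30,
    "epsilon": 1.0,
    "activity_tol": 1e-6,
    "background_draws": 10000,
    "alteration_method": "pattern",  # or "fisher"
    "paths": {},
}


class PipelineConfig(dict):
    """Validated configuration mapping; unknown keys are preserved."""

    def __init__(self, data: dict | None = None):
        merged = {**_DEFAULTS, **(data or {})}
        if not (0 < merged["alpha"] < 1):
            raise ValueError("alpha must lie in (0, 1)")
        super().__init__(merged)

    def path(self, key: str, required: bool = True) -> Path | None:
        p = self.get("paths", {}).get(key)
        if p is None:
            if required:
                raise FileNotFoundError(f"config paths.{key} is not set")
            return None
        p = Path(p)
        if required and not p.exists():
            raise FileNotFoundError(f"config paths.{key}: {p} does not exist")
        return p

    def outdir(self) -> Path:
        out = Path(self["outdir"])
        out.mkdir(parents=True, exist_ok=True)
        return out

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        return PipelineConfig(yaml.safe_load(fh) or {})


def _write_manifest(cfg: PipelineConfig, stage: str, outputs: list[str]) -> Path:
    import networkx
    import scipy

    out = cfg.outdir()
    manifest = {
        "stage": stage,
        "config_sha256": cfg.digest(),
        "seed": cfg["seed"],
        "outputs": outputs,
        "versions": {
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "networkx": networkx.__version__,
        },
    }
    path = out / f"manifest_{stage}.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def _read_model(cfg: PipelineConfig) -> model_io.MetabolicModel:
    path = cfg.path("model")
    if path.suffix.lower() in (".xml", ".sbml"):
        return model_io.read_sbml(path)
    return model_io.read_toy_model(path)


def _load_counts(cfg: PipelineConfig) -> expression.CountMatrix:
    return expression.load_counts(
        cfg.path("counts"), cfg.path("sample_sheet"), cfg.path("gene_lengths", required=False)
    )


# ---------------------------------------------------------------------------
# stage implementations
# ---------------------------------------------------------------------------

def stage_simulate(cfg: PipelineConfig) -> list[str]:
    """Generate a synthetic study (model, counts, metabolome, annotations)."""
    out = cfg.outdir()
    rcfg = synthetic.RecoveryConfig(
        alpha=cfg["alpha"], background_draws=cfg["background_draws"]
    )
    seed = cfg["seed"]
    model, labels, ann = synthetic.make_toy_gem(
        rcfg.n_pathways, rcfg.reactions_per_pathway, seed=seed
    )
    rng = np.random.default_rng(seed)
    term = f"pathway_{int(rng.integers(rcfg.n_pathways))}"
    planted_rxns = sorted(r for r, t in labels.items() if t == term)
    truth = synthetic.SyntheticTruth(
        planted_pathway=term,
        planted_reactions=planted_rxns,
        planted_genes=sorted(set().union(*[model.reaction(r).gpr.genes for r in planted_rxns])),
        planted_metabolites=sorted(m for m, t in ann.annotations.items() if term in t),
        seed=seed,
    )
    cm = synthetic.simulate_counts(model, truth, rcfg.n_expr_a, rcfg.n_expr_b)
    at = synthetic.simulate_metabolome(truth, sorted(ann.universe), rcfg.n_met_a, rcfg.n_met_b)

    model_io.write_toy_model(model, out / "model.tsv")
    cm.counts.to_csv(out / "counts.tsv", sep="\t")
    pd.DataFrame(
        {"sample_id": cm.samples, "group": [cm.groups[s] for s in cm.samples],
         "cell_type": cm.cell_type}
    ).to_csv(out / "sample_sheet.tsv", sep="\t", index=False)
    cm.gene_lengths.rename("length_kb").rename_axis("gene_id").reset_index().to_csv(
        out / "gene_lengths.tsv", sep="\t", index=False
    )
    at.abundances.to_csv(out / "abundances.tsv", sep="\t")
    pd.DataFrame(
        {"sample_id": at.samples, "group": [at.groups[s] for s in at.samples],
         "cell_type": at.cell_type}
    ).to_csv(out / "met_sample_sheet.tsv", sep="\t", index=False)
    at.assays.rename("assay").rename_axis("metabolite_id").reset_index().to_csv(
        out / "metabolite_assays.tsv", sep="\t", index=False
    )
    pd.DataFrame(sorted(at.assay_lod.items()), columns=["assay", "lod"]).to_csv(
        out / "assay_lods.tsv", sep="\t", index=False
    )
    rows = [(m, t) for m, terms in sorted(ann.annotations.items()) for t in sorted(terms)]
    pd.DataFrame(rows, columns=["metabolite_id", "pathway_term"]).to_csv(
        out / "annotations.tsv", sep="\t", index=False
    )
    (out / "truth.json").write_text(json.dumps(asdict(truth), indent=2) + "\n")
    outputs = [
        "model.tsv", "counts.tsv", "sample_sheet.tsv", "gene_lengths.tsv",
        "abundances.tsv", "met_sample_sheet.tsv", "metabolite_assays.tsv",
        "assay_lods.tsv", "annotations.tsv", "truth.json",
    ]
    _write_manifest(cfg, "simulate", outputs)
    return outputs


def stage_normalize(cfg: PipelineConfig) -> list[str]:
    out = cfg.outdir()
    cm = _load_counts(cfg)
    cmf = expression.filter_low_expression(cm, cfg["cpm_cutoff"], cfg["min_fraction"])
    nm = expression.getmm_normalize(cmf)
    q1, q3 = expression.quartile_thresholds(nm)
    nm.values.to_csv(out / "normalized.tsv", sep="\t")
    nm.scale_factors.rename_axis("sample_id").reset_index().to_csv(
        out / "scale_factors.tsv", sep="\t", index=False
    )
    (out / "thresholds.json").write_text(json.dumps({"q1": q1, "q3": q3}) + "\n")
    outputs = ["normalized.tsv", "scale_factors.tsv", "thresholds.json"]
    _write_manifest(cfg, "normalize", outputs)
    return outputs


def stage_imat(cfg: PipelineConfig) -> list[str]:
    out = cfg.outdir()
    model = _read_model(cfg)
    cm = _load_counts(cfg)
    cmf = expression.filter_low_expression(cm, cfg["cpm_cutoff"], cfg["min_fraction"])
    nm = expression.getmm_normalize(cmf)
    q1, q3 = expression.quartile_thresholds(nm)
    cats = expression.categorize_genes(nm, q1, q3)
    rsi = imat.gene_states_to_reaction_sets(model, cats)
    icfg = imat.ImatConfig(
        epsilon=cfg["epsilon"], activity_tol=cfg["activity_tol"], seed=cfg["seed"]
    )
    am = imat.run_imat_all(model, rsi, icfg)
    am.data.rename_axis("reaction_id").to_csv(out / "activity_matrix.tsv", sep="\t")
    log = {
        s: {"n_high": len(rh), "n_low": len(rl)} for s, (rh, rl) in rsi.per_sample.items()
    }
    (out / "imat_log.json").write_text(json.dumps(log, indent=2) + "\n")
    outputs = ["activity_matrix.tsv", "imat_log.json"]
    _write_manifest(cfg, "imat", outputs)
    return outputs


def _read_activity(cfg: PipelineConfig) -> tuple[imat.ActivityMatrix, dict[str, str]]:
    am_path = cfg.outdir() / "activity_matrix.tsv"
    if not am_path.exists():
        raise FileNotFoundError(f"{am_path} not found; run the imat stage first")
    df = pd.read_csv(am_path, sep="\t", index_col=0)
    sheet = pd.read_csv(cfg.path("sample_sheet"), sep="\t")
    groups = dict(zip(sheet["sample_id"], sheet["group"]))
    return imat.ActivityMatrix(data=df), groups


def stage_altered(cfg: PipelineConfig) -> list[str]:
    out = cfg.outdir()
    am, groups = _read_activity(cfg)
    if cfg["alteration_method"] == "fisher":
        altered = alterations.call_altered_fisher(am, groups, alpha=cfg["alpha"])
    else:
        altered = alterations.call_altered_pattern(am, groups)
    altered.table.rename_axis("reaction_id").to_csv(out / "altered_reactions.tsv", sep="\t")
    outputs = ["altered_reactions.tsv"]
    n = len(am.samples)
    if cfg["alteration_method"] == "pattern" and n <= alterations.EXACT_ENUMERATION_MAX_SAMPLES:
        rep = alterations.permutation_validate(am, groups)
        mc = alterations.montecarlo_validate(am, groups, n_draws=2000, seed=cfg["seed"])
        (out / "validation.json").write_text(
            json.dumps(
                {
                    "observed": rep.observed,
                    "permutation_p": rep.pvalue,
                    "monte_carlo_p": mc.pvalue,
                    "n_draws": mc.n_draws,
                    "seed": mc.seed,
                    "notes": mc.notes,
                },
                indent=2,
            )
            + "\n"
        )
        outputs.append("validation.json")
    _write_manifest(cfg, "altered", outputs)
    return outputs


def stage_reporter(cfg: PipelineConfig) -> list[str]:
    out = cfg.outdir()
    model = _read_model(cfg)
    pvals_path = cfg.path("gene_pvalues", required=False)
    if pvals_path is not None:
        stats = expression.load_gene_pvalues(pvals_path)
    else:
        cm = _load_counts(cfg)
        cmf = expression.filter_low_expression(cm, cfg["cpm_cutoff"], cfg["min_fraction"])
        stats = expression.simple_de_test(cmf)
    graph = reporter.build_bipartite_graph(model)
    rt = reporter.score_metabolites(
        graph,
        stats,
        reporter.BackgroundConfig(n_draws=cfg["background_draws"], seed=cfg["seed"]),
        alpha=cfg["alpha"],
    )
    rt.table.rename_axis("metabolite_id").to_csv(out / "reporter_metabolites.tsv", sep="\t")
    _write_manifest(cfg, "reporter", ["reporter_metabolites.tsv"])
    return ["reporter_metabolites.tsv"]


def stage_metabolome(cfg: PipelineConfig) -> list[str]:
    out = cfg.outdir()
    at = metabolome.load_abundance_table(
        cfg.path("abundances"),
        cfg.path("met_sample_sheet"),
        cfg.path("metabolite_assays", required=False),
        cfg.path("assay_lods", required=False),
    )
    atf = metabolome.filter_missing(at, cfg["max_na_fraction"])
    ati = metabolome.impute_half_lod(atf)
    mst = metabolome.differential_abundance(ati, alpha=cfg["alpha"])
    mst.table.rename_axis("metabolite_id").to_csv(out / "metabolite_stats.tsv", sep="\t")
    _write_manifest(cfg, "metabolome", ["metabolite_stats.tsv"])
    return ["metabolite_stats.tsv"]


def stage_enrich(cfg: PipelineConfig) -> list[str]:
    """Enrichment of all three metabolite sources that are available."""
    out = cfg.outdir()
    ann = enrichment.load_annotation_table(cfg.path("annotations"))
    model = _read_model(cfg)
    mapping = None
    mpath = cfg.path("mapping", required=False)
    if mpath is not None:
        mdf = pd.read_csv(mpath, sep="\t")
        mapping = dict(zip(mdf["model_base_id"], mdf["annotation_id"]))
    base_of = {m.id: m.base_id for m in model.metabolites}
    outputs = []
    sources: dict[str, frozenset[str]] = {}
    alt_path = out / "altered_reactions.tsv"
    if alt_path.exists():
        rxns = list(pd.read_csv(alt_path, sep="\t")["reaction_id"])
        sources["imat_reactions"] = enrichment.metabolites_of_reactions(model, rxns).base_ids
    rep_path = out / "reporter_metabolites.tsv"
    if rep_path.exists():
        df = pd.read_csv(rep_path, sep="\t")
        mets = df.loc[df["is_reporter"], "metabolite_id"]
        sources["reporter"] = frozenset(base_of.get(m, m) for m in mets)
    met_path = out / "metabolite_stats.tsv"
    if met_path.exists():
        df = pd.read_csv(met_path, sep="\t")
        sources["metabolome"] = frozenset(df.loc[df["significant"], "metabolite_id"])
    if not sources:
        raise FileNotFoundError("no upstream stage outputs found; nothing to enrich")
    for name, ids in sources.items():
        query = enrichment.MetaboliteQuerySet(source=name, base_ids=ids)
        table = enrichment.enrich(query, ann, alpha=cfg["alpha"], mapping=mapping, with_fdr=True)
        fname = f"enrichment_{name}.tsv"
        table.table.rename_axis("term").to_csv(out / fname, sep="\t")
        outputs.append(fname)
    _write_manifest(cfg, "enrich", outputs)
    return outputs


def stage_compare(cfg: PipelineConfig) -> list[str]:
    """Join the per-source enrichment tables: common/unique significant terms,
    the overlap-coefficient matrix, and the multi-set intersection test."""
    out = cfg.outdir()
    ann = enrichment.load_annotation_table(cfg.path("annotations"))
    tables = {}
    for name in ("imat_reactions", "reporter", "metabolome"):
        path = out / f"enrichment_{name}.tsv"
        if path.exists():
            df = pd.read_csv(path, sep="\t", index_col=0)
            tables[name] = set(df.index[df["significant"]])
    if len(tables) < 2:
        raise FileNotFoundError("need at least two enrichment tables; run enrich first")
    names = sorted(tables)
    common = set.intersection(*tables.values())
    report = {
        "sources": names,
        "n_significant": {n: len(tables[n]) for n in names},
        "common_terms": sorted(common),
        "unique_terms": {
            n: sorted(tables[n] - set.union(*[tables[m] for m in names if m != n]))
            for n in names
        },
        "overlap_coefficient": {},
    }
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if tables[a] and tables[b]:
                report["overlap_coefficient"][f"{a}|{b}"] = enrichment.overlap_coefficient(
                    tables[a], tables[b]
                )
    if all(tables.values()):
        universe = {t for terms in ann.annotations.values() for t in terms}
        sets = [tables[n] & universe for n in names]
        if all(sets):
            k, fold, p = enrichment.super_exact_test(sets, len(universe))
            report["super_exact"] = {"intersection": k, "fold": fold, "pvalue": p}
    (out / "comparison.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    _write_manifest(cfg, "compare", ["comparison.json"])
    return ["comparison.json"]


def stage_recover(cfg: PipelineConfig) -> list[str]:
    out = cfg.outdir()
    rcfg = synthetic.RecoveryConfig(
        alpha=cfg["alpha"], background_draws=cfg["background_draws"]
    )
    report = synthetic.end_to_end_recovery(rcfg, seed=cfg["seed"])
    (out / "recovery.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    _write_manifest(cfg, "recover", ["recovery.json"])
    return ["recovery.json"]


STAGES = {
    "simulate": stage_simulate,
    "normalize": stage_normalize,
    "imat": stage_imat,
    "altered": stage_altered,
    "reporter": stage_reporter,
    "metabolome": stage_metabolome,
    "enrich": stage_enrich,
    "compare": stage_compare,
    "recover": stage_recover,
}


def run_stage(name: str, cfg: PipelineConfig) -> list[str]:
    if name not in STAGES:
        raise ValueError(f"unknown stage {name!r}; choose from {sorted(STAGES)}")
    return STAGES[name](cfg)
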