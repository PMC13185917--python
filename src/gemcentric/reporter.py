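"""Reporter metabolite analysis.

A bipartite gene-metabolite graph is built from the metabolic model: an edge
joins a metabolite and a gene whenever some reaction both involves the
metabolite (as substrate or product) and carries the gene in its GPR.  Each
metabolite is then scored by aggregating the differential-expression p-values
of its k neighbor genes:

    z_g     = Phi^-1(1 - p_g)
    z_agg   = sum_{g in N(m)} z_g / sqrt(k)            (Stouffer aggregation)
    z_corr  = (z_agg - mu_k) / sigma_k
    p_m     = 1 - Phi(z_corr)

where (mu_k, sigma_k) are estimated from random size-k gene subsets of the
scored gene pool (the background correction).  Because the correction is an
affine standardization against the same statistic under the null, replacing
sum/sqrt(k) by the plain mean yields identical corrected scores — the choice
of aggregation form is immaterial once background-corrected.

Metabolites with p < alpha (default 0.05) are reporter metabolites: hubs of
coordinated transcriptional change in the metabolic network.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import norm

from .expression import GeneStatTable
from .model_io import MetabolicModel

logger = logging.getLogger(__name__)

__all__ = [
    "BackgroundConfig",
    "ReporterTable",
    "build_bipartite_graph",
    "score_metabolites",
    "reporter_summary",
    "collapse_to_base_id",
]

P_CLIP = 1e-15


@dataclass(frozen=True)
class BackgroundConfig:
    n_draws: int = 10000
    seed: int = 0
    aggregation: str = "stouffer"  # "stouffer" (sum/sqrt(k)) or "mean"

    def __post_init__(self):
        if self.aggregation not in ("stouffer", "mean"):
            raise ValueError("aggregation must be 'stouffer' or 'mean'")
        if self.n_draws < 100:
            raise ValueError("n_draws must be >= 100")


@dataclass
class ReporterTable:
    table: pd.DataFrame  # index metabolite id; columns k, z_agg, z_corr, p, is_reporter
    alpha: float

    @property
    def reporters(self) -> list[str]:
        return list(self.table.index[self.table["is_reporter"]])


def build_bipartite_graph(
    model: MetabolicModel, exclude_metabolites: set[str] | None = None
) -> nx.Graph:
    """Bipartite metabolite-gene graph from reactions with non-empty GPRs.

    Node attribute ``bipartite`` is "metabolite" or "gene".  Isolated nodes
    never enter the graph.  ``exclude_metabolites`` (metabolite ids) allows
    pruning currency metabolites; off by default.
    """
    exclude = exclude_metabolites or set()
    g = nx.Graph()
    for r in model.reactions:
        genes = r.gpr.genes
        if not genes:
            continue
        mets = [m for m in r.stoichiometry if m not in exclude]
        for mid in mets:
            for gene in genes:
                g.add_node(mid, bipartite="metabolite")
                g.add_node(gene, bipartite="gene")
                g.add_edge(mid, gene)
    if g.number_of_edges() == 0:
        raise ValueError("bipartite graph is empty (no gene-associated reactions)")
    n_met = sum(1 for _, d in g.nodes(data=True) if d["bipartite"] == "metabolite")
    logger.info(
        "bipartite graph: %d metabolites, %d genes, %d edges",
        n_met, g.number_of_nodes() - n_met, g.number_of_edges(),
    )
    return g


def _aggregate(z: np.ndarray, aggregation: str) -> float:
    if aggregation == "mean":
        return float(z.mean())
    return float(z.sum() / np.sqrt(z.size))


def _background(
    z_pool: np.ndarray, ks: list[int], cfg: BackgroundConfig
) -> dict[int, tuple[float, float]]:
    """(mu_k, sigma_k) of the aggregation statistic over random size-k subsets.

    Subsets are drawn without replacement within a draw, with replacement
    across draws.  Vectorised via the k-smallest-of-uniforms trick, chunked
    to bound memory.
    """
    rng = np.random.default_rng(cfg.seed)
    pool = z_pool.size
    out: dict[int, tuple[float, float]] = {}
    for k in sorted(set(ks)):
        if k > pool:
            raise ValueError(f"neighbor count k={k} exceeds gene pool size {pool}")
        stats_k = np.empty(cfg.n_draws)
        chunk = max(1, min(cfg.n_draws, int(2e6 / max(pool, 1))))
        done = 0
        while done < cfg.n_draws:
            m = min(chunk, cfg.n_draws - done)
            u = rng.random((m, pool))
            idx = np.argpartition(u, k - 1, axis=1)[:, :k]
            zs = z_pool[idx]
            if cfg.aggregation == "mean":
                stats_k[done : done + m] = zs.mean(axis=1)
            else:
                stats_k[done : done + m] = zs.sum(axis=1) / np.sqrt(k)
            done += m
        out[k] = (float(stats_k.mean()), float(stats_k.std(ddof=0)))
    return out


def score_metabolites(
    graph: nx.Graph,
    stats: GeneStatTable,
    bg: BackgroundConfig = BackgroundConfig(),
    alpha: float = 0.05,
) -> ReporterTable:
    """Score every metabolite node by its neighbor genes' aggregated z-scores."""
    gene_nodes = {n for n, d in graph.nodes(data=True) if d["bipartite"] == "gene"}
    scored = gene_nodes & set(stats.pvalues.index)
    dropped = len(gene_nodes) - len(scored)
    if dropped:
        logger.info("dropping %d graph genes without p-values", dropped)
    if not scored:
        raise ValueError("no graph gene has a p-value")
    p = stats.pvalues.loc[sorted(scored)].clip(P_CLIP, 1 - P_CLIP)
    z = pd.Series(norm.isf(p.values), index=p.index)
    z_pool = z.values

    met_nodes = [n for n, d in graph.nodes(data=True) if d["bipartite"] == "metabolite"]
    neighbors: dict[str, list[str]] = {}
    for m in met_nodes:
        nb = [g for g in graph.neighbors(m) if g in scored]
        if nb:
            neighbors[m] = nb
    if not neighbors:
        raise ValueError("no metabolite retains a scored neighbor gene")

    ks = [len(nb) for nb in neighbors.values()]
    background = _background(z_pool, ks, bg)

    rows = []
    for m, nb in neighbors.items():
        k = len(nb)
        z_agg = _aggregate(z.loc[nb].values, bg.aggregation)
        mu_k, sigma_k = background[k]
        if sigma_k <= 1e-12 * max(1.0, abs(mu_k)):
            warnings.warn(f"degenerate background (sigma=0) for k={k}", UserWarning)
            z_corr = 0.0
        else:
            z_corr = (z_agg - mu_k) / sigma_k
        p_m = float(norm.sf(z_corr))
        rows.append((m, k, z_agg, z_corr, p_m, p_m < alpha))
    table = pd.DataFrame(
        rows, columns=["metabolite_id", "k", "z_agg", "z_corr", "p", "is_reporter"]
    ).set_index("metabolite_id")
    return ReporterTable(table=table, alpha=alpha)


def reporter_summary(rt: ReporterTable, top_n: int) -> pd.DataFrame:
    """Top metabolites by ascending p; ties broken by descending k, then id."""
    if rt.table.empty:
        raise ValueError("empty reporter table")
    ordered = (
        rt.table.reset_index()
        .sort_values(by=["p", "k", "metabolite_id"], ascending=[True, False, True])
        .set_index("metabolite_id")
    )
    return ordered.head(top_n)


def collapse_to_base_id(rt: ReporterTable, model: MetabolicModel) -> pd.Series:
    """Min-p per base metabolite across compartments (for reporting/enrichment)."""
    base = {m.id: m.base_id for m in model.metabolites}
    p = rt.table["p"].rename(index=lambda mid: base.get(mid, mid))
    return p.groupby(level=0).min()
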