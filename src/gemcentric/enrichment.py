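"""Metabolite-set pathway statistics.

Three query sets of metabolites — those of the iMAT-altered reactions, the
reporter metabolites, and the differentially abundant metabolites — are
tested against a local pathway annotation table with the hypergeometric
upper tail: for a term annotating n_P of the N annotated metabolites and a
mapped query of size q with x hits, p = P(X >= x), X ~ Hypergeom(N, n_P, q).

Two set-similarity statistics compare sources: the overlap coefficient
OC(M1, M2) = |A1 ∩ A2| / min(|A1|, |A2|) on the unions A_i of the pathway
annotations of metabolite lists M_i, and the exact multi-set intersection
test, which computes the null distribution of the m-set intersection size
under independent uniform draws of the observed sizes from the background by
iterated conditional hypergeometric convolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .alterations import AlteredReactionSet
from .model_io import MetabolicModel

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationTable",
    "MetaboliteQuerySet",
    "EnrichmentTable",
    "load_annotation_table",
    "metabolites_of_reactions",
    "enrich",
    "annotations_of",
    "overlap_coefficient",
    "super_exact_test",
    "multiset_intersection_pmf",
]


@dataclass
class AnnotationTable:
    """Metabolite (base_id) -> set of pathway terms; the annotated metabolites
    form the enrichment universe (organism-restricted background)."""

    annotations: dict[str, frozenset[str]]
    organism: str = "Homo sapiens"

    def __post_init__(self):
        empties = [m for m, t in self.annotations.items() if not t]
        if empties:
            raise ValueError(f"metabolites with empty annotation: {empties[:5]}")
        if not self.annotations:
            raise ValueError("annotation table is empty")

    @property
    def universe(self) -> frozenset[str]:
        return frozenset(self.annotations)

    @property
    def n_universe(self) -> int:
        return len(self.annotations)

    def term_members(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for met, terms in self.annotations.items():
            for t in terms:
                out.setdefault(t, set()).add(met)
        return out


@dataclass
class MetaboliteQuerySet:
    source: str  # "metabolome" | "imat_reactions" | "reporter"
    base_ids: frozenset[str]
    mapped_count: int | None = None


@dataclass
class EnrichmentTable:
    table: pd.DataFrame  # index term; x, n_pathway, q, N, pvalue, significant[, fdr]
    source: str
    alpha: float

    @property
    def significant_terms(self) -> set[str]:
        return set(self.table.index[self.table["significant"]])


def load_annotation_table(path, organism: str = "Homo sapiens") -> AnnotationTable:
    """Read a two-column TSV (metabolite_id, pathway_term)."""
    df = pd.read_csv(path, sep="\t")
    ann: dict[str, set[str]] = {}
    for met, term in zip(df["metabolite_id"], df["pathway_term"]):
        ann.setdefault(str(met), set()).add(str(term))
    return AnnotationTable({m: frozenset(t) for m, t in ann.items()}, organism=organism)


def metabolites_of_reactions(
    model: MetabolicModel, reactions: AlteredReactionSet | list[str]
) -> MetaboliteQuerySet:
    """Union of substrates and products of the listed reactions, collapsed to
    base_id (compartments merged) and deduplicated."""
    rxn_ids = reactions.reaction_ids if isinstance(reactions, AlteredReactionSet) else list(reactions)
    base_ids: set[str] = set()
    for rid in rxn_ids:
        r = model.reaction(rid)  # raises KeyError for unknown ids
        for mid in r.stoichiometry:
            base_ids.add(model.metabolite(mid).base_id)
    return MetaboliteQuerySet(source="imat_reactions", base_ids=frozenset(base_ids))


def enrich(
    query: MetaboliteQuerySet,
    ann: AnnotationTable,
    alpha: float = 0.05,
    mapping: dict[str, str] | None = None,
    with_fdr: bool = False,
) -> EnrichmentTable:
    """Hypergeometric over-representation of a metabolite set per pathway term.

    ``mapping`` optionally translates query base_ids to annotation ids
    (explicit two-column mapping; no fuzzy name matching).  Unmapped query
    metabolites are excluded from q.  Terms with no query hit are omitted.
    """
    ids = set(query.base_ids)
    if mapping:
        ids = {mapping.get(m, m) for m in ids}
    mapped = ids & ann.universe
    n_unmapped = len(ids) - len(mapped)
    if n_unmapped:
        logger.info("enrich[%s]: %d query metabolites not in annotation universe", query.source, n_unmapped)
    if not mapped:
        raise ValueError(
            "no query metabolite maps into the annotation universe; "
            "provide an identifier mapping"
        )
    query.mapped_count = len(mapped)
    N = ann.n_universe
    q = len(mapped)
    rows = []
    for term, members in sorted(ann.term_members().items()):
        x = len(mapped & members)
        if x == 0:
            continue
        n_p = len(members)
        p = float(hypergeom.sf(x - 1, N, n_p, q))
        rows.append((term, x, n_p, q, N, p))
    table = pd.DataFrame(
        rows, columns=["term", "x", "n_pathway", "q", "N", "pvalue"]
    ).set_index("term")
    table["significant"] = table["pvalue"] < alpha
    if with_fdr and len(table):
        from scipy.stats import false_discovery_control

        table["fdr"] = false_discovery_control(table["pvalue"].values)
    return EnrichmentTable(table=table, source=query.source, alpha=alpha)


def annotations_of(base_ids, ann: AnnotationTable) -> frozenset[str]:
    """Union of the pathway annotations of a metabolite list (the A_i sets)."""
    out: set[str] = set()
    for m in base_ids:
        out |= ann.annotations.get(m, frozenset())
    return frozenset(out)


def overlap_coefficient(a1, a2) -> float:
    """OC(A1, A2) = |A1 ∩ A2| / min(|A1|, |A2|)."""
    s1, s2 = set(a1), set(a2)
    if not s1 or not s2:
        raise ValueError("overlap coefficient undefined for empty sets")
    return len(s1 & s2) / min(len(s1), len(s2))


def multiset_intersection_pmf(sizes: list[int], n_universe: int) -> np.ndarray:
    """Exact pmf of |S_1 ∩ ... ∩ S_m| for independent uniform draws of the
    given sizes from a universe of size ``n_universe``.

    By exchangeability the running intersection given its size t is uniform
    over t-subsets, so intersecting with the next set is Hypergeom(N, t, n):
    the pmf follows by iterated conditional convolution.
    """
    if len(sizes) < 1:
        raise ValueError("need at least one set")
    for n in sizes:
        if not (0 <= n <= n_universe):
            raise ValueError(f"set size {n} outside [0, {n_universe}]")
    pmf = np.zeros(n_universe + 1)
    pmf[sizes[0]] = 1.0
    support = np.arange(n_universe + 1)
    for n in sizes[1:]:
        new = np.zeros_like(pmf)
        for t in np.nonzero(pmf)[0]:
            new += pmf[t] * hypergeom.pmf(support, n_universe, t, n)
        pmf = new
    return pmf


def super_exact_test(sets: list, n_universe: int) -> tuple[int, float, float]:
    """Exact multi-set intersection test.

    Returns (observed intersection size k, fold enrichment k / E[K], and
    p = P(K >= k) under independent uniform draws of the observed sizes).
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 sets")
    sets = [set(s) for s in sets]
    for s in sets:
        if len(s) > n_universe:
            raise ValueError("a set exceeds the universe size")
    k = len(set.intersection(*sets))
    sizes = [len(s) for s in sets]
    pmf = multiset_intersection_pmf(sizes, n_universe)
    p = float(pmf[k:].sum())
    expected = n_universe * float(np.prod([n / n_universe for n in sizes]))
    fold = k / expected if expected > 0 else np.inf
    return k, fold, p
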