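"""Metabolite abundance tables: missingness filter, LOD imputation, testing.

The processing order is fixed: (1) drop metabolites missing in strictly more
than ``max_na_fraction`` of the cell type's samples (default 30%), (2)
replace every remaining missing value by half the limit of detection (LOD)
of the metabolite's assay — missingness in targeted metabolomics is
censoring at the LOD, so LOD/2 is a conventional left-censored fill — and
(3) a two-sided Student's (pooled-variance) t-test on log2 abundances per
metabolite between the two genotype groups, significant at nominal alpha.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "AbundanceTable",
    "MetaboliteStatTable",
    "ImputationError",
    "filter_missing",
    "impute_half_lod",
    "differential_abundance",
    "load_abundance_table",
]


class ImputationError(ValueError):
    """A missing value has no LOD to impute from."""


@dataclass
class AbundanceTable:
    """Metabolite x sample abundances (NaN = missing / below LOD)."""

    abundances: pd.DataFrame          # metabolites x samples, positive where present
    groups: dict[str, str]            # sample -> genotype label
    assays: pd.Series | None = None   # metabolite -> assay label
    assay_lod: dict[str, float] = field(default_factory=dict)
    metabolite_lod: pd.Series | None = None  # per-metabolite override
    cell_type: str = ""

    def __post_init__(self):
        vals = self.abundances.values
        if np.any(vals[~np.isnan(vals)] <= 0):
            raise ValueError("abundances must be positive where present")
        missing = [s for s in self.abundances.columns if s not in self.groups]
        if missing:
            raise ValueError(f"samples without group label: {missing}")

    def lod_for(self, metabolite: str) -> float | None:
        if self.metabolite_lod is not None and metabolite in self.metabolite_lod.index:
            v = self.metabolite_lod.loc[metabolite]
            if pd.notna(v):
                return float(v)
        if self.assays is not None and metabolite in self.assays.index:
            assay = self.assays.loc[metabolite]
            if assay in self.assay_lod:
                return float(self.assay_lod[assay])
        return None

    @property
    def metabolites(self) -> list[str]:
        return list(self.abundances.index)

    @property
    def samples(self) -> list[str]:
        return list(self.abundances.columns)


@dataclass
class MetaboliteStatTable:
    table: pd.DataFrame  # index metabolite; mean_log2_a, mean_log2_b, t, pvalue, significant
    alpha: float
    group_a: str
    group_b: str

    @property
    def significant(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])


def filter_missing(at: AbundanceTable, max_na_fraction: float = 0.30) -> AbundanceTable:
    """Drop metabolites missing in strictly more than ``max_na_fraction`` of samples."""
    frac = at.abundances.isna().mean(axis=1)
    keep = frac <= max_na_fraction
    n_removed = int((~keep).sum())
    logger.info("filter_missing: removed %d of %d metabolites", n_removed, len(keep))
    if not keep.any():
        raise ValueError("all metabolites removed by the missingness filter")
    kept = keep[keep].index
    return AbundanceTable(
        abundances=at.abundances.loc[kept],
        groups=dict(at.groups),
        assays=None if at.assays is None else at.assays.reindex(kept),
        assay_lod=dict(at.assay_lod),
        metabolite_lod=None if at.metabolite_lod is None else at.metabolite_lod.reindex(kept).dropna(),
        cell_type=at.cell_type,
    )


def impute_half_lod(at: AbundanceTable) -> AbundanceTable:
    """Replace every missing value with LOD/2 of its metabolite's assay."""
    filled = at.abundances.copy()
    for met in filled.index[filled.isna().any(axis=1)]:
        lod = at.lod_for(met)
        if lod is None:
            raise ImputationError(f"metabolite {met!r} has missing values but no LOD")
        filled.loc[met] = filled.loc[met].fillna(lod / 2.0)
    return AbundanceTable(
        abundances=filled,
        groups=dict(at.groups),
        assays=at.assays,
        assay_lod=dict(at.assay_lod),
        metabolite_lod=at.metabolite_lod,
        cell_type=at.cell_type,
    )


def differential_abundance(
    at: AbundanceTable, alpha: float = 0.05, equal_var: bool = True
) -> MetaboliteStatTable:
    """Two-sided t-test per metabolite on log2 abundances between the two groups.

    Pooled-variance (Student's) by default; set ``equal_var=False`` for Welch.
    Zero-variance metabolites get p = 1.
    """
    if at.abundances.isna().any().any():
        raise ValueError("table still has missing values; run impute_half_lod first")
    by_group: dict[str, list[str]] = {}
    for s in at.samples:
        by_group.setdefault(at.groups[s], []).append(s)
    if len(by_group) != 2:
        raise ValueError(f"expected exactly 2 groups, found {sorted(by_group)}")
    (ga, sa), (gb, sb) = sorted(by_group.items())
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError("both groups need >= 2 samples")
    logged = np.log2(at.abundances)
    a = logged[sa].values
    b = logged[sb].values
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    zero_var = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    if zero_var.any():
        logger.warning("%d metabolites with zero variance in both groups: p set to 1", zero_var.sum())
    t = np.where(zero_var, 0.0, t)
    p = np.where(zero_var | ~np.isfinite(p), 1.0, p)
    table = pd.DataFrame(
        {
            "mean_log2_a": a.mean(axis=1),
            "mean_log2_b": b.mean(axis=1),
            "t": t,
            "pvalue": p,
            "significant": p < alpha,
        },
        index=logged.index,
    )
    return MetaboliteStatTable(table=table, alpha=alpha, group_a=ga, group_b=gb)


def load_abundance_table(
    abundance_path, sample_sheet_path, assay_path=None, lod_path=None, metabolite_lod_path=None
) -> AbundanceTable:
    """Load the TSV dialect: abundances (metabolite x sample, empty cell = NA),
    sample sheet (sample_id, group[, cell_type]), metabolite metadata
    (metabolite_id, assay), assay LODs (assay, lod), optional per-metabolite
    LODs (metabolite_id, lod)."""
    ab = pd.read_csv(abundance_path, sep="\t", index_col=0)
    sheet = pd.read_csv(sample_sheet_path, sep="\t")
    groups = dict(zip(sheet["sample_id"], sheet["group"]))
    cell_type = str(sheet["cell_type"].iloc[0]) if "cell_type" in sheet.columns else ""
    assays = None
    if assay_path is not None:
        meta = pd.read_csv(assay_path, sep="\t")
        assays = pd.Series(meta["assay"].values, index=meta["metabolite_id"].values)
    assay_lod: dict[str, float] = {}
    if lod_path is not None:
        lods = pd.read_csv(lod_path, sep="\t")
        assay_lod = dict(zip(lods["assay"], lods["lod"].astype(float)))
    met_lod = None
    if metabolite_lod_path is not None:
        ml = pd.read_csv(metabolite_lod_path, sep="\t")
        met_lod = pd.Series(ml["lod"].astype(float).values, index=ml["metabolite_id"].values)
    return AbundanceTable(
        abundances=ab, groups=groups, assays=assays, assay_lod=assay_lod,
        metabolite_lod=met_lod, cell_type=cell_type,
    )
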