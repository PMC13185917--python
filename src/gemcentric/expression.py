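"""RNA-seq count handling: filtering, geTMM normalization, gene categories.

geTMM is gene-length-corrected TMM: raw counts are first divided by gene
length in kilobases (reads per kilobase, RPK), then trimmed-mean-of-M-values
(TMM) scale factors are computed on the RPK matrix and the columns are scaled
to per-million units.  The TMM factor computation follows the canonical
recipe: per-gene log-ratios (M) and average log-intensities (A) against a
reference sample, double trimming (30% on M, 5% on A, rank-based), and a
precision-weighted mean of the surviving M values; the reference sample is
the one whose upper-quartile/library-size ratio is closest to the mean of
those ratios.  Factors are normalized to geometric mean 1.

Per-sample gene categories (low / moderate / high) are derived from quartile
thresholds of the per-gene mean normalized expression of a cell type: a gene
is *low* in a sample when its normalized value falls strictly below the first
quartile of the mean vector, *high* when strictly above the third quartile.
These categories drive the iMAT reaction-state assignment downstream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "NormalizedMatrix",
    "GeneCategoryTable",
    "GeneStatTable",
    "EmptyResultError",
    "DegenerateSampleError",
    "InsufficientReplicationError",
    "filter_low_expression",
    "getmm_normalize",
    "tmm_norm_factors",
    "quartile_thresholds",
    "categorize_genes",
    "simple_de_test",
    "load_gene_pvalues",
    "load_counts",
]

LOW, MODERATE, HIGH = "low", "moderate", "high"


class EmptyResultError(ValueError):
    """A filtering step removed everything."""


class DegenerateSampleError(ValueError):
    """A sample has no usable signal (e.g. all-zero counts)."""


class InsufficientReplicationError(ValueError):
    """A group has too few samples for the requested test."""


@dataclass
class CountMatrix:
    """Raw counts, genes x samples, with group labels per sample."""

    counts: pd.DataFrame  # genes x samples, nonnegative integers
    groups: dict[str, str]
    cell_type: str = ""
    gene_lengths: pd.Series | None = None  # kilobases, indexed by gene

    def __post_init__(self):
        if self.counts.shape[1] < 2:
            raise ValueError("a CountMatrix needs at least 2 samples")
        if (self.counts.values < 0).any():
            raise ValueError("counts must be nonnegative")
        missing = [s for s in self.counts.columns if s not in self.groups]
        if missing:
            raise ValueError(f"samples without group label: {missing}")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def group_samples(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for s in self.samples:
            out.setdefault(self.groups[s], []).append(s)
        return out


@dataclass
class NormalizedMatrix:
    values: pd.DataFrame  # genes x samples, geTMM units
    scale_factors: pd.Series  # per sample, geometric mean 1
    groups: dict[str, str] = field(default_factory=dict)
    cell_type: str = ""

    def __post_init__(self):
        if (self.scale_factors <= 0).any():
            raise ValueError("scale factors must be positive")


@dataclass
class GeneCategoryTable:
    categories: pd.DataFrame  # genes x samples, entries in {low, moderate, high}
    q1: float
    q3: float

    def __post_init__(self):
        if self.q1 > self.q3:
            raise ValueError("q1 > q3")

    def sample_categories(self, sample: str) -> dict[str, str]:
        return self.categories[sample].to_dict()


@dataclass
class GeneStatTable:
    pvalues: pd.Series  # indexed by gene, two-sided p in [0,1]
    direction: pd.Series | None = None  # optional sign of the effect

    def __post_init__(self):
        if self.pvalues.index.has_duplicates:
            raise ValueError("duplicate gene ids in p-value table")
        p = self.pvalues.values.astype(float)
        if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
            raise ValueError("p-values must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Filtering and normalization
# ---------------------------------------------------------------------------

def filter_low_expression(
    cm: CountMatrix, cpm_cutoff: float = 0.1, min_fraction: float = 0.5
) -> CountMatrix:
    """Drop genes with CPM below ``cpm_cutoff`` in >= ``min_fraction`` of samples."""
    if cpm_cutoff <= 0 or min_fraction <= 0:
        raise ValueError("cutoffs must be positive")
    lib = cm.counts.sum(axis=0)
    if (lib == 0).any():
        raise DegenerateSampleError("sample(s) with all-zero counts")
    cpm = cm.counts.div(lib, axis=1) * 1e6
    low_frac = (cpm < cpm_cutoff).mean(axis=1)
    keep = low_frac < min_fraction
    n_removed = int((~keep).sum())
    logger.info("filter_low_expression: removed %d of %d genes", n_removed, len(keep))
    if not keep.any():
        raise EmptyResultError("all genes removed by the CPM filter")
    return CountMatrix(
        counts=cm.counts.loc[keep],
        groups=dict(cm.groups),
        cell_type=cm.cell_type,
        gene_lengths=None if cm.gene_lengths is None else cm.gene_lengths.loc[keep[keep].index],
    )


def _tmm_pair_factor(
    obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
    logratio_trim: float, sum_trim: float,
) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        p_obs = obs / n_obs
        p_ref = ref / n_ref
        log_r = np.log2(p_obs / p_ref)
        abs_e = 0.5 * np.log2(p_obs * p_ref)
        # binomial asymptotic variance of M on the proportion scale; the
        # proportion form keeps the factors invariant to global column scaling
        v = (1.0 - p_obs) / p_obs + (1.0 - p_ref) / p_ref
    keep = np.isfinite(log_r) & np.isfinite(abs_e) & (abs_e > -1e10)
    log_r, abs_e, v = log_r[keep], abs_e[keep], v[keep]
    if log_r.size == 0 or np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_l = np.floor(n * logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * sum_trim) + 1
    hi_s = n + 1 - lo_s
    rank_r = stats.rankdata(log_r)
    rank_e = stats.rankdata(abs_e)
    sel = (rank_r >= lo_l) & (rank_r <= hi_l) & (rank_e >= lo_s) & (rank_e <= hi_s)
    if not sel.any():
        return 1.0
    w = 1.0 / v[sel]
    f = 2.0 ** (np.sum(w * log_r[sel]) / np.sum(w))
    return float(f) if np.isfinite(f) else 1.0


def tmm_norm_factors(
    mat: pd.DataFrame, logratio_trim: float = 0.30, sum_trim: float = 0.05
) -> pd.Series:
    """TMM scale factors for a (genes x samples) nonnegative matrix.

    Returns per-sample factors with geometric mean 1; the effective library
    size of sample *s* is ``colsum(s) * factor(s)``.
    """
    x = mat.values.astype(float)
    lib = x.sum(axis=0)
    if (lib == 0).any():
        raise DegenerateSampleError("sample(s) with all-zero values")
    q75 = np.array([np.quantile(x[:, j], 0.75) for j in range(x.shape[1])]) / lib
    ref_j = int(np.argmin(np.abs(q75 - q75.mean())))
    factors = np.array(
        [
            _tmm_pair_factor(x[:, j], x[:, ref_j], lib[j], lib[ref_j], logratio_trim, sum_trim)
            for j in range(x.shape[1])
        ]
    )
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=mat.columns, name="tmm_factor")


def getmm_normalize(cm: CountMatrix) -> NormalizedMatrix:
    """geTMM: RPK (counts per kilobase), TMM factors on RPK, scaled per million."""
    if cm.gene_lengths is None:
        warnings.warn(
            "gene lengths absent; using 1 kb for all genes (plain TMM)", UserWarning
        )
        lengths = pd.Series(1.0, index=cm.counts.index)
    else:
        lengths = cm.gene_lengths.reindex(cm.counts.index)
        if lengths.isna().any() or (lengths <= 0).any():
            raise ValueError("gene lengths must be positive and cover every gene")
    rpk = cm.counts.div(lengths, axis=0).astype(float)
    lib = rpk.sum(axis=0)
    if (lib == 0).any():
        raise DegenerateSampleError("sample(s) with all-zero counts")
    factors = tmm_norm_factors(rpk)
    eff_lib = lib * factors
    values = rpk.div(eff_lib, axis=1) * 1e6
    return NormalizedMatrix(
        values=values, scale_factors=factors, groups=dict(cm.groups), cell_type=cm.cell_type
    )


# ---------------------------------------------------------------------------
# Quartile thresholds and gene categories
# ---------------------------------------------------------------------------

def quartile_thresholds(nm: NormalizedMatrix) -> tuple[float, float]:
    """Q1/Q3 (linear interpolation) of the per-gene mean normalized expression."""
    if nm.values.shape[0] < 4:
        raise ValueError("need at least 4 genes for quartile thresholds")
    means = nm.values.mean(axis=1).values
    q1, q3 = np.percentile(means, [25, 75])
    return float(q1), float(q3)


def categorize_genes(nm: NormalizedMatrix, q1: float, q3: float) -> GeneCategoryTable:
    """Per-sample categories: strictly below q1 -> low, strictly above q3 -> high."""
    if q1 > q3:
        raise ValueError("q1 > q3")
    vals = nm.values
    cats = pd.DataFrame(MODERATE, index=vals.index, columns=vals.columns, dtype=object)
    cats = cats.mask(vals < q1, LOW).mask(vals > q3, HIGH)
    return GeneCategoryTable(categories=cats, q1=q1, q3=q3)


# ---------------------------------------------------------------------------
# Differential expression (built-in stand-in; real runs may plug in p-values)
# ---------------------------------------------------------------------------

def simple_de_test(cm: CountMatrix) -> GeneStatTable:
    """Per-gene two-sided Welch t-test on log2(geTMM + 1) between the two groups.

    A lightweight built-in for synthetic runs; externally computed per-gene
    p-values (e.g. from a negative-binomial GLM) can be supplied instead via
    :func:`load_gene_pvalues`.
    """
    by_group = cm.group_samples()
    if len(by_group) != 2:
        raise ValueError(f"expected exactly 2 groups, found {sorted(by_group)}")
    (ga, sa), (gb, sb) = sorted(by_group.items())
    if len(sa) < 2 or len(sb) < 2:
        raise InsufficientReplicationError(
            f"groups must have >=2 samples (got {len(sa)} vs {len(sb)})"
        )
    nm = getmm_normalize(cm)
    logged = np.log2(nm.values + 1.0)
    a = logged[sa].values
    b = logged[sb].values
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    zero_var = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    p = np.where(zero_var | ~np.isfinite(p), 1.0, p)
    direction = np.sign(b.mean(axis=1) - a.mean(axis=1))
    return GeneStatTable(
        pvalues=pd.Series(p, index=logged.index, name="pvalue"),
        direction=pd.Series(direction, index=logged.index, name="direction"),
    )


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

def load_gene_pvalues(path) -> GeneStatTable:
    """Load a two-column TSV (gene_id, pvalue) of externally computed p-values."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "pvalue"}
    if not required.issubset(df.columns):
        raise ValueError(f"p-value table needs columns {sorted(required)}")
    if df["gene_id"].duplicated().any():
        raise ValueError("duplicate gene ids in p-value table")
    return GeneStatTable(pvalues=pd.Series(df["pvalue"].values, index=df["gene_id"].values))


def load_counts(counts_path, sample_sheet_path, gene_lengths_path=None) -> CountMatrix:
    """Load counts TSV (genes x samples) plus a sample sheet (sample_id, group[, cell_type])."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    sheet = pd.read_csv(sample_sheet_path, sep="\t")
    groups = dict(zip(sheet["sample_id"], sheet["group"]))
    cell_type = str(sheet["cell_type"].iloc[0]) if "cell_type" in sheet.columns else ""
    lengths = None
    if gene_lengths_path is not None:
        gl = pd.read_csv(gene_lengths_path, sep="\t")
        lengths = pd.Series(gl["length_kb"].values, index=gl["gene_id"].values)
    return CountMatrix(
        counts=counts.round().astype(int), groups=groups, cell_type=cell_type, gene_lengths=lengths
    )
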