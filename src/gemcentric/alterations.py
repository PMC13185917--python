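"""Altered-reaction calling between two genotype groups.

For small cohorts (three replicates per genotype) a reaction is called
altered when its per-group active-sample counts match an explicit pattern
list; the default 3-vs-3 rule set is {(3,0), (3,1), (2,0)} and their group
swaps — fully discordant, all-of-one-group vs exactly-one-of-the-other, and
two-of-one-group vs none-of-the-other.  For larger cohorts a per-reaction
two-sided Fisher's exact test on the 2x2 (active/inactive x group) table is
used instead, at nominal alpha.

Two validation procedures quantify how surprising the observed altered count
is: an exact permutation test over all relabelings of the samples into groups
of the original sizes, and a Monte-Carlo null that redraws each reaction's
activities i.i.d. Bernoulli at its observed across-sample frequency (this
null preserves per-reaction activity frequency but not inter-reaction
correlation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .imat import ActivityMatrix

__all__ = [
    "AlterationRuleSet",
    "AlteredReactionSet",
    "ValidationReport",
    "default_3v3_rules",
    "call_altered_pattern",
    "call_altered_fisher",
    "permutation_validate",
    "montecarlo_validate",
]

EXACT_ENUMERATION_MAX_SAMPLES = 14


@dataclass(frozen=True)
class AlterationRuleSet:
    """Allowed (countA, countB) active-count patterns for group sizes (nA, nB)."""

    n_a: int
    n_b: int
    patterns: frozenset[tuple[int, int]]

    def __post_init__(self):
        for a, b in self.patterns:
            if not (0 <= a <= self.n_a and 0 <= b <= self.n_b):
                raise ValueError(f"pattern {(a, b)} outside [0,{self.n_a}]x[0,{self.n_b}]")
        if self.n_a == self.n_b:
            swapped = {(b, a) for a, b in self.patterns}
            if swapped != set(self.patterns):
                raise ValueError("rule set must be symmetric under group swap")


def default_3v3_rules() -> AlterationRuleSet:
    """The 3-vs-3 rule set: the 3-0, 3-1 and 2-0 cases, both orientations.

    Stated on active counts: fully discordant (3,0)/(0,3); all of one group
    active with exactly one active in the other (3,1)/(1,3); two of one group
    active with none in the other (2,0)/(0,2).
    """
    return AlterationRuleSet(
        n_a=3,
        n_b=3,
        patterns=frozenset({(3, 0), (0, 3), (3, 1), (1, 3), (2, 0), (0, 2)}),
    )


@dataclass
class AlteredReactionSet:
    """Altered reactions with their per-group active counts and direction."""

    table: pd.DataFrame  # index reaction_id; columns count_a, count_b, direction[, pvalue]
    group_a: str
    group_b: str

    @property
    def reaction_ids(self) -> list[str]:
        return list(self.table.index)

    def __len__(self):
        return len(self.table)


@dataclass
class ValidationReport:
    observed: int
    pvalue: float
    null_counts: np.ndarray
    method: str
    n_draws: int | None = None
    seed: int | None = None
    notes: str = ""


def _group_columns(am: ActivityMatrix, groups: dict[str, str]) -> tuple[str, list[str], str, list[str]]:
    labels = sorted({groups[s] for s in am.samples})
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 groups, found {labels}")
    ga, gb = labels
    sa = [s for s in am.samples if groups[s] == ga]
    sb = [s for s in am.samples if groups[s] == gb]
    return ga, sa, gb, sb


def _pattern_counts(data: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray):
    return data[:, idx_a].sum(axis=1), data[:, idx_b].sum(axis=1)


def call_altered_pattern(
    am: ActivityMatrix, groups: dict[str, str], rules: AlterationRuleSet | None = None
) -> AlteredReactionSet:
    """Call altered reactions by active-count pattern matching."""
    if rules is None:
        rules = default_3v3_rules()
    ga, sa, gb, sb = _group_columns(am, groups)
    if len(sa) != rules.n_a or len(sb) != rules.n_b:
        raise ValueError(
            f"group sizes ({len(sa)}, {len(sb)}) do not match rule set "
            f"({rules.n_a}, {rules.n_b})"
        )
    data = am.data.values
    cols = list(am.data.columns)
    idx_a = np.array([cols.index(s) for s in sa])
    idx_b = np.array([cols.index(s) for s in sb])
    ca, cb = _pattern_counts(data, idx_a, idx_b)
    rows = []
    for rid, a, b in zip(am.reactions, ca, cb):
        if (int(a), int(b)) in rules.patterns:
            direction = ga if a > b else gb
            rows.append((rid, int(a), int(b), direction))
    table = pd.DataFrame(
        rows, columns=["reaction_id", "count_a", "count_b", "direction"]
    ).set_index("reaction_id")
    return AlteredReactionSet(table=table, group_a=ga, group_b=gb)


def call_altered_fisher(
    am: ActivityMatrix, groups: dict[str, str], alpha: float = 0.05
) -> AlteredReactionSet:
    """Call altered reactions by two-sided Fisher's exact test at nominal alpha.

    Constant reactions (active or inactive in every sample) get p = 1.
    """
    ga, sa, gb, sb = _group_columns(am, groups)
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError("both groups need >= 2 samples for the Fisher test")
    data = am.data
    rows = []
    for rid in am.reactions:
        a_act = int(data.loc[rid, sa].sum())
        b_act = int(data.loc[rid, sb].sum())
        tbl = [[a_act, len(sa) - a_act], [b_act, len(sb) - b_act]]
        if (a_act + b_act == 0) or (a_act + b_act == len(sa) + len(sb)):
            p = 1.0
        else:
            _, p = stats.fisher_exact(tbl, alternative="two-sided")
        direction = ga if a_act / len(sa) > b_act / len(sb) else gb
        rows.append((rid, a_act, b_act, direction, float(p)))
    full = pd.DataFrame(
        rows, columns=["reaction_id", "count_a", "count_b", "direction", "pvalue"]
    ).set_index("reaction_id")
    return AlteredReactionSet(table=full[full["pvalue"] < alpha], group_a=ga, group_b=gb)


def _altered_count(data: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray, patterns) -> int:
    ca, cb = _pattern_counts(data, idx_a, idx_b)
    return int(sum((int(a), int(b)) in patterns for a, b in zip(ca, cb)))


def permutation_validate(
    am: ActivityMatrix, groups: dict[str, str], rules: AlterationRuleSet | None = None
) -> ValidationReport:
    """Exact permutation test of the altered-reaction count.

    Enumerates all C(nA+nB, nA) relabelings of the samples into groups of the
    original sizes (identity included); p is the fraction of relabelings with
    an altered count >= the observed one.
    """
    if rules is None:
        rules = default_3v3_rules()
    _, sa, _, sb = _group_columns(am, groups)
    n = len(sa) + len(sb)
    if n > EXACT_ENUMERATION_MAX_SAMPLES:
        raise ValueError(
            f"{n} samples exceed the exact-enumeration bound "
            f"({EXACT_ENUMERATION_MAX_SAMPLES}); use montecarlo_validate"
        )
    data = am.data.values
    cols = list(am.data.columns)
    all_idx = np.arange(n)
    idx_a0 = np.array([cols.index(s) for s in sa])
    idx_b0 = np.array([cols.index(s) for s in sb])
    observed = _altered_count(data, idx_a0, idx_b0, rules.patterns)
    null_counts = []
    for combo in combinations(range(n), len(sa)):
        ia = np.array(combo)
        ib = np.setdiff1d(all_idx, ia)
        null_counts.append(_altered_count(data, ia, ib, rules.patterns))
    null_counts = np.array(null_counts)
    p = float(np.mean(null_counts >= observed))
    return ValidationReport(
        observed=observed, pvalue=p, null_counts=null_counts, method="exact_permutation"
    )


def montecarlo_validate(
    am: ActivityMatrix,
    groups: dict[str, str],
    rules: AlterationRuleSet | None = None,
    n_draws: int = 10000,
    seed: int = 0,
) -> ValidationReport:
    """Monte-Carlo null: per-reaction i.i.d. Bernoulli at the observed frequency.

    p = (1 + #draws with count >= observed) / (1 + n_draws).  The null keeps
    each reaction's marginal activity frequency but breaks inter-reaction
    correlation (noted in the report).
    """
    if rules is None:
        rules = default_3v3_rules()
    if n_draws < 100:
        raise ValueError("n_draws must be >= 100")
    _, sa, _, sb = _group_columns(am, groups)
    data = am.data.values
    cols = list(am.data.columns)
    idx_a = np.array([cols.index(s) for s in sa])
    idx_b = np.array([cols.index(s) for s in sb])
    observed = _altered_count(data, idx_a, idx_b, rules.patterns)
    theta = data.mean(axis=1)
    rng = np.random.default_rng(seed)
    n = data.shape[1]
    null_counts = np.empty(n_draws, dtype=int)
    ia = np.arange(len(sa))
    ib = np.arange(len(sa), n)
    for d in range(n_draws):
        draw = (rng.random((data.shape[0], n)) < theta[:, None]).astype(int)
        null_counts[d] = _altered_count(draw, ia, ib, rules.patterns)
    p = float((1 + np.sum(null_counts >= observed)) / (1 + n_draws))
    return ValidationReport(
        observed=observed,
        pvalue=p,
        null_counts=null_counts,
        method="monte_carlo",
        n_draws=n_draws,
        seed=seed,
        notes="null preserves per-reaction activity frequency, not inter-reaction correlation",
    )
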