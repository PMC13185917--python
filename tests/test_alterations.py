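from itertools import product

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from conftest import fisher_enumeration_p
from gemcentric.alterations import (
    AlterationRuleSet,
    call_altered_fisher,
    call_altered_pattern,
    default_3v3_rules,
    montecarlo_validate,
    permutation_validate,
)
from gemcentric.imat import ActivityMatrix

GROUPS_3V3 = {**{f"a{i}": "A" for i in range(3)}, **{f"b{i}": "B" for i in range(3)}}


def matrix_from_patterns(patterns):
    """One reaction per (countA, countB) pattern: first countA / countB samples active."""
    rows = {}
    for idx, (a, b) in enumerate(patterns):
        rows[f"rxn_{idx}_{a}{b}"] = [1] * a + [0] * (3 - a) + [1] * b + [0] * (3 - b)
    return ActivityMatrix(
        data=pd.DataFrame.from_dict(rows, orient="index", columns=list(GROUPS_3V3))
    )


class TestPatternRules:
    def test_default_rule_set_contents(self):
        assert default_3v3_rules().patterns == {(3, 0), (0, 3), (3, 1), (1, 3), (2, 0), (0, 2)}

    def test_full_truth_table(self):
        """Every (countA, countB) in [0,3]^2 is called altered iff it is one of
        the 3-0 / 3-1 / 2-0 cases (either orientation)."""
        all_patterns = list(product(range(4), range(4)))
        am = matrix_from_patterns(all_patterns)
        altered = call_altered_pattern(am, GROUPS_3V3)
        expected = {
            f"rxn_{i}_{a}{b}"
            for i, (a, b) in enumerate(all_patterns)
            if (a, b) in default_3v3_rules().patterns
        }
        assert set(altered.reaction_ids) == expected

    def test_direction_and_swap_symmetry(self):
        am = matrix_from_patterns([(3, 0), (0, 3), (1, 3)])
        altered = call_altered_pattern(am, GROUPS_3V3)
        assert altered.table["direction"].tolist() == ["A", "B", "B"]
        swapped = {s: ("B" if g == "A" else "A") for s, g in GROUPS_3V3.items()}
        altered_sw = call_altered_pattern(am, swapped)
        assert set(altered_sw.reaction_ids) == set(altered.reaction_ids)
        assert (altered_sw.table["direction"] != altered.table["direction"]).all()

    def test_group_size_mismatch_rejected(self):
        am = matrix_from_patterns([(3, 0)])
        rules = AlterationRuleSet(n_a=2, n_b=2, patterns=frozenset({(2, 0), (0, 2)}))
        with pytest.raises(ValueError, match="group sizes"):
            call_altered_pattern(am, GROUPS_3V3, rules)


class TestFisher:
    def make_am(self, a_active, b_active, n=10):
        groups = {**{f"a{i}": "A" for i in range(n)}, **{f"b{i}": "B" for i in range(n)}}
        row = [1] * a_active + [0] * (n - a_active) + [1] * b_active + [0] * (n - b_active)
        am = ActivityMatrix(data=pd.DataFrame({"rx": row}, index=list(groups)).T)
        return am, groups

    def test_fully_discordant_significant(self):
        am, groups = self.make_am(10, 0)
        altered = call_altered_fisher(am, groups)
        assert altered.reaction_ids == ["rx"]
        assert altered.table.loc["rx", "pvalue"] == pytest.approx(2 / comb(20, 10), rel=1e-9)

    def test_balanced_and_constant_not_significant(self):
        for a, b in [(5, 5), (10, 10), (0, 0)]:
            am, groups = self.make_am(a, b)
            assert len(call_altered_fisher(am, groups)) == 0

    @pytest.mark.parametrize("table", [(3, 1, 0, 3), (2, 2, 2, 2), (5, 0, 1, 4), (0, 4, 4, 0)])
    def test_matches_hypergeometric_enumeration(self, table):
        a, b, c, d = table
        from scipy.stats import fisher_exact

        _, p = fisher_exact([[a, b], [c, d]])
        assert p == pytest.approx(fisher_enumeration_p(a, b, c, d), rel=1e-9)


class TestPermutation:
    def test_enumerates_all_relabelings(self):
        am = matrix_from_patterns([(3, 0), (2, 2)])
        rep = permutation_validate(am, GROUPS_3V3)
        assert len(rep.null_counts) == comb(6, 3, exact=True) == 20

    def test_exchangeable_columns_give_p_one(self):
        data = pd.DataFrame(np.ones((5, 6), dtype=int), columns=list(GROUPS_3V3))
        rep = permutation_validate(ActivityMatrix(data=data), GROUPS_3V3)
        assert rep.observed == 0 and rep.pvalue == 1.0

    def test_planted_block_attains_the_permutation_minimum(self):
        """30 reactions at (3,0) over group-balanced noise: only the identity
        labeling and the full group swap reproduce the observed count, so the
        exact p equals 2/20 — the smallest value a swap-symmetric rule set
        admits (the full swap always mirrors the observed patterns)."""
        rows = {f"p{i}": [1, 1, 1, 0, 0, 0] for i in range(30)}
        for i in range(50):
            rows[f"on{i}"] = [1] * 6   # constant rows never match any pattern
            rows[f"off{i}"] = [0] * 6
        am = ActivityMatrix(data=pd.DataFrame.from_dict(rows, orient="index", columns=list(GROUPS_3V3)))
        rep = permutation_validate(am, GROUPS_3V3)
        assert rep.observed == 30
        assert rep.pvalue == pytest.approx(2 / 20)
        assert max(rep.null_counts) == 30

    def test_too_many_samples_directed_to_monte_carlo(self):
        groups = {**{f"a{i}": "A" for i in range(8)}, **{f"b{i}": "B" for i in range(8)}}
        am = ActivityMatrix(data=pd.DataFrame(np.ones((2, 16), dtype=int), columns=list(groups)))
        rules = AlterationRuleSet(n_a=8, n_b=8, patterns=frozenset({(8, 0), (0, 8)}))
        with pytest.raises(ValueError, match="montecarlo"):
            permutation_validate(am, groups, rules)


class TestMonteCarlo:
    def test_all_active_matrix_gives_p_one(self):
        data = pd.DataFrame(np.ones((4, 6), dtype=int), columns=list(GROUPS_3V3))
        rep = montecarlo_validate(ActivityMatrix(data=data), GROUPS_3V3, n_draws=200, seed=0)
        assert rep.observed == 0 and rep.pvalue == 1.0
        assert (rep.null_counts == 0).all()

    def test_seed_determinism(self):
        rng = np.random.default_rng(3)
        data = pd.DataFrame(rng.integers(0, 2, (20, 6)), columns=list(GROUPS_3V3))
        am = ActivityMatrix(data=data)
        r1 = montecarlo_validate(am, GROUPS_3V3, n_draws=300, seed=7)
        r2 = montecarlo_validate(am, GROUPS_3V3, n_draws=300, seed=7)
        assert r1.pvalue == r2.pvalue and (r1.null_counts == r2.null_counts).all()

    def test_planted_block_detected(self):
        """20 reactions at (3,0) over 200 group-balanced reactions: the
        frequency-preserving Bernoulli null rarely reproduces 20 coherent
        discordant patterns, so the criterion has power."""
        rows = {f"p{i}": [1, 1, 1, 0, 0, 0] for i in range(20)}
        for i in range(200):
            rows[f"n{i}"] = [1] * 6 if i % 2 else [0] * 6
        am = ActivityMatrix(data=pd.DataFrame.from_dict(rows, orient="index", columns=list(GROUPS_3V3)))
        rep = montecarlo_validate(am, GROUPS_3V3, n_draws=2000, seed=1)
        assert rep.pvalue <= 0.01
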