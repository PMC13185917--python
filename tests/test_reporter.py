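import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from gemcentric.expression import GeneStatTable
from gemcentric.model_io import MetabolicModel, Metabolite, Reaction, parse_gpr
from gemcentric.reporter import (
    BackgroundConfig,
    build_bipartite_graph,
    collapse_to_base_id,
    reporter_summary,
    score_metabolites,
)


def two_reaction_model():
    mets = [Metabolite("A[c]"), Metabolite("B[c]"), Metabolite("C[c]")]
    rxns = [
        Reaction("R1", {"A[c]": -1.0, "B[c]": 1.0}, 0, 10, parse_gpr("g1 and g2")),
        Reaction("R2", {"B[c]": -1.0, "C[c]": 1.0}, 0, 10, parse_gpr("")),
    ]
    return MetabolicModel(metabolites=mets, reactions=rxns)


def star_graph(n_genes=4):
    """Metabolite M1 adjacent to g1 only; M_all adjacent to every gene."""
    mets = [Metabolite(f"M{i}[c]") for i in range(1, 3)]
    rxns = [
        Reaction("Ra", {"M1[c]": -1.0, "M2[c]": 1.0}, 0, 10, parse_gpr("g1")),
        Reaction(
            "Rb", {"M2[c]": -1.0, "M1[c]": 1.0}, 0, 10,
            parse_gpr(" or ".join(f"g{i}" for i in range(1, n_genes + 1))),
        ),
    ]
    return MetabolicModel(metabolites=mets, reactions=rxns)


class TestGraph:
    def test_edges_follow_shared_reaction_rule(self):
        g = build_bipartite_graph(two_reaction_model())
        got = {frozenset(e) for e in g.edges()}
        assert got == {
            frozenset(e)
            for e in [("A[c]", "g1"), ("A[c]", "g2"), ("B[c]", "g1"), ("B[c]", "g2")]
        }  # R2 has no GPR: C contributes nothing
        assert "C[c]" not in g

    def test_empty_graph_rejected(self):
        mets = [Metabolite("A[c]"), Metabolite("B[c]")]
        rxns = [Reaction("R", {"A[c]": -1.0, "B[c]": 1.0}, 0, 10, parse_gpr(""))]
        with pytest.raises(ValueError, match="empty"):
            build_bipartite_graph(MetabolicModel(metabolites=mets, reactions=rxns))

    def test_exclusion_list_prunes_metabolites(self):
        g = build_bipartite_graph(two_reaction_model(), exclude_metabolites={"A[c]"})
        assert "A[c]" not in g and "B[c]" in g


class TestScoring:
    def stats(self, mapping):
        return GeneStatTable(pvalues=pd.Series(mapping))

    def test_identical_pvalues_degenerate_to_half(self):
        model = star_graph()
        g = build_bipartite_graph(model)
        with pytest.warns(UserWarning, match="degenerate background"):
            rt = score_metabolites(
                g, self.stats({f"g{i}": 0.3 for i in range(1, 5)}),
                BackgroundConfig(n_draws=200, seed=0),
            )
        assert (rt.table["p"] == 0.5).all()
        assert rt.reporters == []

    def test_single_neighbor_aggregate_is_inverse_normal(self):
        model = star_graph()
        g = build_bipartite_graph(model)
        rt = score_metabolites(
            g, self.stats({"g1": 0.001, "g2": 0.5, "g3": 0.5, "g4": 0.5}),
            BackgroundConfig(n_draws=500, seed=1),
        )
        # M1's only neighbor (via Ra and Rb) ... M1 touches g1 (Ra) and all genes (Rb)
        # single-neighbor check on a dedicated metabolite below
        assert rt.table.loc["M1[c]", "k"] == 4

    def test_z_agg_formula_and_determinism(self):
        mets = [Metabolite("M[c]"), Metabolite("N[c]")]
        rxns = [Reaction("R", {"M[c]": -1.0, "N[c]": 1.0}, 0, 10, parse_gpr("g1"))]
        model = MetabolicModel(metabolites=mets, reactions=rxns)
        g = build_bipartite_graph(model)
        stats = self.stats({"g1": 0.001, "g2": 0.5})
        cfg = BackgroundConfig(n_draws=500, seed=3)
        rt = score_metabolites(g, stats, cfg)
        assert rt.table.loc["M[c]", "z_agg"] == pytest.approx(norm.isf(0.001), abs=1e-9)
        rt2 = score_metabolites(g, stats, cfg)
        pd.testing.assert_frame_equal(rt.table, rt2.table)

    def test_aggregation_form_is_immaterial_after_correction(self):
        """Stouffer sum/sqrt(k) and plain-mean aggregation give identical
        background-corrected scores under a shared seed."""
        rng = np.random.default_rng(5)
        mets = [Metabolite(f"M{i}[c]") for i in range(6)]
        rxns = []
        genes = [f"g{i}" for i in range(12)]
        for i in range(5):
            rule = " or ".join(rng.choice(genes, size=rng.integers(1, 5), replace=False))
            rxns.append(
                Reaction(f"R{i}", {f"M{i}[c]": -1.0, f"M{i+1}[c]": 1.0}, 0, 10, parse_gpr(rule))
            )
        model = MetabolicModel(metabolites=mets, reactions=rxns)
        g = build_bipartite_graph(model)
        stats = self.stats({gene: p for gene, p in zip(genes, rng.random(12))})
        rt_s = score_metabolites(g, stats, BackgroundConfig(n_draws=400, seed=9, aggregation="stouffer"))
        rt_m = score_metabolites(g, stats, BackgroundConfig(n_draws=400, seed=9, aggregation="mean"))
        assert np.allclose(rt_s.table["z_corr"], rt_m.table["z_corr"], atol=1e-9)
        assert np.allclose(rt_s.table["p"], rt_m.table["p"], atol=1e-9)

    def test_planted_low_p_neighborhood_flagged(self):
        rng = np.random.default_rng(17)
        n_genes = 200
        genes = [f"g{i}" for i in range(n_genes)]
        mets = [Metabolite(f"M{i}[c]") for i in range(40)]
        rxns = []
        for i in range(39):
            if i == 0:
                rule = " or ".join(genes[:5])  # planted metabolite: 5 signal genes
            else:
                rule = " or ".join(rng.choice(genes[5:], size=4, replace=False))
            rxns.append(
                Reaction(f"R{i}", {mets[i].id: -1.0, mets[i + 1].id: 1.0}, 0, 10, parse_gpr(rule))
            )
        model = MetabolicModel(metabolites=mets, reactions=rxns)
        g = build_bipartite_graph(model)
        pvals = pd.Series(rng.uniform(0, 1, n_genes), index=genes)
        pvals.iloc[:5] = rng.uniform(0, 0.01, 5)
        rt = score_metabolites(g, GeneStatTable(pvalues=pvals), BackgroundConfig(n_draws=1000, seed=2))
        assert "M0[c]" in rt.reporters


class TestSummary:
    def make_rt(self):
        from gemcentric.reporter import ReporterTable

        table = pd.DataFrame(
            {
                "k": [2, 5, 5, 1],
                "z_agg": [1.0, 2.0, 2.0, 0.1],
                "z_corr": [1.0, 2.0, 2.0, 0.1],
                "p": [0.2, 0.01, 0.01, 0.2],
                "is_reporter": [False, True, True, False],
            },
            index=pd.Index(["mB", "mA", "mC", "mD"], name="metabolite_id"),
        )
        return ReporterTable(table=table, alpha=0.05)

    def test_rank_and_tie_rules(self):
        top = reporter_summary(self.make_rt(), 10)
        assert list(top.index) == ["mA", "mC", "mB", "mD"]  # p asc, k desc, id asc
        assert len(reporter_summary(self.make_rt(), 2)) == 2


def test_collapse_to_base_id_takes_min_p():
    from gemcentric.reporter import ReporterTable

    mets = [Metabolite("X[c]"), Metabolite("X[m]"), Metabolite("Y[c]")]
    rxns = [
        Reaction("R1", {"X[c]": -1.0, "X[m]": 1.0}, 0, 10, parse_gpr("g1")),
        Reaction("R2", {"X[m]": -1.0, "Y[c]": 1.0}, 0, 10, parse_gpr("g2")),
    ]
    model = MetabolicModel(metabolites=mets, reactions=rxns)
    table = pd.DataFrame(
        {"k": [1, 2, 1], "z_agg": [0.1] * 3, "z_corr": [0.1] * 3,
         "p": [0.3, 0.02, 0.5], "is_reporter": [False, True, False]},
        index=pd.Index(["X[c]", "X[m]", "Y[c]"], name="metabolite_id"),
    )
    collapsed = collapse_to_base_id(ReporterTable(table=table, alpha=0.05), model)
    assert collapsed["X"] == 0.02 and collapsed["Y"] == 0.5
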